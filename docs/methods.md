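# Methods

## The model

`haplodense` treats a phased haplotype panel as the realization of two
per-chromosome processes and fits each directly, without any population
genetic model (no coalescent, no recombination map, no pedigree):

1. **Allele-frequency law.** The observed allele-1 frequencies of a
   chromosome's markers are modelled as i.i.d. Beta(α, β). The likelihood is
   maximised over (α, β) with L-BFGS-B (lower bounds 10⁻⁶ on both shapes,
   projected-gradient tolerance 10⁻⁸, at most 500 iterations), started at
   the method-of-moments estimates with an analytic gradient
   (digamma terms). The beta family is flexible enough to capture U-shaped,
   unimodal and skewed spectra with two parameters, which is why it is the
   standard desk model for allele-frequency spectra in panmictic or
   selected populations.
2. **LD decay.** Adjacent-marker LD — defined throughout as the absolute
   Pearson correlation of two 0/1 allele columns across haplotypes — is
   regressed on inter-marker physical distance (Kb) with loess. The
   relationship between LD and distance is locally variable along a
   chromosome, which is precisely what a non-parametric local regression
   accommodates.

Both models are fitted **once, on the original panel only**, and reused for
every insertion. Refitting on a partially densified panel would compound
drift: under heavy densification the frequency distribution converges to
the fitted beta rather than the empirical spectrum, so feeding simulated
markers back into the estimates would accelerate exactly the failure mode
the evaluation module is designed to expose.

## Loess details

No installed package provides degree-2 local polynomial regression, so the
smoother is implemented directly:

* **Kernel**: tricube, w = (1 − (|Δ|/h)³)³, with h the distance to the
  k-th nearest training point, k = ⌈span · n⌉. (Some descriptions of this
  smoother say "triweight"; the classical loess weight, and the one
  implemented by the R machinery this design follows, is tricube.)
* **Degree**: 2 (local quadratic), solved by weighted least squares on a
  Vandermonde basis centred at the query point. Windows whose points
  coincide fall back to a weighted mean; the degree drops automatically
  when a window holds too few distinct abscissae.
* **Span selection**: candidate grid 0.25–1.00 in steps of 0.05; 3-fold
  cross-validation (a seeded random partition of the pairs) minimising mean
  squared prediction error; ties favour the larger, smoother span. K = 3
  keeps the cost at 48 refits per chromosome.
* **Degenerate inputs**: fewer than 3 pairs is an error; fewer than 30
  pairs skips CV with a warning and uses the largest span.
* **Prediction**: clamped to [0, 1] (the response is an absolute
  correlation); query distances outside the training range are clamped to
  the nearest training distance, since loess extrapolation is undefined and
  insertions always fall inside existing intervals.

## Inserting a marker

The insertion distance is uniform on the *open* interval between the two
flanking markers, so a new position can never collide with an existing one
(collisions at floating-point resolution are resampled). The target
correlation is imposed against the **immediate left neighbour only**, which
may itself be a previously simulated marker — this keeps the LD chain
contiguous as density grows.

The co-occurrence count uses the **realized** frequencies of both columns
(the left column's observed frequency and the temporary Bernoulli vector's
ones-count divided by N), not the sampled target x\*. Realized values make
the count target exactly attainable: the constructed vector's Pearson
correlation with its anchor is then within 0.5/(N·√(x_L(1−x_L)·x̃(1−x̃)))
of the target — the resolution of one count — whenever the target is
feasible. When the loess target exceeds what the two marginal frequencies
allow (the Fréchet bound on the correlation of two Bernoulli variables),
the count is clamped to the feasible range and the achieved correlation is
the nearest attainable value. With a U-shaped frequency spectrum this
clamping is common, because independently drawn frequencies are often
dissimilar; the calibration tests therefore measure deviation from the
feasibility-clamped target (mean ≈ 0.004 at N = 200), and the acceptance
script additionally reports the raw deviation from the unclamped loess
target (≈ 0.10 under the study conditions) so both views are visible.

Rounding of N·E is nearest-integer: the implied correlation is linear in
the co-occurrence count, so nearest-integer-then-clamp is exactly the
feasible minimiser of the correlation error (ties at half-integers broken
by the rounding rule).

Other numerical choices:

* frequencies are clamped to [1/(2N), 1 − 1/(2N)] before likelihood
  evaluation (the beta log-density diverges at the boundary; 1/(2N) is half
  the resolution of a realized frequency);
* a sampled x\* must satisfy the MAF limit both as a real number and after
  discretisation to round(N·x\*)/N, since the guarantee applies to realized
  counts; sampling is by rejection with an error if the acceptance
  probability collapses;
* monomorphic temporary vectors and realized-MAF failures are redrawn, with
  a budget of 100 attempts per insertion before a diagnostic error;
* batches are allocated across chromosomes proportionally to current marker
  counts (remainder by a seeded lottery weighted by fractional parts), so
  relative chromosome densities are preserved;
* intervals longer than `centromere_gap_kb` (default 5,000 Kb) never
  receive markers: such gaps are poorly covered centromeric regions where
  the LD curve has no training support;
* one `numpy` Generator, seeded once, is threaded through all sampling;
  chromosomes are processed in sorted-id order — runs are bit-reproducible.

## Evaluation

* **KL divergence** (original ‖ densified) of the allele-frequency and the
  adjacent-LD samples: 20 equal-width bins on [0, 1], pseudocount 0.5 per
  bin, natural log. The pseudocount keeps disjoint-support comparisons
  finite; the direction asks how surprising the densified distribution
  makes the original look.
* **Mantel test** between the H×H haplotype correlation matrices before and
  after densification: statistic r = Pearson correlation of the strict
  lower triangles; null generated by jointly permuting rows and columns of
  the second matrix; one-sided upper tail with the +1 correction, so the
  smallest attainable p is 1/(n_permutations + 1).
* **MAF tallies** at the 1% and 5% reporting thresholds.

## The synthetic generator

Test panels are generated with known laws: marker positions from a sorted
uniform draw, frequencies from a specified beta (MAF-rejected), and each
column tied to its left neighbour with target correlation
ρ(d) = floor + (ceiling − floor)·e^(−d/scale). The tie is a
**conditional-Bernoulli** construction: P(new = 1 | left) is derived from
the joint probability p₁₁ = ρ√(x_L(1−x_L)p(1−p)) + x_L·p, clamped to the
Fréchet bounds. This preserves the beta-drawn marginal exactly — a
copy-with-probability-q device would mix the left column's frequency into
the marginal and distort the spectrum — and it is deliberately a different
construction from the densifier's exact-count rearrangement, so closed-loop
tests (fit the models on generator output, check the recovered parameters)
are not self-confirming.

What the generator does *not* emulate: long-range LD beyond the adjacent
chain (real LD blocks correlate markers many steps apart), population
structure, recombination hot spots, and genotyping error. Passing tests
therefore demonstrate that the method recovers and reproduces the features
it models — marginal frequency spectrum and adjacent-pair LD decay — not
that densified panels are indistinguishable from real dense genotyping.

Default study conditions (chosen once): 200 haplotypes, two chromosomes of
500 markers on 25,000 Kb (≈ 50 Kb mean spacing, a scaled-down version of a
typical breeding-panel geometry of several hundred SNP per chromosome);
frequency shapes (0.8, 0.8), a mildly U-shaped spectrum consistent with
panels carrying many low-MAF variants; LD decaying from 0.90 to a floor of
0.05 with a 200 Kb scale; MAF floor 0.01. The acceptance script densifies
this fixture to +25%, +200% and +300%.

## Known limitations

* Correlation is imposed on the left flank only; the right-flank LD of an
  inserted marker is whatever the chain implies, so local LD structure is
  asymmetric around simulated markers.
* Heavy densification from few markers degrades structure by design — the
  Mantel r of the haplotype correlation matrices declines as the simulated
  fraction grows (≈ 0.93 at +25% vs ≈ 0.69 at +200% under the study
  conditions). The method is data-dependent: it cannot add information, only
  markers consistent with what was learned.
* Feasibility clamping attenuates high LD targets between markers of
  dissimilar frequency; the achieved LD distribution is correspondingly
  lighter-tailed than the loess curve alone would suggest.
* No missing data, no multi-allelic sites, no phasing: inputs must be
  complete phased biallelic haplotypes (phase with external tools first).
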