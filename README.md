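# haplodense

Marker densification for phased SNP haplotype panels.

Simulation studies in quantitative genetics and breeding (genomic selection,
QTL mapping, gene dropping) often need far more markers than a real panel
provides, yet coalescent or forward-time simulators require population
assumptions that breeding populations — shaped by long selection and
non-random mating — rarely satisfy, and imputation needs a representative
reference panel that may not exist. `haplodense` takes a third route: it
**learns the realized statistical features of the panel itself** and
simulates new marker columns that match them, with no population model.

## Method

The input is a phased panel of *N* haplotypes over *L* chromosomes, each
marker a 0/1 column with a physical position in kilobases. Per chromosome:

**Learning**

1. Observed allele frequencies *x₁, …, x_P* are modelled as draws from
   Beta(α, β); (α̂, β̂) minimise the negative log-likelihood via
   bound-constrained L-BFGS started at the method-of-moments point.
2. The LD of every consecutive marker pair — the absolute Pearson
   correlation |ρ(Z_k, Z_{k+1})| of the two allele columns — is regressed on
   the inter-marker distance *d* with loess (local quadratic, tricube
   weights); the span λ is chosen by 3-fold cross-validated MSE.

**Simulation** (repeated until the target marker count is reached)

1. Draw a target frequency *x\** from Beta(α̂, β̂), rejecting draws below the
   MAF limit.
2. Pick a random adjacent interval (intervals longer than the centromere-gap
   parameter are excluded), draw the insertion distance *d* uniformly inside
   it, and predict the target correlation ρ̂ = f̂(d)_λ from the loess curve.
3. Draw a temporary vector of independent Bernoulli(*x\**) alleles, then
   rearrange its ones — keeping their count, i.e. the realized frequency —
   so that the number of 1/1 co-occurrences with the left neighbour equals

   round(N · [√(x_k(1−x_k)) · √(x\*(1−x\*)) · ρ̂ + x_k·x\*]),

   clamped to the feasible (Fréchet) range. The rearranged vector becomes
   the new marker column.

Every output marker is guaranteed a MAF at or above the limit; original
columns are never touched; runs are fully deterministic given a seed.
Agreement between original and densified panels is quantified per chromosome
by KL divergence of the allele-frequency and adjacent-LD distributions and
by a Mantel permutation test between the haplotype×haplotype correlation
matrices computed before and after densification.

## Worked example

```python
from haplodense import (HaplotypeDensifier, SyntheticSpec, evaluate,
                        simulate_panel)

panel = simulate_panel(SyntheticSpec(
    n_haplotypes=200, chromosomes=(("1", 25_000.0, 500),), seed=42))

dens = HaplotypeDensifier(maf_limit=0.01, target_min_markers=650,
                          batch_size=50, random_state=7)
dense = dens.fit_transform(panel)
report = evaluate(panel, dense, n_permutations=999, seed=1)

bm, lc = dens.beta_models_["1"], dens.ld_curves_["1"]
print(f"original markers : {panel.n_markers}")
print(f"densified markers: {dense.n_markers} ({len(dens.simulated_markers_)} simulated)")
print(f"beta fit         : alpha={bm.alpha_:.3f}, beta={bm.beta_:.3f}")
print(f"loess span       : {lc.span_:.2f} (CV MSE {lc.cv_error_:.4f})")
print(report.table.to_string(index=False))
```

Output:

```
original markers : 500
densified markers: 650 (150 simulated)
beta fit         : alpha=1.067, beta=0.971
loess span       : 1.00 (CV MSE 0.0505)
chromosome  kl_freq    kl_ld  mantel_r  mantel_p  maf_lt_1pct  maf_lt_5pct
         1 0.009531 0.087926   0.92143     0.001            1           67
```

The fitted beta shapes recover the generator's mildly U-shaped spectrum from
realized frequencies; the small KL divergences say the densified panel's
frequency and LD distributions stay close to the original's; Mantel r = 0.92
with the smallest attainable p (0.001 at 999 permutations) says the
haplotype-similarity structure persisted through +30% densification.

## Command line

```bash
haplodense simulate --out-dir sim --seed 5
haplodense densify  --alleles sim/alleles.txt --map sim/map.txt \
    --target-min-markers 1250 --maf-limit 0.01 --seed 5 --out-dir dense
haplodense evaluate --original-alleles sim/alleles.txt --original-map sim/map.txt \
    --densified-alleles dense/alleles.txt --densified-map dense/map.txt \
    --out-dir eval
haplodense thin     --alleles dense/alleles.txt --map dense/map.txt \
    --target-max-markers 800 --out-dir thin
```

Every run writes a `manifest.json` (all parameters, seed, version,
per-chromosome α̂, β̂ and λ) from which it can be reproduced exactly.

### File formats

* allele file — whitespace-delimited 0/1 matrix, one row per haplotype, no
  header;
* map file — header `marker_id chromosome position_kb`, one row per marker,
  column order matching the allele file;
* optional haplotype-id file — one id per line.

Simulated markers carry the `sim_` id prefix. A minimal phased VCF 4.2
export (`export_vcf`) is available for interoperability.

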