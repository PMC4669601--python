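"""Agreement between an original and a densified panel.

Three complementary views, each computed per chromosome:

* **KL divergence** of the allele-frequency and adjacent-LD distributions
  (original || densified), on 20 equal-width histogram bins over [0, 1] with
  a 0.5 pseudocount per bin, natural log;
* **Mantel permutation test** between the haplotype-by-haplotype Pearson
  correlation matrices computed before and after densification (one-sided,
  upper tail, +1 correction) — structure persistence;
* **MAF tallies** at the 1 % and 5 % reporting thresholds.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from scipy import stats

from .freq import allele_frequencies
from .ld import consecutive_ld
from .panel import HaplotypePanel

__all__ = [
    "kl_divergence",
    "haplotype_correlation_matrix",
    "mantel_test",
    "evaluate",
    "EvaluationReport",
]


def kl_divergence(
    sample_p,
    sample_q,
    n_bins: int = 20,
    support: tuple[float, float] = (0.0, 1.0),
    pseudocount: float = 0.5,
) -> float:
    """KL(p || q) between binned empirical distributions of two samples.

    Both samples are histogrammed into ``n_bins`` equal-width bins on
    ``support``; ``pseudocount`` is added to every bin before normalising, so
    disjoint-support samples still give a finite value. Natural log.
    """
    p = np.asarray(sample_p, dtype=float)
    q = np.asarray(sample_q, dtype=float)
    if p.size == 0 or q.size == 0:
        raise ValueError("samples must be non-empty")
    lo, hi = support
    if np.any((p < lo) | (p > hi)) or np.any((q < lo) | (q > hi)):
        raise ValueError(f"sample values outside support [{lo}, {hi}]")
    edges = np.linspace(lo, hi, n_bins + 1)
    hp = np.histogram(p, bins=edges)[0] + pseudocount
    hq = np.histogram(q, bins=edges)[0] + pseudocount
    return float(stats.entropy(hp, hq))  # normalises and uses natural log


def haplotype_correlation_matrix(
    panel: HaplotypePanel, chromosome: str
) -> np.ndarray:
    """H x H Pearson correlation between haplotype rows on one chromosome."""
    rows = panel.chromosome_alleles(chromosome).astype(float)
    sd = rows.std(axis=1)
    if np.any(sd == 0):
        i = int(np.argmax(sd == 0))
        raise ValueError(
            f"haplotype {panel.haplotype_ids[i]!r} is constant on chromosome "
            f"{chromosome!r}: correlation undefined"
        )
    m = np.corrcoef(rows)
    np.fill_diagonal(m, 1.0)
    return m


def mantel_test(
    a: np.ndarray,
    b: np.ndarray,
    n_permutations: int = 1000,
    rng: np.random.Generator | int = 0,
) -> tuple[float, float]:
    """Mantel statistic and one-sided permutation p-value.

    ``r`` is the Pearson correlation over the strictly-lower-triangle entries
    of the two symmetric matrices. The null distribution permutes the rows
    and columns of ``b`` jointly; ``p = (1 + #{r_perm >= r_obs}) /
    (n_permutations + 1)`` (upper tail).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"matrix shapes differ or not square: {a.shape} vs {b.shape}")
    h = a.shape[0]
    il = np.tril_indices(h, k=-1)
    va = a[il]
    va_c = va - va.mean()
    va_den = np.sqrt(np.sum(va_c**2))

    def corr_with(bm: np.ndarray) -> float:
        vb = bm[il]
        vb_c = vb - vb.mean()
        den = va_den * np.sqrt(np.sum(vb_c**2))
        return float(np.sum(va_c * vb_c) / den)

    r_obs = corr_with(b)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(h)
        if corr_with(b[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return r_obs, p


class EvaluationReport:
    """Per-chromosome comparison table between two panels."""

    COLUMNS = (
        "chromosome",
        "kl_freq",
        "kl_ld",
        "mantel_r",
        "mantel_p",
        "maf_lt_1pct",
        "maf_lt_5pct",
    )

    def __init__(self, table: pd.DataFrame) -> None:
        self.table = table.loc[:, list(self.COLUMNS)].reset_index(drop=True)

    def write(self, path: str | os.PathLike) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def __repr__(self) -> str:
        return f"EvaluationReport({len(self.table)} chromosomes)"


def evaluate(
    original: HaplotypePanel,
    densified: HaplotypePanel,
    n_permutations: int = 1000,
    seed: int = 0,
) -> EvaluationReport:
    """Compare a densified panel against the original it came from.

    Requires the original's marker ids to be a subset of the densified
    panel's. MAF tallies count densified-panel markers below 1 % and 5 %.
    """
    orig_ids = set(original.map.marker_ids)
    dens_ids = set(densified.map.marker_ids)
    if not orig_ids <= dens_ids:
        raise ValueError(
            "original panel's markers are not a subset of the densified panel's"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in original.chromosomes:
        f_orig = allele_frequencies(original, chrom)
        f_dens = allele_frequencies(densified, chrom)
        ld_orig = consecutive_ld(original, chrom).abs_correlations
        ld_dens = consecutive_ld(densified, chrom).abs_correlations
        a = haplotype_correlation_matrix(original, chrom)
        b = haplotype_correlation_matrix(densified, chrom)
        r, p = mantel_test(a, b, n_permutations=n_permutations, rng=rng)
        maf = np.minimum(f_dens, 1.0 - f_dens)
        rows.append(
            {
                "chromosome": chrom,
                "kl_freq": kl_divergence(f_orig, f_dens),
                "kl_ld": kl_divergence(ld_orig, ld_dens),
                "mantel_r": r,
                "mantel_p": p,
                "maf_lt_1pct": int((maf < 0.01).sum()),
                "maf_lt_5pct": int((maf < 0.05).sum()),
            }
        )
    return EvaluationReport(pd.DataFrame(rows))
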