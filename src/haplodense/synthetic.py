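"""Synthetic haplotype panels with known frequency and LD laws.

The generator produces multi-chromosome panels whose allele frequencies
follow a specified beta distribution and whose adjacent-marker |correlation|
decays exponentially with physical distance:

    rho(d) = ld_floor + (ld_ceiling - ld_floor) * exp(-d / ld_scale_kb).

Columns are built left to right with a conditional-Bernoulli device: given
the left column with realized frequency ``x_L`` and a beta-drawn target
frequency ``p`` for the new column, each haplotype's new allele is Bernoulli
with success probability ``p11 / x_L`` where the left allele is 1 and
``(p - p11) / (1 - x_L)`` where it is 0, with

    p11 = rho(d) * sqrt(x_L (1 - x_L) p (1 - p)) + x_L * p

clamped to the Frechet bounds (unreachable targets are silently clamped).
This preserves the marginal frequency ``p`` exactly and is deliberately a
different construction from the densifier's exact co-occurrence-count
rearrangement, so the generator can serve as an independent reference in
tests.

Defaults emulate, at desk scale, a breeding-population SNP panel: a few
hundred haplotypes, a few hundred markers per chromosome at ~50 Kb mean
spacing, a mildly U-shaped frequency spectrum and LD decaying over a few
hundred Kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import HaplotypePanel, MarkerMap

__all__ = ["SyntheticSpec", "simulate_panel", "toy_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic panel generator."""

    n_haplotypes: int = 200
    #: (chromosome id, length in Kb, marker count)
    chromosomes: tuple[tuple[str, float, int], ...] = (
        ("1", 25_000.0, 500),
        ("2", 25_000.0, 500),
    )
    freq_alpha: float = 0.8
    freq_beta: float = 0.8
    ld_scale_kb: float = 200.0
    ld_floor: float = 0.05
    ld_ceiling: float = 0.90
    maf_min: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.freq_alpha <= 0 or self.freq_beta <= 0:
            raise ValueError("beta shapes must be positive")
        if not 0.0 <= self.ld_floor <= self.ld_ceiling <= 1.0:
            raise ValueError("need 0 <= ld_floor <= ld_ceiling <= 1")
        if any(n < 2 for _, _, n in self.chromosomes):
            raise ValueError("every chromosome needs at least 2 markers")
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")


def _draw_target_freq(rng, alpha, beta, maf_min, max_tries=100_000) -> float:
    for _ in range(max_tries):
        p = rng.beta(alpha, beta)
        if maf_min <= min(p, 1 - p) and 0 < p < 1:
            return float(p)
    raise RuntimeError(f"cannot draw a frequency with MAF >= {maf_min}")


def _correlated_column(
    left: np.ndarray, p: float, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """New Bernoulli(p) column with target correlation ``rho`` to ``left``."""
    n = left.size
    x_l = left.mean()
    p11 = rho * np.sqrt(x_l * (1 - x_l) * p * (1 - p)) + x_l * p
    # Frechet bounds on P(left=1, new=1)
    p11 = min(max(p11, max(0.0, x_l + p - 1.0)), min(x_l, p))
    pr1 = p11 / x_l
    pr0 = (p - p11) / (1.0 - x_l)
    u = rng.random(n)
    return np.where(left == 1, u < pr1, u < pr0).astype(np.uint8)


def simulate_panel(spec: SyntheticSpec) -> HaplotypePanel:
    """Generate a panel realizing ``spec``; fully deterministic given its seed.

    Marker positions are a sorted uniform draw on (0, length). The first
    column of each chromosome is an independent Bernoulli draw at a
    beta-sampled frequency; each later column targets
    ``rho(d)`` with its left neighbour. Columns that come out monomorphic
    are redrawn (bounded retries) so the panel is fit-ready.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_haplotypes
    all_cols: list[np.ndarray] = []
    ids: list[str] = []
    chroms: list[str] = []
    positions: list[float] = []

    for chrom_id, length_kb, n_markers in spec.chromosomes:
        pos = np.sort(rng.uniform(0.0, length_kb, size=n_markers))
        # strictly increasing positions (ties have measure zero, but be safe)
        while np.any(np.diff(pos) <= 0):
            pos = np.sort(rng.uniform(0.0, length_kb, size=n_markers))
        left: np.ndarray | None = None
        for k in range(n_markers):
            p = _draw_target_freq(rng, spec.freq_alpha, spec.freq_beta, spec.maf_min)
            for _ in range(100):
                if left is None:
                    col = (rng.random(n) < p).astype(np.uint8)
                else:
                    d = pos[k] - pos[k - 1]
                    rho = spec.ld_floor + (spec.ld_ceiling - spec.ld_floor) * np.exp(
                        -d / spec.ld_scale_kb
                    )
                    col = _correlated_column(left, p, rho, rng)
                if 0 < col.sum() < n:
                    break
            else:
                raise RuntimeError(
                    f"chromosome {chrom_id}: monomorphic column at marker {k}"
                )
            all_cols.append(col)
            ids.append(f"{chrom_id}_m{k + 1}")
            chroms.append(str(chrom_id))
            positions.append(float(pos[k]))
            left = col

    table = pd.DataFrame(
        {"marker_id": ids, "chromosome": chroms, "position_kb": positions}
    )
    hap_ids = tuple(f"hap_{i + 1}" for i in range(n))
    return HaplotypePanel(np.column_stack(all_cols), hap_ids, MarkerMap(table))


#: hand-written toy panel: 6 haplotypes, 8 markers on 2 chromosomes
_TOY_ALLELES = np.array(
    [
        # chr1: m1..m4 at 10, 25, 40, 80 Kb   chr2: m1..m4 at 5, 30, 55, 90 Kb
        [0, 0, 1, 0, 1, 1, 0, 1],
        [0, 0, 0, 1, 1, 1, 1, 0],
        [1, 1, 1, 0, 0, 0, 0, 1],
        [1, 1, 0, 1, 0, 1, 1, 0],
        [0, 1, 1, 0, 1, 0, 0, 1],
        [1, 0, 0, 1, 0, 0, 1, 1],
    ],
    dtype=np.uint8,
)


def toy_fixture() -> HaplotypePanel:
    """Deterministic 6-haplotype, 8-marker, 2-chromosome documentation panel."""
    table = pd.DataFrame(
        {
            "marker_id": [f"c1_m{k}" for k in range(1, 5)]
            + [f"c2_m{k}" for k in range(1, 5)],
            "chromosome": ["1"] * 4 + ["2"] * 4,
            "position_kb": [10.0, 25.0, 40.0, 80.0, 5.0, 30.0, 55.0, 90.0],
        }
    )
    hap_ids = tuple(f"hap_{i + 1}" for i in range(6))
    return HaplotypePanel(_TOY_ALLELES.copy(), hap_ids, MarkerMap(table))
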