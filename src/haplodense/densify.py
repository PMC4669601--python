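"""Marker densification: simulate new SNP columns that match learned features.

For each chromosome the densifier first learns (1) a beta law for the
allele-frequency spectrum and (2) a loess curve of adjacent-marker |Pearson
correlation| against physical distance, both from the original panel only.
New markers are then inserted one at a time:

1. pick a random adjacent-marker interval (long "centromere gap" intervals
   are excluded);
2. draw the insertion distance uniformly on the open interval, and predict
   the target correlation ``rho_hat`` with the left neighbour from the loess
   curve at that distance;
3. draw a target frequency ``x*`` from the fitted beta (MAF-floored);
4. realize the new column: draw a temporary vector V of independent
   Bernoulli(x*) alleles, then rearrange its ones — keeping their count
   fixed — so that the number of 1/1 co-occurrences with the left column
   equals ``round(N * E[Z_left * Z_new])`` with
   ``E = sqrt(x_l (1-x_l)) * sqrt(x (1-x)) * rho_hat + x_l * x``,
   clamped to the feasible (Frechet) range.

Using the realized frequencies of both columns in the expectation makes the
co-occurrence target exactly attainable by construction. Previously inserted
markers become eligible left anchors for later insertions, keeping the LD
chain contiguous as density grows.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .freq import BetaFrequencyModel, allele_frequencies
from .ld import LoessLDCurve, consecutive_ld
from .panel import SIMULATED_PREFIX, HaplotypePanel, MarkerMap, PanelError

__all__ = [
    "DensifyConfig",
    "SimulatedMarker",
    "HaplotypeDensifier",
    "required_cooccurrences",
    "generate_marker",
    "select_interval",
    "densify",
    "thin",
    "InsertionError",
]


class InsertionError(RuntimeError):
    """Raised when a marker cannot be inserted within the retry budget."""


@dataclass(frozen=True)
class DensifyConfig:
    """Run parameters for densification or thinning.

    Exactly one of ``target_min_markers`` (densify) / ``target_max_markers``
    (thin) must be set. ``batch_size`` markers are added per run of the
    insertion loop; ``centromere_gap_kb`` is the interval length above which
    no markers are simulated (poorly covered centromeric regions).
    """

    maf_limit: float = 0.01
    batch_size: int = 100
    target_min_markers: int | None = None
    target_max_markers: int | None = None
    centromere_gap_kb: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_limit < 0.5:
            raise ValueError(f"maf_limit must be in [0, 0.5), got {self.maf_limit}")
        if (self.target_min_markers is None) == (self.target_max_markers is None):
            raise ValueError(
                "exactly one of target_min_markers / target_max_markers must be set"
            )
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.centromere_gap_kb <= 0:
            raise ValueError("centromere_gap_kb must be positive")


@dataclass(frozen=True)
class SimulatedMarker:
    """Record of one inserted marker."""

    chromosome: str
    marker_id: str
    position_kb: float
    sampled_freq: float
    predicted_rho: float
    achieved_n11: int
    allele_vector: np.ndarray = field(repr=False)


def required_cooccurrences(
    x_jk: float, x_star: float, rho_hat: float, n_haplotypes: int
) -> int:
    """Co-occurrence count of allele 1 needed to hit a target correlation.

    Returns ``round(N * E)`` with ``E = sqrt(x_jk (1-x_jk)) *
    sqrt(x* (1-x*)) * rho_hat + x_jk * x*``, clamped to the feasible range
    ``[max(0, n1k + n1* - N), min(n1k, n1*)]`` where ``n1k = round(N x_jk)``
    and ``n1* = round(N x*)``. Because the correlation implied by a
    co-occurrence count is linear in that count, rounding then clamping picks
    the feasible count whose implied correlation is closest to ``rho_hat``.
    """
    n = n_haplotypes
    e = (
        np.sqrt(x_jk * (1.0 - x_jk)) * np.sqrt(x_star * (1.0 - x_star)) * rho_hat
        + x_jk * x_star
    )
    n11 = int(round(n * e))
    n1k = int(round(n * x_jk))
    n1s = int(round(n * x_star))
    lo = max(0, n1k + n1s - n)
    hi = min(n1k, n1s)
    return min(max(n11, lo), hi)


def generate_marker(
    left_alleles: np.ndarray,
    x_star: float,
    rho_hat: float,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> tuple[np.ndarray, int, float]:
    """Realize a new allele column correlated with its left anchor.

    Draws a temporary vector of independent Bernoulli(``x_star``) alleles,
    then places its ones so that exactly ``required_cooccurrences`` of them
    fall on haplotypes carrying allele 1 at the anchor. The ones-count of the
    returned vector equals that of the temporary draw (the realized frequency
    is preserved by the rearrangement).

    Returns ``(alleles, achieved_n11, realized_freq)``.
    """
    left = np.asarray(left_alleles)
    n = left.size
    n1k = int(left.sum())
    if n1k in (0, n):
        raise ValueError("left anchor column is monomorphic")
    x_left = n1k / n

    n1s = 0
    for _ in range(max_retries):
        v = rng.random(n) < x_star
        n1s = int(v.sum())
        if 0 < n1s < n:
            break
    else:
        raise InsertionError(
            f"temporary Bernoulli vector monomorphic after {max_retries} draws "
            f"(x* = {x_star:.4g}, N = {n})"
        )

    x_tilde = n1s / n
    n11 = required_cooccurrences(x_left, x_tilde, rho_hat, n)

    out = np.zeros(n, dtype=np.uint8)
    ones_idx = np.flatnonzero(left == 1)
    zeros_idx = np.flatnonzero(left == 0)
    out[rng.choice(ones_idx, size=n11, replace=False)] = 1
    out[rng.choice(zeros_idx, size=n1s - n11, replace=False)] = 1
    return out, n11, x_tilde


def _eligible_intervals(positions: np.ndarray, centromere_gap_kb: float) -> np.ndarray:
    gaps = np.diff(positions)
    return np.flatnonzero((gaps > 0) & (gaps <= centromere_gap_kb))


def select_interval(
    map: MarkerMap,
    chromosome: str,
    centromere_gap_kb: float,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Uniformly pick an eligible adjacent interval; returns its marker ids."""
    idx = map.chromosome_index(chromosome)
    pos = map.positions_kb[idx]
    elig = _eligible_intervals(pos, centromere_gap_kb)
    if elig.size == 0:
        raise InsertionError(
            f"chromosome {chromosome!r}: no interval of length <= "
            f"{centromere_gap_kb} Kb available"
        )
    k = int(rng.choice(elig))
    ids = map.marker_ids[idx]
    return str(ids[k]), str(ids[k + 1])


class _ChromState:
    """Mutable per-chromosome working state during densification."""

    __slots__ = ("positions", "ids", "columns", "simulated")

    def __init__(self, positions, ids, columns) -> None:
        self.positions: list[float] = list(positions)
        self.ids: list[str] = list(ids)
        self.columns: list[np.ndarray] = list(columns)
        self.simulated: list[bool] = [False] * len(self.ids)

    def insert(self, k: int, position: float, marker_id: str, col: np.ndarray) -> None:
        self.positions.insert(k, position)
        self.ids.insert(k, marker_id)
        self.columns.insert(k, col)
        self.simulated.insert(k, True)


class HaplotypeDensifier(BaseEstimator, TransformerMixin):
    """Learn a panel's realized features and simulate markers matching them.

    ``fit`` estimates, per chromosome, the beta allele-frequency law and the
    loess LD-vs-distance curve from the input panel; ``transform`` inserts
    simulated markers until the panel carries at least ``target_min_markers``
    columns. Original columns are never modified. Fully deterministic given
    ``random_state``.

    Parameters mirror the method's run options: ``maf_limit`` (minimum MAF of
    every output marker), ``batch_size`` (markers added per insertion run),
    ``target_min_markers``, ``centromere_gap_kb`` (intervals longer than this
    receive no markers), ``random_state``.

    Attributes (after ``fit``): ``beta_models_`` and ``ld_curves_`` keyed by
    chromosome; after ``transform``: ``simulated_markers_``.
    """

    _MAF_RETRIES = 100

    def __init__(
        self,
        maf_limit: float = 0.01,
        batch_size: int = 100,
        target_min_markers: int | None = None,
        centromere_gap_kb: float = 5000.0,
        random_state: int = 0,
    ) -> None:
        self.maf_limit = maf_limit
        self.batch_size = batch_size
        self.target_min_markers = target_min_markers
        self.centromere_gap_kb = centromere_gap_kb
        self.random_state = random_state

    # -- learning ----------------------------------------------------------

    def fit(self, X: HaplotypePanel, y=None) -> "HaplotypeDensifier":
        panel = X
        panel.require_min_markers(2)
        n = panel.n_haplotypes
        self.beta_models_: dict[str, BetaFrequencyModel] = {}
        self.ld_curves_: dict[str, LoessLDCurve] = {}
        for chrom in panel.chromosomes:
            freqs = allele_frequencies(panel, chrom)
            model = BetaFrequencyModel(boundary_eps=1.0 / (2 * n))
            self.beta_models_[chrom] = model.fit(freqs)
            pairs = consecutive_ld(panel, chrom)
            self.ld_curves_[chrom] = LoessLDCurve(
                random_state=self.random_state
            ).fit(pairs.distances_kb, pairs.abs_correlations)
        self.n_haplotypes_ = n
        return self

    # -- simulation --------------------------------------------------------

    def _insert_one(
        self, state: _ChromState, chrom: str, rng: np.random.Generator, sim_counter: int
    ) -> SimulatedMarker:
        model = self.beta_models_[chrom]
        curve = self.ld_curves_[chrom]
        n = self.n_haplotypes_
        pos_set = set(state.positions)
        last_err = "no eligible interval"
        for _ in range(self._MAF_RETRIES):
            pos_arr = np.asarray(state.positions)
            elig = _eligible_intervals(pos_arr, self.centromere_gap_kb)
            if elig.size == 0:
                raise InsertionError(
                    f"chromosome {chrom!r}: no interval of length <= "
                    f"{self.centromere_gap_kb} Kb available"
                )
            k = int(rng.choice(elig))
            gap = state.positions[k + 1] - state.positions[k]
            # open interval ]0, gap[: resample on (measure-zero) collisions
            while True:
                d = rng.uniform(0.0, gap)
                position = state.positions[k] + d
                if 0.0 < d < gap and position not in pos_set:
                    break
            x_star = float(
                model.sample(rng, maf_limit=self.maf_limit, n_haplotypes=n)
            )
            rho_hat = curve.predict_one(d)
            col, n11, x_tilde = generate_marker(state.columns[k], x_star, rho_hat, rng)
            n1 = int(round(n * x_tilde))
            if min(n1, n - n1) / n >= self.maf_limit:
                marker_id = f"{SIMULATED_PREFIX}{chrom}_{sim_counter}"
                state.insert(k + 1, position, marker_id, col)
                return SimulatedMarker(
                    chrom, marker_id, position, x_star, rho_hat, n11, col
                )
            last_err = f"realized MAF {min(n1, n - n1) / n:.4g} < {self.maf_limit}"
        raise InsertionError(
            f"chromosome {chrom!r}: insertion failed after {self._MAF_RETRIES} "
            f"attempts ({last_err})"
        )

    def transform(self, X: HaplotypePanel) -> HaplotypePanel:
        panel = X
        if self.target_min_markers is None:
            raise ValueError("target_min_markers must be set for densification")
        rng = np.random.default_rng(self.random_state)
        chroms = panel.chromosomes
        states: dict[str, _ChromState] = {}
        for chrom in chroms:
            idx = panel.map.chromosome_index(chrom)
            states[chrom] = _ChromState(
                panel.map.positions_kb[idx],
                panel.map.marker_ids[idx],
                [panel.alleles[:, j] for j in idx],
            )

        self.simulated_markers_: list[SimulatedMarker] = []
        sim_counter = 0
        total = panel.n_markers
        while total < self.target_min_markers:
            batch = self.batch_size
            counts = np.array([len(states[c].ids) for c in chroms], dtype=float)
            quota = np.floor(batch * counts / counts.sum()).astype(int)
            short = batch - int(quota.sum())
            if short > 0:
                frac = batch * counts / counts.sum() - quota
                p = frac / frac.sum() if frac.sum() > 0 else None
                extra = rng.choice(len(chroms), size=short, replace=False, p=p)
                quota[extra] += 1
            for ci, chrom in enumerate(chroms):
                for _ in range(int(quota[ci])):
                    sim_counter += 1
                    self.simulated_markers_.append(
                        self._insert_one(states[chrom], chrom, rng, sim_counter)
                    )
            total += batch

        return _assemble(panel, chroms, states)

    def fit_transform(self, X: HaplotypePanel, y=None, **kwargs) -> HaplotypePanel:
        return self.fit(X).transform(X)


def _assemble(
    panel: HaplotypePanel, chroms: list[str], states: dict[str, _ChromState]
) -> HaplotypePanel:
    cols, ids, chrom_col, pos = [], [], [], []
    for chrom in chroms:
        st = states[chrom]
        cols.extend(st.columns)
        ids.extend(st.ids)
        chrom_col.extend([chrom] * len(st.ids))
        pos.extend(st.positions)
    alleles = np.column_stack(cols)
    table = pd.DataFrame(
        {"marker_id": ids, "chromosome": chrom_col, "position_kb": pos}
    )
    return HaplotypePanel(alleles, panel.haplotype_ids, MarkerMap(table))


def densify(
    panel: HaplotypePanel, config: DensifyConfig
) -> tuple[HaplotypePanel, list[SimulatedMarker]]:
    """Insert simulated markers until the panel has >= target_min_markers."""
    if config.target_min_markers is None:
        raise ValueError("config must set target_min_markers for densify()")
    dens = HaplotypeDensifier(
        maf_limit=config.maf_limit,
        batch_size=config.batch_size,
        target_min_markers=config.target_min_markers,
        centromere_gap_kb=config.centromere_gap_kb,
        random_state=config.seed,
    )
    out = dens.fit(panel).transform(panel)
    return out, dens.simulated_markers_


def thin(
    panel: HaplotypePanel,
    target_max_markers: int,
    rng: np.random.Generator | int = 0,
) -> HaplotypePanel:
    """Remove uniformly random markers until exactly ``target_max_markers`` remain.

    Every chromosome keeps at least 2 markers.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n_chrom = len(panel.chromosomes)
    if target_max_markers < 2 * n_chrom:
        raise PanelError(
            f"target {target_max_markers} would leave a chromosome with fewer "
            f"than 2 markers ({n_chrom} chromosomes)"
        )
    if target_max_markers > panel.n_markers:
        raise PanelError("target exceeds current marker count")
    chrom_of = panel.map.table["chromosome"].to_numpy()
    keep = np.ones(panel.n_markers, dtype=bool)
    counts = {c: int((chrom_of == c).sum()) for c in panel.chromosomes}
    n_keep = panel.n_markers
    while n_keep > target_max_markers:
        k = int(rng.integers(panel.n_markers))
        if keep[k] and counts[chrom_of[k]] > 2:
            keep[k] = False
            counts[chrom_of[k]] -= 1
            n_keep -= 1
    table = panel.map.table.loc[keep].reset_index(drop=True)
    return HaplotypePanel(
        panel.alleles[:, keep], panel.haplotype_ids, MarkerMap(table)
    )
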