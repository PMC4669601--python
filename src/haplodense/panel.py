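"""Core containers: a marker map and a phased haplotype panel.

A panel is an N x P binary matrix (N haplotypes, P biallelic SNP coded 0/1)
bound column-wise to a marker map giving, for each marker, its chromosome and
physical position in kilobases (Kb). All downstream modelling (allele-frequency
beta fits, LD-vs-distance loess curves, marker insertion) operates per
chromosome on this pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["MarkerMap", "HaplotypePanel", "PanelError", "SIMULATED_PREFIX"]

#: marker ids created by the densifier carry this prefix in written maps
SIMULATED_PREFIX = "sim_"


class PanelError(ValueError):
    """Raised when a panel or map violates its structural invariants."""


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker metadata: id, chromosome and position (Kb) per marker.

    Invariants enforced at construction:

    * marker ids are globally unique;
    * within each chromosome positions are strictly increasing;
    * rows are sorted by (chromosome, position).
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED_COLUMNS = ("marker_id", "chromosome", "position_kb")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise PanelError(f"marker map missing columns: {missing}")
        df = df.loc[:, list(self.REQUIRED_COLUMNS)].copy()
        df["marker_id"] = df["marker_id"].astype(str)
        df["chromosome"] = df["chromosome"].astype(str)
        df["position_kb"] = df["position_kb"].astype(float)
        if df["marker_id"].duplicated().any():
            dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise PanelError(f"duplicate marker id {dup!r}")
        if (df["position_kb"] < 0).any():
            raise PanelError("negative position_kb in marker map")
        df = df.sort_values(
            ["chromosome", "position_kb"], kind="stable"
        ).reset_index(drop=True)
        for chrom, sub in df.groupby("chromosome", sort=False):
            pos = sub["position_kb"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                k = int(np.argmax(np.diff(pos) <= 0))
                raise PanelError(
                    f"chromosome {chrom}: positions not strictly increasing "
                    f"near {pos[k]:g} Kb (duplicate or unsorted position)"
                )
        object.__setattr__(self, "table", df)

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome ids in sorted order."""
        return sorted(self.table["chromosome"].unique())

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def positions_kb(self) -> np.ndarray:
        return self.table["position_kb"].to_numpy()

    def chromosome_index(self, chromosome: str) -> np.ndarray:
        """Column indices belonging to ``chromosome`` (in map order)."""
        mask = (self.table["chromosome"] == str(chromosome)).to_numpy()
        if not mask.any():
            raise KeyError(f"chromosome {chromosome!r} not in marker map")
        return np.flatnonzero(mask)

    def positions(self, chromosome: str) -> np.ndarray:
        return self.table["position_kb"].to_numpy()[self.chromosome_index(chromosome)]


@dataclass(frozen=True)
class HaplotypePanel:
    """A phased 0/1 haplotype matrix aligned to a :class:`MarkerMap`.

    ``alleles[i, k]`` is the allele of haplotype ``i`` at the map's k-th
    marker. Columns are kept sorted by (chromosome, position); constructing a
    panel with an unsorted map permutes the columns consistently.
    """

    alleles: np.ndarray = field(repr=False)
    haplotype_ids: tuple[str, ...]
    map: MarkerMap

    def __post_init__(self) -> None:
        alleles = np.asarray(self.alleles)
        if alleles.ndim != 2:
            raise PanelError("alleles must be a 2-D matrix")
        bad = ~np.isin(alleles, (0, 1))
        if bad.any():
            i, k = np.argwhere(bad)[0]
            raise PanelError(
                f"non-binary allele value {alleles[i, k]!r} at row {i}, column {k}"
            )
        alleles = alleles.astype(np.uint8)
        n, p = alleles.shape
        if p != len(self.map):
            raise PanelError(
                f"allele matrix has {p} columns but marker map has {len(self.map)}"
            )
        ids = tuple(str(h) for h in self.haplotype_ids)
        if len(ids) != n:
            raise PanelError(f"{len(ids)} haplotype ids for {n} rows")
        if len(set(ids)) != n:
            raise PanelError("haplotype ids are not unique")
        alleles.setflags(write=False)
        object.__setattr__(self, "alleles", alleles)
        object.__setattr__(self, "haplotype_ids", ids)

    @classmethod
    def from_unsorted(
        cls,
        alleles: np.ndarray,
        haplotype_ids: Sequence[str],
        map_table: pd.DataFrame,
    ) -> "HaplotypePanel":
        """Build a panel, permuting columns so they follow map sort order."""
        df = map_table.reset_index(drop=True)
        order = np.lexsort(
            (
                df["position_kb"].to_numpy(dtype=float),
                df["chromosome"].astype(str).to_numpy(),
            )
        )
        alleles = np.asarray(alleles)
        if alleles.ndim != 2 or alleles.shape[1] != len(order):
            raise PanelError(
                f"allele matrix shape {alleles.shape} does not match map "
                f"({len(order)} markers)"
            )
        mm = MarkerMap(df.iloc[order].reset_index(drop=True))
        return cls(alleles[:, order], tuple(haplotype_ids), mm)

    # -- accessors ---------------------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    @property
    def chromosomes(self) -> list[str]:
        return self.map.chromosomes

    def chromosome_alleles(self, chromosome: str) -> np.ndarray:
        """N x P_j allele sub-matrix for one chromosome (read-only view)."""
        return self.alleles[:, self.map.chromosome_index(chromosome)]

    def require_min_markers(self, k: int = 2) -> None:
        """Raise unless every chromosome carries at least ``k`` markers."""
        counts = self.map.table["chromosome"].value_counts()
        low = counts[counts < k]
        if not low.empty:
            raise PanelError(
                f"chromosome(s) {list(low.index)} have fewer than {k} markers"
            )
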