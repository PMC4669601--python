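"""Plain-text reader/writer for haplotype panels, plus minimal phased-VCF export.

File dialect (documented in the README):

* **allele file** — whitespace-delimited 0/1 matrix, one row per haplotype,
  one column per marker, no header;
* **map file** — whitespace-delimited with header
  ``marker_id chromosome position_kb``, one row per marker, column order
  matching the allele file;
* **haplotype-id file** (optional) — one id per line; defaults to ``hap_1..N``.

``read_panel`` sorts columns by (chromosome, position) and permutes alleles
consistently; ``write_panel`` emits columns in that sorted order, so a
write/read round trip is bit-exact.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import HaplotypePanel, MarkerMap, PanelError

__all__ = ["read_panel", "write_panel", "export_vcf"]


def read_panel(
    haplotype_path: str | os.PathLike,
    map_path: str | os.PathLike,
    ids_path: str | os.PathLike | None = None,
) -> HaplotypePanel:
    """Read a panel from an allele matrix file and a marker map file."""
    map_table = pd.read_csv(map_path, sep=r"\s+")
    missing = [c for c in MarkerMap.REQUIRED_COLUMNS if c not in map_table.columns]
    if missing:
        raise PanelError(
            f"{map_path}: map header must contain {MarkerMap.REQUIRED_COLUMNS}, "
            f"missing {missing}"
        )

    rows: list[list[str]] = []
    with open(haplotype_path) as fh:
        for line in fh:
            if line.strip():
                rows.append(line.split())
    if not rows:
        raise PanelError(f"{haplotype_path}: empty allele file")
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise PanelError(
                f"{haplotype_path}: row {i + 1} has {len(row)} fields, expected {width}"
            )
        for k, tok in enumerate(row):
            if tok not in ("0", "1"):
                raise PanelError(
                    f"{haplotype_path}: non-binary allele {tok!r} at row {i + 1}, "
                    f"column {k + 1}"
                )
    alleles = np.array(rows, dtype=np.uint8)
    if alleles.shape[1] != len(map_table):
        raise PanelError(
            f"allele file has {alleles.shape[1]} markers but map file has "
            f"{len(map_table)}"
        )

    if ids_path is not None:
        with open(ids_path) as fh:
            ids: Sequence[str] = [ln.strip() for ln in fh if ln.strip()]
        if len(ids) != alleles.shape[0]:
            raise PanelError(
                f"{ids_path}: {len(ids)} haplotype ids for {alleles.shape[0]} rows"
            )
    else:
        ids = [f"hap_{i + 1}" for i in range(alleles.shape[0])]

    return HaplotypePanel.from_unsorted(alleles, ids, map_table)


def write_panel(
    panel: HaplotypePanel,
    haplotype_path: str | os.PathLike,
    map_path: str | os.PathLike,
    ids_path: str | os.PathLike | None = None,
) -> None:
    """Write a panel to the plain-text dialect read by :func:`read_panel`."""
    panel.require_min_markers(1)
    np.savetxt(haplotype_path, panel.alleles, fmt="%d", delimiter=" ")
    panel.map.table.to_csv(map_path, sep=" ", index=False)
    if ids_path is not None:
        with open(ids_path, "w") as fh:
            fh.write("\n".join(panel.haplotype_ids) + "\n")


def export_vcf(
    panel: HaplotypePanel,
    path: str | os.PathLike,
    haploid: bool = False,
) -> None:
    """Export as a minimal phased VCF 4.2.

    Haplotype pairs (rows ``2i``, ``2i+1``) form one pseudo-diploid sample
    with a phased GT (``0|1`` style) unless ``haploid`` is set, in which case
    each haplotype becomes one haploid sample. Positions are emitted in base
    pairs as ``round(position_kb * 1000)``; REF/ALT are placeholder ``A``/``T``.
    """
    n = panel.n_haplotypes
    if not haploid and n % 2 != 0:
        raise PanelError(
            f"odd haplotype count {n}: cannot pair into diploid samples "
            "(pass haploid=True)"
        )
    if haploid:
        samples = list(panel.haplotype_ids)
    else:
        samples = [
            f"{panel.haplotype_ids[2 * i]}_{panel.haplotype_ids[2 * i + 1]}"
            for i in range(n // 2)
        ]

    tab = panel.map.table
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haplodense\n")
        for chrom in panel.chromosomes:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for k in range(panel.n_markers):
            chrom = tab["chromosome"].iloc[k]
            pos_bp = int(round(tab["position_kb"].iloc[k] * 1000))
            col = panel.alleles[:, k]
            if haploid:
                gts = [str(int(a)) for a in col]
            else:
                gts = [
                    f"{int(col[2 * i])}|{int(col[2 * i + 1])}" for i in range(n // 2)
                ]
            fh.write(
                f"{chrom}\t{pos_bp}\t{tab['marker_id'].iloc[k]}\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
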