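"""The ancestral homology matrix: ancestral chromosomes × extant taxa.

Each row of the matrix is one ancestral chromosome; each cell lists the
segment(s) of one taxon homologous to it, in the segment-token grammar,
optionally annotated with a structural flag: ``inv`` (pericentric
inversion) or ``inv/cr`` (inversion/centromere repositioning).  Bare
``?`` cells are regions not yet resolved by chromosome painting.

File dialect: UTF-8 TSV, ``# key: value`` header lines (``caption_2n``),
a column header naming the row key and the taxa, then one row per
ancestral chromosome.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .painting import PaintingMap, PaintingError
from .segments import Cell, SegmentRef, format_cell, parse_cell

__all__ = [
    "AncestralMatrix",
    "read_ancestral_matrix",
    "write_ancestral_matrix",
    "painting_map_between",
]


class AncestralMatrixError(ValueError):
    pass


@dataclass(frozen=True)
class AncestralMatrix:
    row_key: str
    rows: Tuple[str, ...]
    taxa: Tuple[str, ...]
    cells: Dict[Tuple[str, str], Cell]
    caption_2n: Optional[int] = None

    def __post_init__(self) -> None:
        for row in self.rows:
            for taxon in self.taxa:
                if (row, taxon) not in self.cells:
                    raise AncestralMatrixError(f"row {row!r} missing cell for taxon {taxon!r}")

    def cell(self, row: str, taxon: str) -> Cell:
        return self.cells[(row, taxon)]

    def column(self, taxon: str) -> Dict[str, Cell]:
        if taxon not in self.taxa:
            raise AncestralMatrixError(f"taxon {taxon!r} not a matrix column")
        return {row: self.cells[(row, taxon)] for row in self.rows}

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def derived_2n(self) -> int:
        """2n implied by the row count (one sex pair added)."""
        return 2 * len(self.rows) + 2

    def to_frame(self) -> pd.DataFrame:
        data = {
            taxon: [format_cell(self.cells[(row, taxon)]) for row in self.rows]
            for taxon in self.taxa
        }
        return pd.DataFrame(data, index=pd.Index(self.rows, name=self.row_key))


def read_ancestral_matrix(source: io.TextIOBase | str) -> AncestralMatrix:
    if isinstance(source, str):
        source = io.StringIO(source)
    meta: dict = {}
    header: Optional[List[str]] = None
    rows: List[str] = []
    cells: Dict[Tuple[str, str], Cell] = {}
    for row in csv.reader(source, delimiter="\t"):
        if not row or not any(c.strip() for c in row):
            continue
        first = row[0].strip()
        if first.startswith("#"):
            key, _, value = first.lstrip("#").partition(":")
            meta[key.strip()] = value.strip()
            continue
        if header is None:
            header = [c.strip() for c in row]
            if len(header) < 2:
                raise AncestralMatrixError(f"matrix header needs a row key and >=1 taxon: {row!r}")
            continue
        if not first:
            raise AncestralMatrixError(f"matrix row with missing key: {row!r}")
        if len(row) != len(header):
            raise AncestralMatrixError(
                f"row {first!r} has {len(row) - 1} cells for {len(header) - 1} taxa"
            )
        rows.append(first)
        for taxon, text in zip(header[1:], row[1:]):
            cells[(first, taxon)] = parse_cell(text, taxon)
    if header is None:
        raise AncestralMatrixError("empty ancestral matrix")
    caption_2n = int(meta["caption_2n"]) if "caption_2n" in meta else None
    return AncestralMatrix(
        row_key=header[0],
        rows=tuple(rows),
        taxa=tuple(header[1:]),
        cells=cells,
        caption_2n=caption_2n,
    )


def write_ancestral_matrix(mat: AncestralMatrix) -> str:
    out = []
    if mat.caption_2n is not None:
        out.append(f"# caption_2n: {mat.caption_2n}")
    out.append("\t".join((mat.row_key,) + mat.taxa))
    for row in mat.rows:
        out.append("\t".join([row] + [format_cell(mat.cells[(row, taxon)]) for taxon in mat.taxa]))
    return "\n".join(out) + "\n"


def painting_map_between(mat: AncestralMatrix, probe_taxon: str, target_taxon: str) -> PaintingMap:
    """Derive the probe_taxon → target_taxon painting map implied by the matrix.

    Each matrix row links the probe-taxon segments to the target-taxon
    segments homologous to the same ancestral chromosome.  Probe units
    are whole chromosomes (painting resolution); target segments keep
    their arm/qualifier annotations.  Uncertainty-flagged probe tokens
    and unresolved (``?``) cells contribute no links — uncertain regions
    must propagate as absences, never as evidence.
    """
    for taxon in (probe_taxon, target_taxon):
        if taxon not in mat.taxa:
            raise AncestralMatrixError(f"taxon {taxon!r} not a matrix column")
    per_probe: Dict[str, List[SegmentRef]] = {}
    order: List[str] = []
    for row in mat.rows:
        src = mat.cells[(row, probe_taxon)]
        dst = mat.cells[(row, target_taxon)]
        if src.unresolved or dst.unresolved:
            continue
        for s in src.refs:
            if s.uncertain:
                continue
            bucket = per_probe.setdefault(s.chromosome, [])
            if s.chromosome not in order:
                order.append(s.chromosome)
            for d in dst.refs:
                if d.uncertain:
                    continue
                if d not in bucket:
                    bucket.append(d)
    entries = tuple((label, tuple(per_probe[label])) for label in order if per_probe[label])
    return PaintingMap(probe_taxon, target_taxon, entries)
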