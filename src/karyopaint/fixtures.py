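"""Packaged fixtures: the published homology tables, parsed and validated.

Every fixture ships as a plain-text TSV under ``karyopaint/data/`` with a
provenance line; ``MANIFEST.tsv`` indexes them.  :func:`load_fixture`
returns the typed object for a fixture name.  Short aliases keyed to the
source tables (``table1`` for the TML→TIN painting map, ``table2`` for
the arm-level maps, ``table3`` for the ancestral matrix,
``hsa_assoc_discussion`` for the published association list) are
accepted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Dict, FrozenSet, Tuple

from .ancestral import AncestralMatrix, read_ancestral_matrix
from .karyotype import Karyotype, read_karyotype, validate_karyotype
from .painting import (
    PaintingMap,
    deconvolve_probe_peaks,
    read_painting_table,
    read_peak_assignments,
)

__all__ = ["load_fixture", "fixture_text", "PublishedAssociation", "FixtureError", "FIXTURES"]


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class PublishedAssociation:
    """One published HSA syntenic association and where it was reported."""

    pair: FrozenSet[str]
    clade: str
    target_chromosomes: Tuple[str, ...]
    status: str  # "present" | "absent"

    @property
    def label(self) -> str:
        return "/".join(sorted(self.pair, key=lambda x: (len(x), x)))


def fixture_text(filename: str) -> str:
    ref = resources.files("karyopaint.data").joinpath(filename)
    try:
        return ref.read_text(encoding="utf-8")
    except FileNotFoundError as err:
        raise FixtureError(f"fixture file {filename!r} not packaged") from err


def _load_karyotype(code: str) -> Karyotype:
    k = read_karyotype(fixture_text(f"karyotype_{code}.tsv"))
    findings = validate_karyotype(k)
    if findings:
        raise FixtureError(f"karyotype fixture {code} failed validation: {[str(f) for f in findings]}")
    return k


def _load_tml_tin() -> PaintingMap:
    peaks = read_painting_table(fixture_text("tml_tin_peaks.tsv"))
    assignments = read_peak_assignments(fixture_text("tml_tin_peak_assignments.tsv"))
    m = deconvolve_probe_peaks(peaks, assignments)
    if not m.is_deconvolved:
        raise FixtureError("TML→TIN fixture failed to deconvolve")
    return m


def _load_arm_maps() -> Dict[str, PaintingMap]:
    return {
        code: read_painting_table(fixture_text(f"tml_{code.lower()}_arms.tsv"))
        for code in ("LAF", "PCA", "TIN")
    }


def _load_matrix() -> AncestralMatrix:
    mat = read_ancestral_matrix(fixture_text("apk_matrix.tsv"))
    if mat.caption_2n is not None and mat.derived_2n() != mat.caption_2n:
        raise FixtureError(
            f"ancestral matrix: {mat.n_rows} rows imply 2n={mat.derived_2n()}, caption says {mat.caption_2n}"
        )
    return mat


def _load_associations() -> Tuple[PublishedAssociation, ...]:
    out = []
    rows = csv.reader(fixture_text("hsa_associations.tsv").splitlines(), delimiter="\t")
    header_seen = False
    for row in rows:
        if not row or row[0].startswith("#"):
            continue
        if not header_seen:
            if row[:2] != ["pair", "clade"]:
                raise FixtureError(f"bad association fixture header: {row!r}")
            header_seen = True
            continue
        pair, clade, targets, status = (c.strip() for c in row[:4])
        out.append(
            PublishedAssociation(
                pair=frozenset(pair.split("/")),
                clade=clade,
                target_chromosomes=tuple(t for t in targets.split(";") if t),
                status=status,
            )
        )
    return tuple(out)


FIXTURES = {
    "tml_tin": _load_tml_tin,
    "tml_tin_peaks": lambda: read_painting_table(fixture_text("tml_tin_peaks.tsv")),
    "tml_tin_assignments": lambda: read_peak_assignments(fixture_text("tml_tin_peak_assignments.tsv")),
    "tml_arm_maps": _load_arm_maps,
    "apk_matrix": _load_matrix,
    "hsa_assoc_published": _load_associations,
    "karyotype_TIN": lambda: _load_karyotype("TIN"),
    "karyotype_TML": lambda: _load_karyotype("TML"),
    "karyotype_APK": lambda: _load_karyotype("APK"),
    "karyotype_LAF": lambda: _load_karyotype("LAF"),
    "karyotype_PCA": lambda: _load_karyotype("PCA"),
}

_ALIASES = {
    "table1": "tml_tin",
    "table1_peaks": "tml_tin_peaks",
    "table2": "tml_arm_maps",
    "table3": "apk_matrix",
    "hsa_assoc_discussion": "hsa_assoc_published",
}


def load_fixture(name: str):
    """Load a packaged fixture by name (see :data:`FIXTURES` and aliases)."""
    key = _ALIASES.get(name, name)
    if key not in FIXTURES:
        raise FixtureError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    return FIXTURES[key]()
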