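"""Painting homology maps: the directed probe→target tables Zoo-FISH produces.

A :class:`PaintingMap` records, for each probe unit of the probe species,
the ordered list of target-species segments it hybridised to.  A probe
unit is normally a single chromosome, but flow-sorted probe sets contain
*composite peaks* (two chromosomes co-sorted into one peak, written
``"6+X"``); :func:`deconvolve_probe_peaks` resolves these to per-
chromosome entries given an assignment of each member to its targets.

File dialect: UTF-8 tab-separated, ``# key: value`` header lines naming
the probe and target species, one ``probe<TAB>targets`` row per entry,
``+`` joining composite-peak members and ``;`` separating targets.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .segments import (
    SegmentRef,
    SegmentParseError,
    format_segment_token,
    parse_segment_token,
)

__all__ = [
    "PaintingMap",
    "PaintingError",
    "read_painting_table",
    "write_painting_table",
    "deconvolve_probe_peaks",
    "read_peak_assignments",
]

logger = logging.getLogger(__name__)

KNOWN_SPECIES = ("TIN", "TML", "LAF", "PCA", "OAF", "HSA", "APK")


class PaintingError(ValueError):
    pass


@dataclass(frozen=True)
class PaintingMap:
    """Directed homology map probe_species → target_species.

    ``entries`` preserves source order.  ``paths`` is populated by map
    composition and carries, per (probe unit, target chromosome), the
    intermediate evidence chain.
    """

    probe_species: str
    target_species: str
    entries: Tuple[Tuple[str, Tuple[SegmentRef, ...]], ...]
    paths: Optional[Mapping[Tuple[str, str], Tuple[Tuple[SegmentRef, ...], ...]]] = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        for unit, targets in self.entries:
            if not targets:
                raise PaintingError(f"probe unit {unit!r} has an empty target list")

    @property
    def probe_units(self) -> Tuple[str, ...]:
        return tuple(unit for unit, _ in self.entries)

    @property
    def is_deconvolved(self) -> bool:
        units = self.probe_units
        return len(set(units)) == len(units) and not any("+" in u for u in units)

    def targets_of(self, probe_label: str) -> Tuple[SegmentRef, ...]:
        """Targets of a single probe chromosome (deconvolved maps)."""
        out: List[SegmentRef] = []
        for unit, targets in self.entries:
            unit_label = parse_segment_token(unit).chromosome if "+" not in unit else None
            if unit == probe_label or unit_label == probe_label:
                out.extend(targets)
        if not out:
            raise KeyError(f"probe {probe_label!r} not in map {self.probe_species}->{self.target_species}")
        return tuple(out)

    def target_chromosomes_of(self, probe_label: str) -> Tuple[str, ...]:
        seen: dict[str, None] = {}
        for ref in self.targets_of(probe_label):
            seen.setdefault(ref.chromosome, None)
        return tuple(seen)

    def as_dict(self) -> Dict[str, Tuple[SegmentRef, ...]]:
        out: Dict[str, List[SegmentRef]] = {}
        for unit, targets in self.entries:
            out.setdefault(unit, []).extend(targets)
        return {u: tuple(t) for u, t in out.items()}


def _parse_targets(cell: str, species: str) -> Tuple[SegmentRef, ...]:
    parts = [p.strip() for p in cell.split(";")]
    if not any(parts):
        raise PaintingError("empty target field")
    return tuple(parse_segment_token(p, species) for p in parts if p)


def read_painting_table(source: io.TextIOBase | str) -> PaintingMap:
    """Read the TSV dialect.  Duplicate identical probe rows are collapsed
    with a logged notice (the flow karyotype can present one chromosome in
    two peaks, e.g. via NOR heteromorphism); duplicate rows with
    *conflicting* targets are an error."""
    if isinstance(source, str):
        source = io.StringIO(source)
    meta: dict = {}
    entries: List[Tuple[str, Tuple[SegmentRef, ...]]] = []
    header_seen = False
    for row in csv.reader(source, delimiter="\t"):
        if not row or not any(c.strip() for c in row):
            continue
        first = row[0].strip()
        if first.startswith("#"):
            key, _, value = first.lstrip("#").partition(":")
            meta[key.strip()] = value.strip()
            continue
        if not header_seen:
            if [c.strip() for c in row[:2]] != ["probe", "targets"]:
                raise PaintingError(f"bad painting table header: {row!r}")
            header_seen = True
            continue
        if len(row) < 2:
            raise PaintingError(f"row {row!r} has no target field")
        unit = first
        targets = _parse_targets(row[1], meta.get("target_species", ""))
        dup = next((t for u, t in entries if u == unit), None)
        if dup is not None:
            if dup == targets:
                logger.info("painting table: duplicate row for probe %r collapsed", unit)
                continue
            raise PaintingError(f"conflicting duplicate rows for probe {unit!r}")
        entries.append((unit, targets))
    for key in ("probe_species", "target_species"):
        if key not in meta:
            raise PaintingError(f"painting table missing {key} header")
        if meta[key] not in KNOWN_SPECIES:
            raise PaintingError(f"unknown species code {meta[key]!r}")
    return PaintingMap(meta["probe_species"], meta["target_species"], tuple(entries))


def write_painting_table(m: PaintingMap) -> str:
    out = [f"# probe_species: {m.probe_species}", f"# target_species: {m.target_species}"]
    out.append("probe\ttargets")
    for unit, targets in m.entries:
        out.append(unit + "\t" + ";".join(format_segment_token(t) for t in targets))
    return "\n".join(out) + "\n"


# --- composite-peak deconvolution -----------------------------------------

Assignment = Mapping[str, Mapping[str, Sequence[SegmentRef]]]


def deconvolve_probe_peaks(m: PaintingMap, assignments: Assignment) -> PaintingMap:
    """Resolve composite probe peaks to single-chromosome entries.

    ``assignments`` maps a composite probe unit (e.g. ``"6+X"``) to a
    per-member target assignment ``{"6": [...], "X": [...]}``.  Every
    member and every observed target must be covered; targets attributed
    to several members of one peak are an error, as is an assignment
    that leaves an observed target unattributed.

    Entries for the same probe chromosome arising from different peaks
    (pure + mixed peaks both existed in the probe set) are merged with
    duplicate targets collapsed.  The union of targets is preserved.
    """
    per_probe: Dict[str, List[SegmentRef]] = {}
    order: List[str] = []

    def add(label: str, refs: Iterable[SegmentRef]) -> None:
        bucket = per_probe.setdefault(label, [])
        if label not in order:
            order.append(label)
        for ref in refs:
            if ref not in bucket:
                bucket.append(ref)

    for unit, targets in m.entries:
        if "+" not in unit:
            add(unit, targets)
            continue
        members = [p.strip() for p in unit.split("+")]
        if unit not in assignments:
            raise PaintingError(f"no deconvolution assignment for composite peak {unit!r}")
        assignment = assignments[unit]
        missing_members = [mm for mm in members if mm not in assignment]
        if missing_members:
            raise PaintingError(
                f"assignment for peak {unit!r} missing members {missing_members}"
            )
        attributed = {ref for refs in assignment.values() for ref in refs}
        unattributed = [t for t in targets if t not in attributed]
        if unattributed:
            raise PaintingError(
                f"assignment for peak {unit!r} leaves targets unattributed: "
                + ", ".join(format_segment_token(t) for t in unattributed)
            )
        for member in members:
            add(member, assignment[member])
    entries = tuple((label, tuple(per_probe[label])) for label in order)
    return PaintingMap(m.probe_species, m.target_species, entries)


def read_peak_assignments(source: io.TextIOBase | str) -> Dict[str, Dict[str, Tuple[SegmentRef, ...]]]:
    """Read a peak-assignment TSV: columns peak / member / targets."""
    if isinstance(source, str):
        source = io.StringIO(source)
    out: Dict[str, Dict[str, Tuple[SegmentRef, ...]]] = {}
    header_seen = False
    for row in csv.reader(source, delimiter="\t"):
        if not row or row[0].strip().startswith("#") or not any(c.strip() for c in row):
            continue
        if not header_seen:
            if [c.strip() for c in row[:3]] != ["peak", "member", "targets"]:
                raise PaintingError(f"bad assignment header: {row!r}")
            header_seen = True
            continue
        peak, member, targets = row[0].strip(), row[1].strip(), row[2]
        out.setdefault(peak, {})[member] = _parse_targets(targets, "")
    return out
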