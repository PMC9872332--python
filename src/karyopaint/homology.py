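"""Algebra over painting maps and detection of syntenic associations.

Whole-chromosome painting resolves homology at chromosome/arm level, so
the algebra here — inversion, composition through an intermediary
species, segment census — matches at **whole-chromosome granularity**.
Arm and region qualifiers ride along as evidence but never create or
block a match: a painting table cannot support arm-level adjacency
claims, and the operations do not pretend otherwise.

A *syntenic association* is the classic Zoo-FISH cladistic marker: two
reference-species chromosomes (e.g. HSA 5 and HSA 21) whose segments
co-occur on a single chromosome of the target species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

from .ancestral import AncestralMatrix
from .painting import PaintingMap, PaintingError
from .karyotype import Finding
from .segments import SegmentRef, format_segment_token, parse_segment_token

__all__ = [
    "AssociationHit",
    "AssociationReport",
    "invert_map",
    "compose_maps",
    "count_homologous_segments",
    "detect_syntenic_associations",
    "check_matrix_consistency",
]


def _require_deconvolved(m: PaintingMap, op: str) -> None:
    if not m.is_deconvolved:
        raise PaintingError(f"{op} requires a deconvolved map (single-chromosome probe units)")


def invert_map(m: PaintingMap) -> PaintingMap:
    """Swap probe and target sides of a deconvolved map.

    Each link (probe unit, target segment) becomes (target segment as
    probe unit, probe unit as target segment), so arm/qualifier
    information changes sides but is never dropped and
    ``invert_map(invert_map(m)) == m``.
    """
    _require_deconvolved(m, "invert_map")
    per_unit: Dict[str, List[SegmentRef]] = {}
    order: List[str] = []
    for unit, targets in m.entries:
        back_ref = parse_segment_token(unit)
        for t in targets:
            new_unit = format_segment_token(t)
            bucket = per_unit.setdefault(new_unit, [])
            if new_unit not in order:
                order.append(new_unit)
            if back_ref not in bucket:
                bucket.append(back_ref)
    entries = tuple((u, tuple(per_unit[u])) for u in order)
    return PaintingMap(m.target_species, m.probe_species, entries)


def compose_maps(a_to_b: PaintingMap, b_to_c: PaintingMap) -> PaintingMap:
    """Compose two maps through their shared species, A → B → C.

    Matching is at whole-chromosome granularity on the B side; the
    resulting map records, in ``paths``, the (B segment, C segment)
    evidence chain for every produced link.
    """
    if a_to_b.target_species != b_to_c.probe_species:
        raise PaintingError(
            f"cannot compose {a_to_b.probe_species}->{a_to_b.target_species} "
            f"with {b_to_c.probe_species}->{b_to_c.target_species}"
        )
    _require_deconvolved(a_to_b, "compose_maps")
    _require_deconvolved(b_to_c, "compose_maps")
    b_index: Dict[str, List[Tuple[SegmentRef, SegmentRef]]] = {}
    for unit, targets in b_to_c.entries:
        b_ref = parse_segment_token(unit)
        for t in targets:
            b_index.setdefault(b_ref.chromosome, []).append((b_ref, t))
    entries: List[Tuple[str, Tuple[SegmentRef, ...]]] = []
    paths: Dict[Tuple[str, str], Tuple[Tuple[SegmentRef, ...], ...]] = {}
    order: List[str] = []
    per_unit: Dict[str, List[SegmentRef]] = {}
    chains: Dict[Tuple[str, str], List[Tuple[SegmentRef, ...]]] = {}
    for unit, targets in a_to_b.entries:
        a_label = parse_segment_token(unit).chromosome
        if a_label not in order:
            order.append(a_label)
            per_unit[a_label] = []
        for b_seg in targets:
            for b_ref, c_seg in b_index.get(b_seg.chromosome, []):
                whole = c_seg.whole()
                if whole not in per_unit[a_label]:
                    per_unit[a_label].append(whole)
                chains.setdefault((a_label, c_seg.chromosome), []).append((b_seg, c_seg))
    for a_label in order:
        if per_unit[a_label]:
            entries.append((a_label, tuple(per_unit[a_label])))
    paths = {key: tuple(v) for key, v in chains.items()}
    return PaintingMap(a_to_b.probe_species, b_to_c.target_species, tuple(entries), paths=paths)


@dataclass(frozen=True)
class SegmentCensus:
    total: int
    per_probe: Mapping[str, int]
    multi_signal_probes: Tuple[str, ...]

    def breakdown(self) -> Dict[str, int]:
        return dict(self.per_probe)


def count_homologous_segments(m: PaintingMap, convention: str = "all") -> SegmentCensus:
    """Census of homologous segments: Σ over probes of |target list|.

    ``convention="all"`` counts every probe including the sex
    chromosomes once each; ``"autosomal"`` restricts to autosomal
    probes.  The census also lists probes with more than one signal
    (split chromosomes).
    """
    if convention not in ("all", "autosomal"):
        raise ValueError(f"unknown census convention {convention!r}")
    _require_deconvolved(m, "count_homologous_segments")
    per_probe: Dict[str, int] = {}
    for unit, targets in m.entries:
        label = parse_segment_token(unit).chromosome
        if convention == "autosomal" and label in ("X", "Y"):
            continue
        seen: Set[str] = set()
        n = 0
        for t in targets:
            if t.chromosome not in seen:
                seen.add(t.chromosome)
                n += 1
        per_probe[label] = per_probe.get(label, 0) + n
    multi = tuple(sorted((p for p, n in per_probe.items() if n > 1), key=_natural_key))
    return SegmentCensus(total=sum(per_probe.values()), per_probe=per_probe, multi_signal_probes=multi)


def _natural_key(label: str):
    return (0, int(label)) if label.isdigit() else (1, label)


@dataclass(frozen=True)
class AssociationHit:
    """Both members of a source pair painted onto one target chromosome."""

    source_pair: FrozenSet[str]
    target_chromosome: str
    evidence: Tuple[Tuple[SegmentRef, ...], ...] = ()

    @property
    def label(self) -> str:
        return "/".join(sorted(self.source_pair, key=_natural_key))


@dataclass(frozen=True)
class AssociationReport:
    hits: Tuple[AssociationHit, ...]
    absent: Tuple[FrozenSet[str], ...]
    unresolved: Tuple[str, ...] = ()

    def hits_for(self, pair: Iterable[str]) -> Tuple[AssociationHit, ...]:
        pair = frozenset(pair)
        return tuple(h for h in self.hits if h.source_pair == pair)

    def is_present(self, pair: Iterable[str]) -> bool:
        return bool(self.hits_for(pair))


def detect_syntenic_associations(
    composed: PaintingMap,
    candidate_pairs: Sequence[Iterable[str]],
) -> AssociationReport:
    """Test candidate source-chromosome pairs for co-occurrence.

    A hit is emitted for pair {a, b} on target chromosome c iff segments
    of both a and b map to c.  Co-occurrence is the criterion — painting
    resolution cannot assess adjacency.  Candidates with no shared
    target are reported in ``absent`` explicitly.
    """
    known = {parse_segment_token(u).chromosome for u in composed.probe_units}
    hits: List[AssociationHit] = []
    absent: List[FrozenSet[str]] = []
    for raw_pair in candidate_pairs:
        pair = frozenset(raw_pair)
        unknown = sorted(p for p in pair if p not in known)
        if unknown:
            raise PaintingError(
                f"candidate pair {sorted(pair)} references unknown chromosome(s) {unknown} "
                f"in the {composed.probe_species} map"
            )
        a, b = sorted(pair, key=_natural_key)
        shared = [c for c in composed.target_chromosomes_of(a) if c in composed.target_chromosomes_of(b)]
        if not shared:
            absent.append(pair)
            continue
        for c in shared:
            evidence: List[Tuple[SegmentRef, ...]] = []
            if composed.paths:
                for member in (a, b):
                    for chain in composed.paths.get((member, c), ()):
                        evidence.append((SegmentRef(member),) + chain)
            hits.append(AssociationHit(pair, c, tuple(evidence)))
    return AssociationReport(hits=tuple(hits), absent=tuple(absent))


def check_matrix_consistency(mat: AncestralMatrix, pairwise: PaintingMap) -> List[Finding]:
    """Cross-check the ancestral matrix against an independent pairwise map.

    For each matrix row, every (certain) probe-species chromosome in the
    row must paint onto the row's target-species chromosome(s) according
    to the pairwise map.  One finding per contradicted row; uncertain
    tokens and unresolved cells never create findings — they are the
    caller's ``unresolved`` report, not contradictions.
    """
    probe_t, target_t = pairwise.probe_species, pairwise.target_species
    for taxon in (probe_t, target_t):
        if taxon not in mat.taxa:
            raise PaintingError(f"pairwise map species {taxon!r} is not a matrix column")
    findings: List[Finding] = []
    for row in mat.rows:
        src = mat.cell(row, probe_t)
        dst = mat.cell(row, target_t)
        if src.unresolved or dst.unresolved:
            continue
        expected: Set[str] = set()
        for s in src.certain_refs():
            try:
                expected.update(pairwise.target_chromosomes_of(s.chromosome))
            except KeyError:
                findings.append(
                    Finding(
                        "matrix-vs-map",
                        f"{probe_t} {s.chromosome} absent from the pairwise map",
                        f"{mat.row_key} {row}",
                    )
                )
        stray = [d.chromosome for d in dst.certain_refs() if d.chromosome not in expected]
        if stray and expected:
            findings.append(
                Finding(
                    "matrix-vs-map",
                    f"{target_t} {', '.join(stray)} not among painting targets "
                    f"{sorted(expected, key=_natural_key)} of {probe_t} cell",
                    f"{mat.row_key} {row}",
                )
            )
    return findings
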