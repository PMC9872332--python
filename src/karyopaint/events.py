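"""Rearrangement-event inference and chromosomal change rates.

Whole-chromosome painting supports a parsimony-minimal reading of
karyotype differences: a probe chromosome hybridising to k target
chromosomes witnesses k−1 fissions (equivalently, read in the opposite
polarity, k−1 fusions).  A fusion/fission is *Robertsonian* (centric)
when the split side consists of acrocentrics and the joined homolog is
bi-armed — the arm count is conserved while 2n changes by 2.

Pericentric inversions and centromere repositionings change morphology
without changing painting-level content, so they are never inferred from
a map; they enter only as annotations (structural flags of the ancestral
matrix, or curated statements).

Event polarity is always stated ancestor → descendant and must be given
explicitly; nothing here guesses ancestry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

from .ancestral import AncestralMatrix, AncestralMatrixError
from .homology import AssociationReport, invert_map, _natural_key
from .karyotype import Finding, Karyotype
from .painting import PaintingMap, PaintingError
from .segments import format_segment_token, parse_segment_token

__all__ = [
    "EventRecord",
    "EventSummary",
    "PairwiseEvents",
    "LineageEvents",
    "SharedAssociation",
    "EVENT_TYPES",
    "infer_pairwise_events",
    "count_lineage_events",
    "compute_change_rate",
    "find_shared_associations",
    "summarize_events",
]

EVENT_TYPES = ("fusion", "fission", "pericentric_inversion", "centromere_repositioning")
PAINTING_TYPES = ("fusion", "fission")


@dataclass(frozen=True)
class EventRecord:
    type: str
    lineage: Tuple[str, str]  # (from_taxon, to_taxon)
    sources: Tuple[str, ...]  # chromosome labels on the ancestral side
    products: Tuple[str, ...]  # chromosome labels on the derived side
    evidence: str = "painting"  # "painting" | "annotation"
    robertsonian: bool = False

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        if self.evidence not in ("painting", "annotation"):
            raise ValueError(f"unknown evidence class {self.evidence!r}")
        if self.type in ("pericentric_inversion", "centromere_repositioning") and self.evidence != "annotation":
            raise ValueError(f"{self.type} is not derivable from painting; evidence must be annotation")
        if self.type == "fusion" and (len(self.sources) < 2 or len(self.products) != 1):
            raise ValueError("fusion needs >=2 sources and exactly 1 product")
        if self.type == "fission" and (len(self.sources) != 1 or len(self.products) < 2):
            raise ValueError("fission needs exactly 1 source and >=2 products")


@dataclass(frozen=True)
class EventSummary:
    counts: Mapping[str, int]
    total: int
    robertsonian_count: int
    rate: Optional[float] = None

    def __post_init__(self) -> None:
        assert self.total == sum(self.counts.values())
        assert self.robertsonian_count <= self.counts.get("fusion", 0) + self.counts.get("fission", 0)


def summarize_events(
    events: Sequence[EventRecord], divergence_myr: Optional[float] = None
) -> EventSummary:
    """Tally events per type; k-way merges/splits were already emitted as
    k−1 records, so the total is the parsimony-minimal change count."""
    counts = {t: 0 for t in EVENT_TYPES}
    rb = 0
    for e in events:
        counts[e.type] += 1
        if e.robertsonian:
            rb += 1
    counts = {t: n for t, n in counts.items() if n}
    total = sum(counts.values())
    rate = compute_change_rate(total, divergence_myr) if divergence_myr is not None else None
    return EventSummary(counts=counts, total=total, robertsonian_count=rb, rate=rate)


@dataclass(frozen=True)
class PairwiseEvents:
    events: Tuple[EventRecord, ...]
    findings: Tuple[Finding, ...] = ()

    @property
    def summary(self) -> EventSummary:
        return summarize_events(self.events)


def _morphology(k: Optional[Karyotype], label: str) -> Optional[str]:
    if k is None:
        return None
    c = k.get(label)
    if c is None or c.morphology == "unknown":
        return None
    return c.morphology


def _robertsonian_check(
    joined: str,
    split: Sequence[str],
    k_joined: Optional[Karyotype],
    k_split: Optional[Karyotype],
) -> Tuple[bool, Optional[str]]:
    """True iff the joined homolog is bi-armed and all split products are
    acrocentric; (False, warning) when morphology is missing."""
    morphs = [_morphology(k_split, lbl) for lbl in split]
    joined_m = _morphology(k_joined, joined)
    missing = [lbl for lbl, mph in zip(split, morphs) if mph is None]
    if joined_m is None:
        missing.append(joined)
    if missing:
        return False, f"morphology unknown for {', '.join(missing)}; Robertsonian test skipped"
    ok = all(m == "acrocentric" for m in morphs) and joined_m != "acrocentric"
    return ok, None


def infer_pairwise_events(
    m: PaintingMap,
    k_from: Optional[Karyotype] = None,
    k_to: Optional[Karyotype] = None,
    annotations: Sequence[EventRecord] = (),
) -> PairwiseEvents:
    """Infer fusion/fission events between two karyotypes from a painting map.

    ``m`` must be deconvolved and oriented from_taxon → to_taxon.  A
    probe with k targets yields k−1 fissions; a target receiving k
    probes yields k−1 fusions (counted once, on the inverted view).
    Karyotypes supply the morphology for the Robertsonian flag; missing
    morphology downgrades the event to an unflagged fusion/fission with
    a warning finding.  ``annotations`` (inversions/repositionings and
    any curated events) are appended verbatim.
    """
    if not m.is_deconvolved:
        raise PaintingError("infer_pairwise_events requires a deconvolved map")
    lineage = (m.probe_species, m.target_species)
    events: List[EventRecord] = []
    findings: List[Finding] = []

    for unit, _ in m.entries:
        source = parse_segment_token(unit).chromosome
        targets = m.target_chromosomes_of(source)
        if len(targets) < 2:
            continue
        rb, warning = _robertsonian_check(source, targets, k_from, k_to)
        if warning:
            findings.append(Finding("morphology-missing", warning, f"{lineage[0]} {source}"))
        for i in range(len(targets) - 1):
            events.append(
                EventRecord(
                    type="fission",
                    lineage=lineage,
                    sources=(source,),
                    products=tuple(targets),
                    robertsonian=rb,
                )
            )

    inverted = invert_map(m)
    for unit, _ in inverted.entries:
        product = parse_segment_token(unit).chromosome
        sources = inverted.target_chromosomes_of(product)
        if len(sources) < 2:
            continue
        rb, warning = _robertsonian_check(product, sources, k_to, k_from)
        if warning:
            findings.append(Finding("morphology-missing", warning, f"{lineage[1]} {product}"))
        for i in range(len(sources) - 1):
            events.append(
                EventRecord(
                    type="fusion",
                    lineage=lineage,
                    sources=tuple(sources),
                    products=(product,),
                    robertsonian=rb,
                )
            )

    events.extend(annotations)
    return PairwiseEvents(events=tuple(events), findings=tuple(findings))


@dataclass(frozen=True)
class LineageEvents:
    taxon: str
    events: Tuple[EventRecord, ...]
    unresolved: Tuple[str, ...]

    @property
    def summary(self) -> EventSummary:
        return summarize_events(self.events)

    def count(self, event_type: str) -> int:
        return sum(1 for e in self.events if e.type == event_type)


def count_lineage_events(
    mat: AncestralMatrix,
    taxon: str,
    include_uncertain: bool = True,
) -> LineageEvents:
    """Count rearrangements along the lineage ancestral → ``taxon``.

    Fusions: a taxon chromosome homologous to k ≥ 2 ancestral rows
    witnesses k−1 fusions.  Fissions: an ancestral row split over k ≥ 2
    taxon chromosomes witnesses k−1 fissions.  Structural cell flags
    contribute annotation events (``inv`` → pericentric inversion,
    ``inv/cr`` → centromere repositioning).

    Uncertainty: bare ``?`` cells are always excluded and reported in
    ``unresolved``.  Tokens merely uncertainty-flagged (``16p?``)
    participate in the tallies by default but are reported as
    unresolved too; ``include_uncertain=False`` drops them from the
    tallies entirely (the more conservative reading).
    """
    column = mat.column(taxon)  # raises if taxon absent
    lineage = (mat.row_key, taxon)
    events: List[EventRecord] = []
    unresolved: List[str] = []

    rows_per_label: Dict[str, List[str]] = {}
    for row, cell in column.items():
        if cell.unresolved:
            unresolved.append(f"{mat.row_key} {row}: cell unresolved (?)")
            continue
        labels: List[str] = []
        for ref in cell.refs:
            if ref.uncertain:
                unresolved.append(f"{mat.row_key} {row}: uncertain token {format_segment_token(ref)}")
                if not include_uncertain:
                    continue
            if ref.chromosome not in labels:
                labels.append(ref.chromosome)
        for label in labels:
            rows_per_label.setdefault(label, []).append(row)
        if len(labels) >= 2:
            for _ in range(len(labels) - 1):
                events.append(
                    EventRecord(
                        type="fission",
                        lineage=lineage,
                        sources=(row,),
                        products=tuple(labels),
                    )
                )
        if cell.flag == "inv":
            events.append(
                EventRecord(
                    type="pericentric_inversion",
                    lineage=lineage,
                    sources=(row,),
                    products=tuple(labels),
                    evidence="annotation",
                )
            )
        elif cell.flag == "inv/cr":
            events.append(
                EventRecord(
                    type="centromere_repositioning",
                    lineage=lineage,
                    sources=(row,),
                    products=tuple(labels),
                    evidence="annotation",
                )
            )

    for label in sorted(rows_per_label, key=_natural_key):
        rows = rows_per_label[label]
        if len(rows) >= 2:
            for _ in range(len(rows) - 1):
                events.append(
                    EventRecord(
                        type="fusion",
                        lineage=lineage,
                        sources=tuple(rows),
                        products=(label,),
                    )
                )
    return LineageEvents(taxon=taxon, events=tuple(events), unresolved=tuple(unresolved))


def compute_change_rate(events: int, divergence_myr: float) -> float:
    """Chromosomal change rate in changes/myr, unrounded."""
    if events < 0:
        raise ValueError("event count must be non-negative")
    if not divergence_myr > 0:
        raise ValueError(f"divergence time must be positive, got {divergence_myr}")
    return events / divergence_myr


@dataclass(frozen=True)
class SharedAssociation:
    pair: FrozenSet[str]
    present_in: Tuple[str, ...]
    absent_in: Tuple[str, ...]
    unresolved_in: Tuple[str, ...]
    clade_shared: bool
    derived: bool

    @property
    def label(self) -> str:
        return "/".join(sorted(self.pair, key=_natural_key))


def find_shared_associations(
    hits_per_taxon: Mapping[str, AssociationReport],
    outgroup: str,
) -> List[SharedAssociation]:
    """Classify associations as clade-shared / derived across taxa.

    An association is *clade-shared* when present in every ingroup
    taxon, and additionally *derived* (a candidate synapomorphy) when
    absent or unresolved in the outgroup.  A taxon whose report tested
    the pair in neither its hits nor its absent list counts as
    unresolved, which conservatively blocks the synapomorphy call.
    """
    if outgroup not in hits_per_taxon:
        raise ValueError(f"outgroup {outgroup!r} not among supplied taxa {sorted(hits_per_taxon)}")
    ingroup = sorted(t for t in hits_per_taxon if t != outgroup)
    if len(ingroup) < 2:
        raise ValueError("need at least two ingroup taxa")
    pairs: List[FrozenSet[str]] = []
    for report in hits_per_taxon.values():
        for h in report.hits:
            if h.source_pair not in pairs:
                pairs.append(h.source_pair)
        for p in report.absent:
            if p not in pairs:
                pairs.append(p)
    out: List[SharedAssociation] = []
    for pair in pairs:
        present, absent, unresolved = [], [], []
        for taxon in sorted(hits_per_taxon):
            report = hits_per_taxon[taxon]
            if report.is_present(pair):
                present.append(taxon)
            elif pair in report.absent:
                absent.append(taxon)
            else:
                unresolved.append(taxon)
        clade_shared = all(t in present for t in ingroup)
        derived = clade_shared and outgroup not in present
        out.append(
            SharedAssociation(
                pair=pair,
                present_in=tuple(present),
                absent_in=tuple(absent),
                unresolved_in=tuple(unresolved),
                clade_shared=clade_shared,
                derived=derived,
            )
        )
    return out
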