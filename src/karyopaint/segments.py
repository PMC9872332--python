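"""Segment-token grammar for painted homology tables.

Zoo-FISH homology tables describe each painted segment with a compact
token: a chromosome label, an optional arm (``p``, ``q`` or ``pq``), an
optional band-letter run (e.g. ``2qhi`` = bands h-i on 2q), an optional
positional qualifier after a hyphen (``prox``, ``dist``, ``qprox`` ...),
an optional trailing ``?`` marking regions not yet resolved by painting,
and an optional parenthesised alternative label whose meaning the source
tables leave undefined.  Examples of tokens this module round-trips::

    7         17q-dist      2qhi      12p-qprox     21pq-prox
    16p?      27 (24)       1qd       8q-prox       2pq-prox

A table *cell* is a small expression over tokens: ``, `` separates the
several chromosomes an ancestral segment split into, ``/`` joins
reference-species segments that are syntenic on one chromosome,
`` + `` joins segments in outgroup cells, and a trailing ``inv`` or
``inv/cr`` flag annotates a pericentric inversion or an
inversion/centromere-repositioning.  A bare ``?`` is an unresolved cell.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

__all__ = [
    "SegmentRef",
    "Cell",
    "SegmentParseError",
    "parse_segment_token",
    "format_segment_token",
    "parse_cell",
    "format_cell",
]

ARMS = ("p", "q", "pq", "whole")

_TOKEN_RE = re.compile(
    r"""^
    (?P<label>[A-Z]?\d+|[XY])
    (?P<arm>pq|p|q)?
    (?P<band>[a-i]+)?
    (?:-(?P<qual>[a-z-]+))?
    (?P<unc>\?)?
    (?:\s*\((?P<alt>[^()]+)\))?
    $""",
    re.VERBOSE,
)


class SegmentParseError(ValueError):
    """Raised for a token or cell that does not fit the grammar."""

    def __init__(self, token: str, position: Optional[int] = None, reason: str = ""):
        self.token = token
        self.position = position
        msg = f"unparseable segment token {token!r}"
        if position is not None:
            msg += f" (item {position})"
        if reason:
            msg += f": {reason}"
        super().__init__(msg)


@dataclass(frozen=True)
class SegmentRef:
    """One painted homologous segment.

    ``arm`` is ``whole`` when the token names the full chromosome.
    ``band`` carries a band-letter run as an opaque qualifier (no band
    coordinate system is imposed; painting gives arm-level resolution).
    """

    chromosome: str
    arm: str = "whole"
    band: str = ""
    qualifier: str = ""
    uncertain: bool = False
    alt_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.arm == "whole" and (self.band or self.qualifier):
            raise ValueError("a whole-chromosome segment cannot carry arm qualifiers")

    @property
    def token(self) -> str:
        return format_segment_token(self)

    def whole(self) -> "SegmentRef":
        """The same reference at whole-chromosome granularity."""
        return SegmentRef(self.chromosome, uncertain=self.uncertain)


def parse_segment_token(token: str, species: str = "") -> SegmentRef:
    """Parse one segment token such as ``"17q-dist"`` or ``"16p?"``.

    ``species`` is used only to contextualise error messages.
    """
    text = token.strip()
    if not text:
        raise SegmentParseError(token, reason="empty token")
    m = _TOKEN_RE.match(text)
    if m is None:
        where = f" in {species} column" if species else ""
        raise SegmentParseError(token, reason=f"does not match the grammar{where}")
    arm = m.group("arm") or "whole"
    band = m.group("band") or ""
    qual = m.group("qual") or ""
    if arm == "whole" and (band or qual):
        # e.g. "7-dist" without an arm letter: not produced by the tables
        raise SegmentParseError(token, reason="qualifier without an arm")
    return SegmentRef(
        chromosome=m.group("label"),
        arm=arm,
        band=band,
        qualifier=qual,
        uncertain=m.group("unc") is not None,
        alt_label=m.group("alt"),
    )


def format_segment_token(ref: SegmentRef) -> str:
    """Serialise a :class:`SegmentRef` back to its table token (lossless)."""
    out = ref.chromosome
    if ref.arm != "whole":
        out += ref.arm
    out += ref.band
    if ref.qualifier:
        out += "-" + ref.qualifier
    if ref.uncertain:
        out += "?"
    if ref.alt_label is not None:
        out += f" ({ref.alt_label})"
    return out


# --- cells -----------------------------------------------------------------

FLAGS = ("inv", "inv/cr")
_SEPS = (" + ", ", ", "/")


@dataclass(frozen=True)
class Cell:
    """A parsed homology-table cell: segment refs, separator style, flag.

    ``unresolved`` is True for a bare ``?`` cell (no chromosome named).
    ``sep`` records which joiner the source used so the cell serialises
    byte-identically.
    """

    refs: Tuple[SegmentRef, ...] = ()
    sep: str = ", "
    flag: Optional[str] = None
    unresolved: bool = False

    @property
    def chromosomes(self) -> Tuple[str, ...]:
        return tuple(r.chromosome for r in self.refs)

    def certain_refs(self) -> Tuple[SegmentRef, ...]:
        return tuple(r for r in self.refs if not r.uncertain)


def parse_cell(text: str, species: str = "") -> Cell:
    """Parse a full table cell, e.g. ``"1, 16p?"`` or ``"3 inv/cr"``."""
    body = text.strip()
    if not body:
        raise SegmentParseError(text, reason="empty cell")
    if body == "?":
        return Cell(unresolved=True)
    flag: Optional[str] = None
    for f in ("inv/cr", "inv"):  # longest first: "inv/cr" contains "inv"
        if body.endswith(" " + f):
            flag = f
            body = body[: -len(f) - 1].rstrip()
            break
    sep = ", "
    if " + " in body:
        sep = " + "
    elif "," in body:
        sep = ", "
    elif "/" in body:
        sep = "/"
    if sep == ", ":
        parts = [p.strip() for p in body.split(",")]
    else:
        parts = [p.strip() for p in body.split(sep.strip() if sep == "/" else sep)]
    if len(parts) == 1:
        sep = ", "  # canonical, irrelevant for single-token cells
    refs = []
    for i, part in enumerate(parts):
        try:
            refs.append(parse_segment_token(part, species))
        except SegmentParseError as err:
            raise SegmentParseError(text, position=i, reason=str(err)) from err
    return Cell(refs=tuple(refs), sep=sep, flag=flag)


def format_cell(cell: Cell) -> str:
    if cell.unresolved:
        return "?"
    body = cell.sep.join(format_segment_token(r) for r in cell.refs)
    if cell.flag:
        body += " " + cell.flag
    return body


def refs_at_chromosome_level(refs: Iterable[SegmentRef]) -> Tuple[str, ...]:
    """Distinct chromosome labels, in first-appearance order."""
    seen: dict[str, None] = {}
    for r in refs:
        seen.setdefault(r.chromosome, None)
    return tuple(seen)
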