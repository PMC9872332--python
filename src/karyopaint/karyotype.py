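"""Karyotype bookkeeping: diploid number (2n) and autosomal fundamental number (FN).

A karyotype is a species' chromosome complement.  Each autosome entry
represents one homologous *pair*; the sex system contributes one further
pair.  Morphology classes follow standard cytogenetic usage: metacentric,
submetacentric and subtelocentric chromosomes are *bi-armed* (two arms),
acrocentrics are one-armed.  Two extra classes encode what comparative
tables actually state: ``biarmed`` (bi-armed, centromere class not
specified) and ``unknown`` (morphology not reported — FN not derivable).

FN here is the **autosomal** fundamental number: twice the per-pair arm
sum over autosome pairs, sex chromosomes excluded.  This is the only
convention under which the Amazonian manatee (TIN, 2n=56 with 19
bi-armed + 8 acrocentric autosome pairs) and the Florida manatee (TML,
2n=48 with 23 bi-armed pairs) both yield FN=92.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

__all__ = [
    "ChromosomeDef",
    "Karyotype",
    "Finding",
    "MORPHOLOGIES",
    "BIARMED_MORPHOLOGIES",
    "compute_diploid_number",
    "compute_fundamental_number",
    "validate_karyotype",
    "read_karyotype",
    "write_karyotype",
]

MORPHOLOGIES = (
    "metacentric",
    "submetacentric",
    "subtelocentric",
    "acrocentric",
    "biarmed",
    "unknown",
)
BIARMED_MORPHOLOGIES = ("metacentric", "submetacentric", "subtelocentric", "biarmed")
CATEGORIES = ("autosome", "X", "Y")


class KaryotypeError(ValueError):
    pass


@dataclass(frozen=True)
class Finding:
    """A validation finding: machine-checkable, never raised."""

    code: str
    message: str
    subject: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.subject}: {self.message}" if self.subject else f"[{self.code}] {self.message}"


@dataclass(frozen=True)
class ChromosomeDef:
    label: str
    category: str = "autosome"
    morphology: str = "unknown"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise KaryotypeError(f"bad category {self.category!r} for chromosome {self.label!r}")
        if self.morphology not in MORPHOLOGIES:
            raise KaryotypeError(f"bad morphology {self.morphology!r} for chromosome {self.label!r}")

    @property
    def biarmed(self) -> bool:
        if self.morphology == "unknown":
            raise KaryotypeError(f"morphology unknown for chromosome {self.label!r}")
        return self.morphology in BIARMED_MORPHOLOGIES

    @property
    def arms(self) -> int:
        return 2 if self.biarmed else 1


@dataclass(frozen=True)
class Karyotype:
    species_code: str
    chromosomes: Tuple[ChromosomeDef, ...]
    sex_system: str = "XX/XY"
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))

    @property
    def autosomes(self) -> Tuple[ChromosomeDef, ...]:
        return tuple(c for c in self.chromosomes if c.category == "autosome")

    def get(self, label: str) -> Optional[ChromosomeDef]:
        for c in self.chromosomes:
            if c.label == label:
                return c
        return None

    @property
    def diploid_number(self) -> int:
        return compute_diploid_number(self)

    @property
    def fundamental_number(self) -> int:
        return compute_fundamental_number(self)


def compute_diploid_number(k: Karyotype) -> int:
    """2n = 2 x (autosome pairs) + 2 for the sex pair."""
    if not k.chromosomes:
        raise KaryotypeError(f"karyotype {k.species_code!r} has no chromosomes")
    if not k.autosomes:
        raise KaryotypeError(f"karyotype {k.species_code!r} has no autosome pairs")
    if not k.sex_system:
        raise KaryotypeError(f"karyotype {k.species_code!r} has no declared sex system")
    return 2 * len(k.autosomes) + 2


def compute_fundamental_number(k: Karyotype) -> int:
    """Autosomal FN: 2 x sum of arms over autosome pairs (sex pair excluded)."""
    if not k.chromosomes:
        raise KaryotypeError(f"karyotype {k.species_code!r} has no chromosomes")
    total = 0
    for c in k.autosomes:
        if c.morphology == "unknown":
            raise KaryotypeError(
                f"cannot derive FN for {k.species_code}: morphology unknown for chromosome {c.label!r}"
            )
        total += c.arms
    return 2 * total


def validate_karyotype(k: Karyotype) -> List[Finding]:
    """Check label uniqueness, morphology presence, and printed-vs-derived 2n/FN.

    Printed values are carried in ``k.metadata`` under ``printed_2n`` /
    ``printed_FN``.  Mismatches are findings, not errors: the source
    literature itself disagrees (an older census gives TIN FN=82 where
    the current morphology census yields 92), and such conflicts should
    surface, not abort.
    """
    findings: List[Finding] = []
    seen: dict[str, int] = {}
    for c in k.chromosomes:
        seen[c.label] = seen.get(c.label, 0) + 1
    for label, n in seen.items():
        if n > 1:
            findings.append(Finding("duplicate-label", f"chromosome label appears {n} times", label))
    missing = [c.label for c in k.autosomes if c.morphology == "unknown"]
    derivable_fn = not missing
    if missing and "printed_FN" in k.metadata:
        findings.append(
            Finding("missing-morphology", f"FN not derivable; morphology unknown for {', '.join(missing)}", k.species_code)
        )
    printed_2n = k.metadata.get("printed_2n")
    if printed_2n is not None and k.chromosomes:
        derived = compute_diploid_number(k)
        if int(printed_2n) != derived:
            findings.append(
                Finding("2n-mismatch", f"printed 2n={printed_2n} but derived 2n={derived}", k.species_code)
            )
    printed_fn = k.metadata.get("printed_FN")
    if printed_fn is not None and derivable_fn:
        derived = compute_fundamental_number(k)
        if int(printed_fn) != derived:
            findings.append(
                Finding("FN-mismatch", f"printed FN={printed_fn} but derived FN={derived}", k.species_code)
            )
    return findings


# --- karyotype definition file --------------------------------------------
#
# Structured text, UTF-8: "# key: value" header lines, then a tab-separated
# table with columns label / category / morphology.


def read_karyotype(source: io.TextIOBase | str) -> Karyotype:
    if isinstance(source, str):
        source = io.StringIO(source)
    meta: dict = {}
    rows: List[ChromosomeDef] = []
    reader = csv.reader(source, delimiter="\t")
    header_seen = False
    for row in reader:
        if not row or not any(cell.strip() for cell in row):
            continue
        first = row[0].strip()
        if first.startswith("#"):
            key, _, value = first.lstrip("#").partition(":")
            meta[key.strip()] = value.strip()
            continue
        if not header_seen:
            if [c.strip() for c in row[:3]] != ["label", "category", "morphology"]:
                raise KaryotypeError(f"bad karyotype table header: {row!r}")
            header_seen = True
            continue
        label, category, morphology = (c.strip() for c in row[:3])
        rows.append(ChromosomeDef(label, category, morphology))
    if "species_code" not in meta:
        raise KaryotypeError("karyotype file missing species_code header")
    metadata = {}
    for key in ("printed_2n", "printed_FN"):
        if key in meta:
            metadata[key] = int(meta[key])
    if "provenance" in meta:
        metadata["provenance"] = meta["provenance"]
    return Karyotype(
        species_code=meta["species_code"],
        chromosomes=tuple(rows),
        sex_system=meta.get("sex_system", "XX/XY"),
        metadata=metadata,
    )


def write_karyotype(k: Karyotype) -> str:
    out = [f"# species_code: {k.species_code}", f"# sex_system: {k.sex_system}"]
    for key in ("printed_2n", "printed_FN", "provenance"):
        if key in k.metadata:
            out.append(f"# {key}: {k.metadata[key]}")
    out.append("label\tcategory\tmorphology")
    for c in k.chromosomes:
        out.append(f"{c.label}\t{c.category}\t{c.morphology}")
    return "\n".join(out) + "\n"
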