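"""Core domain types for Y-chromosome STR and SNP profiles.

Y-STR alleles are named by repeat count; microvariant alleles carry a
fractional part (e.g. ``38.2`` for a partial repeat) which is restricted to
the steps actually observed in capillary-electrophoresis nomenclature
(.1/.2/.3).  A locus call is an *ordered list* of alleles: one entry for a
normal single-copy locus, two for the duplicated multi-copy loci
(DYS385a/b, DYF387S1a/b, DYS527a/b), more in the presence of copy-number
variants, and an empty list for a null (dropped-out) call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "AlleleCall",
    "STRProfile",
    "SNPState",
    "SNPProfile",
    "parse_allele",
    "format_allele",
]

_ALLOWED_FRACTIONS = (0, 1, 2, 3)


class AlleleCall(float):
    """A single STR allele call, stored as a decimal repeat count.

    Behaves as a float (so sorting and repeat arithmetic work directly) but
    validates on construction: the value must be positive and its fractional
    part must be one of the observed microvariant steps .0/.1/.2/.3, to one
    decimal digit.
    """

    __slots__ = ()

    def __new__(cls, value: float) -> "AlleleCall":
        v = round(float(value), 1)
        if v <= 0:
            raise ValueError(f"allele repeat value must be positive, got {value!r}")
        tenth = round(v * 10) % 10
        if tenth not in _ALLOWED_FRACTIONS:
            raise ValueError(
                f"allele fractional part must be .0/.1/.2/.3, got {value!r}"
            )
        return super().__new__(cls, v)

    @property
    def is_microvariant(self) -> bool:
        return round(float(self) * 10) % 10 != 0

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"AlleleCall({format_allele(self)})"


def parse_allele(token: str) -> AlleleCall:
    """Parse one allele token (e.g. ``"17"`` or ``"38.2"``)."""
    token = token.strip()
    try:
        return AlleleCall(float(token))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"unparseable allele token {token!r}") from exc


def format_allele(value: float) -> str:
    """Render an allele the way forensic tables print it: ``17`` or ``38.2``."""
    v = round(float(value), 1)
    if round(v * 10) % 10 == 0:
        return str(int(round(v)))
    return f"{v:.1f}"


@dataclass
class STRProfile:
    """One male sample's Y-STR allele calls.

    ``calls`` maps canonical locus name to a sorted (ascending) list of
    :class:`AlleleCall`; an empty list denotes a null call.
    """

    sample_id: str
    population: str
    calls: dict[str, list[AlleleCall]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, alleles in self.calls.items():
            self.calls[locus] = sorted(AlleleCall(a) for a in alleles)

    def get(self, locus: str) -> list[AlleleCall]:
        return self.calls.get(locus, [])

    def is_null(self, locus: str) -> bool:
        return len(self.get(locus)) == 0


class SNPState(str, Enum):
    """Binary-marker state: ancestral, derived, or no-call."""

    ANCESTRAL = "A"
    DERIVED = "D"
    NO_CALL = "N"


@dataclass
class SNPProfile:
    """One sample's Y-SNP marker states over a haplogroup-defining panel."""

    sample_id: str
    population: str
    states: dict[str, SNPState] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = {m: SNPState(s) for m, s in self.states.items()}

    def state(self, marker: str) -> SNPState:
        return self.states.get(marker, SNPState.NO_CALL)
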