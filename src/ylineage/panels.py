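"""Y-STR panel (kit) definitions and locus-name normalization.

Four commercial genotyping systems are built in:

========================  =====  ============================================
panel                     loci   multi-copy loci
========================  =====  ============================================
``yfiler``                17     DYS385a/b
``ppy23``                 23     DYS385a/b
``yfiler_plus``           27     DYS385a/b, DYF387S1a/b
``yfiler_platinum``       38     DYS385a/b, DYF387S1a/b, DYS527a/b
========================  =====  ============================================

A duplicated locus such as DYS385a/b is a single column whose cell holds
the (unordered) pair of alleles; it counts as two loci toward the kit
sizes above.  Each smaller panel is a subset of the 38-locus panel, so a
table typed on the large system can be re-scored under any of the others.
Published tables spell locus names inconsistently (``DYS389II`` vs
``DYS389-2``, ``DYF387S1`` vs ``DYS387S1``, ``Y-GATA-H4`` vs ``YGATAH4``);
a built-in alias map normalizes these case-insensitively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Panel",
    "normalize_locus",
    "get_panel",
    "builtin_panels",
    "YFILER",
    "PPY23",
    "YFILER_PLUS",
    "YFILER_PLATINUM",
    "MULTI_COPY_LOCI",
]

MULTI_COPY_LOCI = ("DYS385a/b", "DYF387S1a/b", "DYS527a/b")


@dataclass(frozen=True)
class Panel:
    """An ordered set of Y-STR loci with expected copy number per locus."""

    name: str
    loci: tuple[str, ...]
    expected_copies: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        copies = {
            locus: self.expected_copies.get(
                locus, 2 if locus in MULTI_COPY_LOCI else 1
            )
            for locus in self.loci
        }
        object.__setattr__(self, "loci", tuple(self.loci))
        object.__setattr__(self, "expected_copies", copies)

    @property
    def n_loci(self) -> int:
        """Total locus count, with duplicated loci counting twice."""
        return sum(self.expected_copies.values())

    def __len__(self) -> int:
        return len(self.loci)

    def __contains__(self, locus: str) -> bool:
        return locus in self.expected_copies

    def single_copy_loci(self) -> tuple[str, ...]:
        return tuple(l for l in self.loci if self.expected_copies[l] == 1)

    def subset(self, loci) -> "Panel":
        """Restrict to the given loci (panel order preserved); idempotent."""
        keep = {normalize_locus(l) for l in loci}
        missing = keep - set(self.loci)
        if missing:
            raise KeyError(f"loci not in panel {self.name!r}: {sorted(missing)}")
        kept = tuple(l for l in self.loci if l in keep)
        return Panel(
            name=self.name,
            loci=kept,
            expected_copies={l: self.expected_copies[l] for l in kept},
        )


_SINGLE_YFILER = (
    "DYS19", "DYS389I", "DYS389II", "DYS390", "DYS391", "DYS392", "DYS393",
    "DYS437", "DYS438", "DYS439", "DYS448", "DYS456", "DYS458", "DYS635",
    "YGATAH4",
)

_YFILER_LOCI = _SINGLE_YFILER + ("DYS385a/b",)

_PPY23_LOCI = _YFILER_LOCI + (
    "DYS481", "DYS533", "DYS549", "DYS570", "DYS576", "DYS643",
)

_YFILER_PLUS_LOCI = _YFILER_LOCI + (
    "DYS449", "DYS460", "DYS481", "DYS518", "DYS533", "DYS570", "DYS576",
    "DYS627", "DYF387S1a/b",
)

_YFILER_PLATINUM_LOCI = _YFILER_PLUS_LOCI + (
    "DYS444", "DYS447", "DYS522", "DYS549", "DYS596", "DYS612", "DYS622",
    "DYS643", "DYS645", "DYS527a/b",
)


def _panel(name: str, loci: tuple[str, ...]) -> Panel:
    return Panel(name=name, loci=loci)


YFILER = _panel("yfiler", _YFILER_LOCI)
PPY23 = _panel("ppy23", _PPY23_LOCI)
YFILER_PLUS = _panel("yfiler_plus", _YFILER_PLUS_LOCI)
YFILER_PLATINUM = _panel("yfiler_platinum", _YFILER_PLATINUM_LOCI)

_BUILTINS = {
    "yfiler": YFILER,
    "ppy23": PPY23,
    "yfiler_plus": YFILER_PLUS,
    "yfiler_platinum": YFILER_PLATINUM,
}

_ALIASES = {
    "DYS389-1": "DYS389I",
    "DYS3891": "DYS389I",
    "DYS389-2": "DYS389II",
    "DYS3892": "DYS389II",
    "YGATA-H4": "YGATAH4",
    "Y-GATA-H4": "YGATAH4",
    "GATAH4": "YGATAH4",
    "GATA-H4": "YGATAH4",
    # merged multi-copy columns under their various spellings
    "DYS385": "DYS385a/b",
    "DYS385A/B": "DYS385a/b",
    "DYS385AB": "DYS385a/b",
    "DYF387S1": "DYF387S1a/b",
    "DYF387S1A/B": "DYF387S1a/b",
    # some reports spell DYF387S1 as DYS387S1
    "DYS387S1": "DYF387S1a/b",
    "DYS387S1A/B": "DYF387S1a/b",
    "DYS527": "DYS527a/b",
    "DYS527A/B": "DYS527a/b",
}

_CANONICAL = {l.upper(): l for l in _YFILER_PLATINUM_LOCI}


def normalize_locus(name: str) -> str:
    """Map a locus name to its canonical spelling (case-insensitive).

    Raises ``KeyError`` for names outside the known 38-locus universe plus
    the derived network locus DYS389b.
    """
    key = name.strip().replace(" ", "").upper()
    key = _ALIASES.get(key, key)
    key = key.upper()
    if key in _CANONICAL:
        return _CANONICAL[key]
    if key in _ALIASES:  # alias resolved to canonical mixed-case form
        return _ALIASES[key]
    if key == "DYS389B":
        return "DYS389b"
    raise KeyError(f"unknown Y-STR locus name: {name!r}")


def get_panel(name: str) -> Panel:
    """Look up a built-in panel by name."""
    key = name.strip().lower().replace("-", "_").replace(" ", "_")
    if key not in _BUILTINS:
        raise KeyError(f"unknown panel {name!r}; built-ins: {sorted(_BUILTINS)}")
    return _BUILTINS[key]


def builtin_panels() -> dict[str, Panel]:
    return dict(_BUILTINS)
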