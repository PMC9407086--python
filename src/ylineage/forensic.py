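"""Forensic summary statistics for Y-STR data.

Per-locus statistics
--------------------
Gene diversity (the haploid heterozygosity analogue) at a locus with
allele frequencies :math:`p_i` estimated from :math:`n` samples:

.. math:: GD = \\frac{n}{n-1}\\left(1 - \\sum_i p_i^2\\right)

Multi-copy loci (DYS385a/b etc.) are scored on the sorted allele pair, each
distinct pair counting as one "allele" of the locus.

Panel-level statistics
----------------------
From the haplotype frequency spectrum of a population under a panel —
``spectrum[k]`` = number of distinct haplotypes observed exactly ``k``
times among ``n`` complete haplotypes — the four standard forensic
parameters are

* match probability ``MP = Σ_k spectrum[k]·(k/n)²``,
* haplotype diversity ``HD = (n/(n−1))·(1 − MP)``,
* discrimination capacity ``DC = H/n`` with ``H`` the number of distinct
  haplotypes,
* fraction of unique haplotypes ``FUH = spectrum[1]/n``.

All values are kept at full precision; forensic tables conventionally
print them rounded half-up to five decimals (:func:`round_half_up`).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

from .panels import Panel
from .profiles import AlleleCall, STRProfile, format_allele

logger = logging.getLogger(__name__)

__all__ = [
    "LocusFrequencies",
    "HaplotypeSpectrum",
    "ForensicParams",
    "VariantReport",
    "locus_frequencies",
    "gene_diversity",
    "haplotype_spectrum",
    "forensic_parameters",
    "variant_screen",
    "variant_haplogroup_crosstab",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, as forensic tables print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


AlleleKey = tuple[AlleleCall, ...]


def _allele_key(calls: list[AlleleCall]) -> AlleleKey:
    return tuple(sorted(calls))


def format_allele_key(key: AlleleKey) -> str:
    return "-".join(format_allele(a) for a in key)


@dataclass
class LocusFrequencies:
    """Observed allele (or allele-pair) frequencies at one locus."""

    locus: str
    n: int
    freqs: dict[AlleleKey, float]

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if self.freqs and abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.locus}: frequencies sum to {total}, not 1")


def locus_frequencies(profiles: list[STRProfile], locus: str) -> LocusFrequencies:
    """Tabulate allele frequencies at a locus, ignoring null calls.

    For multi-copy loci the key is the sorted allele list, so each distinct
    pair (or CNV-expanded list) counts as one haplotype of the locus.
    """
    counts: Counter[AlleleKey] = Counter()
    for p in profiles:
        calls = p.get(locus)
        if calls:
            counts[_allele_key(calls)] += 1
    n = sum(counts.values())
    if n == 0:
        raise ValueError(f"no non-null calls at locus {locus}")
    return LocusFrequencies(
        locus=locus, n=n, freqs={k: c / n for k, c in counts.items()}
    )


def gene_diversity(freqs: LocusFrequencies) -> float:
    """Unbiased gene diversity ``(n/(n−1))(1 − Σp²)`` at one locus."""
    if freqs.n < 2:
        raise ValueError("gene diversity requires n >= 2 samples")
    if not freqs.freqs:
        raise ValueError("empty frequency table")
    sum_sq = sum(p * p for p in freqs.freqs.values())
    return (freqs.n / (freqs.n - 1)) * (1.0 - sum_sq)


@dataclass
class HaplotypeSpectrum:
    """Haplotype frequency spectrum of one population under one panel.

    ``spectrum[k]`` counts distinct haplotypes seen exactly ``k`` times;
    ``n`` is the number of samples with complete haplotypes, so
    ``Σ k·spectrum[k] = n``.
    """

    panel: str
    population: str
    n: int
    spectrum: dict[int, int]

    def __post_init__(self) -> None:
        self.spectrum = {
            int(k): int(v) for k, v in sorted(self.spectrum.items()) if v > 0
        }
        if any(k < 1 for k in self.spectrum):
            raise ValueError("spectrum keys must be positive multiplicities")
        total = sum(k * v for k, v in self.spectrum.items())
        if total != self.n:
            raise ValueError(
                f"spectrum mass {total} does not match sample count n={self.n}"
            )

    @property
    def n_haplotypes(self) -> int:
        """Number of distinct haplotypes H."""
        return sum(self.spectrum.values())

    @classmethod
    def from_counts(cls, panel: str, population: str, spectrum: dict[int, int]
                    ) -> "HaplotypeSpectrum":
        n = sum(k * v for k, v in spectrum.items())
        return cls(panel=panel, population=population, n=n, spectrum=spectrum)


def haplotype_key(profile: STRProfile, panel: Panel) -> tuple[AlleleKey, ...] | None:
    """Panel haplotype identity: tuple of sorted allele lists over the panel
    loci, or ``None`` if any panel locus is null."""
    key = []
    for locus in panel.loci:
        calls = profile.get(locus)
        if not calls:
            return None
        key.append(_allele_key(calls))
    return tuple(key)


def haplotype_spectrum(profiles: list[STRProfile], panel: Panel,
                       population: str | None = None) -> HaplotypeSpectrum:
    """Count the haplotype frequency spectrum of one population.

    Samples with a null call at any panel locus are excluded (and logged);
    variant-bearing samples are kept — their haplotypes are simply
    distinct.
    """
    if not profiles:
        raise ValueError("empty profile list")
    if population is None:
        population = profiles[0].population
    counts: Counter = Counter()
    for p in profiles:
        key = haplotype_key(p, panel)
        if key is None:
            logger.info(
                "sample %s excluded from %s spectrum (null call)", p.sample_id, panel.name
            )
            continue
        counts[key] += 1
    if not counts:
        raise ValueError(f"no complete haplotypes under panel {panel.name}")
    spectrum = Counter(counts.values())
    n = sum(counts.values())
    return HaplotypeSpectrum(
        panel=panel.name, population=population, n=n, spectrum=dict(spectrum)
    )


@dataclass
class ForensicParams:
    """The four forensic parameters of a haplotype spectrum."""

    n: int
    H: int
    FUH: float
    HD: float
    MP: float
    DC: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.FUH <= self.DC <= 1.0):
            raise ValueError("expected 0 <= FUH <= DC <= 1")
        if not (1.0 / self.n <= self.MP <= 1.0 + 1e-12):
            raise ValueError("expected 1/n <= MP <= 1")
        if abs(self.HD - (self.n / (self.n - 1)) * (1.0 - self.MP)) > 1e-12:
            raise ValueError("HD inconsistent with MP")

    def rounded(self, ndigits: int = 5) -> dict[str, float]:
        """Display rounding as printed in forensic parameter tables."""
        return {
            "n": self.n,
            "H": self.H,
            "FUH": round_half_up(self.FUH, ndigits),
            "HD": round_half_up(self.HD, ndigits),
            "MP": round_half_up(self.MP, ndigits),
            "DC": round_half_up(self.DC, ndigits),
        }


def forensic_parameters(spectrum: HaplotypeSpectrum) -> ForensicParams:
    """Compute FUH, HD, MP and DC from a haplotype frequency spectrum.

    Intermediate arithmetic is exact (rational), so printed-precision
    comparisons are free of floating-point accumulation error.
    """
    n = spectrum.n
    if n < 2:
        raise ValueError("forensic parameters require n >= 2")
    H = spectrum.n_haplotypes
    mp = sum(
        Fraction(c) * Fraction(k, n) ** 2 for k, c in spectrum.spectrum.items()
    )
    hd = Fraction(n, n - 1) * (1 - mp)
    return ForensicParams(
        n=n,
        H=H,
        FUH=spectrum.spectrum.get(1, 0) / n,
        HD=float(hd),
        MP=float(mp),
        DC=H / n,
    )


@dataclass
class VariantReport:
    """Screen results: microvariants, copy-number variants, null calls."""

    microvariants: list[tuple[str, str, AlleleKey]] = field(default_factory=list)
    cnvs: list[tuple[str, str, AlleleKey]] = field(default_factory=list)
    nulls: list[tuple[str, str]] = field(default_factory=list)


def variant_screen(profiles: list[STRProfile], panel: Panel) -> VariantReport:
    """Screen profiles for microvariants, CNVs and null alleles.

    * microvariant — any allele with a nonzero fractional part;
    * CNV — more alleles at a locus than the panel's expected copy number
      (a CNV list containing a fractional allele is listed under both);
    * null — zero alleles at a panel locus.

    The report is sorted by locus (panel order) then sample.
    """
    micro, cnvs, nulls = [], [], []
    order = {locus: i for i, locus in enumerate(panel.loci)}
    for p in profiles:
        for locus in panel.loci:
            calls = p.get(locus)
            if not calls:
                nulls.append((p.sample_id, locus))
                continue
            key = _allele_key(calls)
            if any(a.is_microvariant for a in calls):
                micro.append((p.sample_id, locus, key))
            if len(calls) > panel.expected_copies[locus]:
                cnvs.append((p.sample_id, locus, key))
    sort_key = lambda rec: (order[rec[1]], rec[0])
    return VariantReport(
        microvariants=sorted(micro, key=sort_key),
        cnvs=sorted(cnvs, key=sort_key),
        nulls=sorted(nulls, key=sort_key),
    )


def variant_haplogroup_crosstab(
    report: VariantReport,
    calls: dict[str, str],
    locus: str,
    fraction: float,
    clade: str,
    tree=None,
) -> dict[tuple[str, str], int]:
    """2×2 carrier × clade-membership contingency counts.

    A *carrier* has a microvariant at *locus* whose fractional offset is
    *fraction* (e.g. ``0.2`` for the DYS518 ``.2`` alleles).  Membership in
    *clade* is assessed on the haplogroup label in *calls*: via descent in
    *tree* when given, otherwise by exact label or prefix match.  The
    sample universe is the key set of *calls*; a carrier without a
    haplogroup call is an error.

    Returns a mapping with keys ``(carrier|non_carrier, in_clade|out_clade)``.
    """
    tenth = round(fraction * 10)
    carriers = set()
    for sample, loc, key in report.microvariants:
        if loc == locus and any(
            round(float(a) * 10) % 10 == tenth for a in key
        ):
            carriers.add(sample)
    missing = carriers - set(calls)
    if missing:
        raise KeyError(f"no haplogroup call for carrier samples: {sorted(missing)}")

    if tree is not None:
        members = set(tree.clade_labels(clade))
        in_clade = lambda label: label in members
    else:
        in_clade = lambda label: label == clade or label.startswith(clade)

    table = {
        ("carrier", "in_clade"): 0,
        ("carrier", "out_clade"): 0,
        ("non_carrier", "in_clade"): 0,
        ("non_carrier", "out_clade"): 0,
    }
    for sample, label in calls.items():
        row = "carrier" if sample in carriers else "non_carrier"
        col = "in_clade" if in_clade(label) else "out_clade"
        table[(row, col)] += 1
    return table
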