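"""Bundled published summary tables for two Shanghai Han populations.

A forensic population study of Han males from the Pudong district
(n = 689) and Chongming Island (n = 530), typed on the 38-locus Yfiler
Platinum system, published its haplotype frequency spectra under four
commercial panels and its Y-SNP haplogroup frequency lists.  Those
summary tables are bundled here as worked-example inputs: the spectra
feed :func:`ylineage.forensic.forensic_parameters` and the haplogroup
percent lists feed :func:`ylineage.haplogroups.clade_frequency`.

``SHANGHAI_SPECTRA[(population, panel)]`` maps multiplicity ``k`` to the
number of distinct haplotypes observed exactly ``k`` times.
``SHANGHAI_HAPLOGROUP_PERCENT[population]`` maps called haplogroup label
to its printed percent frequency (two decimals; O2a1 in Chongming was
printed with one).
"""

from __future__ import annotations

from .forensic import HaplotypeSpectrum
from .haplogroups import FrequencyVector

__all__ = [
    "SHANGHAI_SPECTRA",
    "SHANGHAI_SAMPLE_SIZES",
    "SHANGHAI_HAPLOGROUP_PERCENT",
    "shanghai_spectrum",
    "shanghai_haplogroup_vector",
]

SHANGHAI_SAMPLE_SIZES = {"Pudong": 689, "Chongming": 530}

SHANGHAI_SPECTRA: dict[tuple[str, str], dict[int, int]] = {
    ("Pudong", "yfiler"): {1: 573, 2: 30, 3: 9, 4: 6, 5: 1},
    ("Chongming", "yfiler"): {1: 388, 2: 27, 3: 9, 4: 3, 5: 3, 6: 3, 7: 1, 9: 1},
    ("Pudong", "ppy23"): {1: 630, 2: 26, 3: 1, 4: 1},
    ("Chongming", "ppy23"): {1: 462, 2: 15, 3: 6, 4: 2, 5: 1, 7: 1},
    ("Pudong", "yfiler_plus"): {1: 657, 2: 16},
    ("Chongming", "yfiler_plus"): {1: 508, 2: 8, 3: 2},
    ("Pudong", "yfiler_platinum"): {1: 669, 2: 10},
    ("Chongming", "yfiler_platinum"): {1: 522, 2: 4},
}

SHANGHAI_HAPLOGROUP_PERCENT: dict[str, dict[str, float]] = {
    "Chongming": {
        "C2": 7.17, "C": 0.19, "D1a1a1": 0.75, "D": 0.19,
        "N": 9.06, "N1a1": 4.53,
        "O1a": 29.62, "O1b2": 0.19, "O1b": 4.15,
        "O2a1": 13.4, "O2a2a1a2": 3.77, "O2a2b1a1": 9.43, "O2a2b": 14.15,
        "O2a2": 1.13, "O2": 0.75, "QR": 1.51,
    },
    "Pudong": {
        "C2": 6.97, "D1a1a1": 1.31,
        "N": 4.79, "N1a1": 2.47,
        "O1a": 24.53, "O1b2": 0.15, "O1b": 6.82,
        "O2a1": 22.35, "O2a2a1a2": 2.61, "O2a2b1a1": 10.89, "O2a2b": 10.89,
        "O2a2": 1.89, "O2": 2.18, "QR": 2.18,
    },
}


def shanghai_spectrum(population: str, panel: str) -> HaplotypeSpectrum:
    """The published haplotype spectrum for one population × panel."""
    key = (population, panel)
    if key not in SHANGHAI_SPECTRA:
        raise KeyError(f"no bundled spectrum for {key}")
    return HaplotypeSpectrum.from_counts(
        panel=panel, population=population, spectrum=dict(SHANGHAI_SPECTRA[key])
    )


def shanghai_haplogroup_vector(population: str) -> FrequencyVector:
    """The published haplogroup percent list for one population."""
    if population not in SHANGHAI_HAPLOGROUP_PERCENT:
        raise KeyError(f"no bundled haplogroup table for {population!r}")
    return FrequencyVector(
        population=population,
        percent=dict(SHANGHAI_HAPLOGROUP_PERCENT[population]),
        n=SHANGHAI_SAMPLE_SIZES[population],
    )
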