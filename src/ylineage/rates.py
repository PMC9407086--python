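"""Default per-locus Y-STR mutation rates (per generation).

Values are representative locus-wise estimates in the range reported by
large father–son pair studies (roughly 4e-4 to 7e-2 per generation):
slow loci such as DYS438/DYS645 sit near 4e-4, ordinary tetranucleotide
loci near 2e-3, and the rapidly mutating loci (DYS570, DYS576, DYS518,
DYS627, DYS449, DYS612) above 1e-2.  They drive both the simulator and
the mutation-rate-derived locus weights of the median-joining network;
either use accepts a user-supplied table instead.

Multi-copy loci carry a single rate applied to each copy independently.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["DEFAULT_MUTATION_RATES", "read_rate_table", "write_rate_table"]

DEFAULT_MUTATION_RATES: dict[str, float] = {
    "DYS19": 2.2e-3,
    "DYS389I": 2.5e-3,
    "DYS389II": 2.8e-3,
    "DYS390": 2.1e-3,
    "DYS391": 2.6e-3,
    "DYS392": 5.0e-4,
    "DYS393": 1.1e-3,
    "DYS437": 1.2e-3,
    "DYS438": 4.0e-4,
    "DYS439": 5.1e-3,
    "DYS448": 1.4e-3,
    "DYS456": 4.2e-3,
    "DYS458": 6.4e-3,
    "DYS635": 3.5e-3,
    "YGATAH4": 2.4e-3,
    "DYS385a/b": 2.3e-3,
    "DYS481": 5.0e-3,
    "DYS533": 3.7e-3,
    "DYS549": 3.9e-3,
    "DYS570": 1.24e-2,
    "DYS576": 1.43e-2,
    "DYS643": 1.2e-3,
    "DYS449": 1.22e-2,
    "DYS460": 5.7e-3,
    "DYS518": 1.80e-2,
    "DYS627": 1.23e-2,
    "DYF387S1a/b": 1.50e-2,
    "DYS444": 3.0e-3,
    "DYS447": 2.0e-3,
    "DYS522": 2.5e-3,
    "DYS596": 8.0e-4,
    "DYS612": 1.45e-2,
    "DYS622": 3.0e-3,
    "DYS645": 4.0e-4,
    "DYS527a/b": 1.0e-2,
    # derived network locus: rate of the long DYS389II amplicon minus the
    # contained DYS389I region, approximated by the DYS389I rate
    "DYS389b": 2.5e-3,
}


def read_rate_table(path) -> dict[str, float]:
    """Read a TSV/CSV ``locus<TAB>rate`` table into a rate mapping."""
    from .panels import normalize_locus

    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError(f"rate table {path} needs columns: locus, rate")
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        out[normalize_locus(str(row.iloc[0]))] = float(row.iloc[1])
    return out


def write_rate_table(rates: dict[str, float], path) -> None:
    pd.DataFrame(
        {"locus": list(rates), "rate": [rates[l] for l in rates]}
    ).to_csv(path, sep="\t", index=False)
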