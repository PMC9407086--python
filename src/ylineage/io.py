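"""Readers and writers for STR genotype tables, SNP marker tables, panel
definition files, and Newick trees, plus the DYS389b derived-locus
transformation.

Table dialect
-------------
STR tables are delimited text (tab for ``.tsv``/``.txt``, comma for
``.csv``) with header ``sample_id, population, <locus...>``.  A cell holds
one allele (``13``, microvariants as ``17.2``), a delimited list for
multi-copy loci or duplications (``13-17``, with ``,`` also accepted on
read), or nothing for a null call.  SNP tables share the layout with cell
values ``A`` (ancestral), ``D`` (derived), ``N``/empty (no call).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import skbio

from .panels import Panel, normalize_locus
from .profiles import (
    AlleleCall,
    SNPProfile,
    SNPState,
    STRProfile,
    format_allele,
    parse_allele,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_str_table",
    "write_str_table",
    "read_snp_table",
    "write_snp_table",
    "read_panel_file",
    "write_panel_file",
    "derive_dys389b",
    "write_newick",
    "read_newick",
]

_CELL_DELIMS = ("-", ",", "/")


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _parse_cell(cell, sample: str, locus: str) -> list[AlleleCall]:
    """Parse one genotype cell into a sorted allele list."""
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return []
    text = str(cell).strip()
    if not text or text.lower() in ("na", "nan", "null", "."):
        return []
    for delim in _CELL_DELIMS:
        if delim in text:
            tokens = [t for t in text.split(delim) if t.strip()]
            break
    else:
        tokens = [text]
    try:
        return sorted(parse_allele(t) for t in tokens)
    except ValueError as exc:
        raise ValueError(
            f"sample {sample!r}, locus {locus!r}: {exc}"
        ) from exc


def read_str_table(path, panel: Panel, delimiter: str | None = None) -> list[STRProfile]:
    """Read a wide STR genotype table, validating columns against *panel*.

    Parameters
    ----------
    path
        Delimited text file with header ``sample_id, population, <locus...>``.
    panel
        Every locus column must belong to this panel; an unknown column is
        a hard error.
    delimiter
        Field delimiter override (default: by file extension).
    """
    df = pd.read_csv(path, sep=delimiter or _sep_for(path), dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need sample_id, population and locus columns")
    locus_cols: dict[str, str] = {}
    for col in df.columns[2:]:
        try:
            canonical = normalize_locus(col)
        except KeyError as exc:
            raise ValueError(f"{path}: unknown locus column {col!r}") from exc
        if canonical not in panel:
            raise ValueError(
                f"{path}: locus column {col!r} ({canonical}) not in panel {panel.name!r}"
            )
        locus_cols[col] = canonical
    profiles = []
    for _, row in df.iterrows():
        sample = str(row.iloc[0])
        calls = {
            canonical: _parse_cell(row[col], sample, canonical)
            for col, canonical in locus_cols.items()
        }
        profiles.append(
            STRProfile(sample_id=sample, population=str(row.iloc[1]), calls=calls)
        )
    return profiles


def write_str_table(
    profiles: list[STRProfile], path, loci: list[str] | None = None,
    delimiter: str | None = None, cell_delimiter: str = "-",
) -> None:
    """Write profiles as a wide table; allele lists joined with ``-``."""
    if loci is None:
        seen: dict[str, None] = {}
        for p in profiles:
            for locus in p.calls:
                seen.setdefault(locus)
        loci = list(seen)
    rows = []
    for p in profiles:
        row = {"sample_id": p.sample_id, "population": p.population}
        for locus in loci:
            row[locus] = cell_delimiter.join(format_allele(a) for a in p.get(locus))
        rows.append(row)
    pd.DataFrame(rows, columns=["sample_id", "population", *loci]).to_csv(
        path, sep=delimiter or _sep_for(path), index=False
    )


def read_snp_table(path, delimiter: str | None = None) -> list[SNPProfile]:
    """Read a SNP marker-state table (cells A/D/N, empty = no call)."""
    df = pd.read_csv(path, sep=delimiter or _sep_for(path), dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need sample_id, population and marker columns")
    markers = list(df.columns[2:])
    profiles = []
    for _, row in df.iterrows():
        states = {}
        for m in markers:
            raw = row[m]
            text = "" if (raw is None or pd.isna(raw)) else str(raw).strip().upper()
            if text in ("", "N", "NA", "."):
                states[m] = SNPState.NO_CALL
            elif text in ("A", "D"):
                states[m] = SNPState(text)
            else:
                raise ValueError(
                    f"{path}: sample {row.iloc[0]!r}, marker {m!r}: "
                    f"invalid state {raw!r} (expected A/D/N)"
                )
        profiles.append(
            SNPProfile(sample_id=str(row.iloc[0]), population=str(row.iloc[1]), states=states)
        )
    return profiles


def write_snp_table(profiles: list[SNPProfile], path, markers: list[str] | None = None,
                    delimiter: str | None = None) -> None:
    if markers is None:
        seen: dict[str, None] = {}
        for p in profiles:
            for m in p.states:
                seen.setdefault(m)
        markers = list(seen)
    rows = []
    for p in profiles:
        row = {"sample_id": p.sample_id, "population": p.population}
        for m in markers:
            row[m] = p.state(m).value
        rows.append(row)
    pd.DataFrame(rows, columns=["sample_id", "population", *markers]).to_csv(
        path, sep=delimiter or _sep_for(path), index=False
    )


def read_panel_file(path, name: str | None = None) -> Panel:
    """Read a TSV ``locus<TAB>copies`` panel definition."""
    df = pd.read_csv(path, sep=_sep_for(path))
    loci = [normalize_locus(str(l)) for l in df.iloc[:, 0]]
    copies = {l: int(c) for l, c in zip(loci, df.iloc[:, 1])}
    bad = {l: c for l, c in copies.items() if c not in (1, 2)}
    if bad:
        raise ValueError(f"{path}: expected copy numbers in {{1,2}}, got {bad}")
    return Panel(name=name or Path(path).stem, loci=tuple(loci), expected_copies=copies)


def write_panel_file(panel: Panel, path) -> None:
    pd.DataFrame(
        {"locus": panel.loci, "copies": [panel.expected_copies[l] for l in panel.loci]}
    ).to_csv(path, sep="\t", index=False)


def derive_dys389b(profile: STRProfile) -> tuple[STRProfile, str | None]:
    """Augment a profile with the derived locus DYS389b = DYS389II − DYS389I.

    The DYS389II amplicon physically contains the DYS389I repeat block, so
    the difference isolates the distal block and removes the double
    counting when both loci enter a haplotype network.

    Returns ``(profile, flag)``.  ``flag`` is ``None`` on success; otherwise
    it describes why the sample must be excluded from network analysis
    (missing or multi-valued parent locus, fractional repeat, or a
    non-positive difference, which is biologically implausible).  The
    returned profile is augmented only when the flag is ``None``.
    """
    i_calls = profile.get("DYS389I")
    ii_calls = profile.get("DYS389II")
    for locus, calls in (("DYS389I", i_calls), ("DYS389II", ii_calls)):
        if len(calls) == 0:
            return profile, f"missing {locus}"
        if len(calls) > 1:
            return profile, f"multi-valued {locus}: {[format_allele(a) for a in calls]}"
        if calls[0].is_microvariant:
            return profile, f"fractional {locus} allele {format_allele(calls[0])}"
    diff = float(ii_calls[0]) - float(i_calls[0])
    if diff <= 0:
        return profile, f"implausible DYS389b={format_allele(diff) if diff else '0'}"
    calls = dict(profile.calls)
    calls["DYS389b"] = [AlleleCall(diff)]
    return (
        STRProfile(sample_id=profile.sample_id, population=profile.population, calls=calls),
        None,
    )


def write_newick(tree: skbio.TreeNode, path) -> None:
    """Serialize a tree (with branch lengths) to standard Newick text.

    Negative branch lengths (possible from neighbor joining on
    non-additive distances) are written as-is but logged.
    """
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            logger.warning(
                "negative branch length %.6g at node %r written as-is",
                node.length, node.name,
            )
    tree.write(str(path), format="newick")


def read_newick(path) -> skbio.TreeNode:
    return skbio.TreeNode.read(str(path), format="newick")
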