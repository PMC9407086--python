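"""Hierarchical Y-SNP haplogroup calling and frequency analysis.

The Y chromosome's non-recombining region accumulates SNPs along paternal
lineages, so derived states at the defining markers nest perfectly in a
rooted clade hierarchy.  The built-in tree covers a 24-marker pedigree
panel spanning the major East Asian clades (C, D, N, O and their
subclades, plus E, G, IJK/IJ/I, K and QR), with clade placements per the
ISOGG nomenclature.

A sample is assigned the deepest clade whose defining marker is derived
and whose typed ancestors are all derived; a no-call at an intermediate
marker does not block deeper assignment (the deeper derived state implies
the ancestor, which is recorded as imputed).  Derived markers off the
chosen path are biologically impossible on a tree and are flagged as
conflicts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forensic import round_half_up
from .profiles import SNPProfile, SNPState

logger = logging.getLogger(__name__)

__all__ = [
    "HaplogroupTree",
    "HaplogroupCall",
    "FrequencyVector",
    "builtin_tree",
    "call_haplogroup",
    "haplogroup_frequencies",
    "clade_frequency",
    "pca",
]


@dataclass(frozen=True)
class _Node:
    label: str
    marker: str | None
    parent: str | None


class HaplogroupTree:
    """Rooted clade hierarchy keyed by clade label and by defining marker."""

    def __init__(self, nodes: list[tuple[str, str | None, str | None]]):
        """``nodes`` is a list of ``(label, defining_marker, parent_label)``;
        exactly one node (the root) has parent ``None``."""
        self._nodes: dict[str, _Node] = {}
        self._children: dict[str, list[str]] = {}
        self._by_marker: dict[str, str] = {}
        roots = []
        for label, marker, parent in nodes:
            if label in self._nodes:
                raise ValueError(f"duplicate clade label {label!r}")
            if marker is not None:
                if marker in self._by_marker:
                    raise ValueError(f"duplicate defining marker {marker!r}")
                self._by_marker[marker] = label
            self._nodes[label] = _Node(label, marker, parent)
            self._children.setdefault(label, [])
            if parent is None:
                roots.append(label)
            else:
                self._children.setdefault(parent, []).append(label)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, got {roots}")
        self.root = roots[0]
        for node in self._nodes.values():
            if node.parent is not None and node.parent not in self._nodes:
                raise ValueError(f"unknown parent {node.parent!r} of {node.label!r}")
        # preorder index for deterministic tie-breaking
        self._preorder: dict[str, int] = {}
        stack = [self.root]
        while stack:
            label = stack.pop()
            self._preorder[label] = len(self._preorder)
            stack.extend(reversed(self._children[label]))
        if len(self._preorder) != len(self._nodes):
            raise ValueError("tree contains nodes unreachable from the root")

    def __contains__(self, label: str) -> bool:
        return label in self._nodes

    @property
    def labels(self) -> list[str]:
        return sorted(self._nodes, key=self._preorder.get)

    @property
    def markers(self) -> list[str]:
        return list(self._by_marker)

    def marker_of(self, label: str) -> str | None:
        return self._nodes[label].marker

    def clade_of_marker(self, marker: str) -> str:
        return self._by_marker[marker]

    def parent(self, label: str) -> str | None:
        return self._nodes[label].parent

    def children(self, label: str) -> list[str]:
        return list(self._children[label])

    def path_to_root(self, label: str) -> list[str]:
        """Labels from *label* up to (and including) the root."""
        if label not in self._nodes:
            raise KeyError(f"unknown clade {label!r}")
        path = [label]
        while (parent := self._nodes[path[-1]].parent) is not None:
            path.append(parent)
        return path

    def depth(self, label: str) -> int:
        return len(self.path_to_root(label)) - 1

    def preorder_index(self, label: str) -> int:
        return self._preorder[label]

    def clade_labels(self, label: str) -> list[str]:
        """*label* and all its descendants, in preorder."""
        if label not in self._nodes:
            raise KeyError(f"unknown clade {label!r}")
        out, stack = [], [label]
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(reversed(self._children[cur]))
        return out

    def derived_markers_for(self, label: str) -> set[str]:
        """Markers expected derived for a lineage belonging to *label*."""
        return {
            m for l in self.path_to_root(label)
            if (m := self._nodes[l].marker) is not None
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"clade": l, "marker": self._nodes[l].marker or "",
             "parent": self._nodes[l].parent or ""}
            for l in self.labels
        ]
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "HaplogroupTree":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        return cls(
            [
                (row["clade"], row["marker"] or None, row["parent"] or None)
                for _, row in df.iterrows()
            ]
        )


# 24-marker pedigree panel tree (ISOGG placements).  The root "Y" carries
# no marker; IJK-M522 subsumes IJ, I, K, N, O and QR.
_BUILTIN_NODES: list[tuple[str, str | None, str | None]] = [
    ("Y", None, None),
    ("E", "M96", "Y"),
    ("D", "JST021355", "Y"),
    ("D1a1a1", "N1", "D"),
    ("D1a2a", "P47", "D"),
    ("C", "M130", "Y"),
    ("C2", "M217", "C"),
    ("G", "M201", "Y"),
    ("IJK", "M522", "Y"),
    ("IJ", "M429", "IJK"),
    ("I", "M170", "IJ"),
    ("K", "M9", "IJK"),
    ("N", "M231", "K"),
    ("N1a1", "M46", "N"),
    ("O", "P186", "K"),
    ("O1a", "M119", "O"),
    ("O1b", "M268", "O"),
    ("O1b2", "M176", "O1b"),
    ("O2", "M122", "O"),
    ("O2a1", "KL1", "O2"),
    ("O2a2", "P201", "O2"),
    ("O2a2a1a2", "M7", "O2a2"),
    ("O2a2b", "P164", "O2a2"),
    ("O2a2b1a1", "M117", "O2a2b"),
    ("QR", "M45", "K"),
]

_BUILTIN: HaplogroupTree | None = None


def builtin_tree() -> HaplogroupTree:
    """The built-in 24-marker haplogroup tree."""
    global _BUILTIN
    if _BUILTIN is None:
        _BUILTIN = HaplogroupTree(_BUILTIN_NODES)
    return _BUILTIN


@dataclass
class HaplogroupCall:
    """Result of hierarchical haplogroup assignment for one sample."""

    sample_id: str
    label: str
    path_consistent: bool = True
    conflicts: list[str] = field(default_factory=list)
    imputed_ancestors: list[str] = field(default_factory=list)

    @property
    def resolved(self) -> bool:
        return self.label != "unresolved"


def call_haplogroup(profile: SNPProfile, tree: HaplogroupTree | None = None
                    ) -> HaplogroupCall:
    """Assign the deepest supported clade for one SNP profile.

    A clade is *supported* when its defining marker is derived and no typed
    ancestor marker is ancestral (no-calls are imputed from the deeper
    derived state).  Among supported clades the deepest wins; depth ties
    break by tree preorder.  Derived markers not on the chosen root path
    are recorded as conflicts and clear ``path_consistent``.
    """
    if tree is None:
        tree = builtin_tree()
    derived = {
        m for m, s in profile.states.items() if s is SNPState.DERIVED
    }
    unknown = [m for m in derived if m not in tree._by_marker]
    if unknown:
        raise KeyError(f"markers not in tree: {sorted(unknown)}")

    candidates = []
    for marker in derived:
        label = tree.clade_of_marker(marker)
        blocked = False
        imputed = []
        for anc in tree.path_to_root(label)[1:]:
            anc_marker = tree.marker_of(anc)
            if anc_marker is None:
                continue
            state = profile.state(anc_marker)
            if state is SNPState.ANCESTRAL:
                blocked = True
                break
            if state is SNPState.NO_CALL:
                imputed.append(anc)
        if not blocked:
            candidates.append((label, imputed))

    if not candidates:
        if derived:
            logger.info(
                "sample %s unresolved: derived markers %s all blocked by "
                "ancestral ancestors", profile.sample_id, sorted(derived),
            )
        return HaplogroupCall(
            sample_id=profile.sample_id,
            label="unresolved",
            path_consistent=not derived,
            conflicts=sorted(derived),
        )

    label, imputed = min(
        candidates,
        key=lambda c: (-tree.depth(c[0]), tree.preorder_index(c[0])),
    )
    on_path = tree.derived_markers_for(label)
    conflicts = sorted(derived - on_path)
    return HaplogroupCall(
        sample_id=profile.sample_id,
        label=label,
        path_consistent=not conflicts,
        conflicts=conflicts,
        imputed_ancestors=imputed,
    )


@dataclass
class FrequencyVector:
    """Haplogroup frequencies (percent) for one population."""

    population: str
    percent: dict[str, float]
    n: int = 0

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {k: round_half_up(v, ndigits) for k, v in self.percent.items()}


def haplogroup_frequencies(calls: list[HaplogroupCall], population: str = ""
                           ) -> FrequencyVector:
    """Percent frequency of each called haplogroup label.

    Unresolved samples are excluded from the denominator (and logged).
    """
    resolved = [c for c in calls if c.resolved]
    if not resolved:
        raise ValueError("no resolved haplogroup calls")
    dropped = len(calls) - len(resolved)
    if dropped:
        logger.info("%d unresolved samples excluded from frequencies", dropped)
    n = len(resolved)
    counts: dict[str, int] = {}
    for c in resolved:
        counts[c.label] = counts.get(c.label, 0) + 1
    return FrequencyVector(
        population=population,
        percent={k: 100.0 * v / n for k, v in sorted(counts.items())},
        n=n,
    )


def clade_frequency(vec: FrequencyVector, clade: str,
                    tree: HaplogroupTree | None = None) -> float:
    """Cumulative percent of a clade: its own frequency plus all
    descendants present in the vector."""
    if tree is None:
        tree = builtin_tree()
    if clade not in tree:
        raise KeyError(f"unknown clade {clade!r}")
    members = tree.clade_labels(clade)
    return float(sum(vec.percent.get(label, 0.0) for label in members))


def pca(freq_table: pd.DataFrame, n_components: int = 2,
        mode: str = "correlation"):
    """Principal component analysis of a populations × clades frequency table.

    Parameters
    ----------
    freq_table
        Rows = populations (index), columns = clade frequencies.
    mode
        ``"correlation"`` (default) standardizes columns before the
        eigendecomposition; ``"covariance"`` centers only.

    Returns
    -------
    scores : DataFrame (populations × components)
    variance_explained : ndarray of percents, ordered non-increasing.

    Constant columns carry no information in correlation mode and are
    dropped with a log message.  Sign convention: within each component
    the loading of largest magnitude is made positive.
    """
    if freq_table.shape[0] < 3:
        raise ValueError("PCA requires at least 3 populations")
    X = freq_table.to_numpy(dtype=float)
    std = X.std(axis=0, ddof=1)
    if mode == "correlation":
        keep = std > 1e-12
        if not keep.all():
            logger.info(
                "dropping constant columns from PCA: %s",
                list(freq_table.columns[~keep]),
            )
        X = X[:, keep]
        std = std[keep]
        Z = (X - X.mean(axis=0)) / std
    elif mode == "covariance":
        Z = X - X.mean(axis=0)
    else:
        raise ValueError(f"unknown PCA mode {mode!r}")
    if Z.shape[1] < 2:
        raise ValueError("PCA requires at least 2 informative clades")

    # SVD of the centered/standardized matrix == eigendecomposition of the
    # correlation/covariance matrix
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = s**2 / (Z.shape[0] - 1)
    total = eigvals.sum()
    k = min(n_components, len(s))
    loadings = Vt[:k]
    scores = U[:, :k] * s[:k]
    for i in range(k):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    variance_explained = 100.0 * eigvals[:k] / total
    score_df = pd.DataFrame(
        scores,
        index=freq_table.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return score_df, variance_explained
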