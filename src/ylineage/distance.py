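"""Population differentiation from Y-STR repeat scores: AMOVA-based Rst,
multidimensional scaling, and neighbor-joining trees.

Rst
---
Rst is the microsatellite analogue of Fst: an analysis of molecular
variance (AMOVA) on repeat counts.  With per-sample repeat-score vectors
and squared-difference distance :math:`d(i,j)=\\sum_l (a_{il}-a_{jl})^2`,
the sums of squares partition into within- and among-population
components; with :math:`K` groups of sizes :math:`n_k` totalling
:math:`N`:

.. math::

    MS_{among} &= (SS_{total} - SS_{within})/(K-1) \\\\
    MS_{within} &= SS_{within}/(N-K) \\\\
    n_c &= (N - \\sum_k n_k^2/N)/(K-1) \\\\
    \\sigma^2_{among} &= (MS_{among} - MS_{within})/n_c \\\\
    R_{st} &= \\sigma^2_{among}/(\\sigma^2_{among} + MS_{within})

Only single-copy loci enter (repeat arithmetic is undefined on unordered
allele pairs); samples with a null or copy-number-variant call at a chosen
locus are dropped; microvariant alleles enter with their decimal value.
Slightly negative estimates (sampling noise around zero differentiation)
are reported raw with a log flag rather than truncated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio
from sklearn.isotonic import IsotonicRegression

from .profiles import STRProfile

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "MdsResult",
    "repeat_score_matrix",
    "pairwise_rst",
    "rst_matrix",
    "mds",
    "neighbor_joining",
]


@dataclass
class DistanceMatrix:
    """A symmetric pairwise distance matrix over labelled populations."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "DistanceMatrix":
        """Read a square labelled TSV, or PHYLIP square format (first line
        the taxon count, then label + row per line)."""
        with open(path) as fh:
            first = fh.readline().split()
        if len(first) == 1 and first[0].isdigit():
            n = int(first[0])
            df = pd.read_csv(
                path, sep=r"\s+", skiprows=1, header=None, index_col=0, nrows=n
            )
            labels = [str(l) for l in df.index]
            return cls(labels=labels, values=df.to_numpy(dtype=float))
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(labels=[str(l) for l in df.index], values=df.to_numpy(float))


def repeat_score_matrix(profiles: list[STRProfile], loci: list[str],
                        dys389_adjust: bool = False) -> np.ndarray:
    """Per-sample repeat-score vectors over single-copy loci.

    Samples with a null or multi-allele (CNV) call at any chosen locus are
    dropped with a log message.  With ``dys389_adjust`` the DYS389II score
    is replaced by DYS389II − DYS389I (removing the contained repeat
    block); the raw score is the default.
    """
    rows = []
    for p in profiles:
        vec = []
        usable = True
        for locus in loci:
            calls = p.get(locus)
            if len(calls) != 1:
                reason = "null" if not calls else "CNV"
                logger.info(
                    "sample %s dropped from Rst (%s call at %s)",
                    p.sample_id, reason, locus,
                )
                usable = False
                break
            value = float(calls[0])
            if dys389_adjust and locus == "DYS389II":
                i_calls = p.get("DYS389I")
                if len(i_calls) != 1:
                    usable = False
                    break
                value -= float(i_calls[0])
            vec.append(value)
        if usable:
            rows.append(vec)
    return np.asarray(rows, dtype=float).reshape(len(rows), len(loci))


def _amova_rst(groups: list[np.ndarray]) -> float:
    """Variance-component Rst from per-group repeat-score matrices."""
    K = len(groups)
    N = sum(g.shape[0] for g in groups)
    X = np.vstack(groups)
    ss_total = float(((X - X.mean(axis=0)) ** 2).sum())
    ss_within = float(
        sum(((g - g.mean(axis=0)) ** 2).sum() for g in groups)
    )
    ms_among = (ss_total - ss_within) / (K - 1)
    ms_within = ss_within / (N - K)
    n_c = (N - sum(g.shape[0] ** 2 for g in groups) / N) / (K - 1)
    sigma_among = (ms_among - ms_within) / n_c
    denom = sigma_among + ms_within
    if denom == 0.0:
        return 0.0
    return sigma_among / denom


def pairwise_rst(pop_a: list[STRProfile], pop_b: list[STRProfile],
                 loci: list[str], dys389_adjust: bool = False) -> float:
    """AMOVA Rst between two populations on the given single-copy loci."""
    a = repeat_score_matrix(pop_a, loci, dys389_adjust)
    b = repeat_score_matrix(pop_b, loci, dys389_adjust)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError(
            f"need >= 2 usable samples per population, got {a.shape[0]} and {b.shape[0]}"
        )
    rst = _amova_rst([a, b])
    if rst < 0:
        logger.info("negative Rst estimate %.6g reported raw", rst)
    return rst


def rst_matrix(populations: dict[str, list[STRProfile]], loci: list[str],
               dys389_adjust: bool = False) -> DistanceMatrix:
    """Pairwise Rst over every pair of named populations."""
    labels = list(populations)
    if len(labels) < 2:
        raise ValueError("need at least 2 populations")
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pairwise_rst(
                populations[labels[i]], populations[labels[j]], loci,
                dys389_adjust,
            )
    return DistanceMatrix(labels=labels, values=values)


@dataclass
class MdsResult:
    """Low-dimensional embedding of a distance matrix."""

    coordinates: pd.DataFrame
    stress: float
    converged: bool
    stress_history: list[float] = field(default_factory=list)


def _classical_mds(d: np.ndarray, dims: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    coords = np.zeros((n, dims))
    for k in range(min(dims, n)):
        if eigvals[k] > 1e-12:
            coords[:, k] = eigvecs[:, k] * np.sqrt(eigvals[k])
    return coords


def _stress1(diss: np.ndarray, config_d: np.ndarray) -> tuple[float, np.ndarray]:
    """Kruskal stress-1 and the isotonic disparities (upper triangle)."""
    iu = np.triu_indices_from(diss, k=1)
    order = np.argsort(diss[iu], kind="stable")
    d_flat = config_d[iu]
    disp_sorted = IsotonicRegression().fit_transform(
        np.arange(len(order)), d_flat[order]
    )
    disparities = np.empty_like(d_flat)
    disparities[order] = disp_sorted
    denom = float((d_flat**2).sum())
    if denom == 0:
        return 0.0, disparities
    stress = float(np.sqrt(((d_flat - disparities) ** 2).sum() / denom))
    return stress, disparities


def _config_distances(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def mds(dist: DistanceMatrix, dims: int = 2, nonmetric: bool = True,
        max_iter: int = 200, tol: float = 1e-6) -> MdsResult:
    """Embed a distance matrix in ``dims`` dimensions.

    The classical (Torgerson) solution — double-center −½D², take the top
    eigenvectors scaled by the square root of their eigenvalues — is
    computed first.  With ``nonmetric=True`` (default) it seeds a Kruskal
    stress-1 minimization: isotonic disparities followed by a Guttman
    transform per iteration, stopping when the stress improvement falls
    below ``tol``, ``max_iter`` is reached, or an update would increase
    stress (the previous configuration is kept, so the recorded stress
    history is non-increasing).

    Negative input distances are clamped to 0 with a log message; an
    all-zero matrix is degenerate and rejected.
    """
    d = dist.values.copy()
    if (d < 0).any():
        logger.info("clamping %d negative distances to 0", int((d < 0).sum() / 2))
        d = np.clip(d, 0.0, None)
    if not (d > 0).any():
        raise ValueError("degenerate all-zero distance matrix")
    n = d.shape[0]
    x = _classical_mds(d, dims)
    stress, _ = _stress1(d, _config_distances(x))
    history = [stress]
    converged = not nonmetric
    if nonmetric:
        iu = np.triu_indices(n, k=1)
        for _ in range(max_iter):
            config_d = _config_distances(x)
            stress, disparities = _stress1(d, config_d)
            disp = np.zeros((n, n))
            disp[iu] = disparities
            disp = disp + disp.T
            # Guttman transform
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(config_d > 0, disp / config_d, 0.0)
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            x_new = b @ x / n
            new_stress, _ = _stress1(d, _config_distances(x_new))
            if new_stress > history[-1]:
                break
            x = x_new
            improved = history[-1] - new_stress
            history.append(new_stress)
            if improved < tol:
                converged = True
                break
    coords = pd.DataFrame(
        x, index=dist.labels, columns=[f"dim{i + 1}" for i in range(dims)]
    )
    return MdsResult(
        coordinates=coords, stress=history[-1], converged=converged,
        stress_history=history,
    )


def neighbor_joining(dist: DistanceMatrix) -> skbio.TreeNode:
    """Saitou–Nei neighbor joining.

    Produces an unrooted binary tree (internal degree 3, represented with
    a trifurcating root).  On additive distances the tree's path lengths
    reproduce the input matrix exactly.  Q-matrix ties break by
    lexicographic label order of the joined pair, so the result is
    deterministic.
    """
    labels = list(dist.labels)
    if len(labels) < 3:
        raise ValueError("neighbor joining requires at least 3 labels")
    d = {
        (a, b): float(dist.values[i, j])
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
    }
    nodes: dict[str, skbio.TreeNode] = {
        l: skbio.TreeNode(name=l) for l in labels
    }
    active = list(labels)
    fresh = 0

    while len(active) > 3:
        m = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * d[(a, b)] - r[a] - r[b]
                key = (q, *sorted((a, b)))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        la = d[(a, b)] / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lb = d[(a, b)] - la
        new = f"_nj{fresh}"
        fresh += 1
        parent = skbio.TreeNode(name=None)
        nodes[a].length = la
        nodes[b].length = lb
        parent.extend([nodes[a], nodes[b]])
        nodes[new] = parent
        for c in active:
            if c in (a, b):
                continue
            d[(new, c)] = d[(c, new)] = (d[(a, c)] + d[(b, c)] - d[(a, b)]) / 2
        d[(new, new)] = 0.0
        active = [c for c in active if c not in (a, b)] + [new]

    a, b, c = active
    # three-point formulas for the final star join
    la = (d[(a, b)] + d[(a, c)] - d[(b, c)]) / 2
    lb = (d[(a, b)] + d[(b, c)] - d[(a, c)]) / 2
    lc = (d[(a, c)] + d[(b, c)] - d[(a, b)]) / 2
    root = skbio.TreeNode(name=None)
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = length
        root.append(node)
    return root
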