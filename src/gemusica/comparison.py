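"""Sample comparison in melody space.

Melodies from one analysis are stacked into a feature grid (one frequency or
key index per signature position per sample) and compared by pairwise
Manhattan distance with complete-linkage clustering, and by Pearson
correlation. The relative-correlation report emulates the control-anchored
statistic used for perturbation experiments: each query sample's mean
correlation rho to a reference group is divided by the mean correlation of
the unperturbed control queries (rho0), so controls average to 1 by
construction, and control vs. perturbed relative values are compared with a
two-sided Welch t-test.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .matrix import ExpressionMatrix, IdentifierError
from .sonification import Melody

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "DendrogramNode",
    "RelativeCorrelationReport",
    "melody_feature_matrix",
    "pairwise_manhattan",
    "complete_linkage",
    "to_newick",
    "pearson",
    "relative_correlation",
    "compare_groups",
    "permutation_test_means",
    "write_distance_matrix",
]

FeatureSpace = Literal["frequency", "key"]


# ---------------------------------------------------------------------------
# feature grid


def melody_feature_matrix(melodies: Sequence[Melody], space: FeatureSpace = "frequency") -> ExpressionMatrix:
    """Stack melodies into an N-positions x n-samples feature grid.

    All melodies must come from one analysis (same config, calibration and
    probe order). ``space`` selects frequencies in Hz (the canonical melody
    representation) or raw key indices.
    """
    if not melodies:
        raise ValueError("no melodies given")
    if space not in ("frequency", "key"):
        raise ValueError(f"unknown feature space {space!r}")
    first = melodies[0]
    probe_order = tuple(n.probe_id for n in first.notes)
    for mel in melodies[1:]:
        if mel.config != first.config or mel.calibration != first.calibration:
            raise ValueError(f"melody {mel.sample_id!r}: incompatible config/calibration")
        if tuple(n.probe_id for n in mel.notes) != probe_order:
            raise ValueError(f"melody {mel.sample_id!r}: probe order differs")
    if space == "frequency":
        cols = [[n.frequency for n in mel.notes] for mel in melodies]
    else:
        cols = [[float(n.key_index) for n in mel.notes] for mel in melodies]
    values = np.array(cols, float).T
    # scale_tag is nominal here: the grid holds melody features, not intensities
    return ExpressionMatrix(probe_order, tuple(m.sample_id for m in melodies), values, "log2")


# ---------------------------------------------------------------------------
# distances and clustering


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal."""

    sample_ids: tuple[str, ...]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.d, float)
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0) or d.min() < 0:
            raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")
        object.__setattr__(self, "d", d)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def get(self, a: str, b: str) -> float:
        ia = self.sample_ids.index(a)
        ib = self.sample_ids.index(b)
        return float(self.d[ia, ib])


def pairwise_manhattan(features: ExpressionMatrix) -> DistanceMatrix:
    """Manhattan (city-block) distance between sample columns."""
    if features.n_samples < 2:
        raise ValueError("need at least 2 samples for pairwise distances")
    vals = features.values
    if not np.all(np.isfinite(vals)):
        raise ValueError("features contain non-finite values")
    d = np.abs(vals[:, :, None] - vals[:, None, :]).sum(axis=0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(features.sample_ids, d)


@dataclass(frozen=True)
class DendrogramNode:
    """Binary merge-tree node; leaves carry a sample id, internal nodes a height."""

    height: float
    name: str | None = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            assert self.name is not None
            return [self.name]
        a, b = self.children  # type: ignore[misc]
        return a.leaves() + b.leaves()


@dataclass(frozen=True)
class Dendrogram:
    root: DendrogramNode
    sample_ids: tuple[str, ...]

    def merge_heights(self) -> list[float]:
        """All internal-node heights, sorted ascending."""
        heights: list[float] = []

        def walk(node: DendrogramNode) -> None:
            if not node.is_leaf:
                heights.append(node.height)
                for child in node.children:  # type: ignore[union-attr]
                    walk(child)

        walk(self.root)
        return sorted(heights)

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Cut the tree into ``n_clusters`` flat clusters (split highest merges first).

        Returns sample id -> cluster index (indices ordered by first leaf).
        """
        if not 1 <= n_clusters <= len(self.sample_ids):
            raise ValueError(f"n_clusters must lie in [1, {len(self.sample_ids)}]")
        clusters: list[DendrogramNode] = [self.root]
        while len(clusters) < n_clusters:
            # split the cluster whose root merge is highest; ties by first leaf
            splittable = [c for c in clusters if not c.is_leaf]
            victim = max(splittable, key=lambda c: (c.height, c.leaves()[0]))
            clusters.remove(victim)
            clusters.extend(victim.children)  # type: ignore[arg-type]
        out: dict[str, int] = {}
        for idx, c in enumerate(sorted(clusters, key=lambda c: self.sample_ids.index(c.leaves()[0]))):
            for leaf in c.leaves():
                out[leaf] = idx
        return out


def complete_linkage(dm: DistanceMatrix) -> Dendrogram:
    """Agglomerative clustering with complete (maximum) linkage.

    Inter-cluster distance is the maximum pairwise distance between members.
    Ties are broken deterministically: among equally close pairs, merge the
    pair whose (lexicographically smallest member, then second member) label
    pair sorts first. Merge heights are non-decreasing.
    """
    if dm.n < 2:
        raise ValueError("need at least 2 samples to cluster")
    # cluster label = lexicographically smallest leaf name in the cluster
    clusters: dict[str, tuple[DendrogramNode, frozenset[int]]] = {
        sid: (DendrogramNode(0.0, name=sid), frozenset([i]))
        for i, sid in enumerate(dm.sample_ids)
    }
    d = dm.d

    def cluster_dist(a: frozenset[int], b: frozenset[int]) -> float:
        return max(float(d[i, j]) for i in a for j in b)

    while len(clusters) > 1:
        best: tuple[float, tuple[str, str]] | None = None
        for la, lb in itertools.combinations(sorted(clusters), 2):
            dist = cluster_dist(clusters[la][1], clusters[lb][1])
            key = (dist, (la, lb))
            if best is None or key < best:
                best = key
        assert best is not None
        height, (la, lb) = best
        node_a, set_a = clusters.pop(la)
        node_b, set_b = clusters.pop(lb)
        merged = DendrogramNode(height, children=(node_a, node_b))
        clusters[min(la, lb)] = (merged, set_a | set_b)
    (root, _), = clusters.values()
    return Dendrogram(root, dm.sample_ids)


def to_newick(t: Dendrogram) -> str:
    """Serialize a dendrogram as Newick; branch length = parent - child height."""

    def fmt(node: DendrogramNode, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{node.name}:{length:.10g}"
        a, b = node.children  # type: ignore[misc]
        return f"({fmt(a, node.height)},{fmt(b, node.height)}):{length:.10g}"

    root = t.root
    if root.is_leaf:
        return f"{root.name}:0;"
    a, b = root.children  # type: ignore[misc]
    return f"({fmt(a, root.height)},{fmt(b, root.height)});"


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Square labeled TSV of pairwise distances."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("sample_id\t" + "\t".join(dm.sample_ids) + "\n")
        for sid, row in zip(dm.sample_ids, dm.d):
            fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# correlation statistics


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; errors on short or constant input."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class RelativeCorrelationReport:
    """Control-anchored relative correlations of query samples to a reference group.

    ``rho`` maps each query sample to its mean Pearson correlation with the
    reference samples; ``rho_rel`` divides by ``rho0_mean`` (the mean rho of
    the control queries), so control relative values average to 1.
    """

    reference_group: str
    control_ids: tuple[str, ...]
    perturbed_ids: tuple[str, ...]
    rho: dict[str, float]
    rho_rel: dict[str, float]
    rho0_mean: float
    control_mean: float
    control_sd: float
    perturbed_mean: float
    perturbed_sd: float

    def group_values(self, which: Literal["control", "perturbed"]) -> np.ndarray:
        ids = self.control_ids if which == "control" else self.perturbed_ids
        return np.array([self.rho_rel[s] for s in ids])

    def to_json(self) -> str:
        return json.dumps(
            {
                "reference_group": self.reference_group,
                "rho0_mean": self.rho0_mean,
                "control_mean": self.control_mean,
                "control_sd": self.control_sd,
                "perturbed_mean": self.perturbed_mean,
                "perturbed_sd": self.perturbed_sd,
                "rho": self.rho,
                "rho_rel": self.rho_rel,
            },
            indent=2,
        )


def _require_samples(features: ExpressionMatrix, ids: Sequence[str], what: str) -> list[str]:
    missing = [s for s in ids if s not in features.sample_ids]
    if missing:
        raise IdentifierError(f"{what} sample(s) absent from features: {missing}")
    if not ids:
        raise ValueError(f"no {what} samples given")
    return list(ids)


def relative_correlation(
    features: ExpressionMatrix,
    control_ids: Sequence[str],
    perturbed_ids: Sequence[str],
    reference_ids: Sequence[str],
    reference_group: str = "reference",
) -> RelativeCorrelationReport:
    """Fig-6-style relative correlation of query samples to one reference group.

    Each query's rho is the mean over reference samples of its Pearson
    correlation with that sample (references pooled); rho values are then
    anchored by the control-query mean rho0.
    """
    control_ids = _require_samples(features, control_ids, "control")
    perturbed_ids = _require_samples(features, perturbed_ids, "perturbed")
    reference_ids = _require_samples(features, reference_ids, "reference")
    ref_cols = [features.column(s) for s in reference_ids]
    rho: dict[str, float] = {}
    for sid in [*control_ids, *perturbed_ids]:
        q = features.column(sid)
        rho[sid] = float(np.mean([pearson(q, r) for r in ref_cols]))
    rho0 = float(np.mean([rho[s] for s in control_ids]))
    if rho0 == 0:
        raise ZeroDivisionError("mean control correlation rho0 is zero; cannot normalize")
    rho_rel = {s: v / rho0 for s, v in rho.items()}
    ctrl = np.array([rho_rel[s] for s in control_ids])
    pert = np.array([rho_rel[s] for s in perturbed_ids])
    return RelativeCorrelationReport(
        reference_group=reference_group,
        control_ids=tuple(control_ids),
        perturbed_ids=tuple(perturbed_ids),
        rho=rho,
        rho_rel=rho_rel,
        rho0_mean=rho0,
        control_mean=float(ctrl.mean()),
        control_sd=float(ctrl.std(ddof=1)) if len(ctrl) > 1 else 0.0,
        perturbed_mean=float(pert.mean()),
        perturbed_sd=float(pert.std(ddof=1)) if len(pert) > 1 else 0.0,
    )


@dataclass(frozen=True)
class WelchResult:
    statistic: float
    df: float
    pvalue: float


def compare_groups(report: RelativeCorrelationReport) -> WelchResult:
    """Two-sided Welch two-sample t-test on relative rho, control vs. perturbed.

    Welch's unequal-variance form suits the small, possibly heteroscedastic
    groups this statistic is applied to. Two degenerate cases are defined
    explicitly: identical groups give (0, p=1); zero within-group variance
    with different means gives (inf, p=0).
    """
    a = report.group_values("control")
    b = report.group_values("perturbed")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(len(a) + len(b) - 2), 1.0)
        return WelchResult(float("inf"), float(len(a) + len(b) - 2), 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def permutation_test_means(
    a: np.ndarray, b: np.ndarray, n_permutations: int = 10_000, seed: int = 0
) -> float:
    """Two-sided permutation test on the difference of group means.

    Monte-Carlo reference for :func:`compare_groups`; the p-value includes
    the observed labeling (add-one correction).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    n_a = len(a)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if abs(perm[:n_a].mean() - perm[n_a:].mean()) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)
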