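"""Cross-dataset set analysis and protein-list variability statistics.

Four pieces of machinery:

* exclusive intersections among named protein sets (the numbers behind an
  UpSet plot): every element of the union is assigned to the exact
  combination of sets containing it, so the counts partition the union;
* pairwise protein-list dissimilarity (Jaccard distance on accession sets)
  and the hierarchical clustering tree built on the resulting matrix;
* entanglement between two dendrograms over the same labels -- a [0, 1]
  leaf-order disagreement score (0 = perfectly aligned, 1 = exactly
  reversed);
* an exact Wilcoxon rank-sum (Mann-Whitney) test for the small group sizes
  that replicate-pair variability comparisons produce, with the two-sided
  p-value obtained from the full permutation distribution.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu, rankdata

from .errors import ValidationError
from .filter_ladder import STAGES, FilterLadderResult
from .report_io import RunKey, StudyTable

logger = logging.getLogger(__name__)

#: Largest group size for which the exact permutation distribution is used.
EXACT_ENUMERATION_LIMIT = 12


# ---------------------------------------------------------------------------
# exclusive intersections
# ---------------------------------------------------------------------------

def exclusive_intersections(named_sets: Mapping[object, Iterable[str]]) -> pd.DataFrame:
    """Partition the union of 1-30 named sets by exact membership
    combination.

    Returns a DataFrame with columns ``combination`` (tuple of set names),
    ``exclusive_count`` and ``members``, sorted by count descending, then
    combination size, then lexicographically.
    """
    if not named_sets:
        raise ValidationError("exclusive_intersections requires at least one set")
    if len(named_sets) > 30:
        raise ValidationError("exclusive_intersections supports at most 30 sets")
    sets = {name: frozenset(s) for name, s in named_sets.items()}
    groups: dict[tuple, set[str]] = {}
    for element in frozenset().union(*sets.values()):
        combo = tuple(sorted((n for n, s in sets.items() if element in s), key=str))
        groups.setdefault(combo, set()).add(element)
    rows = [{"combination": c, "exclusive_count": len(m), "members": tuple(sorted(m))}
            for c, m in groups.items()]
    rows.sort(key=lambda r: (-r["exclusive_count"], len(r["combination"]),
                             tuple(map(str, r["combination"]))))
    return pd.DataFrame(rows, columns=["combination", "exclusive_count", "members"])


# ---------------------------------------------------------------------------
# list dissimilarity and the variability matrix
# ---------------------------------------------------------------------------

def list_dissimilarity(list_a: Iterable[str], list_b: Iterable[str]) -> float:
    """Jaccard distance 1 - |A∩B| / |A∪B| between two accession sets."""
    a, b = frozenset(list_a), frozenset(list_b)
    union = a | b
    if not union:
        raise ValidationError("list dissimilarity undefined for two empty sets")
    return 1.0 - len(a & b) / len(union)


@dataclass(frozen=True)
class VariabilityMatrix:
    """Symmetric pairwise dissimilarity matrix over labelled protein lists."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValidationError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("variability matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("self-dissimilarity must be zero")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValidationError("dissimilarities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def variability_matrix(lists: Mapping[RunKey, Iterable[str]]) -> VariabilityMatrix:
    """All pairwise Jaccard distances; labels in ``dataset_sample_replicate``
    codification, sorted by run key."""
    if len(lists) < 2:
        raise ValidationError("variability matrix requires >= 2 lists")
    keys = sorted(lists)
    sets = [frozenset(lists[k]) for k in keys]
    n = len(keys)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        mat[i, j] = mat[j, i] = list_dissimilarity(sets[i], sets[j])
    return VariabilityMatrix(tuple(str(k) for k in keys), mat)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dendrogram:
    """Rooted binary merge tree over labels, as a scipy linkage matrix."""

    labels: tuple[str, ...]
    linkage: np.ndarray

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if (np.diff(heights) < -1e-12).any():
            raise ValidationError("merge heights must be non-decreasing")

    def leaf_order(self) -> tuple[str, ...]:
        return tuple(self.labels[i] for i in sch.leaves_list(self.linkage))

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def to_newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = render(node.left), render(node.right)
            return f"({left}:{node.dist - node.left.dist:.6g},{right}:{node.dist - node.right.dist:.6g})"

        return render(tree) + ";"


def cluster(matrix: VariabilityMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of the variability matrix.

    Complete linkage is the default; single and average are accepted too.
    """
    if linkage not in ("complete", "single", "average"):
        raise ValidationError(f"unsupported linkage {linkage!r}")
    if len(matrix.labels) < 2:
        raise ValidationError("clustering requires >= 2 labels")
    condensed = squareform(matrix.values, checks=False)
    return Dendrogram(matrix.labels, sch.linkage(condensed, method=linkage))


# ---------------------------------------------------------------------------
# entanglement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EntanglementResult:
    value: float
    exponent: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValidationError(f"entanglement {self.value} outside [0, 1]")


def _leaf_order(tree) -> tuple[str, ...]:
    if isinstance(tree, Dendrogram):
        return tree.leaf_order()
    return tuple(tree)


def untangle_leaf_order(tree: Dendrogram, reference) -> tuple[str, ...]:
    """Leaf order of ``tree`` after rotating merge nodes to best follow a
    reference order.

    Each internal node's children are swapped when the mean reference rank
    of the right subtree's leaves precedes the left's -- the step-wise
    untangling used before drawing a tanglegram.  The tree topology is
    untouched; only the drawing order changes.
    """
    ref = {lab: i for i, lab in enumerate(_leaf_order(reference))}
    root = sch.to_tree(tree.linkage)

    def walk(node) -> list[str]:
        if node.is_leaf():
            return [tree.labels[node.id]]
        left, right = walk(node.left), walk(node.right)
        if np.mean([ref[x] for x in right]) < np.mean([ref[x] for x in left]):
            left, right = right, left
        return left + right

    return tuple(walk(root))


def entanglement(tree_left, tree_right, L: float = 1.5,
                 untangle: bool = False) -> EntanglementResult:
    """Leaf-order disagreement between two trees over the same labels.

    With rank_left/rank_right the positions of each label in the two leaf
    orders, the raw score sum(|rank_left - rank_right| ** L) is normalized
    by its maximum (attained when one order is the exact reversal of the
    other), giving a value in [0, 1]; lower is better aligned.  Either
    argument may be a :class:`Dendrogram` or an explicit label sequence
    (e.g. a manually set reference order).

    With ``untangle=True`` and a :class:`Dendrogram` on the right, the right
    tree's merge nodes are first rotated toward the left order
    (:func:`untangle_leaf_order`), so the score reflects topological
    agreement rather than the clustering's arbitrary branch orientation.
    """
    if untangle and isinstance(tree_right, Dendrogram):
        tree_right = untangle_leaf_order(tree_right, tree_left)
    left, right = _leaf_order(tree_left), _leaf_order(tree_right)
    if set(left) != set(right) or len(left) != len(right):
        raise ValidationError("entanglement requires two trees over the identical label set")
    n = len(left)
    if n < 2:
        return EntanglementResult(0.0, L)
    pos_right = {lab: i for i, lab in enumerate(right)}
    raw = sum(abs(i - pos_right[lab]) ** L for i, lab in enumerate(left))
    max_raw = sum(abs(i - (n - 1 - i)) ** L for i in range(n))
    return EntanglementResult(min(1.0, raw / max_raw), L)


# ---------------------------------------------------------------------------
# exact Wilcoxon rank-sum (Mann-Whitney)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first group
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" | "normal"

    def __post_init__(self) -> None:
        if not (0.0 <= self.statistic <= self.n1 * self.n2):
            raise ValidationError("W must lie in [0, n1*n2]")
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError("p-value must lie in (0, 1]")


def _ranksum_counts(doubled_ranks: Sequence[int], n1: int) -> np.ndarray:
    """Number of ways to choose n1 of the pooled (doubled, integer) ranks
    attaining each possible doubled rank-sum.  Dynamic program over the
    permutation distribution; equivalent to enumerating all C(n, n1)
    assignments."""
    total = int(sum(doubled_ranks))
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in doubled_ranks:
        for k in range(n1, 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    return dp[n1]


def rank_sum_exact(group_a: Sequence[float], group_b: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test, exact for small groups.

    The statistic is the Mann-Whitney U of ``group_a`` computed from pooled
    midranks.  For group sizes up to 12 the two-sided p-value is exact:
    2 * min(P(U <= w), P(U >= w)) over the full permutation distribution,
    capped at 1.  Larger groups fall back to the normal approximation (a
    notice is logged).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks for ties
    r_a = float(ranks[:n1].sum())
    u = r_a - n1 * (n1 + 1) / 2.0

    if max(n1, n2) <= EXACT_ENUMERATION_LIMIT:
        doubled = np.round(2 * ranks).astype(int)
        counts = _ranksum_counts(doubled, n1)
        total = counts.sum()
        s_obs = int(round(2 * r_a))
        p_low = counts[: s_obs + 1].sum() / total
        p_high = counts[s_obs:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return RankSumResult(u, p, n1, n2, "exact")

    logger.info("group sizes (%d, %d) exceed the exact enumeration regime; "
                "using the normal approximation", n1, n2)
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return RankSumResult(float(res.statistic), float(res.pvalue), n1, n2, "normal")


def exact_critical_value(n1: int, n2: int, alpha: float = 0.05) -> int | None:
    """Largest integer c with 2 * P(U <= c) <= alpha under the tie-free
    exact null distribution; None if even c = 0 is not significant."""
    ranks = [2 * r for r in range(1, n1 + n2 + 1)]
    counts = _ranksum_counts(ranks, n1)
    total = counts.sum()
    offset = n1 * (n1 + 1)  # doubled minimum rank-sum
    best = None
    for c in range(n1 * n2 + 1):
        p_low = counts[: offset + 2 * c + 1].sum() / total
        if 2 * p_low <= alpha:
            best = c
        else:
            break
    return best


# ---------------------------------------------------------------------------
# study-level glue
# ---------------------------------------------------------------------------

def stage_run_lists(study: StudyTable, ladder: FilterLadderResult,
                    stage: str) -> dict[RunKey, frozenset[str]]:
    """Per-run protein lists at a ladder stage: the run's reported
    accessions intersected with its dataset's stage set."""
    if stage not in STAGES:
        raise ValidationError(f"unknown ladder stage {stage!r}")
    out = {}
    for key in sorted(study.runs):
        out[key] = study.runs[key].accessions & ladder.stage_set(key.dataset, stage)
    return out


def design_leaf_order(study: StudyTable) -> tuple[str, ...]:
    """The manually set reference leaf order: runs in design order."""
    return tuple(str(k) for k in sorted(study.runs))


def protocol_variability_comparison(study: StudyTable, ladder: FilterLadderResult,
                                    stage: str, dataset_group_a: Sequence[int],
                                    dataset_group_b: Sequence[int]) -> RankSumResult:
    """Compare within-dataset protein-list variability between two groups of
    datasets (e.g. the two extraction protocols) at a given ladder stage.

    For each dataset, all pairwise Jaccard distances between its runs' stage
    lists are computed; the values are pooled per group and submitted to the
    exact rank-sum test.
    """
    lists = stage_run_lists(study, ladder, stage)

    def group_values(datasets: Sequence[int]) -> list[float]:
        values = []
        for d in datasets:
            keys = [k for k in sorted(lists) if k.dataset == d]
            if len(keys) < 2:
                raise ValidationError(f"dataset {d} has fewer than 2 runs")
            for i, j in itertools.combinations(keys, 2):
                values.append(list_dissimilarity(lists[i], lists[j]))
        return values

    return rank_sum_exact(group_values(dataset_group_a), group_values(dataset_group_b))
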