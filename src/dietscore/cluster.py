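"""Gower dissimilarity, generalized Ward agglomeration and diagnostics.

Countries (or country x gender strata) are clustered on mixed feature
tables — component points, or raw g/day intakes. Gower's coefficient
averages per-variable dissimilarities over the variables on which a pair
is comparable::

    d(i, j) = sum_k delta_ijk * d_ijk / sum_k delta_ijk

with ``d_ijk = |x_ik - x_jk| / Range(k)`` for numeric variables and a
0/1 mismatch for categorical ones; ``delta_ijk`` is 1 when both units
have a valid value for variable k.

Agglomeration uses Ward's objective generalized to non-Euclidean
dissimilarities via the Lance-Williams recurrence applied directly to
the Gower matrix::

    d(ij, k) = [(n_i + n_k) d(i,k) + (n_j + n_k) d(j,k) - n_k d(i,j)]
               / (n_i + n_j + n_k)

Ties between equally close pairs break on the lexicographically
smallest (first-leaf, second-leaf) pair, making merge order fully
deterministic. Silhouette widths ``S(i) = (b(i) - a(i)) / max(a(i),
b(i))`` diagnose a chosen partition; the cut point is selected by
maximizing the average silhouette over a candidate range of k while
inspecting the scree of merge heights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .errors import ClusteringError, IncomparablePairError, ParameterError

__all__ = [
    "FeatureTable",
    "DissimilarityMatrix",
    "ClusterTree",
    "SilhouetteReport",
    "ConcordanceReport",
    "gower_matrix",
    "ward_agglomerate",
    "cut_dendrogram",
    "silhouette",
    "choose_k",
    "region_concordance",
]


@dataclass(frozen=True)
class FeatureTable:
    """Units x variables table feeding Gower's distance.

    ``data`` is indexed by unit id; ``categorical`` names the columns
    treated as categorical (0/1 mismatch), every other column is numeric
    and range-normalized. Missing entries (NaN) make a unit incomparable
    on that variable.
    """

    data: pd.DataFrame
    categorical: tuple[str, ...] = ()

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise ParameterError("duplicate unit ids in feature table")
        unknown = set(self.categorical) - set(self.data.columns)
        if unknown:
            raise ParameterError(f"categorical columns not in table: {sorted(unknown)}")
        object.__setattr__(self, "categorical", tuple(self.categorical))

    @property
    def units(self) -> tuple[str, ...]:
        return tuple(str(u) for u in self.data.index)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(str(c) for c in self.data.columns)


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Square symmetric dissimilarities with a zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if values.shape != (n, n):
            raise ClusteringError(f"matrix shape {values.shape} != ({n}, {n})")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ClusteringError("dissimilarity matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise ClusteringError("dissimilarity matrix has a non-zero diagonal")
        if (values < -1e-12).any():
            raise ClusteringError("dissimilarity matrix has negative entries")
        values = np.clip((values + values.T) / 2.0, 0.0, None)
        np.fill_diagonal(values, 0.0)
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def gower_matrix(table: FeatureTable) -> DissimilarityMatrix:
    """Gower's dissimilarity over every pair of units in ``table``.

    Numeric variables are scaled by their observed range over the
    analyzed units; a numeric variable with zero range carries no
    information and is dropped with a warning. Raises
    :class:`IncomparablePairError` if some pair shares no valid
    variable.
    """
    if len(table.data) < 2:
        raise ParameterError("gower_matrix needs at least 2 units")
    n = len(table.data)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for col in table.data.columns:
        series = table.data[col]
        if col in table.categorical:
            codes = pd.Categorical(series).codes.astype(float)  # -1 for NaN
            valid = codes >= 0
            diff = (codes[:, None] != codes[None, :]).astype(float)
        else:
            x = pd.to_numeric(series, errors="raise").to_numpy(dtype=float)
            valid = np.isfinite(x)
            if valid.sum() < 2:
                continue
            rng = np.nanmax(x[valid]) - np.nanmin(x[valid])
            if rng == 0.0:
                warnings.warn(
                    f"variable {col!r} has zero range over the analyzed units; "
                    "dropped from Gower distances",
                    stacklevel=2,
                )
                continue
            diff = np.abs(x[:, None] - x[None, :]) / rng
        delta = np.outer(valid, valid).astype(float)
        num += np.where(delta > 0, np.nan_to_num(diff), 0.0)
        den += delta
    off = ~np.eye(n, dtype=bool)
    if (den[off] == 0).any():
        i, j = np.argwhere((den == 0) & off)[0]
        raise IncomparablePairError(
            f"units {table.units[i]!r} and {table.units[j]!r} share no comparable variable"
        )
    d = np.zeros((n, n))
    d[off] = num[off] / den[off]
    return DissimilarityMatrix(ids=table.units, values=d)


@dataclass(frozen=True)
class ClusterTree:
    """Agglomeration history in scipy linkage layout.

    ``merges`` has one row per merge: (cluster a, cluster b, height,
    new size), clusters below ``n`` being leaves and row ``i`` creating
    cluster ``n + i``. ``monotonic`` records whether merge heights were
    non-decreasing (Ward's recurrence preserves this; violations are
    flagged, not fatal).
    """

    leaf_ids: tuple[str, ...]
    merges: np.ndarray
    monotonic: bool = True

    def __post_init__(self):
        merges = np.asarray(self.merges, dtype=float)
        n = len(self.leaf_ids)
        if merges.shape != (n - 1, 4):
            raise ClusteringError(f"expected {n - 1} merges of 4 fields, got {merges.shape}")
        merges.setflags(write=False)
        object.__setattr__(self, "merges", merges)
        object.__setattr__(self, "leaf_ids", tuple(str(i) for i in self.leaf_ids))

    @property
    def n(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2].copy()

    def to_scipy_linkage(self) -> np.ndarray:
        """The merge table as a scipy ``linkage`` matrix (for dendrograms)."""
        return np.array(self.merges, dtype=float)

    def to_newick(self) -> str:
        """Nested-parenthesis text rendering of the dendrogram."""
        reps: dict[int, str] = {i: name for i, name in enumerate(self.leaf_ids)}
        for step, (a, b, h, _) in enumerate(self.merges):
            reps[self.n + step] = f"({reps.pop(int(a))},{reps.pop(int(b))}):{h:g}"
        (root,) = reps.values()
        return root + ";"


def ward_agglomerate(D: DissimilarityMatrix) -> ClusterTree:
    """Generalized Ward agglomeration of a dissimilarity matrix.

    At each step the pair of active clusters at minimum dissimilarity is
    merged (ties: lexicographically smallest first-leaf pair) and
    distances to the merged cluster are rebuilt with the Lance-Williams
    Ward recurrence applied directly to the input dissimilarities.
    """
    n = D.n
    if n < 2:
        raise ClusteringError("need at least 2 units to agglomerate")
    # working matrix indexed by active-slot; slot i initially = leaf i
    work = D.values.astype(float).copy()
    size = {i: 1 for i in range(n)}
    first_leaf = {i: i for i in range(n)}
    slot_of = {i: i for i in range(n)}  # cluster id -> row/col in `work`
    active = list(range(n))
    merges = np.zeros((n - 1, 4))
    monotonic = True
    last_height = -np.inf
    next_id = n
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                d = work[slot_of[a], slot_of[b]]
                fa, fb = sorted((first_leaf[a], first_leaf[b]))
                key = (d, fa, fb)
                if best is None or key < best[0]:
                    best = (key, a, b)
        (height, _, _), a, b = best
        if first_leaf[b] < first_leaf[a]:
            a, b = b, a
        if height < last_height - 1e-12:
            monotonic = False
        last_height = max(last_height, height)
        na, nb = size[a], size[b]
        sa, sb = slot_of[a], slot_of[b]
        # Lance-Williams Ward update toward every other active cluster
        for c in active:
            if c in (a, b):
                continue
            sc, nc = slot_of[c], size[c]
            dnew = (
                (na + nc) * work[sa, sc]
                + (nb + nc) * work[sb, sc]
                - nc * work[sa, sb]
            ) / (na + nb + nc)
            work[sa, sc] = work[sc, sa] = dnew
        merges[step] = (a, b, height, na + nb)
        size[next_id] = na + nb
        first_leaf[next_id] = min(first_leaf[a], first_leaf[b])
        slot_of[next_id] = sa  # merged cluster reuses a's slot
        active.remove(a)
        active.remove(b)
        active.append(next_id)
        next_id += 1
    if not monotonic:
        warnings.warn("merge heights are not monotone non-decreasing", stacklevel=2)
    return ClusterTree(leaf_ids=D.ids, merges=merges, monotonic=monotonic)


def cut_dendrogram(tree: ClusterTree, k: int) -> np.ndarray:
    """Labels per leaf for the partition into ``k`` clusters.

    Obtained by undoing the last ``k - 1`` merges; label integers are
    assigned in order of each cluster's first leaf, so label 0 always
    contains the first unit.
    """
    n = tree.n
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step in range(n - k):
        a, b, _, _ = tree.merges[step]
        merged = members.pop(int(a)) + members.pop(int(b))
        members[n + step] = merged
    clusters = sorted(members.values(), key=min)
    labels = np.empty(n, dtype=int)
    for label, leaves in enumerate(clusters):
        labels[leaves] = label
    return labels


@dataclass(frozen=True)
class SilhouetteReport:
    """Per-unit a(i), b(i), S(i) plus cluster and overall means."""

    ids: tuple[str, ...]
    labels: np.ndarray
    a: np.ndarray
    b: np.ndarray
    s: np.ndarray
    cluster_means: Mapping[int, float]
    overall: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster": self.labels, "a": self.a, "b": self.b, "silhouette": self.s},
            index=self.ids,
        )


def silhouette(D: DissimilarityMatrix, labels: Sequence[int]) -> SilhouetteReport:
    """Silhouette widths for a partition of the units of ``D``.

    ``a(i)`` is the mean dissimilarity to the rest of i's cluster,
    ``b(i)`` the smallest mean dissimilarity to another cluster, and
    ``S(i) = (b - a) / max(a, b)``. Members of singleton clusters get
    S(i) = 0 by convention. Requires at least two non-empty clusters.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (D.n,):
        raise ParameterError(f"labels length {labels.shape} != number of units {D.n}")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ClusteringError("silhouette undefined for a single cluster")
    d = D.values
    a = np.zeros(D.n)
    b = np.zeros(D.n)
    s = np.zeros(D.n)
    for i in range(D.n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            continue  # singleton: S(i) = 0
        a[i] = d[i, own].sum() / (n_own - 1)
        b[i] = min(d[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a[i], b[i])
        s[i] = 0.0 if denom == 0 else (b[i] - a[i]) / denom
    cluster_means = {int(c): float(s[labels == c].mean()) for c in uniq}
    return SilhouetteReport(
        ids=D.ids,
        labels=labels,
        a=a,
        b=b,
        s=s,
        cluster_means=cluster_means,
        overall=float(s.mean()),
    )


@dataclass(frozen=True)
class ChooseKResult:
    k: int
    silhouette_by_k: Mapping[int, float]
    merge_heights: np.ndarray


def choose_k(
    tree: ClusterTree, D: DissimilarityMatrix, k_range: Iterable[int]
) -> ChooseKResult:
    """Pick the cut with maximal average silhouette over ``k_range``.

    Ties go to the smallest k. The result also carries the full merge
    height sequence so a scree plot can be inspected alongside.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ParameterError("k_range is empty")
    if ks[0] < 2 or ks[-1] > tree.n - 1:
        raise ParameterError(f"k_range must lie within [2, {tree.n - 1}], got {ks}")
    by_k = {k: silhouette(D, cut_dendrogram(tree, k)).overall for k in ks}
    best = max(by_k, key=lambda k: (by_k[k], -k))
    return ChooseKResult(k=best, silhouette_by_k=by_k, merge_heights=tree.heights)


@dataclass(frozen=True)
class ConcordanceReport:
    """Cluster x region contingency table with chance-corrected agreement
    (adjusted Rand index, in [-1, 1])."""

    table: pd.DataFrame
    ari: float


def region_concordance(
    ids: Sequence[str],
    labels: Sequence[int],
    region_map: Mapping[str, str],
) -> ConcordanceReport:
    """Cross-tabulate cluster labels against a unit -> region map and
    score their agreement with the adjusted Rand index."""
    ids = [str(i) for i in ids]
    missing = sorted(set(ids) - set(region_map))
    if missing:
        raise ParameterError(f"units without a region: {', '.join(missing)}")
    regions = [region_map[i] for i in ids]
    table = pd.crosstab(
        pd.Series(list(labels), index=ids, name="cluster"),
        pd.Series(regions, index=ids, name="region"),
    )
    return ConcordanceReport(table=table, ari=float(adjusted_rand_score(regions, list(labels))))
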