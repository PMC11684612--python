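"""Subsample-selection strategies for two-phase study designs.

Phase 1 profiles every sample cheaply (16S); these strategies pick the k
samples to carry into the expensive phase 2 (shotgun metagenomics).  Five
are driven by biological diversity structure:

- representative: PAM k-medoids on the Bray-Curtis matrix; the k medoids.
- diverse: top k by inverse Simpson diversity.
- extreme: the samples that merge earliest when an agglomerative
  dendrogram is built on the inverted dissimilarity (mutually most
  dissimilar samples join first).
- discriminant: samples closest to the centroid of the opposite phenotype
  class (ascending distance).
- distinct: samples farthest from the opposite-class centroid
  (descending distance).

Two are data driven, selecting from the extremes of an ordination:

- pca: 1/3 of k from each extreme of PC1, 1/6 from each extreme of PC2.
- spca: the same allocation on sparse principal-component scores.

All strategies are deterministic: ties break by position in the table's
sample order (samples are enumerated from lowest to highest sample ID
before ordination, and callers are expected to keep that convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.cluster.hierarchy import linkage
from sklearn.decomposition import PCA

from .diversity import DistanceMatrix, dissimilarity_matrix, simpson_profile
from .feature_table import FeatureTable, PhenotypeMetadata

__all__ = [
    "SelectionResult",
    "PcaModel",
    "select",
    "select_representative",
    "select_diverse",
    "select_extreme",
    "select_discriminant",
    "select_distinct",
    "select_pca",
    "class_centroid",
    "pca_scores",
    "pam",
    "METHODS",
]

METHODS = ("representative", "diverse", "extreme", "discriminant", "distinct", "pca", "spca")


@dataclass(frozen=True)
class SelectionResult:
    """An ordered subsample of k sample IDs with the scores that ranked them."""

    method: str
    k: int
    selected: tuple[str, ...]
    scores: dict[str, float] | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if len(self.selected) != self.k:
            raise ValueError(f"selected {len(self.selected)} samples, expected k={self.k}")
        if len(set(self.selected)) != self.k:
            raise ValueError("selected sample IDs are not unique")
        object.__setattr__(self, "selected", tuple(self.selected))

    def as_set(self) -> frozenset[str]:
        return frozenset(self.selected)


@dataclass(frozen=True)
class PcaModel:
    """Principal-component decomposition of a samples x features table."""

    sample_ids: tuple[str, ...]
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components
    explained_variance_fraction: np.ndarray
    sparse: bool = False
    keep_count: int | None = None


def _check_k(k: int, n: int, minimum: int = 1) -> None:
    if not (minimum <= k <= n):
        raise ValueError(f"k={k} out of range [{minimum}, {n}]")


def _require_relative(table: FeatureTable) -> None:
    if table.mode != "relative":
        raise ValueError("selection requires a relative-frequency table; "
                         "apply to_relative_frequency first")


# ---------------------------------------------------------------------------
# PAM k-medoids (deterministic BUILD + SWAP)

#: 2-exchange refinement is explored only while the neighbourhood stays
#: below this many candidate moves (it is quadratic in both k and n - k)
_PAM_DEEP_LIMIT = 50_000


def pam(d: np.ndarray, k: int) -> tuple[list[int], float]:
    """Partitioning Around Medoids on a precomputed distance matrix.

    Deterministic: BUILD greedily seeds the k medoids, then SWAP applies
    the best single medoid <-> non-medoid exchange until none lowers the
    total distance of points to their nearest medoid.  On small instances
    (where the move set stays under ``_PAM_DEEP_LIMIT``) a 2-exchange
    neighbourhood is additionally searched, which escapes the rare
    single-swap local optima.  Ties break toward the lowest index.

    Returns (sorted medoid indices, objective value).
    """
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    # BUILD: first medoid minimizes total distance; then greedy gain.
    medoids = [int(np.argmin(d.sum(axis=0)))]
    nearest = d[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.minimum(d, nearest[None, :]).sum(axis=1)
        gains[medoids] = np.inf
        j = int(np.argmin(gains))
        medoids.append(j)
        nearest = np.minimum(nearest, d[j])

    def objective(meds) -> float:
        return float(d[list(meds)].min(axis=0).sum())

    best = objective(medoids)
    if k == n:
        return sorted(medoids), best
    improved = True
    while improved:
        improved = False
        # best single swap, evaluated vectorized per removed medoid
        sub = d[medoids]  # k x n
        order = np.argsort(sub, axis=0, kind="stable")
        nearest_val = sub[order[0], np.arange(n)]
        nearest_arg = order[0]
        second_val = sub[order[1], np.arange(n)] if k >= 2 else np.full(n, np.inf)
        nonmed = np.array([h for h in range(n) if h not in medoids], dtype=int)
        cand_obj, cand = best, None
        for mi in range(k):
            base = np.where(nearest_arg == mi, second_val, nearest_val)
            objs = np.minimum(d[nonmed], base[None, :]).sum(axis=1)
            hi = int(np.argmin(objs))
            if objs[hi] < cand_obj - 1e-12:
                cand_obj = float(objs[hi])
                cand = medoids.copy()
                cand[mi] = int(nonmed[hi])
        # variable-neighbourhood descent: widen to r-exchanges while cheap
        r = 2
        while cand is None and r <= min(k, 3):
            moves = _comb(k, r) * _comb(n - k, r)
            if moves > _PAM_DEEP_LIMIT:
                break
            for mis in combinations(range(k), r):
                for hs in combinations(nonmed.tolist(), r):
                    trial = medoids.copy()
                    for mi, h in zip(mis, hs):
                        trial[mi] = h
                    obj = objective(trial)
                    if obj < cand_obj - 1e-12:
                        cand_obj, cand = obj, trial
            r += 1
        if cand is not None:
            medoids, best = cand, cand_obj
            improved = True
    return sorted(medoids), best


def _comb(n: int, r: int) -> int:
    from math import comb

    return comb(max(n, 0), r)


def pam_exhaustive(d: np.ndarray, k: int) -> tuple[list[int], float]:
    """Exact k-medoid optimum by enumeration (oracle; tiny n only)."""
    n = d.shape[0]
    best, best_meds = np.inf, None
    for meds in combinations(range(n), k):
        obj = float(d[list(meds)].min(axis=0).sum())
        if obj < best - 1e-12:
            best, best_meds = obj, list(meds)
    return best_meds, best


def select_representative(table: FeatureTable, k: int,
                          distances: DistanceMatrix | None = None) -> SelectionResult:
    """k medoids of PAM clustering on the Bray-Curtis matrix.

    Each medoid is the sample nearest the center of its cluster, so the
    subsample spans the community types present in the cohort.
    """
    _require_relative(table)
    _check_k(k, table.n_samples)
    dm = distances if distances is not None else dissimilarity_matrix(table)
    medoids, obj = pam(dm.d, k)
    selected = tuple(table.sample_ids[i] for i in medoids)
    return SelectionResult(
        method="representative", k=k, selected=selected,
        params={"objective": obj, "metric": dm.metric},
    )


# ---------------------------------------------------------------------------
# Ranking strategies

def _ranked_selection(table, k, scores: np.ndarray, method: str,
                      descending: bool, params: dict) -> SelectionResult:
    # stable sort => ties resolve by table sample order
    order = np.argsort(-scores if descending else scores, kind="stable")
    sel = [table.sample_ids[i] for i in order[:k]]
    return SelectionResult(
        method=method, k=k, selected=tuple(sel),
        scores={table.sample_ids[i]: float(scores[i]) for i in range(table.n_samples)},
        params=params,
    )


def select_diverse(table: FeatureTable, k: int) -> SelectionResult:
    """Top k samples by inverse Simpson diversity (most even communities).

    1/lambda and the Gini-Simpson 1-lambda are both strictly decreasing
    in lambda, so either form yields the same ranking.
    """
    _require_relative(table)
    _check_k(k, table.n_samples)
    inv = np.array(
        [simpson_profile(row, mode="relative").inverse_simpson for row in table.values]
    )
    return _ranked_selection(table, k, inv, "diverse", descending=True,
                             params={"score": "inverse_simpson"})


def class_centroid(table: FeatureTable, members) -> np.ndarray:
    """Mean relative-abundance vector of a set of samples."""
    members = list(members)
    if not members:
        raise ValueError("empty member set")
    idx = [table.sample_index(s) for s in members]
    return table.values[idx].mean(axis=0)


def _opposite_centroid_distances(table: FeatureTable,
                                 phenotype: PhenotypeMetadata) -> np.ndarray:
    from .diversity import bray_curtis

    labels = phenotype.label_array(table.sample_ids)
    dists = np.empty(table.n_samples)
    for cls in phenotype.classes:
        mask = labels == cls
        if not mask.any():
            raise ValueError(f"phenotype class {cls!r} has no samples in the table")
    centroids = {
        cls: class_centroid(table, [s for s, l in zip(table.sample_ids, labels) if l == cls])
        for cls in phenotype.classes
    }
    other = {phenotype.classes[0]: phenotype.classes[1],
             phenotype.classes[1]: phenotype.classes[0]}
    for i, lab in enumerate(labels):
        dists[i] = bray_curtis(table.values[i], centroids[other[lab]])
    return dists


def select_discriminant(table: FeatureTable, phenotype: PhenotypeMetadata,
                        k: int) -> SelectionResult:
    """k samples closest (Bray-Curtis) to the opposite phenotype class's
    centroid, ascending — the samples least typical of their own class."""
    _require_relative(table)
    _check_k(k, table.n_samples)
    d = _opposite_centroid_distances(table, phenotype)
    return _ranked_selection(table, k, d, "discriminant", descending=False,
                             params={"score": "bc_to_opposite_centroid"})


def select_distinct(table: FeatureTable, phenotype: PhenotypeMetadata,
                    k: int) -> SelectionResult:
    """k samples farthest from the opposite-class centroid, descending —
    the samples most typical of their own class."""
    _require_relative(table)
    _check_k(k, table.n_samples)
    d = _opposite_centroid_distances(table, phenotype)
    return _ranked_selection(table, k, d, "distinct", descending=True,
                             params={"score": "bc_to_opposite_centroid"})


# ---------------------------------------------------------------------------
# Extreme selection via inverted-dissimilarity dendrogram

def extreme_merge_order(dm: DistanceMatrix, linkage_method: str = "average") -> list[int]:
    """Sample indices in the order they first join another cluster when the
    dendrogram is built on the inverted dissimilarity d' = 1 - BC.

    d' is a strictly decreasing transform of BC (order-equivalent to the
    additive inverse -BC but non-negative), so the most mutually
    dissimilar samples merge first.  Ties: lower merge height first (the
    linkage orders merges by height), then sample order.
    """
    n = dm.n_samples
    inv = 1.0 - dm.d
    np.fill_diagonal(inv, 0.0)
    condensed = inv[np.triu_indices(n, k=1)]
    Z = linkage(condensed, method=linkage_method)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    order: list[int] = []
    seen: set[int] = set()
    for step, (a, b, _h, _cnt) in enumerate(Z):
        merged = members.pop(int(a)) + members.pop(int(b))
        members[n + step] = merged
        for idx in sorted(set(merged) - seen):
            order.append(idx)
            seen.add(idx)
    return order


def select_extreme(table: FeatureTable, k: int, linkage: str = "average",
                   distances: DistanceMatrix | None = None) -> SelectionResult:
    """First k samples in merge order of the inverted-dissimilarity
    dendrogram: the mutually most dissimilar (outlying) samples."""
    _require_relative(table)
    _check_k(k, table.n_samples, minimum=2)
    dm = distances if distances is not None else dissimilarity_matrix(table)
    order = extreme_merge_order(dm, linkage_method=linkage)
    selected = tuple(table.sample_ids[i] for i in order[:k])
    return SelectionResult(method="extreme", k=k, selected=selected,
                           params={"linkage": linkage})


# ---------------------------------------------------------------------------
# Ordination-driven strategies

def _sparse_pca(x: np.ndarray, n_components: int, keep_count: int,
                max_iter: int = 500, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Cardinality-constrained sparse PCA by hard-thresholded power
    iteration with projection deflation, initialized from the dense PCA
    loadings.  Deterministic; with keep_count = n_features it reduces to
    plain power iteration and recovers the dense solution."""
    n, m = x.shape
    xc = x - x.mean(axis=0)
    init = PCA(n_components=n_components).fit(xc).components_  # comps x feats
    loadings = np.zeros((m, n_components))
    xd = xc.copy()
    for c in range(n_components):
        v = init[c].copy()
        v /= np.linalg.norm(v)
        for _ in range(max_iter):
            z = xd.T @ (xd @ v)
            if keep_count < m:
                keep = np.argsort(-np.abs(z), kind="stable")[:keep_count]
                mask = np.zeros(m, dtype=bool)
                mask[keep] = True
                z = np.where(mask, z, 0.0)
            nz = np.linalg.norm(z)
            if nz == 0:
                break
            z /= nz
            if np.linalg.norm(z - v) < tol:
                v = z
                break
            v = z
        if v @ init[c] < 0:  # align sign with the dense initialization
            v = -v
        loadings[:, c] = v
        s = xd @ v
        xd = xd - np.outer(s, v)  # projection deflation
    scores = xc @ loadings
    return scores, loadings


def pca_scores(table: FeatureTable, n_components: int = 2, sparse: bool = False,
               keep_count: int | None = None) -> PcaModel:
    """Centered (covariance-based, unscaled) PCA of the samples.

    The sparse variant constrains each component's loadings to at most
    ``keep_count`` non-zero features (default ceil(0.1 * n_features)).
    """
    x = table.values
    if n_components > min(table.n_samples, table.n_features):
        raise ValueError("n_components exceeds min(n_samples, n_features)")
    xc = x - x.mean(axis=0)
    total_var = float((xc**2).sum() / (table.n_samples - 1))
    if total_var <= 0:
        raise ValueError("table has zero variance; PCA is degenerate")
    if sparse:
        if keep_count is None:
            keep_count = max(1, int(np.ceil(0.1 * table.n_features)))
        if keep_count < 1:
            raise ValueError("keep_count must be >= 1")
        scores, loadings = _sparse_pca(x, n_components, keep_count)
        comp_var = scores.var(axis=0, ddof=1)
        evf = comp_var / total_var
    else:
        model = PCA(n_components=n_components)
        scores = model.fit_transform(x)
        loadings = model.components_.T
        evf = model.explained_variance_ratio_
    return PcaModel(
        sample_ids=table.sample_ids,
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=np.asarray(evf, dtype=float),
        sparse=sparse,
        keep_count=keep_count if sparse else None,
    )


def _take_extremes(order: list[int], chosen: set[int], count: int) -> list[int]:
    """Take ``count`` yet-unchosen indices from the front of a sorted order."""
    picked = []
    for i in order:
        if len(picked) == count:
            break
        if i not in chosen:
            picked.append(i)
            chosen.add(i)
    return picked


def select_pca(table: FeatureTable, k: int, sparse: bool = False,
               keep_count: int | None = None,
               model: PcaModel | None = None) -> SelectionResult:
    """Select from the extremes of the first two principal components.

    Allocation: floor(k/3) samples from each extreme of PC1, then, among
    the samples not yet selected, floor(k/6) from each extreme of PC2;
    any remainder is allocated one at a time alternating PC1-top,
    PC1-bottom, PC2-top, PC2-bottom.  Ties break by sample order.  The
    ``spca`` method is the same allocation on sparse scores.
    """
    _require_relative(table)
    _check_k(k, table.n_samples)
    if model is None:
        n_comp = min(2, table.n_samples - 1, table.n_features)
        model = pca_scores(table, n_components=n_comp, sparse=sparse,
                           keep_count=keep_count)
    pc1 = model.scores[:, 0]
    pc2 = model.scores[:, 1] if model.scores.shape[1] > 1 else np.zeros_like(pc1)
    # stable sorts => score ties resolve by sample order at either extreme
    pc1_top = list(np.argsort(-pc1, kind="stable"))
    pc1_bot = list(np.argsort(pc1, kind="stable"))
    pc2_top = list(np.argsort(-pc2, kind="stable"))
    pc2_bot = list(np.argsort(pc2, kind="stable"))
    a, b = k // 3, k // 6
    r = k - 2 * a - 2 * b
    chosen: set[int] = set()
    picked: list[int] = []
    picked += _take_extremes(pc1_top, chosen, a)
    picked += _take_extremes(pc1_bot, chosen, a)
    picked += _take_extremes(pc2_top, chosen, b)
    picked += _take_extremes(pc2_bot, chosen, b)
    rotation = [pc1_top, pc1_bot, pc2_top, pc2_bot]
    ri = 0
    while r > 0:
        got = _take_extremes(rotation[ri % 4], chosen, 1)
        picked += got
        r -= len(got)
        ri += 1
    selected = tuple(table.sample_ids[i] for i in picked)
    method = "spca" if sparse else "pca"
    return SelectionResult(
        method=method, k=k, selected=selected,
        scores={table.sample_ids[i]: float(pc1[i]) for i in range(table.n_samples)},
        params={
            "allocation": {"pc1_per_extreme": a, "pc2_per_extreme": b, "remainder": k - 2 * a - 2 * b},
            "explained_variance_fraction": [float(v) for v in model.explained_variance_fraction],
            "keep_count": model.keep_count,
        },
    )


# ---------------------------------------------------------------------------

def select(method: str, table: FeatureTable, k: int,
           phenotype: PhenotypeMetadata | None = None, **params) -> SelectionResult:
    """Dispatch a selection strategy by name."""
    if method == "representative":
        return select_representative(table, k, **params)
    if method == "diverse":
        return select_diverse(table, k)
    if method == "extreme":
        return select_extreme(table, k, **params)
    if method in ("discriminant", "distinct"):
        if phenotype is None:
            raise ValueError(f"{method} selection requires phenotype metadata")
        fn = select_discriminant if method == "discriminant" else select_distinct
        return fn(table, phenotype, k)
    if method == "pca":
        return select_pca(table, k, sparse=False, **params)
    if method == "spca":
        return select_pca(table, k, sparse=True, **params)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
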