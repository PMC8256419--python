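"""Regulation filtering, left-censored imputation, normalization, clustering.

The preprocessing chain mirrors standard practice for SILAC-style
phosphoproteomics ratio tables:

1. keep only *regulated* sites — at most one missing ratio and at least one
   ratio outside [0.5, 2];
2. impute remaining missing cells by draws from a left-censoring model — a
   normal distribution fitted to the observed log2 ratios of each condition,
   truncated above at a low quantile of that column (missing-not-at-random
   values sit below the detection limit);
3. optionally quantile-normalize conditions to a common distribution;
4. cluster site profiles with fuzzy C-means or k-means, with the cluster
   number chosen by the elbow or silhouette method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import BadK, InsufficientData, MissingData
from .io_formats import QuantTable, SiteID


@dataclass
class ClusterAssignment:
    """Hard (and, for FCM, fuzzy) cluster labels for every site.

    ``labels`` maps each site to a cluster index in 1..k. In fuzzy mode
    ``memberships`` holds the |sites| × k membership matrix (rows sum to 1)
    aligned with ``site_order``; the hard label is the argmax membership.
    """

    labels: dict[SiteID, int]
    memberships: np.ndarray | None = None
    site_order: list[SiteID] | None = None

    @property
    def k(self) -> int:
        return max(self.labels.values()) if self.labels else 0

    def cluster_ids(self) -> list[int]:
        return sorted(set(self.labels.values()))

    def sites_in(self, cluster: int) -> list[SiteID]:
        return [s for s, c in self.labels.items() if c == cluster]


def filter_regulated_sites(
    qt: QuantTable,
    max_missing: int = 1,
    lo: float = 0.5,
    hi: float = 2.0,
) -> QuantTable:
    """Keep sites with ≤ ``max_missing`` missing ratios and at least one
    observed ratio strictly above ``hi`` or strictly below ``lo``.

    Idempotent; an empty result is allowed.
    """
    if not lo < hi:
        raise ValueError(f"need lo < hi, got {lo} >= {hi}")
    keep: list[int] = []
    for i in range(qt.n_sites):
        row = qt.values[i]
        obs = row[~np.isnan(row)]
        n_missing = len(row) - len(obs)
        if n_missing > max_missing:
            continue
        if np.any(obs > hi) or np.any(obs < lo):
            keep.append(i)
    return QuantTable(
        [qt.sites[i] for i in keep],
        list(qt.conditions),
        qt.values[keep].copy() if keep else np.empty((0, len(qt.conditions))),
    )


def impute_left_censored(
    qt: QuantTable,
    seed: int,
    censor_quantile: float = 0.01,
) -> QuantTable:
    """Impute missing ratios from a truncated-normal left-censoring model.

    Per condition, a normal distribution is fitted to the observed log2
    ratios and truncated above at the ``censor_quantile`` quantile of those
    observed log2 values; missing cells receive back-transformed draws.
    Observed cells are never altered. Deterministic given ``seed``.

    Raises :class:`InsufficientData` if any column with missing cells has
    fewer than 3 observations.
    """
    out = qt.copy()
    mask = out.mask
    if not mask.any():
        return out
    rng = np.random.default_rng(seed)
    log_values = np.log2(out.values)
    for j, cond in enumerate(out.conditions):
        col_missing = np.flatnonzero(mask[:, j])
        obs = log_values[~mask[:, j], j]
        if len(obs) < 3:
            raise InsufficientData(
                f"column {cond!r} has {len(obs)} observations (< 3)"
            )
        if len(col_missing) == 0:
            continue
        mu, sd = float(np.mean(obs)), float(np.std(obs, ddof=1))
        upper = float(np.quantile(obs, censor_quantile))
        if sd <= 0:
            draws = np.full(len(col_missing), upper)
        else:
            b = (upper - mu) / sd
            draws = stats.truncnorm.rvs(
                -np.inf, b, loc=mu, scale=sd, size=len(col_missing), random_state=rng
            )
        out.values[col_missing, j] = 2.0 ** draws
    return out


def quantile_normalize(qt: QuantTable) -> QuantTable:
    """Force every condition column onto the common rank-mean distribution.

    After the operation all columns share the identical sorted value vector
    (the per-rank mean of the input columns); within-column order is
    preserved. Requires a complete matrix.
    """
    if qt.mask.any():
        raise MissingData("quantile normalization requires a complete matrix")
    X = qt.values
    n = X.shape[0]
    rank_means = np.sort(X, axis=0).mean(axis=1)
    ranks = np.apply_along_axis(stats.rankdata, 0, X)  # average ties
    out = np.interp(ranks, np.arange(1, n + 1), rank_means)
    return QuantTable(list(qt.sites), list(qt.conditions), out)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _fcm(
    X: np.ndarray,
    k: int,
    m: float,
    seed: int,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> np.ndarray:
    """Fuzzy C-means membership matrix (Bezdek alternating optimization)."""
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    u = rng.random((n, k))
    u /= u.sum(axis=1, keepdims=True)
    exponent = 2.0 / (m - 1.0)
    for _ in range(max_iter):
        w = u ** m
        centers = (w.T @ X) / w.sum(axis=0)[:, None]
        d = np.maximum(cdist(X, centers), 1e-12)
        inv = d ** (-exponent)
        u_new = inv / inv.sum(axis=1, keepdims=True)
        if np.abs(u_new - u).max() < tol:
            return u_new
        u = u_new
    return u


def cluster_profiles(
    qt: QuantTable,
    k: int,
    method: str = "fcm",
    fuzzifier: float = 2.0,
    seed: int = 0,
) -> ClusterAssignment:
    """Cluster site profiles into ``k`` groups.

    ``method`` is ``"fcm"`` (fuzzy C-means, memberships returned, hard label
    = argmax) or ``"kmeans"`` (25 restarts). Cluster indices run 1..k and are
    renumbered by first appearance in site order, so the labeling is
    deterministic given the seed.
    """
    if not 1 <= k <= qt.n_sites:
        raise BadK(f"k={k} out of range [1, {qt.n_sites}]")
    if qt.mask.any():
        raise MissingData("clustering requires a complete matrix")
    X = qt.values
    memberships: np.ndarray | None = None
    if method == "fcm":
        memberships = _fcm(X, k, fuzzifier, seed)
        raw = memberships.argmax(axis=1)
    elif method == "kmeans":
        km = KMeans(n_clusters=k, n_init=25, random_state=seed)
        raw = km.fit_predict(X)
    else:
        raise ValueError(f"unknown method {method!r}")
    # renumber clusters by first appearance -> stable 1..k labels
    remap: dict[int, int] = {}
    for lbl in raw:
        if lbl not in remap:
            remap[lbl] = len(remap) + 1
    labels = {site: remap[lbl] for site, lbl in zip(qt.sites, raw)}
    if memberships is not None:
        order = [old for old, _ in sorted(remap.items(), key=lambda kv: kv[1])]
        # clusters that never win an argmax keep their columns, appended after
        order += [c for c in range(k) if c not in remap]
        memberships = memberships[:, order]
    return ClusterAssignment(labels, memberships, list(qt.sites))


def _wss(X: np.ndarray, k: int, seed: int) -> float:
    km = KMeans(n_clusters=k, n_init=25, random_state=seed)
    km.fit(X)
    return float(km.inertia_)


def select_k(
    qt: QuantTable,
    k_range,
    method: str = "silhouette",
    seed: int = 0,
) -> int:
    """Choose a cluster number over ``k_range``.

    ``elbow`` picks the k maximizing the second difference of the
    within-cluster sum of squares (the sharpest bend of the WSS curve);
    ``silhouette`` maximizes the mean silhouette width. A length-1 range
    returns its only value.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise BadK("empty k_range")
    if qt.mask.any():
        raise MissingData("k selection requires a complete matrix")
    if any(k < 1 or k > qt.n_sites for k in ks):
        raise BadK(f"k_range {ks} outside [1, {qt.n_sites}]")
    if len(ks) == 1:
        return ks[0]
    X = qt.values
    if method == "elbow":
        wss = [_wss(X, k, seed) for k in ks]
        if len(ks) < 3:
            return ks[0]
        second_diff = [
            wss[i - 1] - 2 * wss[i] + wss[i + 1] for i in range(1, len(ks) - 1)
        ]
        return ks[1 + int(np.argmax(second_diff))]
    if method == "silhouette":
        best_k, best_score = ks[0], -np.inf
        for k in ks:
            if k < 2 or k > qt.n_sites - 1:
                raise BadK(f"silhouette needs 2 <= k <= n_sites-1, got {k}")
            labels = KMeans(n_clusters=k, n_init=25, random_state=seed).fit_predict(X)
            score = silhouette_score(X, labels)
            if score > best_score:
                best_k, best_score = k, score
        return best_k
    raise ValueError(f"unknown method {method!r}")
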