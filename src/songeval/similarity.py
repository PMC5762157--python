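"""Syllable distances, the dissimilarity index, clustering and tutor scoring.

Two distance channels are computed over a set of syllables: Euclidean
distance between 101-entry summary vectors, and dynamic time warping (with a
warping penalty) over the five per-frame feature tracks.  Each channel is
rank-normalized to percentiles over all pairs, the two are fused by their
geometric mean, and a final dissimilarity index is obtained as one minus the
Pearson correlation between rows of the combined matrix — a score between 0
(perfect similarity) and 2 (complete anticorrelation, no similarity).
Syllable types are complete-linkage clusters of this index; a rendition's
tutor similarity is its index to the closest tutor syllable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .features import DTW_FEATURES, FeatureTrack

log = logging.getLogger(__name__)

UNCLASSIFIED = "UNCLASSIFIED"
DEFAULT_WARP_PENALTY = 0.6  # in pooled-z frame-cost units; see methods note
DEFAULT_K_RANGE = (4, 25)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise syllable distances with a named channel."""

    values: np.ndarray
    ids: list[str]
    channel: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.ids):
            raise ValueError("ids do not match matrix size")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T]):
            raise ValueError("distance matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class ClusterAssignment:
    """Syllable-type labels from complete-linkage clustering."""

    labels: pd.Series  # syllable_id -> "type_<i>" or UNCLASSIFIED
    k: int
    merge_log: list = field(default_factory=list)

    def members(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    @property
    def classified_fraction(self) -> float:
        return float((self.labels != UNCLASSIFIED).mean())


def summary_euclidean(
    vectors: pd.DataFrame, standardize: bool = True
) -> DistanceMatrix:
    """Euclidean distances between 101-entry summary vectors.

    Dimensions are z-scored across syllables by default (the 101 summary
    statistics have wildly different units); zero-variance dimensions are
    dropped from the metric.
    """
    if vectors.shape[1] != 101:
        raise ValueError(f"summary vectors must have 101 entries, got {vectors.shape[1]}")
    x = vectors.to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=0)
        mu = x.mean(axis=0)
        keep = sd > 0
        x = (x[:, keep] - mu[keep]) / sd[keep]
    d = squareform(pdist(x, metric="euclidean"))
    return DistanceMatrix(d, list(vectors.index), "summary_euclidean")


@njit(cache=True)
def _dtw_kernel(a: np.ndarray, b: np.ndarray, penalty: float) -> float:  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    big = 1e300
    prev = np.full(m + 1, big)
    cur = np.full(m + 1, big)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            c = 0.0
            for f in range(a.shape[1]):
                dd = a[i - 1, f] - b[j - 1, f]
                c += dd * dd
            c = np.sqrt(c)
            if i == 1 and j == 1:
                best = 0.0
            else:
                best = prev[j - 1]  # diagonal
                if prev[j] + penalty < best:
                    best = prev[j] + penalty
                if cur[j - 1] + penalty < best:
                    best = cur[j - 1] + penalty
            cur[j] = c + best
        prev, cur = cur, prev
        cur[:] = big
    return prev[m]


def dtw_distance(
    a: FeatureTrack | np.ndarray,
    b: FeatureTrack | np.ndarray,
    warp_penalty: float = DEFAULT_WARP_PENALTY,
    feature_scales: np.ndarray | None = None,
) -> float:
    """Dynamic-time-warping distance between two feature tracks.

    Minimal accumulated frame-to-frame Euclidean cost over monotone
    alignment paths; every non-diagonal step adds ``warp_penalty``, which
    penalizes temporal stretching while tolerating small timing
    perturbations of sub-syllabic events.  Symmetric in its arguments.

    ``feature_scales`` divides each feature column before the cost is
    computed (used by :func:`dtw_matrix` to pool-standardize units).
    """
    xa = a.dtw_array() if isinstance(a, FeatureTrack) else np.atleast_2d(np.asarray(a, float).T).T
    xb = b.dtw_array() if isinstance(b, FeatureTrack) else np.atleast_2d(np.asarray(b, float).T).T
    if xa.ndim == 1:
        xa = xa[:, None]
    if xb.ndim == 1:
        xb = xb[:, None]
    if xa.size == 0 or xb.size == 0:
        raise ValueError("empty feature track")
    if xa.shape[1] != xb.shape[1]:
        raise ValueError("tracks must share the same feature set")
    if feature_scales is not None:
        xa = xa / feature_scales
        xb = xb / feature_scales
    return float(_dtw_kernel(np.ascontiguousarray(xa, float),
                             np.ascontiguousarray(xb, float),
                             float(warp_penalty)))


def dtw_matrix(
    tracks: list[FeatureTrack],
    warp_penalty: float = DEFAULT_WARP_PENALTY,
) -> DistanceMatrix:
    """All-pairs DTW distances over the five-feature tracks.

    Features are standardized by their pooled across-frame standard
    deviation (computed over all tracks) so that Hz-scaled and log-scaled
    features contribute comparably to the frame cost.
    """
    if not tracks:
        raise ValueError("no tracks")
    arrays = [tr.dtw_array() for tr in tracks]
    pooled = np.concatenate(arrays, axis=0)
    scales = pooled.std(axis=0, ddof=0)
    scales[scales <= 0] = 1.0
    xs = [np.ascontiguousarray(a / scales) for a in arrays]
    n = len(xs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _dtw_kernel(xs[i], xs[j], float(warp_penalty))
    return DistanceMatrix(d, [tr.syllable_id for tr in tracks], "dtw")


def percentile_normalize(d: DistanceMatrix) -> DistanceMatrix:
    """Replace each off-diagonal distance by its percentile rank over all pairs.

    Mid-rank ties; output values lie in (0, 1) on the grid
    ``(rank - 0.5) / n_pairs`` (all-tied input maps to exactly 0.5).
    """
    if d.n < 2:
        raise ValueError("need at least 2 syllables")
    cond = squareform(d.values, checks=False)
    ranks = rankdata(cond, method="average")
    pct = (ranks - 0.5) / cond.size
    if np.all(cond == cond[0]):
        log.warning("all pairwise distances tied; percentiles set to 0.5")
    return DistanceMatrix(squareform(pct), d.ids, "percentile")


def combine(p1: DistanceMatrix, p2: DistanceMatrix) -> DistanceMatrix:
    """Element-wise geometric mean of two percentile channels."""
    if p1.ids != p2.ids:
        raise ValueError("id mismatch between channels")
    if p1.channel != "percentile" or p2.channel != "percentile":
        raise ValueError("combine expects percentile channels")
    return DistanceMatrix(np.sqrt(p1.values * p2.values), p1.ids, "combined")


def dissimilarity_index(c: DistanceMatrix) -> DistanceMatrix:
    """One minus the correlation between rows of the combined matrix.

    Each syllable is characterized by its combined-distance profile to all
    syllables; entry (i, j) is ``1 - Pearson(row_i, row_j)``, in [0, 2]:
    identical profiles give 0, perfectly anticorrelated profiles give 2.
    For each pair the two structural entries at positions i and j (the zero
    diagonal and the pair's own distance) are excluded from the correlation,
    so a rendition with the same profile as a tutor syllable scores exactly
    0 against it.  Zero-variance profiles have undefined correlation and are
    flagged NaN.
    """
    if c.channel not in ("combined", "percentile"):
        raise ValueError("dissimilarity_index expects the combined channel")
    if c.n < 3:
        raise ValueError("need at least 3 syllables")
    x = c.values
    n = c.n
    m = n - 2  # entries used per pair after excluding positions i and j
    # Masked-correlation sums in closed form: the diagonal is zero, so only
    # the pair's own distance R_ij leaves each row sum / square / product.
    rs = x.sum(axis=1)
    rq = (x**2).sum(axis=1)
    sx = rs[:, None] - x
    sy = rs[None, :] - x
    sxx = rq[:, None] - x**2
    syy = rq[None, :] - x**2
    sxy = x @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / m
        vx = sxx - sx**2 / m
        vy = syy - sy**2 / m
        r = cov / np.sqrt(vx * vy)
    d = 1.0 - r
    bad = ~np.isfinite(d)
    np.fill_diagonal(bad, False)
    if bad.any():
        log.warning("%d pair(s) with zero-variance profile flagged NaN",
                    int(bad.sum() // 2))
        d[bad] = np.nan
    d = np.clip(d, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, c.ids, "dissimilarity_index")


def combined_distance(
    vectors: pd.DataFrame,
    tracks: list[FeatureTrack],
    warp_penalty: float = DEFAULT_WARP_PENALTY,
) -> DistanceMatrix:
    """Full distance chain: two channels -> percentiles -> geometric mean ->
    dissimilarity index."""
    ids = list(vectors.index)
    track_ids = [tr.syllable_id for tr in tracks]
    if ids != track_ids:
        raise ValueError("summary vectors and tracks must list the same syllables")
    p1 = percentile_normalize(summary_euclidean(vectors))
    p2 = percentile_normalize(dtw_matrix(tracks, warp_penalty))
    return dissimilarity_index(combine(p1, p2))


def _medoid(values: np.ndarray, members: np.ndarray) -> int:
    """Index (into the full matrix) of the member minimizing summed distance."""
    sub = values[np.ix_(members, members)]
    return int(members[np.argmin(np.nansum(sub, axis=1))])


def cluster_syllables(
    d: DistanceMatrix,
    k: int,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    max_scatter: float | None = None,
    merge: list[list[str]] | None = None,
    enforce_k_range: bool = True,
) -> ClusterAssignment:
    """Complete-linkage clustering of the dissimilarity index into ``k`` types.

    Clusters whose scatter (mean member-to-medoid index) exceeds
    ``max_scatter`` are rejected: their members become ``UNCLASSIFIED``,
    mirroring the fact that not all juvenile syllables form coherent types.
    ``merge`` lists groups of resulting type labels to merge (a declarative
    replacement for manual cluster curation).
    """
    if d.channel != "dissimilarity_index":
        raise ValueError("clustering expects the dissimilarity_index channel")
    if enforce_k_range and not (k_range[0] <= k <= k_range[1]):
        raise ValueError(f"k={k} outside configured range {k_range}")
    if d.n < k:
        raise ValueError(f"cannot form {k} clusters from {d.n} syllables")
    vals = np.nan_to_num(d.values, nan=2.0)
    merge_log: list = []
    if np.nanmax(vals) == 0:
        log.warning("all syllables identical; single degenerate cluster")
        labels = pd.Series("type_1", index=d.ids)
        merge_log.append("degenerate: all distances zero")
        return ClusterAssignment(labels=labels, k=1, merge_log=merge_log)
    z = linkage(squareform(vals, checks=False), method="complete")
    flat = fcluster(z, t=k, criterion="maxclust")
    labels = pd.Series([f"type_{c}" for c in flat], index=d.ids)

    if merge:
        for group in merge:
            target = group[0]
            for other in group[1:]:
                labels[labels == other] = target
                merge_log.append(f"merged {other} -> {target}")

    if max_scatter is not None:
        for lab in labels.unique():
            members = np.flatnonzero((labels == lab).to_numpy())
            sc = cluster_scatter(d, [d.ids[i] for i in members])
            if sc > max_scatter:
                labels[labels == lab] = UNCLASSIFIED
                merge_log.append(f"rejected {lab}: scatter {sc:.3f} > {max_scatter}")
    return ClusterAssignment(labels=labels, k=k, merge_log=merge_log)


def prototypicality(d: DistanceMatrix, assignment: ClusterAssignment) -> pd.Series:
    """Distance of each classified rendition to its cluster center (medoid).

    The dissimilarity index is not embeddable in a vector space, so the
    cluster center is the medoid under the index; unclassified renditions
    get NaN.
    """
    scores = pd.Series(np.nan, index=assignment.labels.index, dtype=float)
    for lab in assignment.labels.unique():
        if lab == UNCLASSIFIED:
            continue
        members = np.flatnonzero((assignment.labels == lab).to_numpy())
        med = _medoid(d.values, members)
        for i in members:
            scores.iloc[i] = d.values[i, med]
    return scores


def cluster_scatter(d: DistanceMatrix, member_ids: list[str]) -> float:
    """Mean member-to-medoid dissimilarity (lower = tighter cluster)."""
    if not member_ids:
        raise ValueError("empty cluster")
    idx = np.array([d.ids.index(m) for m in member_ids])
    med = _medoid(d.values, idx)
    return float(np.nanmean(d.values[idx, med]))


def tutor_similarity(
    d: DistanceMatrix,
    juvenile_ids: list[str],
    tutor_ids: list[str],
) -> pd.DataFrame:
    """Tutor-similarity score per rendition: index to the closest tutor.

    ``d`` must be a dissimilarity-index matrix computed jointly over tutors
    and juvenile renditions (the index needs a common row space).  Scores
    are on the 0-2 scale with 0 = perfect similarity.
    """
    if not tutor_ids:
        raise ValueError("empty tutor set")
    pos = {s: i for i, s in enumerate(d.ids)}
    t_idx = np.array([pos[t] for t in tutor_ids])
    rows = []
    for j in juvenile_ids:
        dd = d.values[pos[j], t_idx]
        best = int(np.nanargmin(dd))
        rows.append({"syllable_id": j, "tutor_similarity": float(dd[best]),
                     "closest_tutor": tutor_ids[best]})
    return pd.DataFrame(rows)


def median_split(scores: pd.Series, min_n: int = 40) -> pd.Series:
    """Median split of tutor-similarity distance scores into high/low halves.

    Lower distance = more tutor-similar, so the lower half is labeled
    ``high`` (similarity) and the upper half ``low``; counts differ by at
    most one, with the extra rendition going to ``high`` for odd n.  Ties at
    the median are broken by stable order.

    Raises
    ------
    ValueError
        If fewer than ``min_n`` renditions are available (the
        40-classified-syllable inclusion rule); callers exclude the
        recording.
    """
    n = len(scores)
    if n < min_n:
        raise ValueError(f"only {n} renditions; need >= {min_n}")
    order = np.argsort(scores.to_numpy(), kind="stable")
    labels = np.empty(n, dtype=object)
    n_high = (n + 1) // 2
    labels[order[:n_high]] = "high"
    labels[order[n_high:]] = "low"
    return pd.Series(labels, index=scores.index, name="split")
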