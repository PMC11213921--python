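"""Odor response vectors: matrix normalization, VRC-elbow k-means,
mixture-specific units, and response-map consistency.

Response magnitudes from many animals are pooled into a units x stimuli
matrix, normalized per animal (minimum-subtracted square-root transform,
then animal-wide z-scaling) and per row (rescaled to [-1, 1]), projected
onto principal components retaining >= 99% of the variance, and clustered
with k-means.  The number of clusters is picked on the Variance Ratio
Criterion curve

    VRC(k) = SSB * (N - k) / (SSW * (k - 1)),

with SSB/SSW the between/within-cluster sums of squares and N the number of
observations, choosing the k whose point lies farthest from the chord joining
the curve's endpoints (the elbow).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "ResponseMatrix",
    "VRCCurve",
    "normalize_matrix",
    "vrc",
    "choose_k_elbow",
    "kmeans_online",
    "cluster_vectors",
    "mixture_specific_fraction",
    "consistency_analysis",
    "linkage_to_newick",
]

log = logging.getLogger(__name__)


@dataclass
class ResponseMatrix:
    """Units x stimuli response magnitudes with per-row animal/phenotype."""

    values: np.ndarray                 # (n_units, n_stimuli)
    stimuli: tuple
    animal: np.ndarray                 # (n_units,) animal id per row
    phenotype: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.animal = np.asarray(self.animal)
        if self.values.shape != (self.animal.size, len(self.stimuli)):
            raise ValueError("values shape inconsistent with animals/stimuli")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("missing entries in response matrix")


@dataclass
class VRCCurve:
    k_values: np.ndarray
    vrc_values: np.ndarray
    ssb: np.ndarray
    ssw: np.ndarray
    N: int
    chosen_k: int | None = None
    degenerate: bool = False           # some SSW == 0


def normalize_matrix(raw: ResponseMatrix) -> ResponseMatrix:
    """Per-animal minimum-subtraction, square-root transform and z-scaling,
    then per-row rescaling to [-1, 1].

    The square root tames the right-skew of dF/F0 magnitudes; the animal-wise
    z-scale removes inter-animal gain differences; the row rescale makes every
    unit's tuning pattern comparable regardless of absolute response size.
    Constant rows map to all-zeros (warned).
    """
    if raw.normalized:
        return raw
    vals = raw.values.copy()
    for aid in np.unique(raw.animal):
        sel = raw.animal == aid
        block = vals[sel]
        block = np.sqrt(block - block.min())
        sd = block.std()
        block = (block - block.mean()) / (sd if sd > 0 else 1.0)
        vals[sel] = block
    # per-row rescale to [-1, 1]
    lo = vals.min(axis=1, keepdims=True)
    hi = vals.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span.ravel() == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant rows mapped to zeros")
    span[span == 0] = 1.0
    vals = 2.0 * (vals - lo) / span - 1.0
    vals[flat] = 0.0
    return ResponseMatrix(vals, raw.stimuli, raw.animal, raw.phenotype,
                          normalized=True)


def _ss(points: np.ndarray, labels: np.ndarray):
    grand = points.mean(axis=0)
    ssb = ssw = 0.0
    for lab in np.unique(labels):
        sub = points[labels == lab]
        mu = sub.mean(axis=0)
        ssb += sub.shape[0] * float(((mu - grand) ** 2).sum())
        ssw += float(((sub - mu) ** 2).sum())
    return ssb, ssw


def vrc(points, labels) -> float:
    """Variance Ratio Criterion of a labeling: SSB(N-k) / (SSW(k-1)).

    Returns +inf when SSW is zero (perfectly tight clusters)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1 and np.asarray(labels).size > 1:
        points = points.T
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = uniq.size
    if k < 2:
        raise ValueError("need at least 2 non-empty clusters")
    N = points.shape[0]
    ssb, ssw = _ss(points, labels)
    if ssw == 0:
        return float("inf")
    return ssb * (N - k) / (ssw * (k - 1))


def choose_k_elbow(curve: VRCCurve) -> int:
    """Elbow of the VRC curve: the k farthest (perpendicular distance) from
    the chord joining the first and last finite VRC points; ties and a
    perfectly linear curve give the smallest k."""
    k = np.asarray(curve.k_values, dtype=float)
    v = np.asarray(curve.vrc_values, dtype=float)
    finite = np.isfinite(v)
    if not finite.all():
        warnings.warn("non-finite VRC values excluded from elbow chord")
    k, v = k[finite], v[finite]
    if k.size == 0:
        raise ValueError("no finite VRC values")
    if k.size == 1:
        return int(k[0])
    p0 = np.array([k[0], v[0]])
    p1 = np.array([k[-1], v[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    pts = np.column_stack([k, v]) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
    best = int(k[dist.argmax()])  # argmax returns the first (smallest k) tie
    return best


def _online_pass(X, labels, centers, counts):
    """MacQueen-style single-point reassignment pass; returns #moves.

    Moving point x from cluster a to b changes the total within-cluster sum
    of squares by n_b/(n_b+1)*d(x,c_b)^2 - n_a/(n_a-1)*d(x,c_a)^2; a point is
    moved when that change is negative, with centroids updated incrementally.
    """
    moves = 0
    k = centers.shape[0]
    for i in range(X.shape[0]):
        a = labels[i]
        if counts[a] <= 1:
            continue
        x = X[i]
        d2 = ((centers - x) ** 2).sum(axis=1)
        gain_stay = counts[a] / (counts[a] - 1) * d2[a]
        costs = np.array([counts[b] / (counts[b] + 1) * d2[b] if b != a else np.inf
                          for b in range(k)])
        b = int(costs.argmin())
        if costs[b] < gain_stay:
            centers[a] = (centers[a] * counts[a] - x) / (counts[a] - 1)
            centers[b] = (centers[b] * counts[b] + x) / (counts[b] + 1)
            counts[a] -= 1
            counts[b] += 1
            labels[i] = b
            moves += 1
    return moves


def kmeans_online(X: np.ndarray, k: int, n_replicates: int = 500,
                  seed: int = 0, max_iter: int = 1_000_000,
                  online_passes: int = 10):
    """Best-of-replicates k-means (squared Euclidean) with an online update
    phase after batch convergence.

    Each replicate is an independent centroid initialization; the replicate
    with the lowest within-cluster sum of squares wins.  After the batch
    (Lloyd) phase converges, single-point reassignment passes run until no
    point moves (or ``online_passes`` passes).
    """
    if X.shape[0] < k:
        raise ValueError("fewer rows than clusters")
    km = KMeans(n_clusters=k, n_init=n_replicates, max_iter=min(max_iter, 10_000),
                algorithm="lloyd", random_state=np.random.default_rng(seed).integers(2**31))
    labels = km.fit_predict(X)
    centers = km.cluster_centers_.copy()
    counts = np.bincount(labels, minlength=k).astype(float)
    labels = labels.copy()
    for _ in range(online_passes):
        if _online_pass(X, labels, centers, counts) == 0:
            break
    inertia = float(((X - centers[labels]) ** 2).sum())
    return labels, centers, inertia


def vrc_curve(X: np.ndarray, k_range=range(2, 21), n_replicates: int = 50,
              seed: int = 0):
    """VRC over a k range, clustering at each k; returns (curve, labels_by_k)."""
    ks, vs, ssbs, ssws = [], [], [], []
    labels_by_k = {}
    degenerate = False
    for k in k_range:
        if X.shape[0] <= k:
            break
        labels, _, _ = kmeans_online(X, k, n_replicates=n_replicates, seed=seed + k)
        ssb, ssw = _ss(X, labels)
        ks.append(k)
        ssbs.append(ssb)
        ssws.append(ssw)
        if ssw == 0:
            degenerate = True
            vs.append(float("inf"))
        else:
            vs.append(ssb * (X.shape[0] - k) / (ssw * (k - 1)))
        labels_by_k[k] = labels
    curve = VRCCurve(np.array(ks), np.array(vs), np.array(ssbs), np.array(ssws),
                     N=X.shape[0], degenerate=degenerate)
    return curve, labels_by_k


def cluster_vectors(matrix: ResponseMatrix, k_range=range(2, 21),
                    n_replicates: int = 50, seed: int = 0,
                    variance_retained: float = 0.99):
    """Cluster normalized response vectors into odor response vector classes.

    The normalized matrix is projected onto principal components retaining at
    least ``variance_retained`` cumulative variance; k-means runs in PC space
    for each k in ``k_range``; k is chosen at the VRC elbow.  Returns
    ``(labels, centroids, curve)`` with centroids = per-cluster mean response
    vectors in the normalized (pre-PCA) space.
    """
    mat = normalize_matrix(matrix)
    X = _project_pca(mat.values, variance_retained)
    curve, labels_by_k = vrc_curve(X, k_range, n_replicates, seed)
    if curve.degenerate and not np.isfinite(curve.vrc_values).any():
        k = int(curve.k_values[0])
        warnings.warn("degenerate clustering (SSW=0 everywhere); k forced to minimum")
    else:
        k = choose_k_elbow(curve)
    curve.chosen_k = k
    labels = labels_by_k[k]
    centroids = np.array([mat.values[labels == c].mean(axis=0)
                          for c in range(k)])
    return labels, centroids, curve


def _project_pca(values: np.ndarray, variance_retained: float) -> np.ndarray:
    """PCA projection keeping the smallest number of leading components whose
    cumulative explained variance reaches the threshold."""
    n_comp = min(values.shape[0] - 1, values.shape[1])
    if n_comp < 1:
        return values - values.mean(axis=0)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(values)
    cum = np.cumsum(pca.explained_variance_ratio_)
    if cum[-1] <= 0 or not np.isfinite(cum[-1]):
        return scores
    keep = int(np.searchsorted(cum, variance_retained - 1e-12) + 1)
    keep = min(keep, scores.shape[1])
    return scores[:, :keep]


def mixture_specific_fraction(active: pd.DataFrame, mixture: str,
                              components: tuple) -> float:
    """Proportion of mixture responders that ignore both components.

    ``active`` is a units x stimuli boolean table.  Numerator: units active
    for the mixture and inactive for both components; denominator: units
    active for the mixture.  Returns NaN (flagged via warning) when no unit
    responds to the mixture.
    """
    for col in (mixture, *components):
        if col not in active.columns:
            raise KeyError(f"no activity flags for stimulus {col!r}")
    mix = active[mixture].to_numpy(bool)
    c1 = active[components[0]].to_numpy(bool)
    c2 = active[components[1]].to_numpy(bool)
    denom = int(mix.sum())
    if denom == 0:
        warnings.warn(f"no unit responds to {mixture!r}; fraction undefined")
        return float("nan")
    return float((mix & ~c1 & ~c2).sum() / denom)


@dataclass
class ConsistencyResult:
    within: float
    between: float
    linkage: np.ndarray
    cophenetic: float
    newick: str
    distances: pd.DataFrame = field(repr=False, default=None)


def consistency_analysis(maps: dict[str, list], variance_retained: float = 0.95
                         ) -> ConsistencyResult:
    """Within- vs between-odor distances of repeated response maps.

    ``maps`` maps odor label -> list of 2-D mean-intensity maps (trials) for
    one animal.  Each map is rescaled to [0, 1] and flattened (pixels are
    features, maps are observations); PCA keeps >= ``variance_retained``
    cumulative variance; Euclidean distances in PC space are averaged within
    and between odors; an average-linkage tree and its cophenetic correlation
    summarize the geometry.
    """
    odors, feats = [], []
    for odor, trials in maps.items():
        if len(trials) < 1:
            raise ValueError(f"no trials for odor {odor!r}")
        for m in trials:
            m = np.asarray(m, dtype=float)
            rng_ = np.ptp(m)
            m = (m - m.min()) / rng_ if rng_ > 0 else np.zeros_like(m)
            odors.append(odor)
            feats.append(m.ravel())
    if len(set(odors)) < 2:
        raise ValueError("need at least 2 odors")
    X = _project_pca(np.array(feats), variance_retained)
    odors = np.array(odors)
    D = squareform(pdist(X))
    same = odors[:, None] == odors[None, :]
    iu = np.triu_indices(len(odors), k=1)
    within_vals = D[iu][same[iu]]
    between_vals = D[iu][~same[iu]]
    if within_vals.size == 0:
        raise ValueError("within-odor distance undefined with single trials")
    Z = average(pdist(X))
    with np.errstate(invalid="ignore"):
        coph, _ = cophenet(Z, pdist(X))
    dist_df = pd.DataFrame(D, index=odors, columns=odors)
    return ConsistencyResult(float(within_vals.mean()), float(between_vals.mean()),
                             Z, float(coph), linkage_to_newick(Z, odors), dist_df)


def linkage_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(Z)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
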