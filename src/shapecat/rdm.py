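"""Population-level representational geometry.

Split-half neural RDMs, model RDMs (silhouette, aspect ratio, behavioral),
permutation-based representational similarity analysis, nonmetric MDS with
stress curves and intra/inter cluster distances, and agglomerative
single-linkage clustering.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .types import RDM, StimulusDesign

__all__ = [
    "splithalf_rdm",
    "silhouette_rdm",
    "aspect_ratio",
    "aspect_ratio_rdm",
    "rsa_permutation",
    "mds_embed",
    "stress_curve",
    "intra_inter_distances",
    "cluster_hierarchical",
]


# ---------------------------------------------------------------------------
# split-half neural RDM
# ---------------------------------------------------------------------------


def _standardize_columns(a: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-norm columns (channels axis 0) for fast correlation."""
    a = a - a.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(a, axis=0, keepdims=True)
    norms[norms == 0] = 1.0
    return a / norms


def splithalf_rdm(
    per_trial: np.ndarray,
    stimulus_ids: np.ndarray,
    n_iter: int = 100,
    seed: int | np.random.Generator = 0,
) -> RDM:
    """Split-half correlation-distance RDM over stimuli.

    ``per_trial`` is (n_channels, n_stimuli, max_trials), NaN-padded. Per
    iteration the trials of every stimulus are split into disjoint halves
    (odd counts put the extra trial in half A); the stimulus-mean channel
    patterns of half A are Pearson-correlated (across channels) with those
    of half B for every stimulus pair. Coefficients are averaged over
    iterations, the matrix symmetrized by averaging with its transpose,
    and the RDM is 1 - mean correlation with an exactly zero diagonal.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ch, n_stim, _ = per_trial.shape
    if n_ch < 2:
        raise ValueError("need at least 2 channels for pattern correlation")
    counts = (~np.isnan(per_trial[0])).sum(axis=1)
    thin = np.flatnonzero(counts < 2)
    if thin.size:
        raise ValueError(
            f"stimuli {stimulus_ids[thin].tolist()} have fewer than 2 trials; "
            "cannot split"
        )
    acc = np.zeros((n_stim, n_stim))
    for _ in range(n_iter):
        mean_a = np.empty((n_ch, n_stim))
        mean_b = np.empty((n_ch, n_stim))
        for j in range(n_stim):
            n = counts[j]
            perm = rng.permutation(n)
            n_a = (n + 1) // 2  # extra trial to half A
            mean_a[:, j] = per_trial[:, j, perm[:n_a]].mean(axis=1)
            mean_b[:, j] = per_trial[:, j, perm[n_a:]].mean(axis=1)
        acc += _standardize_columns(mean_a).T @ _standardize_columns(mean_b)
    corr = acc / n_iter
    corr = (corr + corr.T) / 2.0
    values = 1.0 - corr
    np.fill_diagonal(values, 0.0)
    return RDM(values, np.asarray(stimulus_ids), "neural")


# ---------------------------------------------------------------------------
# model RDMs from silhouettes
# ---------------------------------------------------------------------------


def silhouette_rdm(design: StimulusDesign) -> RDM:
    """Pixelwise dissimilarity between silhouette masks.

    d(i, j) = sqrt(sum of squared pixel differences) / sqrt(n_pixels) --
    i.e. the RMS pixel difference; for binary masks this is the square
    root of the fraction of differing pixels.
    """
    if not design.silhouettes:
        raise ValueError("design carries no silhouette masks")
    ids = design.stimulus_ids
    missing = [int(i) for i in ids if int(i) not in design.silhouettes]
    if missing:
        raise ValueError(f"missing silhouettes for stimuli {missing}")
    masks = [np.asarray(design.silhouettes[int(i)], dtype=float) for i in ids]
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"silhouette dimensions differ: {shapes}")
    flat = np.stack([m.ravel() for m in masks])  # (n_stim, n_pix)
    n_pix = flat.shape[1]
    diff = flat[:, None, :] - flat[None, :, :]
    values = np.sqrt((diff**2).sum(axis=2)) / np.sqrt(n_pix)
    np.fill_diagonal(values, 0.0)
    return RDM(values, ids, "silhouette")


def aspect_ratio(mask: np.ndarray) -> float:
    """Isoperimetric aspect ratio of a binary mask: P^2 / (4 pi A).

    Equals 1 for a disc and grows with elongation (a square gives 4/pi),
    separating 'stubby' from 'spiky' shapes. The perimeter comes from a
    Crofton estimate on the mask boundary.
    """
    from skimage.measure import perimeter_crofton

    m = np.asarray(mask) > 0
    area = m.sum()
    if area == 0:
        raise ValueError("empty mask")
    per = perimeter_crofton(m, directions=4)
    return float(per**2 / (4.0 * np.pi * area))


def aspect_ratio_rdm(design: StimulusDesign) -> RDM:
    """Pairwise absolute aspect-ratio differences between stimuli."""
    if not design.silhouettes:
        raise ValueError("design carries no silhouette masks")
    ids = design.stimulus_ids
    ars = np.array([aspect_ratio(design.silhouettes[int(i)]) for i in ids])
    values = np.abs(ars[:, None] - ars[None, :])
    return RDM(values, ids, "aspect_ratio")


# ---------------------------------------------------------------------------
# permutation RSA
# ---------------------------------------------------------------------------


def rsa_permutation(
    neural: RDM,
    model: RDM,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    method: str = "spearman",
) -> tuple[float, float]:
    """Correlate two RDMs with a stimulus-label permutation test.

    The observed statistic is the rank (or Pearson) correlation of the
    off-diagonal upper triangles. The null is built by relabeling the
    stimuli of the model RDM (permuting rows and columns together, which
    preserves its geometry) ``n_perm`` times; the one-sided p-value is
    (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if neural.n != model.n or not np.array_equal(neural.labels, model.labels):
        raise ValueError("RDM labels must match")
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v_neural = neural.triu_vector()
    if np.std(v_neural) == 0 or np.std(model.triu_vector()) == 0:
        raise ValueError("constant RDM: correlation undefined")

    n = neural.n
    iu = np.triu_indices(n, k=1)
    if method == "spearman":
        x = stats.rankdata(v_neural)
        model_mat = squareform(stats.rankdata(model.triu_vector()))
    else:
        x = v_neural
        model_mat = model.values
    x = (x - x.mean()) / x.std()

    def _corr_with(mat: np.ndarray) -> float:
        v = mat[iu]
        if method == "spearman":
            v = stats.rankdata(v)
        sd = v.std()
        if sd == 0:
            return 0.0
        return float(np.mean(x * (v - v.mean()) / sd))

    rho = _corr_with(model_mat)
    null = np.empty(n_perm)
    for k in range(n_perm):
        p = rng.permutation(n)
        null[k] = _corr_with(model_mat[np.ix_(p, p)])
    pval = (1.0 + np.sum(null >= rho)) / (n_perm + 1.0)
    return rho, float(pval)


# ---------------------------------------------------------------------------
# nonmetric MDS
# ---------------------------------------------------------------------------


def _stress1(dissim: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix.

    Disparities are the monotone (isotonic) regression of the configuration
    distances on the dissimilarity order.
    """
    from sklearn.isotonic import IsotonicRegression

    iu = np.triu_indices(dissim.shape[0], k=1)
    d = pdist(coords)
    target = dissim[iu]
    iso = IsotonicRegression()
    dhat = iso.fit_transform(target, d)
    denom = np.sum(d**2)
    if denom == 0:
        return float("inf")
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def mds_embed(
    rdm: RDM,
    n_dims: int = 2,
    seed: int = 0,
    n_init: int = 8,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Nonmetric (Kruskal) MDS embedding of an RDM.

    Runs ``n_init`` seeded SMACOF restarts (plus an optional warm start)
    and returns the configuration with the lowest stress-1. Coordinates
    are defined up to rotation, reflection and translation.
    """
    from sklearn.manifold import smacof

    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    if n_dims >= rdm.n:
        raise ValueError(f"n_dims must be below the number of stimuli ({rdm.n})")
    candidates: list[np.ndarray] = []
    ss = np.random.SeedSequence([seed, n_dims])
    for child in ss.spawn(n_init):
        rs = int(np.random.default_rng(child).integers(0, 2**31 - 1))
        coords, _ = smacof(
            rdm.values,
            metric=False,
            n_components=n_dims,
            init=None,
            n_init=1,
            random_state=rs,
            normalized_stress=True,
        )
        candidates.append(coords)
    if init is not None:
        init = np.asarray(init, dtype=float)
        if init.shape != (rdm.n, n_dims):
            raise ValueError("init has wrong shape")
        candidates.append(init.copy())  # un-iterated warm start
        coords, _ = smacof(
            rdm.values,
            metric=False,
            n_components=n_dims,
            init=init,
            n_init=1,
            normalized_stress=True,
        )
        candidates.append(coords)
    stresses = [_stress1(rdm.values, c) for c in candidates]
    best = int(np.argmin(stresses))
    return candidates[best], stresses[best]


def stress_curve(
    rdm: RDM, max_dims: int = 10, seed: int = 0, n_init: int = 8
) -> np.ndarray:
    """Stress-1 of the best embedding for 1..max_dims dimensions.

    Each dimensionality is warm-started from the previous best solution
    padded with a zero coordinate, which makes the curve non-increasing.
    """
    max_dims = min(max_dims, rdm.n - 1)
    stresses = []
    prev = None
    for d in range(1, max_dims + 1):
        init = None
        if prev is not None:
            init = np.hstack([prev, np.zeros((rdm.n, 1))])
        coords, s = mds_embed(rdm, n_dims=d, seed=seed, n_init=n_init, init=init)
        stresses.append(s)
        prev = coords
    return np.asarray(stresses)


def intra_inter_distances(
    coords: np.ndarray, labels: np.ndarray
) -> dict:
    """Within- vs between-group pairwise distances in an embedding.

    Partitions all pairwise Euclidean distances into same-group (intra)
    and different-group (inter) sets for the given per-stimulus labels and
    compares them with a two-sample t-test. Groups with a single member
    contribute no intra distances (warned).
    """
    labels = np.asarray(labels)
    d = pdist(np.asarray(coords, dtype=float))
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    singles = [l for l in np.unique(labels) if (labels == l).sum() == 1]
    if singles:
        warnings.warn(f"groups {singles} have one member and no intra distances", stacklevel=2)
    intra, inter = d[same], d[~same]
    t, p = stats.ttest_ind(intra, inter)
    return {
        "intra": intra,
        "inter": inter,
        "intra_mean": float(intra.mean()) if intra.size else float("nan"),
        "inter_mean": float(inter.mean()),
        "t": float(t),
        "p": float(p),
    }


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------


def cluster_hierarchical(rdm: RDM, max_clusters: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative single-linkage clustering of an RDM.

    Returns ``(Z, flat_labels)`` where ``Z`` is the scipy merge tree
    (heights non-decreasing, a property of single linkage) and
    ``flat_labels`` the flat cut with at most ``max_clusters`` clusters.
    """
    if rdm.n < 2:
        raise ValueError("need at least 2 stimuli to cluster")
    z = linkage(squareform(rdm.values, checks=False), method="single")
    labels = fcluster(z, t=min(max_clusters, rdm.n), criterion="maxclust")
    return z, labels
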