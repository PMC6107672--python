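"""Unsupervised analyses of the feature matrix: sparse peak selection by
orthogonal matching pursuit, hierarchical segmentation by bisecting k-means,
PCA with unit-variance scaling, and probabilistic latent semantic analysis
(PLSA) with deterministic initialization.

Segmentation distance is Euclidean on the OMP-selected, standardized columns;
at each level the segment with the largest within-segment sum of squared
distances is split by plain 2-means, so level ``k+1`` refines level ``k``.

PLSA treats the nonnegative spectra-by-peaks matrix as co-occurrence counts of
(spectrum, peak) and fits the aspect model
``P(w|d) = sum_z P(w|z) P(z|d)`` by EM. Initialization is a rank-k SVD
seeding (absolute values of the leading singular vectors, renormalized), so
repeated runs are bit-identical without a random seed. The per-spectrum
mixtures P(z|d) are the component score images; P(w|z) are the peak loadings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .preprocess import FeatureMatrix

log = logging.getLogger(__name__)


def _standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale columns to unit variance; returns (Z, non-constant mask)."""
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    keep = sd > 0
    if not keep.all():
        log.warning("dropping %d constant columns before scaling",
                    int((~keep).sum()))
    z = (values[:, keep] - mu[keep]) / sd[keep]
    return z, keep


# ---------------------------------------------------------------------------
# OMP peak selection

def select_peaks_omp(features: FeatureMatrix, n_atoms: int | None = None,
                     ) -> list[int]:
    """Greedy orthogonal matching pursuit over the column dictionary.

    The mean-centered, unit-scaled data matrix is approximated by its own
    columns: at each step the column best correlated with the residual
    (summed over all spectra) is selected and the residual is
    re-orthogonalized against the span of the selection. Columns are
    standardized first so selection order reflects the correlation structure
    of the peaks, not their absolute intensity scale. Returns column indices
    in selection order; deterministic, ties break toward the lower index.
    Stops early when the residual is numerically zero (e.g. all columns
    identical), with a warning.
    """
    p = len(features.columns)
    n_atoms = p if n_atoms is None else min(n_atoms, p)
    if n_atoms < 1:
        raise ValueError("n_atoms must be at least 1")
    x = features.values - features.values.mean(axis=0)
    scale = x.std(axis=0)
    x = x / np.where(scale > 0, scale, 1.0)
    norms = np.linalg.norm(x, axis=0)
    norms[norms == 0] = 1.0
    residual = x.copy()
    total = float(np.linalg.norm(x))
    selected: list[int] = []
    basis = np.zeros((x.shape[0], 0))
    for _ in range(n_atoms):
        score = np.linalg.norm(residual.T @ x, axis=1) / norms
        score[selected] = -np.inf
        j = int(np.argmax(score))
        selected.append(j)
        # extend the orthonormal basis by the new column (Gram-Schmidt)
        v = x[:, j] - basis @ (basis.T @ x[:, j])
        nv = np.linalg.norm(v)
        if nv > 1e-10 * max(total, 1.0):
            basis = np.column_stack([basis, v / nv])
        residual = x - basis @ (basis.T @ x)
        if np.linalg.norm(residual) <= 1e-10 * max(total, 1.0):
            if len(selected) < n_atoms:
                log.warning(
                    "residual vanished after %d of %d atoms (degenerate "
                    "columns); stopping selection early", len(selected), n_atoms)
            break
    return selected


# ---------------------------------------------------------------------------
# Bisecting k-means segmentation

@dataclass
class SegmentationTree:
    """Per-level label maps of a top-down bisecting 2-means segmentation.

    ``levels[k]`` has ``k + 1`` distinct labels (levels are 1-based in the
    ``level_labels`` accessor); ``lineage`` records (level, parent, new_label)
    for each split; ``segment_means`` holds the mean spectrum (original
    feature scale) per final-level segment.
    """

    levels: list[np.ndarray]
    lineage: list[tuple[int, int, int]]
    pixel_table: "object"
    segment_means: dict[int, np.ndarray] = field(default_factory=dict)
    selected_columns: list[int] = field(default_factory=list)

    def level_labels(self, k: int) -> np.ndarray:
        if not (1 <= k <= len(self.levels)):
            raise ValueError(f"no level {k} in a {len(self.levels)}-level tree")
        return self.levels[k - 1]

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def bisect_kmeans(features: FeatureMatrix, n_segments: int, seed: int = 0,
                  n_atoms: int | None = 200) -> SegmentationTree:
    """Top-down segmentation by recursive 2-means splitting.

    At each level the segment with the largest within-segment SSE (in the
    standardized, OMP-selected column space) is split. A fixed seed makes the
    whole tree reproducible.
    """
    if n_segments < 2:
        raise ValueError("n_segments must be at least 2")
    n = features.values.shape[0]
    if n < n_segments:
        raise ValueError("fewer spectra than requested segments")
    sel = select_peaks_omp(features, n_atoms=n_atoms)
    # column order does not affect distances; standardize the selected block
    z, _ = _standardize(features.values[:, sel])
    if np.unique(z, axis=0).shape[0] < n_segments:
        raise ValueError("fewer distinct spectra than requested segments")

    labels = np.zeros(n, dtype=np.int64)
    levels = [labels.copy()]
    lineage: list[tuple[int, int, int]] = []
    for new_label in range(1, n_segments):
        # segment with largest within-segment SSE splits
        sse = {}
        for lab in np.unique(labels):
            pts = z[labels == lab]
            if pts.shape[0] >= 2 and np.unique(pts, axis=0).shape[0] >= 2:
                sse[lab] = float(((pts - pts.mean(axis=0)) ** 2).sum())
        if not sse:
            raise ValueError("no splittable segment left")
        parent = max(sse, key=lambda k: (sse[k], -k))
        pts_idx = np.flatnonzero(labels == parent)
        km = KMeans(n_clusters=2, n_init=10, random_state=seed + new_label)
        sub_labels = km.fit_predict(z[pts_idx])
        # child 0 keeps the parent label; child 1 becomes the new segment
        labels = labels.copy()
        labels[pts_idx[sub_labels == 1]] = new_label
        lineage.append((new_label + 1, int(parent), new_label))
        levels.append(labels.copy())

    means = {int(lab): features.values[labels == lab].mean(axis=0)
             for lab in np.unique(labels)}
    return SegmentationTree(levels=levels, lineage=lineage,
                            pixel_table=features.pixel_table,
                            segment_means=means, selected_columns=sel)


# ---------------------------------------------------------------------------
# Latent decompositions

@dataclass
class LatentDecomposition:
    method: str                 # "pca" | "plsa"
    n_components: int
    loadings: np.ndarray        # (k, p) per-component weight per column
    scores: np.ndarray          # (n, k) per-spectrum component values
    column_centers: np.ndarray
    explained: np.ndarray | None = None        # % of variance, PCA only
    log_likelihood: np.ndarray | None = None   # EM trace, PLSA only
    kept_columns: np.ndarray | None = None


def pca(features: FeatureMatrix, n_components: int = 5) -> LatentDecomposition:
    """PCA with unit-variance scaling.

    Columns are standardized before the eigendecomposition; constant columns
    are dropped with a warning. Components are ordered by explained variance;
    each loading vector's largest-magnitude entry is made positive so score
    image polarity is reproducible.
    """
    z, keep = _standardize(features.values)
    if z.shape[1] < n_components:
        raise ValueError(
            f"need at least {n_components} non-constant columns, have {z.shape[1]}")
    n = z.shape[0]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    var = s**2 / (n - 1)
    explained = var / var.sum() * 100.0
    loadings = vt[:n_components]
    scores = u[:, :n_components] * s[:n_components]
    for i in range(n_components):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return LatentDecomposition(
        method="pca", n_components=n_components, loadings=loadings,
        scores=scores, column_centers=features.centers[keep],
        explained=explained[:n_components], kept_columns=keep,
    )


def _nnsvd_init(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic nonnegative seeding from the rank-k SVD (NNDSVD).

    The first component is seeded from the leading singular pair (entrywise
    nonnegative up to sign). Each further singular pair encodes a signed
    contrast between two spectrum populations, so *both* its positive and its
    negative part are used as separate nonnegative seeds until ``k``
    components are filled — a bidirectional group contrast (e.g. peptides up
    in treated vs up in control tissue) then starts from two distinct
    components instead of collapsing onto the dominant side. Entirely
    deterministic.
    """
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    n, p = x.shape
    w0 = np.zeros((k, p))
    d0 = np.zeros((n, k))
    w0[0] = np.abs(vt[0])
    d0[:, 0] = np.abs(u[:, 0]) * s[0]
    seeds = []
    for j in range(1, min(k, len(s))):
        uu, vv = u[:, j], vt[j]
        up, un = np.clip(uu, 0, None), np.clip(-uu, 0, None)
        vp, vn = np.clip(vv, 0, None), np.clip(-vv, 0, None)
        pos = np.linalg.norm(up) * np.linalg.norm(vp)
        neg = np.linalg.norm(un) * np.linalg.norm(vn)
        first, second = ((vp, up, pos), (vn, un, neg)) if pos >= neg \
            else ((vn, un, neg), (vp, up, pos))
        seeds.append((s[j], first))
        seeds.append((s[j], second))
    for i, (sv, (vvec, uvec, energy)) in enumerate(seeds[: k - 1], start=1):
        w0[i] = vvec
        d0[:, i] = uvec * sv * max(energy, 1e-12)
    eps = 1e-9
    p_w_z = w0 + eps
    p_w_z /= p_w_z.sum(axis=1, keepdims=True)
    p_z_d = d0 + eps
    p_z_d /= p_z_d.sum(axis=1, keepdims=True)
    return p_w_z, p_z_d


def plsa(features_or_matrix, n_components: int = 5, tol: float = 1e-7,
         max_iter: int = 500) -> LatentDecomposition:
    """Aspect-model EM on the nonnegative spectra-by-peaks matrix.

    E-step: ``q(z|d,w) ∝ P(w|z) P(z|d)``; M-step re-estimates both factors
    from the expected counts. Both factors are probability simplices after
    every step and the data log-likelihood is non-decreasing. Iteration stops
    when the relative log-likelihood change falls below ``tol``.
    """
    if isinstance(features_or_matrix, FeatureMatrix):
        counts = features_or_matrix.values
        centers = features_or_matrix.centers
    else:
        counts = np.asarray(features_or_matrix, dtype=np.float64)
        centers = np.arange(counts.shape[1], dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("PLSA requires nonnegative counts-like data")
    if n_components < 2:
        raise ValueError("n_components must be at least 2")
    row_tot = counts.sum(axis=1)
    if np.any(row_tot == 0):
        raise ValueError("PLSA input contains empty (all-zero) spectra")
    n, p = counts.shape
    k = n_components
    p_w_z, p_z_d = _nnsvd_init(counts / counts.sum(), k)

    trace = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        # joint responsibilities: (n, p, k) factored to avoid the full tensor
        mix = p_z_d @ p_w_z                       # (n, p) model P(w|d)
        mix = np.maximum(mix, 1e-300)
        ll = float((counts * np.log(mix)).sum())
        trace.append(ll)
        # E+M fused: expected counts for each z
        ratio = counts / mix                      # (n, p)
        new_w = p_w_z * (p_z_d.T @ ratio)         # (k, p)
        new_d = p_z_d * (ratio @ p_w_z.T)         # (n, k)
        p_w_z = new_w / new_w.sum(axis=1, keepdims=True)
        p_z_d = new_d / new_d.sum(axis=1, keepdims=True)
        if prev_ll != -np.inf and abs(ll - prev_ll) <= tol * abs(prev_ll):
            break
        prev_ll = ll
    return LatentDecomposition(
        method="plsa", n_components=k, loadings=p_w_z, scores=p_z_d,
        column_centers=centers, log_likelihood=np.asarray(trace),
    )


def plsa_reconstruct(decomp: LatentDecomposition) -> np.ndarray:
    """Model row distributions P(w|d) from a PLSA fit."""
    return decomp.scores @ decomp.loadings
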