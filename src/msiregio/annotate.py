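"""Marker-based annotation of pathophysiological regions.

The trauma core (tm) and trauma-adjacent tissue (tam) are annotated from the
ion images of one or two marker peaks whose intensity is depressed in the
core (the alpha-actin ions m/z 976.44 / 1198.63 in FFPE muscle). Per section:

1. off-tissue pixels are those whose TIC falls below a fraction (default 10%)
   of the median TIC;
2. when two or more markers are given, their tissue-pixel image correlation
   must exceed a bound (default 0.65) or annotation is refused, naming the
   disagreeing marker;
3. each marker image is lightly denoised (Gaussian, sigma 1 pixel, restricted
   to tissue — ion images are spatially coherent, so per-pixel abundance
   noise is suppressed without moving region boundaries), min-max normalized
   over tissue pixels and blended 70/30 with the pixel's own normalized
   intensity (the denoised field carries the regional structure, the raw term
   lets a decisive pixel measurement win at razor-edge boundaries); the
   blended marker scores are averaged and a two-class Otsu threshold splits
   tissue pixels per section: low side -> tm, high side -> tam.

Denoising and min-max normalization are linear/affine operations, so the
split is invariant under positive affine rescaling of any marker image
(detector gain/offset changes); a kernel-density mode check refuses
annotation when the averaged marker score shows no bimodal structure (e.g. a
single-region section).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from skimage.filters import threshold_otsu

from .core_io import RegionAnnotation
from .markers import roc_auc, wilcoxon_p
from .preprocess import FeatureMatrix

log = logging.getLogger(__name__)


@dataclass
class MarkerRule:
    """How marker images become a region mask."""

    marker_mzs: list[float]
    low_region: str = "tm"
    high_region: str = "tam"
    threshold_method: str = "otsu"
    min_marker_correlation: float = 0.65
    tic_floor_fraction: float = 0.10
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.marker_mzs) < 1:
            raise ValueError("at least one marker m/z is required")
        if not (-1 <= self.min_marker_correlation <= 1):
            raise ValueError("min_marker_correlation outside [-1, 1]")


def _smooth_column(features: FeatureMatrix, j: int, tissue: np.ndarray,
                   sigma: float) -> np.ndarray:
    """Spatially denoise one ion image per section (normalized Gaussian
    convolution over tissue pixels only) and return the tissue-pixel values."""
    from scipy.ndimage import gaussian_filter

    pt = features.pixel_table
    out = np.array(features.values[:, j], dtype=np.float64)
    if sigma <= 0:
        return out[tissue]
    for section in pt["section"].unique():
        sel = (pt["section"] == section).to_numpy() & tissue
        if not sel.any():
            continue
        xs = pt.loc[sel, "pixel_x"].to_numpy()
        ys = pt.loc[sel, "pixel_y"].to_numpy()
        nx, ny = xs.max() + 1, ys.max() + 1
        img = np.zeros((ny, nx))
        w = np.zeros((ny, nx))
        img[ys, xs] = out[sel]
        w[ys, xs] = 1.0
        num = gaussian_filter(img, sigma, mode="constant")
        den = gaussian_filter(w, sigma, mode="constant")
        sm = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        out[np.flatnonzero(sel)] = sm[ys, xs]
    return out[tissue]


def image_correlation(features: FeatureMatrix, mz_a: float, mz_b: float,
                      tissue_mask: np.ndarray | None = None,
                      smooth_sigma: float = 1.0) -> float:
    """Pearson correlation of two ion images over tissue pixels.

    The statistic measures spatial co-localization, so both images are
    lightly denoised first (Gaussian, sigma in pixels, restricted to tissue);
    set ``smooth_sigma=0`` for the raw per-pixel correlation. Smoothing is
    linear, so the result is invariant under affine rescaling of either image.
    """
    ja = features.column_index(mz_a)
    jb = features.column_index(mz_b)
    if tissue_mask is None:
        tissue_mask = np.ones(len(features.pixel_table), dtype=bool)
    else:
        tissue_mask = np.asarray(tissue_mask, dtype=bool)
    va = _smooth_column(features, ja, tissue_mask, smooth_sigma)
    vb = _smooth_column(features, jb, tissue_mask, smooth_sigma)
    if va.size < 3:
        raise ValueError("need at least 3 tissue pixels for a correlation")
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("constant ion image: correlation undefined")
    return float(np.corrcoef(va, vb)[0, 1])


def tissue_mask_from_tic(features: FeatureMatrix,
                         floor_fraction: float = 0.10) -> np.ndarray:
    """Tissue = spectra whose TIC is at least ``floor_fraction`` x median TIC,
    evaluated per section."""
    mask = np.zeros(len(features.pixel_table), dtype=bool)
    tic = features.tic()
    for section in features.pixel_table["section"].unique():
        sel = (features.pixel_table["section"] == section).to_numpy()
        med = np.median(tic[sel])
        mask[sel] = tic[sel] >= floor_fraction * med
    return mask


def _n_density_modes(x: np.ndarray) -> int:
    """Modes of a kernel-density estimate of the marker score (Scott's rule);
    used only to detect the absence of bimodal structure."""
    if np.ptp(x) == 0:
        return 1
    try:
        kde = sstats.gaussian_kde(x)
    except np.linalg.LinAlgError:
        # degenerate (e.g. two-point) sample: count distinct clusters directly
        return min(np.unique(x).size, 2)
    grid = np.linspace(x.min(), x.max(), 256)
    d = kde(grid)
    peaks = [i for i in range(1, 255) if d[i] >= d[i - 1] and d[i] > d[i + 1]
             and d[i] > 0.05 * d.max()]
    return max(len(peaks), 1)


def annotate_from_markers(features: FeatureMatrix, rule: MarkerRule,
                          ) -> RegionAnnotation:
    """Split tissue pixels into tm/tam from the averaged marker images."""
    pt = features.pixel_table
    tissue = tissue_mask_from_tic(features, rule.tic_floor_fraction)
    if tissue.sum() < 4:
        raise ValueError("too few tissue pixels to annotate")

    cols = [features.column_index(mz) for mz in rule.marker_mzs]
    if len(cols) >= 2:
        for a in range(len(cols)):
            for b in range(a + 1, len(cols)):
                r = image_correlation(features, rule.marker_mzs[a],
                                      rule.marker_mzs[b], tissue_mask=tissue)
                if r < rule.min_marker_correlation:
                    raise ValueError(
                        f"annotation refused: markers {rule.marker_mzs[a]:.2f} "
                        f"and {rule.marker_mzs[b]:.2f} disagree "
                        f"(image correlation {r:.3f} < "
                        f"{rule.min_marker_correlation})"
                    )

    smooth_sigma = rule.params.get("smooth_sigma", 1.0)
    raw_weight = rule.params.get("raw_weight", 0.3)
    smoothed = {j: _smooth_column(features, j, tissue, smooth_sigma)
                for j in cols}
    tissue_idx = np.flatnonzero(tissue)
    region = np.array(["off_tissue"] * len(pt), dtype=object)
    # threshold each section separately: sections are independent acquisitions
    for section in pt["section"].unique():
        sel = (pt["section"] == section).to_numpy() & tissue
        in_tissue = np.isin(tissue_idx, np.flatnonzero(sel))
        scores = np.zeros(int(sel.sum()))
        for j in cols:
            # blend the denoised field (regional structure) with the pixel's
            # own measurement, which keeps razor-edge boundary pixels on the
            # side their own intensity dictates
            for weight, v in ((1.0 - raw_weight, smoothed[j][in_tissue]),
                              (raw_weight, features.values[sel, j])):
                span = v.max() - v.min()
                if span == 0:
                    raise ValueError(
                        f"marker image constant on section {section}: "
                        "cannot split")
                scores += weight * (v - v.min()) / span
        scores /= len(cols)
        if _n_density_modes(scores) < 2:
            raise ValueError(
                f"section {section}: no bimodal structure in marker score; "
                "annotation refused")
        thr = threshold_otsu(scores, nbins=512)
        # Ridler-Calvard intermeans refinement: Otsu may sit anywhere inside
        # an empty histogram gap; center the threshold between class means
        for _ in range(10):
            lo, hi = scores[scores <= thr], scores[scores > thr]
            if lo.size == 0 or hi.size == 0:
                break
            new = 0.5 * (lo.mean() + hi.mean())
            if abs(new - thr) < 1e-12:
                break
            thr = new
        lab = np.where(scores <= thr, rule.low_region, rule.high_region)
        region[sel] = lab
    table = pd.DataFrame({
        "pixel_x": pt["pixel_x"], "pixel_y": pt["pixel_y"],
        "section": pt["section"], "group": pt["group"], "region": region,
    })
    return RegionAnnotation(table=table, source="marker_based")


def validate_roi_contrast(features: FeatureMatrix,
                          annotation: RegionAnnotation, marker_mz: float,
                          ) -> tuple[float, float]:
    """tm-vs-tam AUC and rank-sum p for one marker ion.

    The AUC direction is P(random tm intensity > random tam intensity), so a
    marker depressed in the core yields AUC well below 0.5; the conventional
    acceptance is AUC < 0.35 at p < 0.001.
    """
    j = features.column_index(marker_mz)
    ann = annotation.table
    pt = features.pixel_table
    merged = pt.merge(ann, on=["pixel_x", "pixel_y", "section"], how="left",
                      suffixes=("", "_ann"))
    vals = features.values[:, j]
    tm_vals = vals[(merged["region"] == "tm").to_numpy()]
    tam_vals = vals[(merged["region"] == "tam").to_numpy()]
    if tm_vals.size < 2 or tam_vals.size < 2:
        raise ValueError("each region needs at least 2 spectra")
    return roc_auc(tm_vals, tam_vals), wilcoxon_p(tm_vals, tam_vals)
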