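"""Region-contrast statistics: per-peak ROC/AUC, Wilcoxon rank-sum tests,
mean-intensity ratios, balanced subsampling, and the two marker filter
profiles (region markers, treatment markers).

The AUC is the rank-based probability that a random intensity from ROI *a*
exceeds one from ROI *b* (ties count half) — the Mann-Whitney U statistic
divided by ``n_a * n_b``. Discriminative peaks pass a joint gate: AUC outside
(auc_low, auc_high), rank-sum p below a bound, and a mean-intensity ratio (or
normalized intensity delta) beyond its bound. No multiple-testing correction
is applied by default: the joint AUC + p + ratio gate is the filter; an
optional Benjamini-Hochberg column is available.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import RegionAnnotation
from .preprocess import FeatureMatrix

log = logging.getLogger(__name__)

EXACT_LIMIT = 12  # exact rank-sum enumeration up to n_a + n_b of this size


def roc_auc(values_a, values_b) -> float:
    """AUC = P(a > b) + 0.5 P(a = b) via midranks (= U / (n_a n_b))."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 values")
    ranks = stats.rankdata(np.concatenate([a, b]))
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return ranks_a.sum() - n_a * (n_a + 1) / 2.0


def wilcoxon_p(values_a, values_b) -> float:
    """Two-sided rank-sum p-value.

    Exact by full enumeration of group assignments (correct under ties) when
    ``n_a + n_b <= 12``; otherwise the normal approximation with midrank tie
    correction and 0.5 continuity correction.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 values")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks[:n_a], n_a)
    mean_u = n_a * n_b / 2.0
    if n_a + n_b <= EXACT_LIMIT:
        dev = abs(u_obs - mean_u)
        count = total = 0
        for combo in itertools.combinations(range(n_a + n_b), n_a):
            u = _u_statistic(ranks[list(combo)], n_a)
            total += 1
            if abs(u - mean_u) >= dev - 1e-12:
                count += 1
        return count / total
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var_u = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return 1.0
    z = (abs(u_obs - mean_u) - 0.5) / math.sqrt(var_u)
    return float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))


def subsample_balanced(values, n: int = 6000, seed: int = 0):
    """Uniform subsample without replacement; returns everything (with a
    warning) when fewer than ``n`` items are available. Deterministic per seed.
    """
    arr = np.asarray(values)
    if arr.shape[0] <= n:
        if arr.shape[0] < n:
            log.warning("requested %d spectra but only %d available: using all",
                        n, arr.shape[0])
        return arr.copy()
    rng = np.random.default_rng(seed)
    idx = rng.choice(arr.shape[0], size=n, replace=False)
    return arr[np.sort(idx)]


@dataclass
class ContrastSpec:
    """One ROI-vs-ROI contrast with its filter profile.

    ``roi_a`` / ``roi_b`` are (region, group) selectors; ``group=None`` pools
    both groups. Gates: AUC outside (auc_low, auc_high); p < p_max; ratio
    a/b > ratio_high or < ratio_low; optionally a min-max-normalized mean
    intensity delta > min_delta_intensity. ``balance_n`` triggers balanced
    subsampling of each side.
    """

    roi_a: tuple[str, str | None]
    roi_b: tuple[str, str | None]
    auc_low: float = 0.35
    auc_high: float = 0.65
    p_max: float = 0.01
    ratio_low: float | None = 0.8
    ratio_high: float | None = 1.2
    min_delta_intensity: float | None = None
    balance_n: int | None = None
    seed: int = 0
    name: str = "contrast"

    def __post_init__(self):
        if not (0 <= self.auc_low < self.auc_high <= 1):
            raise ValueError("require 0 <= auc_low < auc_high <= 1")
        if self.ratio_low is not None and self.ratio_high is not None:
            if not (self.ratio_low < 1 < self.ratio_high):
                raise ValueError("require ratio_low < 1 < ratio_high")


def treatment_contrast(region: str, treated: str = "MSC-TX",
                       control: str = "control", p_max: float = 0.01,
                       balance_n: int | None = None, seed: int = 0) -> ContrastSpec:
    """Preset: treated vs control within one region (the treatment profile)."""
    return ContrastSpec(roi_a=(region, treated), roi_b=(region, control),
                        auc_low=0.35, auc_high=0.65, p_max=p_max,
                        ratio_low=0.8, ratio_high=1.2, balance_n=balance_n,
                        seed=seed, name=f"{region}_{treated}_vs_{control}")


def region_contrast(p_max: float = 0.001, min_delta_intensity: float = 0.3,
                    balance_n: int | None = None, seed: int = 0) -> ContrastSpec:
    """Preset: tm vs tam pooled over groups (the region-marker profile)."""
    return ContrastSpec(roi_a=("tm", None), roi_b=("tam", None),
                        auc_low=0.35, auc_high=0.65, p_max=p_max,
                        ratio_low=None, ratio_high=None,
                        min_delta_intensity=min_delta_intensity,
                        balance_n=balance_n, seed=seed, name="tm_vs_tam")


@dataclass
class MarkerTable:
    """Per-column contrast statistics with pass/fail gates.

    ``table`` columns: mz, auc, p_value, ratio, delta_norm_intensity, passes,
    direction; rows follow the FeatureMatrix column order.
    """

    table: pd.DataFrame
    contrast: ContrastSpec
    n_a: int = 0
    n_b: int = 0

    def passing_mzs(self) -> list[float]:
        return list(self.table.loc[self.table["passes"], "mz"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _roi_rows(features: FeatureMatrix, annotation: RegionAnnotation,
              roi: tuple[str, str | None]) -> np.ndarray:
    region, group = roi
    ann = annotation.table
    sel = ann["region"] == region
    if group is not None:
        sel &= ann["group"] == group
    keys = set(map(tuple, ann.loc[sel, ["pixel_x", "pixel_y", "section"]]
                   .itertuples(index=False, name=None)))
    pt = features.pixel_table
    mask = np.fromiter(
        ((x, y, s) in keys for x, y, s in
         zip(pt["pixel_x"], pt["pixel_y"], pt["section"])),
        dtype=bool, count=len(pt))
    return np.flatnonzero(mask)


def discover_markers(features: FeatureMatrix, annotation: RegionAnnotation,
                     contrast: ContrastSpec, bh_correction: bool = False,
                     ) -> MarkerTable:
    """Evaluate every feature column under one contrast.

    All raw statistics are retained for failing columns (no censoring); the
    ``passes`` flag applies the AUC gate, then the p gate, then the
    ratio/delta gates. Row order is the FeatureMatrix column order.
    """
    idx_a = _roi_rows(features, annotation, contrast.roi_a)
    idx_b = _roi_rows(features, annotation, contrast.roi_b)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError(f"contrast {contrast.name}: an ROI selected no spectra")
    if np.intersect1d(idx_a, idx_b).size:
        raise ValueError(f"contrast {contrast.name}: ROIs overlap")
    if contrast.balance_n is not None:
        idx_a = subsample_balanced(idx_a, contrast.balance_n, seed=contrast.seed)
        idx_b = subsample_balanced(idx_b, contrast.balance_n,
                                   seed=contrast.seed + 1)
    va_all = features.values[idx_a]
    vb_all = features.values[idx_b]

    rows = []
    for j, col in enumerate(features.columns):
        va, vb = va_all[:, j], vb_all[:, j]
        auc = roc_auc(va, vb)
        p = wilcoxon_p(va, vb)
        mean_a, mean_b = float(va.mean()), float(vb.mean())
        ratio = mean_a / mean_b if mean_b > 0 else float("inf")
        pooled = np.concatenate([va, vb])
        span = pooled.max() - pooled.min()
        delta = abs(mean_a - mean_b) / span if span > 0 else 0.0
        auc_pass = auc < contrast.auc_low or auc > contrast.auc_high
        p_pass = p < contrast.p_max
        gates = [auc_pass, p_pass]
        if contrast.ratio_low is not None and contrast.ratio_high is not None:
            gates.append(np.isfinite(ratio) and
                         (ratio > contrast.ratio_high or ratio < contrast.ratio_low))
        if contrast.min_delta_intensity is not None:
            gates.append(delta > contrast.min_delta_intensity)
        rows.append({
            "mz": col.center, "auc": auc, "p_value": p, "ratio": ratio,
            "delta_norm_intensity": delta, "passes": all(gates),
            "direction": "up_in_a" if auc > 0.5 else "up_in_b",
        })
    table = pd.DataFrame(rows)
    if bh_correction:
        m = len(table)
        order = np.argsort(table["p_value"].to_numpy())
        q = np.empty(m)
        prev = 1.0
        for rank, i in reversed(list(enumerate(order, start=1))):
            prev = min(prev, table["p_value"].iloc[i] * m / rank)
            q[i] = prev
        table["q_value"] = q
    return MarkerTable(table=table, contrast=contrast,
                       n_a=idx_a.size, n_b=idx_b.size)
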