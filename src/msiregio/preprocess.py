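"""Spectral preprocessing: baseline removal, TIC normalization, peak
detection on the joint mean spectrum, and fixed-interval peak alignment.

The stage order is fixed: baseline removal (profile mode only) -> TIC
normalization -> peak detection on the mean spectrum of all sections
processed jointly -> alignment of every spectrum onto the detected peak
intervals, producing one spectra-by-peaks :class:`FeatureMatrix`.

Conventions. "Convolution baseline removal, width 20" is implemented as a
moving minimum followed by a moving average, both with a window of 20 profile
points, subtracted and clipped at zero. Smoothing strengths map to Gaussian
kernels of sigma 1 ("weak"), 2 ("medium") and 4 ("strong") profile points.
Alignment intervals are half-open [center - hw, center + hw) with hw = 0.156
Da by default; the interval value is the mean over profile points in the
interval ("mean interval processing") or, for centroid data, the sum of
centroids falling inside it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import (gaussian_filter1d, maximum_filter1d,
                           minimum_filter1d, uniform_filter1d)
from scipy.signal import find_peaks

from .core_io import MsiDataset

log = logging.getLogger(__name__)

SMOOTHING_SIGMA = {"weak": 1.0, "medium": 2.0, "strong": 4.0}


class ModeError(ValueError):
    """An operation received data in the wrong acquisition mode."""


@dataclass
class PeakInterval:
    center: float
    halfwidth: float

    @property
    def lo(self) -> float:
        return self.center - self.halfwidth

    @property
    def hi(self) -> float:
        return self.center + self.halfwidth

    def contains(self, mz) -> np.ndarray:
        mz = np.asarray(mz)
        return (mz >= self.lo) & (mz < self.hi)


@dataclass
class FeatureMatrix:
    """Aligned spectra x peak-interval matrix with per-row pixel provenance.

    ``values[i, j]`` is the interval-aggregated normalized intensity of
    spectrum ``i`` in peak interval ``j``; ``pixel_table`` carries
    (pixel_x, pixel_y, section, group) for each row.
    """

    values: np.ndarray
    columns: list[PeakInterval]
    pixel_table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.pixel_table), len(self.columns)):
            raise ValueError("feature matrix shape mismatch")
        if np.any(self.values < 0):
            raise ValueError("negative value in feature matrix")
        centers = [c.center for c in self.columns]
        if sorted(centers) != centers:
            raise ValueError("peak intervals must be sorted by center")
        for a, b in zip(self.columns, self.columns[1:]):
            if b.lo < a.hi:
                raise ValueError("overlapping peak intervals")
        dup = self.pixel_table.duplicated(subset=["pixel_x", "pixel_y", "section"])
        if dup.any():
            raise ValueError("a pixel maps to more than one feature-matrix row")

    @property
    def centers(self) -> np.ndarray:
        return np.asarray([c.center for c in self.columns])

    def column_index(self, mz: float, tol: float | None = None) -> int:
        centers = self.centers
        j = int(np.argmin(np.abs(centers - mz)))
        tol = self.columns[j].halfwidth if tol is None else tol
        if abs(centers[j] - mz) > tol:
            raise KeyError(f"no feature column within {tol} Da of m/z {mz}")
        return j

    def subset(self, row_mask: np.ndarray) -> "FeatureMatrix":
        row_mask = np.asarray(row_mask, dtype=bool)
        return FeatureMatrix(
            values=self.values[row_mask],
            columns=list(self.columns),
            pixel_table=self.pixel_table.loc[row_mask].reset_index(drop=True),
            meta=dict(self.meta),
        )

    def tic(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = self.pixel_table.copy()
        for j, c in enumerate(self.columns):
            df[f"{c.center:.4f}"] = self.values[:, j]
        df.to_csv(path, index=False)
        manifest = {
            "columns": [{"center": c.center, "halfwidth": c.halfwidth}
                        for c in self.columns],
            "meta": self.meta,
        }
        path.with_suffix(".columns.json").write_text(json.dumps(manifest))
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path)
        manifest = json.loads(path.with_suffix(".columns.json").read_text())
        columns = [PeakInterval(c["center"], c["halfwidth"])
                   for c in manifest["columns"]]
        id_cols = ["pixel_x", "pixel_y", "section", "group"]
        vals = df[[f"{c.center:.4f}" for c in columns]].to_numpy(dtype=np.float64)
        return cls(values=vals, columns=columns, pixel_table=df[id_cols],
                   meta=manifest.get("meta", {}))


# ---------------------------------------------------------------------------
# Baseline removal

def remove_baseline(spectrum: np.ndarray, width: int = 20) -> np.ndarray:
    """Subtract a smooth baseline from one profile spectrum, clipping at zero.

    Baseline estimate: morphological opening (moving minimum then moving
    maximum, both of window ``width``) followed by a moving-average smoothing
    of the same window. The opening removes structures narrower than the
    window while following linear drift exactly — a plain minimum-then-average
    would under-subtract a sloped baseline by slope x width/2. Peak apex
    positions are unchanged because the subtracted curve varies slowly on the
    scale of a peak.
    """
    if width < 1:
        raise ValueError("baseline width must be >= 1 (profile points)")
    x = np.asarray(spectrum, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("expected a 1-D spectrum")
    opened = maximum_filter1d(
        minimum_filter1d(x, size=width, mode="nearest"),
        size=width, mode="nearest",
    )
    baseline = uniform_filter1d(opened, size=width, mode="nearest")
    return np.clip(x - baseline, 0.0, None)


def remove_baseline_dataset(dataset: MsiDataset, width: int = 20) -> MsiDataset:
    if dataset.axis.mode != "profile":
        raise ModeError("baseline removal is a profile-mode operation; "
                        "got centroid data")
    out = np.vstack([remove_baseline(s, width) for s in dataset.intensities])
    return MsiDataset(
        pixels=dataset.pixels.copy(), axis=dataset.axis, intensities=out,
        section_id=dataset.section_id, group=dataset.group,
        pixel_pitch_um=dataset.pixel_pitch_um, metadata=dict(dataset.metadata),
    )


# ---------------------------------------------------------------------------
# TIC normalization

def tic_normalize(data, floor_fraction: float = 0.1):
    """Scale every retained spectrum to the dataset-wide mean TIC.

    Accepts one :class:`MsiDataset`, a list of them (normalized jointly so
    sections stay comparable), or a :class:`FeatureMatrix`. Spectra whose TIC
    falls below ``floor_fraction`` times the median TIC (off-tissue/background
    positions, and in particular all-zero spectra) cannot meaningfully be
    rescaled — doing so would amplify background noise to tissue intensity —
    so they are flagged, left unscaled, and counted under
    ``metadata/meta["sub_floor_spectra"]``; downstream statistics exclude them
    via the same TIC floor.
    """
    if isinstance(data, FeatureMatrix):
        tics = data.tic()
        target, keep = _tic_target_and_mask(tics, floor_fraction)
        scale = np.where(keep, np.divide(target, tics, out=np.ones_like(tics),
                                         where=tics > 0), 1.0)
        meta = dict(data.meta)
        meta["sub_floor_spectra"] = int((~keep).sum())
        meta["target_tic"] = float(target)
        return FeatureMatrix(values=data.values * scale[:, None],
                             columns=list(data.columns),
                             pixel_table=data.pixel_table.copy(), meta=meta)
    datasets = [data] if isinstance(data, MsiDataset) else list(data)
    all_tics = np.concatenate([ds.tic() for ds in datasets])
    target, _ = _tic_target_and_mask(all_tics, floor_fraction)
    out_sets = []
    for ds in datasets:
        tics = ds.tic()
        keep = tics >= floor_fraction * np.median(all_tics)
        scale = np.where(keep, np.divide(target, tics, out=np.ones_like(tics),
                                         where=tics > 0), 1.0)
        meta = dict(ds.metadata)
        meta["sub_floor_spectra"] = int((~keep).sum())
        meta["target_tic"] = float(target)
        out_sets.append(MsiDataset(
            pixels=ds.pixels.copy(), axis=ds.axis,
            intensities=ds.intensities * scale[:, None],
            section_id=ds.section_id, group=ds.group,
            pixel_pitch_um=ds.pixel_pitch_um, metadata=meta,
        ))
    return out_sets[0] if isinstance(data, MsiDataset) else out_sets


def _tic_target_and_mask(tics: np.ndarray,
                         floor_fraction: float) -> tuple[float, np.ndarray]:
    if not (tics > 0).any():
        raise ValueError("all spectra are empty: nothing to normalize")
    keep = tics >= floor_fraction * np.median(tics)
    keep &= tics > 0
    n_out = int((~keep).sum())
    if n_out:
        log.warning("%d sub-floor spectra flagged and left unscaled", n_out)
    return float(tics[keep].mean()), keep


# ---------------------------------------------------------------------------
# Peak detection

def mean_spectrum(datasets: list[MsiDataset] | MsiDataset) -> tuple[np.ndarray, "MsiDataset"]:
    """Joint mean spectrum over all spectra of all sections."""
    datasets = [datasets] if isinstance(datasets, MsiDataset) else list(datasets)
    ref = datasets[0]
    for ds in datasets[1:]:
        if not np.array_equal(ds.axis.values, ref.axis.values):
            raise ValueError("sections must share one m/z axis for joint detection")
    total = sum(ds.intensities.sum(axis=0) for ds in datasets)
    n = sum(ds.n_pixels for ds in datasets)
    return total / n, ref


def detect_peaks(mean_spec: np.ndarray, axis, smoothing: str = "medium",
                 snr_floor: float = 3.0) -> np.ndarray:
    """Peak centers (m/z) from the smoothed joint mean spectrum.

    Profile mode: Gaussian smoothing at the named strength, then local maxima
    that rise at least ``snr_floor`` times a robust noise estimate (1.4826 x
    MAD of the smoothing residual) above the median smoothed level, with the
    same bound on topographic prominence — so neither a flat noise floor nor
    the shoulder of a neighboring peak counts as signal. Spectra are expected
    to be baseline-removed, leaving the median as the residual floor.
    Centroid mode: the nonzero centroids pass through unchanged.
    """
    mean_spec = np.asarray(mean_spec, dtype=np.float64)
    if mean_spec.size == 0:
        raise ValueError("empty mean spectrum")
    if axis.mode == "centroid":
        return axis.values[mean_spec > 0]
    sigma = SMOOTHING_SIGMA.get(smoothing)
    if sigma is None:
        raise ValueError(f"unknown smoothing strength {smoothing!r}")
    smoothed = gaussian_filter1d(mean_spec, sigma=sigma, mode="nearest")
    resid = mean_spec - smoothed
    noise = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    floor = max(snr_floor * noise, 1e-12)
    idx, _ = find_peaks(smoothed, height=np.median(smoothed) + floor,
                        prominence=floor)
    return axis.values[idx]


# ---------------------------------------------------------------------------
# Peak alignment

def align_peaks(datasets: list[MsiDataset] | MsiDataset,
                peak_centers: np.ndarray,
                halfwidth: float = 0.156,
                aggregation: str = "mean") -> FeatureMatrix:
    """Aggregate every spectrum onto fixed intervals around the peak centers.

    Intervals are [c - hw, c + hw); overlapping intervals are merged onto the
    stronger peak's center (strength = joint mean-spectrum interval intensity)
    and the merge is logged. Output rows follow dataset order, then pixel
    storage order within each dataset.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    if aggregation != "mean":
        raise ValueError("only mean interval processing is implemented")
    datasets = [datasets] if isinstance(datasets, MsiDataset) else list(datasets)
    centers = np.sort(np.asarray(peak_centers, dtype=np.float64))
    if centers.size == 0:
        raise ValueError("no peak centers to align on")
    mspec, ref = mean_spectrum(datasets)

    def strength(c: float) -> float:
        sel = (ref.axis.values >= c - halfwidth) & (ref.axis.values < c + halfwidth)
        return float(mspec[sel].sum())

    merged: list[float] = []
    for c in centers:
        if merged and c - halfwidth < merged[-1] + halfwidth:
            keep = merged[-1] if strength(merged[-1]) >= strength(c) else float(c)
            log.info("merging overlapping intervals at %.4f / %.4f -> %.4f",
                     merged[-1], c, keep)
            merged[-1] = keep
        else:
            merged.append(float(c))
    columns = [PeakInterval(c, halfwidth) for c in merged]

    rows, tables = [], []
    for ds in datasets:
        mat = np.empty((ds.n_pixels, len(columns)))
        for j, col in enumerate(columns):
            sel = col.contains(ds.axis.values)
            if not sel.any():
                mat[:, j] = 0.0
                continue
            block = ds.intensities[:, sel]
            mat[:, j] = block.mean(axis=1) if ds.axis.mode == "profile" \
                else block.sum(axis=1)
        rows.append(mat)
        tables.append(pd.DataFrame({
            "pixel_x": ds.pixels[:, 0], "pixel_y": ds.pixels[:, 1],
            "section": ds.section_id, "group": ds.group,
        }))
    return FeatureMatrix(
        values=np.vstack(rows), columns=columns,
        pixel_table=pd.concat(tables, ignore_index=True),
        meta={"halfwidth": halfwidth, "aggregation": aggregation},
    )
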