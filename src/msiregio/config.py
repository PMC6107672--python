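"""Run configuration: every tunable parameter of every stage, with defaults.

Defaults are the analysis settings the pipeline is built around: convolution
baseline removal of width 20 points, TIC normalization, peak alignment on
±0.156 Da intervals with mean interval processing and medium smoothing,
five-component PCA (unit-variance scaled) and PLSA (deterministic init),
marker acceptance AUC < 0.35 at p < 0.001 with inter-marker image correlation
> 0.65, treatment-marker gates AUC < 0.35 or > 0.65 with p < 0.01 and
intensity ratio > 1.2 or < 0.8, 6000-spectrum balanced subsampling, and an
identity-transfer tolerance of 0.9 Da.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # master seed; every stochastic stage derives its own stream from it
    seed: int | None = None

    # acquisition / axis
    mz_min: float = 800.0
    mz_max: float = 3500.0

    # preprocessing
    baseline_width: int = 20
    baseline_width_units: str = "points"   # "points" | "da" (container convention unclear)
    smoothing: str = "medium"              # weak | medium | strong
    snr_floor: float = 3.0
    align_halfwidth: float = 0.156         # Da; total interval width 0.312
    aggregation: str = "mean"

    # ROI annotation
    marker_mzs: list[float] = field(default_factory=list)  # empty -> ground truth markers
    min_marker_correlation: float = 0.65
    marker_auc_max: float = 0.35
    marker_p_max: float = 0.001
    tic_floor_fraction: float = 0.10

    # unsupervised
    n_components: int = 5
    n_segments: int = 3
    omp_atoms: int = 200                   # capped at the column count

    # marker discovery: treatment profile (region-specific group contrast)
    auc_low: float = 0.35
    auc_high: float = 0.65
    treatment_p_max: float = 0.01
    ratio_low: float = 0.8
    ratio_high: float = 1.2
    # marker discovery: region profile (tm vs tam)
    region_p_max: float = 0.001
    min_delta_intensity: float = 0.3
    balance_n: int = 6000

    # identity transfer
    match_tolerance_da: float = 0.9

    # synthetic-data generator
    grid_nx: int = 40
    grid_ny: int = 40
    tm_fraction: float = 0.25
    n_peaks: int = 50
    n_region_markers: int = 10
    n_treatment_markers: int = 5
    ratio_range: tuple[float, float] = (1.5, 4.0)
    cv: float = 0.3
    tic_cv: float = 0.2
    noise_sd: float = 1.0
    sections_per_group: int = 2
    treated_group: str = "MSC-TX"
    control_group: str = "control"

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("config is missing the master seed")
        if not (0 < self.align_halfwidth < 5):
            raise ValueError("align_halfwidth out of range (0, 5) Da")
        if self.baseline_width < 1:
            raise ValueError("baseline_width must be >= 1")
        if not (0 <= self.auc_low < self.auc_high <= 1):
            raise ValueError("require 0 <= auc_low < auc_high <= 1")
        if not (self.ratio_low < 1 < self.ratio_high):
            raise ValueError("require ratio_low < 1 < ratio_high")
        if not (-1 <= self.min_marker_correlation <= 1):
            raise ValueError("min_marker_correlation outside [-1, 1]")
        if not (0 < self.tm_fraction < 1):
            raise ValueError("tm_fraction must lie in (0, 1)")
        for p in (self.marker_p_max, self.treatment_p_max, self.region_p_max):
            if not (0 < p <= 1):
                raise ValueError("p-value thresholds must lie in (0, 1]")
        if self.smoothing not in ("weak", "medium", "strong"):
            raise ValueError(f"unknown smoothing strength {self.smoothing!r}")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        d["ratio_range"] = list(d["ratio_range"])
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "ratio_range" in d:
            d["ratio_range"] = tuple(d["ratio_range"])
        return cls(**d)

    def paper_scale(self) -> "RunConfig":
        """Preset with three sections per group (full study shape)."""
        return dataclasses.replace(self, sections_per_group=3)
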