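"""Synthetic MALDI-IMS datacubes with planted region and treatment effects.

The generator emulates the statistical structure of a two-group imaging study
of injured skeletal muscle: each section is a pixel grid holding a tissue blob
(an ellipse) with a compact trauma core ("tm") inside trauma-adjacent tissue
("tam"), acquired for a treated (MSC transplantation, "MSC-TX") and a control
group. The peak panel contains

* *region markers* — peptides depressed in the trauma core in both groups
  (emulating the alpha-actin ions used for region annotation); the first two
  double as the annotation markers,
* *treatment markers* — peptides whose intensity differs between groups only
  in the trauma-adjacent region, with planted mean-intensity ratios, and
* *null peaks* — identical everywhere.

Abundance model per pixel and peak:
``intensity = base x factor(region, group) x LogNormal(0, cv) x TIC-multiplier``
with ``TIC-multiplier ~ LogNormal(0, tic_cv)`` shared by all peaks of a pixel,
plus an additive Gaussian noise floor clipped at zero. Off-tissue pixels carry
baseline and noise only. Effects are multiplicative because region contrasts
are reported as intensity ratios. Treatment markers are planted at moderate
base abundance (regulatory peptides are less abundant than structural muscle
proteins), which bounds the TIC-normalization crosstalk they induce on null
peaks to a few percent of intensity — well inside the discriminative-peak
AUC gates.

Profile mode adds Gaussian peak shapes on a regular m/z axis and an
exponentially decaying baseline; centroid mode (the default for pipeline-scale
runs) stores one channel per panel peak.

All randomness flows from one master seed through documented per-stage
derived streams, so identical calls are bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import MsiDataset, MzAxis, PeptideIdTable, RegionAnnotation
from .identify import monoisotopic_mass, neutral_to_mz
from .refdata import REFERENCE_PEPTIDES

OFF_TISSUE, TM, TAM = 0, 1, 2
REGION_NAMES = {OFF_TISSUE: "off_tissue", TM: "tm", TAM: "tam"}


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from the master seed."""
    return (int(master) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class TissueLayout:
    nx: int
    ny: int
    region_mask: np.ndarray  # (ny, nx) int codes, see REGION_NAMES
    geometry: dict = field(default_factory=dict)

    def __post_init__(self):
        tm, tam = self.tm_mask, self.tam_mask
        if np.logical_and(tm, tam).any():
            raise ValueError("tm and tam overlap")
        if not tm.any() or not tam.any():
            raise ValueError("layout must contain both tm and tam pixels")

    @property
    def tm_mask(self) -> np.ndarray:
        return self.region_mask == TM

    @property
    def tam_mask(self) -> np.ndarray:
        return self.region_mask == TAM

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.region_mask != OFF_TISSUE

    def pixels(self) -> np.ndarray:
        """All grid pixels as (n, 2) (x, y), row-major scan order."""
        ys, xs = np.mgrid[0:self.ny, 0:self.nx]
        return np.column_stack([xs.ravel(), ys.ravel()])

    def region_codes_flat(self) -> np.ndarray:
        return self.region_mask.ravel()

    def tm_share(self) -> float:
        return float(self.tm_mask.sum()) / float(self.tissue_mask.sum())


def make_layout(nx: int, ny: int, tm_fraction: float = 0.25,
                seed: int = 0) -> TissueLayout:
    """Elliptical tissue blob with a smaller trauma-core ellipse inside.

    ``tm_fraction`` is the target share of tissue pixels belonging to the
    core; the realized share is within ±20% of the target or the call fails
    (which happens when the grid is too small to host both regions).
    """
    if not (0 < tm_fraction < 1):
        raise ValueError("tm_fraction must lie in (0, 1)")
    if nx < 8 or ny < 8:
        raise ValueError(f"grid {nx}x{ny} too small to host tm and tam regions")
    rng = np.random.default_rng(seed)
    cx = nx / 2 + rng.uniform(-0.05, 0.05) * nx
    cy = ny / 2 + rng.uniform(-0.05, 0.05) * ny
    ax_, ay_ = 0.44 * nx, 0.44 * ny
    ys, xs = np.mgrid[0:ny, 0:nx]
    tissue = ((xs - cx) / ax_) ** 2 + ((ys - cy) / ay_) ** 2 <= 1.0

    s = np.sqrt(tm_fraction)
    tax, tay = s * ax_, s * ay_
    # core center jitter, kept small enough that the core stays inside tissue
    max_off = 0.5 * min(ax_ - tax, ay_ - tay)
    tcx = cx + rng.uniform(-max_off, max_off)
    tcy = cy + rng.uniform(-max_off, max_off)
    tm = (((xs - tcx) / tax) ** 2 + ((ys - tcy) / tay) ** 2 <= 1.0) & tissue

    mask = np.full((ny, nx), OFF_TISSUE, dtype=np.int64)
    mask[tissue] = TAM
    mask[tm] = TM
    layout = TissueLayout(nx=nx, ny=ny, region_mask=mask, geometry={
        "tissue_center": (cx, cy), "tissue_axes": (ax_, ay_),
        "tm_center": (tcx, tcy), "tm_axes": (tax, tay),
    })
    share = layout.tm_share()
    if abs(share - tm_fraction) > 0.2 * tm_fraction:
        raise ValueError(
            f"grid {nx}x{ny} too coarse: realized tm share {share:.3f} misses "
            f"target {tm_fraction:.3f} by more than 20%"
        )
    return layout


@dataclass
class PeakSpec:
    mz: float
    base_intensity: float
    region_effects: dict = field(default_factory=dict)  # (region, group|"*") -> factor
    cv: float = 0.3
    kind: str = "null"       # null | region_marker | treatment_marker
    anchor: bool = False     # designated annotation marker
    sequence: str | None = None
    gene: str | None = None
    description: str | None = None

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")
        if any(f <= 0 for f in self.region_effects.values()):
            raise ValueError("effect factors must be positive")

    def factor(self, region: str, group: str) -> float:
        for key in ((region, group), (region, "*")):
            if key in self.region_effects:
                return self.region_effects[key]
        return 1.0


#: Identity panel for planted treatment markers: reference peptides ordered so
#: that consecutive markers complete two-peptide proteins in both effect
#: directions (Hspa8 up in treated tam, Ca3 up in control tam, then Tnc and
#: Flnc), exercising the two-peptide acceptance rule end to end. Each
#: marker's direction follows its reference peptide's tam intensity ratio.
_IDENTITY_ORDER = ["DAGTIAGLNVLR", "TTPSYVAFTDTER", "GGPLSGPYRLR",
                   "SMLRGGPLSGPYR", "EGDPATINAATEIDAPR", "YAPISGGDHAEIDVPK",
                   "LGSFGSITR", "GVAGVPAEFSIWTR"]


def make_peak_panel(n_peaks: int = 50, n_region_markers: int = 10,
                    n_treatment_markers: int = 5,
                    ratio_range: tuple[float, float] = (1.5, 4.0),
                    seed: int = 0, mz_range: tuple[float, float] = (800.0, 3500.0),
                    cv: float = 0.3, treated_group: str = "MSC-TX",
                    region_factor_range: tuple[float, float] = (0.4, 0.7),
                    ) -> list[PeakSpec]:
    """Build the peak panel: region markers, treatment markers, null peaks.

    Region markers are depressed in the trauma core in *both* groups; the
    first two get fixed factors 0.45 and 0.50 and serve as the annotation
    markers. Treatment markers are planted only in the trauma-adjacent
    region: each gets a ratio magnitude drawn from ``ratio_range`` and a
    direction (up in the treated group, or up in the controls — a peptide
    elevated in control tissue has a treated/control factor 1/ratio). Markers
    carry reference peptide identities, whose own reported tam ratios set the
    direction, so the identification stage can be tested end to end.
    """
    if n_region_markers + n_treatment_markers > n_peaks:
        raise ValueError("marker counts exceed n_peaks")
    if not (1.2 <= ratio_range[0] <= ratio_range[1] <= 4.2):
        raise ValueError("ratio_range must lie within [1.2, 4.2]")
    rng = np.random.default_rng(seed)
    ref_by_seq = {p.sequence: p for p in REFERENCE_PEPTIDES}

    # treatment markers first: their m/z are pinned to peptide neutral masses
    specs: list[PeakSpec] = []
    used_mz: list[float] = []
    for i in range(n_treatment_markers):
        ratio = float(rng.uniform(*ratio_range))
        if i < len(_IDENTITY_ORDER):
            ref = ref_by_seq[_IDENTITY_ORDER[i]]
            mz = neutral_to_mz(monoisotopic_mass(ref.sequence))
            seq, gene, desc = ref.sequence, ref.gene, ref.description
            up_in_treated = ref.ratio_tam > 1.0
        else:
            mz = float(rng.uniform(*mz_range))
            seq = gene = desc = None
            up_in_treated = bool(rng.integers(0, 2))
        factor = ratio if up_in_treated else 1.0 / ratio
        specs.append(PeakSpec(
            mz=mz, base_intensity=float(rng.uniform(150.0, 400.0)),
            region_effects={("tam", treated_group): factor}, cv=cv,
            kind="treatment_marker", sequence=seq, gene=gene, description=desc,
        ))
        used_mz.append(mz)

    def draw_mz() -> float:
        for _ in range(1000):
            m = float(rng.uniform(*mz_range))
            if all(abs(m - u) >= 1.0 for u in used_mz):
                used_mz.append(m)
                return m
        raise RuntimeError("could not place peaks 1 Da apart; panel too dense")

    anchor_factors = (0.45, 0.50)
    for i in range(n_region_markers):
        f = anchor_factors[i] if i < 2 else float(rng.uniform(*region_factor_range))
        specs.append(PeakSpec(
            mz=draw_mz(), base_intensity=float(rng.uniform(100.0, 1000.0)),
            region_effects={("tm", "*"): f}, cv=cv, kind="region_marker",
            anchor=i < 2,
        ))
    for _ in range(n_peaks - n_region_markers - n_treatment_markers):
        specs.append(PeakSpec(
            mz=draw_mz(), base_intensity=float(rng.uniform(100.0, 1000.0)),
            region_effects={}, cv=cv, kind="null",
        ))
    specs.sort(key=lambda s: s.mz)
    return specs


@dataclass
class GroundTruth:
    """Planted structure of a simulated section or batch."""

    layouts: dict[str, TissueLayout]
    planted: pd.DataFrame  # mz, kind, contrast, direction, ratio, sequence, gene
    annotation_marker_mzs: list[float] = field(default_factory=list)

    def __post_init__(self):
        panel_mz = set(self.planted["mz"])
        markers = self.planted[self.planted["kind"] != "null"]["mz"]
        if not set(markers).issubset(panel_mz):
            raise ValueError("planted marker absent from peak panel")

    def treatment_marker_mzs(self) -> list[float]:
        t = self.planted
        return sorted(t.loc[t["kind"] == "treatment_marker", "mz"])

    def region_marker_mzs(self) -> list[float]:
        t = self.planted
        return sorted(t.loc[t["kind"] == "region_marker", "mz"])

    def to_annotation(self, groups: dict[str, str]) -> RegionAnnotation:
        """Ground-truth per-pixel labels for the sections in ``groups``."""
        rows = []
        for section_id, layout in self.layouts.items():
            codes = layout.region_codes_flat()
            px = layout.pixels()
            rows.append(pd.DataFrame({
                "pixel_x": px[:, 0], "pixel_y": px[:, 1],
                "section": section_id, "group": groups[section_id],
                "region": [REGION_NAMES[c] for c in codes],
            }))
        return RegionAnnotation(table=pd.concat(rows, ignore_index=True),
                                source="ground_truth")


def _panel_truth(panel: list[PeakSpec], treated_group: str) -> pd.DataFrame:
    rows = []
    for s in panel:
        if s.kind == "treatment_marker":
            ratio = s.factor("tam", treated_group)
            rows.append(dict(mz=s.mz, kind=s.kind, contrast="tam_treated_vs_control",
                             direction="up_in_treated" if ratio > 1 else "up_in_control",
                             ratio=ratio, sequence=s.sequence, gene=s.gene))
        elif s.kind == "region_marker":
            ratio = s.factor("tm", "any")
            rows.append(dict(mz=s.mz, kind=s.kind, contrast="tm_vs_tam",
                             direction="down_in_tm", ratio=ratio,
                             sequence=None, gene=None))
        else:
            rows.append(dict(mz=s.mz, kind="null", contrast=None, direction=None,
                             ratio=1.0, sequence=None, gene=None))
    return pd.DataFrame(rows)


def simulate_section(layout: TissueLayout, panel: list[PeakSpec], group: str,
                     section_id: str = "section", tic_cv: float = 0.2,
                     baseline_params: dict | None = None, noise_sd: float = 1.0,
                     seed: int = 0, mode: str = "centroid",
                     profile_spacing: float = 0.1, peak_sigma: float = 0.15,
                     treated_group: str = "MSC-TX",
                     ) -> tuple[MsiDataset, GroundTruth]:
    """Simulate one section over the whole grid (off-tissue pixels included)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if tic_cv < 0:
        raise ValueError("tic_cv must be nonnegative")
    rng = np.random.default_rng(seed)
    pixels = layout.pixels()
    codes = layout.region_codes_flat()
    n_pix = len(pixels)
    n_peaks = len(panel)

    # per-pixel, per-peak expected intensity (zero off tissue)
    amplitude = np.zeros((n_pix, n_peaks))
    for j, spec in enumerate(panel):
        for code, region in ((TM, "tm"), (TAM, "tam")):
            sel = codes == code
            amplitude[sel, j] = spec.base_intensity * spec.factor(region, group)
        if spec.cv > 0:
            amplitude[:, j] *= np.exp(rng.normal(0.0, spec.cv, size=n_pix))
    if tic_cv > 0:
        amplitude *= np.exp(rng.normal(0.0, tic_cv, size=n_pix))[:, None]
    amplitude[codes == OFF_TISSUE] = 0.0

    if mode == "centroid":
        axis = MzAxis(np.array([s.mz for s in panel]), mode="centroid")
        signal = amplitude
    elif mode == "profile":
        mzs = np.array([s.mz for s in panel])
        lo, hi = mzs.min() - 5.0, mzs.max() + 5.0
        grid = np.arange(lo, hi + profile_spacing, profile_spacing)
        axis = MzAxis(grid, mode="profile")
        bp = {"amplitude": 20.0, "tau": 500.0}
        bp.update(baseline_params or {})
        baseline = bp["amplitude"] * np.exp(-(grid - grid[0]) / bp["tau"])
        shapes = np.exp(-0.5 * ((grid[None, :] - mzs[:, None]) / peak_sigma) ** 2)
        # peak height chosen so the Gaussian's area equals the centroid amplitude
        shapes /= peak_sigma * np.sqrt(2 * np.pi) / profile_spacing
        signal = amplitude @ shapes + baseline[None, :]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    intensities = np.clip(signal, 0.0, None)

    dataset = MsiDataset(
        pixels=pixels, axis=axis, intensities=intensities,
        section_id=section_id, group=group,
        metadata={"synthetic": True, "seed": int(seed), "mode": mode},
    )
    anchors = [s.mz for s in panel if s.anchor]
    truth = GroundTruth(layouts={section_id: layout},
                        planted=_panel_truth(panel, treated_group),
                        annotation_marker_mzs=anchors)
    return dataset, truth


def simulate_batch(config, seed: int | None = None,
                   ) -> tuple[list[MsiDataset], GroundTruth, PeptideIdTable]:
    """Full study-shaped batch: ``sections_per_group`` sections per group,
    one peak panel shared by all sections, plus a matching identification
    table (planted peptide identities and decoys).
    """
    master = config.seed if seed is None else seed
    if master is None:
        raise ValueError("simulate_batch needs a seed")
    panel = make_peak_panel(
        n_peaks=config.n_peaks, n_region_markers=config.n_region_markers,
        n_treatment_markers=config.n_treatment_markers,
        ratio_range=config.ratio_range, seed=derive_seed(master, "panel"),
        mz_range=(config.mz_min, config.mz_max), cv=config.cv,
        treated_group=config.treated_group,
    )
    datasets, layouts, groups = [], {}, {}
    for group in (config.treated_group, config.control_group):
        for k in range(config.sections_per_group):
            sid = f"{group}_s{k + 1}"
            layout = make_layout(config.grid_nx, config.grid_ny,
                                 config.tm_fraction,
                                 seed=derive_seed(master, f"layout/{sid}"))
            ds, _ = simulate_section(
                layout, panel, group=group, section_id=sid,
                tic_cv=config.tic_cv, noise_sd=config.noise_sd,
                seed=derive_seed(master, f"section/{sid}"),
                treated_group=config.treated_group,
            )
            datasets.append(ds)
            layouts[sid] = layout
            groups[sid] = group
    anchors = [s.mz for s in panel if s.anchor]
    truth = GroundTruth(layouts=layouts,
                        planted=_panel_truth(panel, config.treated_group),
                        annotation_marker_mzs=anchors)

    planted_seqs = [
        (f"SYN_{p.gene}", p.gene, p.description, p.sequence)
        for p in REFERENCE_PEPTIDES
        if p.sequence in set(truth.planted["sequence"].dropna())
    ]
    # decoys: reference peptides not planted, at their true masses
    decoys = [
        (f"SYN_{p.gene}", p.gene, p.description, p.sequence)
        for p in REFERENCE_PEPTIDES
        if p.sequence not in set(truth.planted["sequence"].dropna())
    ]
    id_table = make_id_table(planted_seqs + decoys, mass_error_sd_ppm=5.0,
                             seed=derive_seed(master, "id_table"))
    return datasets, truth, id_table


def make_id_table(sequences_with_proteins, mass_error_sd_ppm: float = 5.0,
                  seed: int = 0) -> PeptideIdTable:
    """Emulated search-engine export: theoretical monoisotopic masses
    perturbed by a Gaussian ppm error, with plausible ion scores."""
    rng = np.random.default_rng(seed)
    rows = []
    for accession, gene, description, sequence in sequences_with_proteins:
        theo = monoisotopic_mass(sequence)  # validates residues
        err = rng.normal(0.0, mass_error_sd_ppm) * 1e-6 * theo
        rows.append({
            "protein_accession": accession, "gene_name": gene,
            "description": description, "sequence": sequence,
            "experimental_neutral_mass": theo + err,
            "score": float(np.round(rng.uniform(30.0, 100.0), 1)),
        })
    return PeptideIdTable(rows=pd.DataFrame(rows, columns=PeptideIdTable.COLUMNS))
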