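"""Data model and I/O for spatial mass-spectrometry datacubes.

An :class:`MsiDataset` is one tissue section: a set of integer pixel
coordinates on an acquisition grid, one intensity vector per pixel over a
shared m/z axis, and section metadata (identifier, treatment group, pixel
pitch). Datasets can be stored either in the open imaging-MS XML+binary
container (imzML, continuous or processed dialect, via pyimzml) or in a plain
internal exchange format (JSON sidecar + CSV intensity matrix) that needs no
binary parser.

Conventions: pixel indices are 0-based, x rightward, y downward. Intensities
are float32 in files and float64 in memory; the round-trip contract is exact
for centroid data and within 1e-6 relative for profile data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class FormatError(ValueError):
    """A container violated its format contract."""


@dataclass
class MzAxis:
    """Shared m/z axis: strictly increasing positive values, profile or centroid."""

    values: np.ndarray
    mode: str = "centroid"  # "profile" | "centroid"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.mode not in ("profile", "centroid"):
            raise ValueError(f"unknown axis mode {self.mode!r}")
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("m/z axis must be a non-empty 1-D array")
        if np.any(self.values <= 0):
            raise ValueError("m/z values must be positive")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("m/z axis must be strictly increasing")

    def __len__(self):
        return self.values.size

    @property
    def range(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])


@dataclass
class MsiDataset:
    """One section's datacube: pixels, shared axis, per-pixel spectra, metadata."""

    pixels: np.ndarray           # (n, 2) int array of (x, y)
    axis: MzAxis
    intensities: np.ndarray      # (n, len(axis)) float64, >= 0
    section_id: str = "section"
    group: str = "control"       # treatment group label, e.g. MSC-TX | control
    pixel_pitch_um: float = 80.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.int64).reshape(-1, 2)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.pixels.shape[0] == 0:
            raise ValueError("dataset has no pixels")
        uniq = {tuple(p) for p in self.pixels}
        if len(uniq) != self.pixels.shape[0]:
            raise ValueError("duplicate pixel coordinates in dataset")
        if self.intensities.shape != (self.pixels.shape[0], len(self.axis)):
            raise ValueError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{self.pixels.shape[0]} pixels x {len(self.axis)} m/z bins"
            )
        if np.any(self.intensities < 0):
            raise ValueError("negative intensity in dataset")

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0]

    def grid_shape(self) -> tuple[int, int]:
        """(ny, nx) of the bounding box, image-style."""
        return (int(self.pixels[:, 1].max()) + 1, int(self.pixels[:, 0].max()) + 1)

    def tic(self) -> np.ndarray:
        return self.intensities.sum(axis=1)


@dataclass
class RegionAnnotation:
    """Per-pixel region and treatment-group labels for one or more sections.

    ``table`` columns: pixel_x, pixel_y, section, group, region; region is one
    of {tm, tam, off_tissue}. ``source`` records how the labels were obtained.
    """

    table: pd.DataFrame
    source: str = "marker_based"  # marker_based | ground_truth | segmentation

    REGIONS = ("tm", "tam", "off_tissue")

    def __post_init__(self):
        required = {"pixel_x", "pixel_y", "section", "group", "region"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns {sorted(missing)}")
        bad = set(self.table["region"]) - set(self.REGIONS)
        if bad:
            raise ValueError(f"unknown region labels {sorted(bad)}")
        dup = self.table.duplicated(subset=["pixel_x", "pixel_y", "section"])
        if dup.any():
            raise ValueError("a pixel carries more than one region label")

    def mask(self, region: str, section: str | None = None,
             group: str | None = None) -> pd.DataFrame:
        t = self.table
        sel = t["region"] == region
        if section is not None:
            sel &= t["section"] == section
        if group is not None:
            sel &= t["group"] == group
        return t[sel]


@dataclass
class PeptideIdTable:
    """Bottom-up LC-MS/MS identification table (search-engine CSV export).

    ``rows`` holds the accepted identifications; ``rejected`` keeps every row
    that failed validation together with the reason, so nothing is silently
    dropped.
    """

    rows: pd.DataFrame
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "reason"]))

    COLUMNS = ["protein_accession", "gene_name", "description", "sequence",
               "experimental_neutral_mass", "score"]


def read_peptide_ids(path: str | Path) -> PeptideIdTable:
    """Read a delimited identification table, validating sequences and masses."""
    path = Path(path)
    raw = pd.read_csv(path)
    missing = [c for c in PeptideIdTable.COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(
            f"identification table {path.name}: expected columns "
            f"{PeptideIdTable.COLUMNS}, found {list(raw.columns)} "
            f"(missing {missing})"
        )
    if raw.empty:
        log.warning("identification table %s is empty", path.name)
        return PeptideIdTable(rows=raw[PeptideIdTable.COLUMNS])
    keep, rejects = [], []
    for i, row in raw.iterrows():
        seq = str(row["sequence"])
        bad = sorted(set(seq) - VALID_RESIDUES)
        if bad:
            rejects.append({"row": i, "reason": f"invalid residue {bad[0]}"})
            continue
        if not float(row["experimental_neutral_mass"]) > 0:
            rejects.append({"row": i, "reason": "nonpositive mass"})
            continue
        keep.append(i)
    if rejects:
        for r in rejects:
            log.warning("rejected row %d of %s: %s", r["row"], path.name, r["reason"])
    return PeptideIdTable(
        rows=raw.loc[keep, PeptideIdTable.COLUMNS].reset_index(drop=True),
        rejected=pd.DataFrame(rejects, columns=["row", "reason"]),
    )


def write_peptide_ids(table: PeptideIdTable, path: str | Path) -> Path:
    path = Path(path)
    table.rows.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Datacube I/O

def write_msi(dataset: MsiDataset, path: str | Path) -> Path:
    """Write a datacube; format chosen by suffix (.imzML or .msi.json)."""
    dataset.validate()
    path = Path(path)
    if path.name.lower().endswith(".imzml"):
        return _write_imzml(dataset, path)
    return _write_internal(dataset, path)


def read_msi(path: str | Path) -> MsiDataset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.name.lower().endswith(".imzml"):
        return _read_imzml(path)
    return _read_internal(path)


def _internal_csv_path(json_path: Path) -> Path:
    return json_path.with_name(json_path.name.replace(".msi.json", ".intensities.csv"))


def _write_internal(dataset: MsiDataset, path: Path) -> Path:
    if not path.name.endswith(".msi.json"):
        path = path.with_name(path.name + ".msi.json")
    sidecar = {
        "format": "msiregio-internal",
        "version": 1,
        "section_id": dataset.section_id,
        "group": dataset.group,
        "pixel_pitch_um": dataset.pixel_pitch_um,
        "mode": dataset.axis.mode,
        "mz": [float(v) for v in dataset.axis.values],
        "pixels": [[int(x), int(y)] for x, y in dataset.pixels],
        "metadata": dataset.metadata,
    }
    path.write_text(json.dumps(sidecar))
    # float32 on disk, matching the container encoding convention
    mat = dataset.intensities.astype(np.float32)
    np.savetxt(_internal_csv_path(path), mat, delimiter=",", fmt="%.9g")
    return path


def _read_internal(path: Path) -> MsiDataset:
    try:
        sidecar = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path.name}: malformed JSON sidecar ({e})") from e
    if sidecar.get("format") != "msiregio-internal":
        raise FormatError(f"{path.name}: not an internal exchange file")
    for key in ("mode", "mz", "pixels"):
        if key not in sidecar:
            raise FormatError(f"{path.name}: sidecar missing record {key!r}")
    csv_path = _internal_csv_path(Path(path))
    if not csv_path.exists():
        raise FormatError(f"{path.name}: intensity matrix {csv_path.name} missing")
    mat = np.loadtxt(csv_path, delimiter=",", dtype=np.float64, ndmin=2)
    axis = MzAxis(np.asarray(sidecar["mz"]), mode=sidecar["mode"])
    return MsiDataset(
        pixels=np.asarray(sidecar["pixels"]),
        axis=axis,
        intensities=mat,
        section_id=sidecar.get("section_id", "section"),
        group=sidecar.get("group", "control"),
        pixel_pitch_um=sidecar.get("pixel_pitch_um", 80.0),
        metadata=sidecar.get("metadata", {}),
    )


def _write_imzml(dataset: MsiDataset, path: Path) -> Path:
    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(str(path), mode="continuous",
                     mz_dtype=np.float64, intensity_dtype=np.float32) as w:
        mz = dataset.axis.values
        for (x, y), spec in zip(dataset.pixels, dataset.intensities):
            # imzML coordinates are 1-based
            w.addSpectrum(mz, spec.astype(np.float32), (int(x) + 1, int(y) + 1))
    meta = {
        "section_id": dataset.section_id, "group": dataset.group,
        "pixel_pitch_um": dataset.pixel_pitch_um, "mode": dataset.axis.mode,
        "metadata": dataset.metadata,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta))
    return path


def _read_imzml(path: Path) -> MsiDataset:
    from pyimzml.ImzMLParser import ImzMLParser

    try:
        parser = ImzMLParser(str(path))
    except Exception as e:  # the XML layer raises several exception types
        raise FormatError(f"{path.name}: malformed imzML ({e})") from e
    coords = [(x - 1, y - 1) for (x, y, _z) in parser.coordinates]
    mz_lists, int_lists = [], []
    for i in range(len(coords)):
        mzs, ints = parser.getspectrum(i)
        mz_lists.append(np.asarray(mzs, dtype=np.float64))
        int_lists.append(np.asarray(ints, dtype=np.float64))
    shared = all(
        len(m) == len(mz_lists[0]) and np.array_equal(m, mz_lists[0])
        for m in mz_lists
    )
    if shared:
        axis_values = mz_lists[0]
        mat = np.vstack(int_lists)
    else:
        # processed dialect: merge per-pixel centroid axes onto their union
        axis_values = np.unique(np.concatenate(mz_lists))
        mat = np.zeros((len(coords), axis_values.size))
        for i, (m, v) in enumerate(zip(mz_lists, int_lists)):
            idx = np.searchsorted(axis_values, m)
            np.add.at(mat[i], idx, v)
    if np.any(mat < 0):
        raise ValueError(f"{path.name}: negative intensity in container")
    meta_path = path.with_suffix(".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    mode = meta.get("mode", "profile" if shared and axis_values.size > 500 else "centroid")
    return MsiDataset(
        pixels=np.asarray(coords),
        axis=MzAxis(axis_values, mode=mode),
        intensities=mat,
        section_id=meta.get("section_id", path.stem),
        group=meta.get("group", "control"),
        pixel_pitch_um=meta.get("pixel_pitch_um", 80.0),
        metadata=meta.get("metadata", {}),
    )


def write_msi_batch(datasets: list[MsiDataset], out_dir: str | Path) -> Path:
    """Write several sections to one directory with a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for ds in datasets:
        p = write_msi(ds, out_dir / f"{ds.section_id}.msi.json")
        entries.append({"section_id": ds.section_id, "group": ds.group,
                        "path": p.name})
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({"sections": entries}))
    return manifest


# ---------------------------------------------------------------------------
# Ion images

def render_ion_image(source, mz: float, interval_halfwidth: float = 0.156,
                     section: str | None = None) -> np.ndarray:
    """Render the 2-D intensity image of one m/z interval.

    ``source`` is an :class:`MsiDataset` or a FeatureMatrix. The image covers
    the pixel grid's bounding box; grid positions never acquired are NaN, not
    zero. For a profile-mode dataset the interval value is the mean over
    profile points inside [mz-hw, mz+hw); for centroid data and for feature
    columns, intensities inside the interval are summed.
    """
    if hasattr(source, "axis"):  # MsiDataset
        ds = source
        lo, hi = ds.axis.range
        if not (lo <= mz <= hi):
            raise ValueError(f"m/z {mz} outside axis range [{lo}, {hi}]")
        sel = (ds.axis.values >= mz - interval_halfwidth) & \
              (ds.axis.values < mz + interval_halfwidth)
        if ds.axis.mode == "profile":
            vals = ds.intensities[:, sel].mean(axis=1) if sel.any() else \
                np.zeros(ds.n_pixels)
        else:
            vals = ds.intensities[:, sel].sum(axis=1)
        pixels = ds.pixels
    else:  # FeatureMatrix duck type: columns, values, pixel table
        fm = source
        centers = np.asarray([c.center for c in fm.columns])
        if not (centers.min() - interval_halfwidth <= mz
                <= centers.max() + interval_halfwidth):
            raise ValueError(f"m/z {mz} outside feature-column range")
        sel = np.abs(centers - mz) < interval_halfwidth
        if section is not None:
            keep = (fm.pixel_table["section"] == section).to_numpy()
        else:
            keep = np.ones(len(fm.pixel_table), dtype=bool)
        vals = fm.values[keep][:, sel].sum(axis=1)
        pixels = fm.pixel_table.loc[keep, ["pixel_x", "pixel_y"]].to_numpy()
    nx = int(pixels[:, 0].max()) + 1
    ny = int(pixels[:, 1].max()) + 1
    img = np.full((ny, nx), np.nan)
    img[pixels[:, 1], pixels[:, 0]] = vals
    return img


def save_ion_image_png(image: np.ndarray, path: str | Path, title: str = "") -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(image, origin="upper", interpolation="nearest")
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
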