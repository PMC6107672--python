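"""End-to-end orchestration of the study-shaped run.

Stages run in fixed order — simulate, preprocess, annotate, segment,
decompose, markers, match, report — communicating through plain CSV/JSON
files in one output directory, so any stage can be rerun or inspected in
isolation and reruns with the same config and seed reproduce every CSV
byte-identically. A :class:`RunManifest` records the config hash, per-stage
outputs and wall time, and the derived-seed registry.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import MarkerRule, annotate_from_markers, tissue_mask_from_tic, \
    validate_roi_contrast
from .config import RunConfig
from .core_io import (MsiDataset, PeptideIdTable, RegionAnnotation,
                      read_msi, read_peptide_ids, render_ion_image,
                      save_ion_image_png, write_msi_batch, write_peptide_ids)
from .identify import build_report, match_ims_to_lcms
from .markers import discover_markers, treatment_contrast
from .preprocess import FeatureMatrix, align_peaks, detect_peaks, mean_spectrum, \
    remove_baseline_dataset, tic_normalize
from .synth import GroundTruth, TissueLayout, derive_seed, simulate_batch
from .unsupervised import bisect_kmeans, pca, plsa

STAGES = ["simulate", "preprocess", "annotate", "segment", "decompose",
          "markers", "match", "report"]


@dataclass
class RunManifest:
    config_hash: str
    out_dir: str
    seed_registry: dict[str, int]
    stages: list[dict] = field(default_factory=list)
    version: str = __version__

    def add(self, name: str, outputs: list[Path], wall_time: float) -> None:
        for p in outputs:
            if not Path(p).exists():
                raise FileNotFoundError(f"stage {name}: missing output {p}")
        self.stages.append({"name": name,
                            "outputs": [str(p) for p in outputs],
                            "wall_time_s": round(wall_time, 3)})

    def save(self, path: Path) -> Path:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))
        return path


def config_hash(cfg: RunConfig) -> str:
    d = dataclasses.asdict(cfg)
    d["ratio_range"] = list(d["ratio_range"])
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _paths(out_dir: Path) -> dict[str, Path]:
    d = Path(out_dir)
    return {
        "config": d / "config.yaml",
        "data": d / "data",
        "truth": d / "data" / "ground_truth.json",
        "ids": d / "data" / "peptide_ids.csv",
        "features": d / "features.csv",
        "annotation": d / "annotation.csv",
        "annotation_png": d / "annotation.png",
        "segmentation": d / "segmentation.csv",
        "pca_scores": d / "pca_scores.csv",
        "pca_loadings": d / "pca_loadings.csv",
        "plsa_scores": d / "plsa_scores.csv",
        "plsa_loadings": d / "plsa_loadings.csv",
        "plsa_loglik": d / "plsa_loglik.csv",
        "markers_tam": d / "markers_tam.csv",
        "markers_tm": d / "markers_tm.csv",
        "matches": d / "matches.csv",
        "proteins": d / "proteins.csv",
        "report": d / "report.csv",
        "manifest": d / "run_manifest.json",
    }


def _save_truth(truth: GroundTruth, path: Path) -> None:
    payload = {
        "annotation_marker_mzs": truth.annotation_marker_mzs,
        "planted": truth.planted.where(pd.notna(truth.planted), None)
                   .to_dict(orient="records"),
        "layouts": {sid: {"nx": lo.nx, "ny": lo.ny,
                          "region_mask": lo.region_mask.tolist()}
                    for sid, lo in truth.layouts.items()},
    }
    path.write_text(json.dumps(payload))


def load_truth(path: Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    layouts = {sid: TissueLayout(nx=d["nx"], ny=d["ny"],
                                 region_mask=np.asarray(d["region_mask"]))
               for sid, d in payload["layouts"].items()}
    return GroundTruth(layouts=layouts,
                       planted=pd.DataFrame(payload["planted"]),
                       annotation_marker_mzs=payload["annotation_marker_mzs"])


# ---------------------------------------------------------------------------
# Stages (each reads upstream outputs from the run directory)

def stage_simulate(cfg: RunConfig, out: Path) -> list[Path]:
    p = _paths(out)
    datasets, truth, ids = simulate_batch(cfg)
    p["data"].mkdir(parents=True, exist_ok=True)
    manifest = write_msi_batch(datasets, p["data"])
    _save_truth(truth, p["truth"])
    write_peptide_ids(ids, p["ids"])
    return [manifest, p["truth"], p["ids"]]


def _load_sections(out: Path) -> list[MsiDataset]:
    p = _paths(out)
    manifest = json.loads((p["data"] / "manifest.json").read_text())
    return [read_msi(p["data"] / e["path"]) for e in manifest["sections"]]


def stage_preprocess(cfg: RunConfig, out: Path) -> list[Path]:
    p = _paths(out)
    datasets = _load_sections(out)
    if datasets[0].axis.mode == "profile":
        datasets = [remove_baseline_dataset(ds, cfg.baseline_width)
                    for ds in datasets]
    datasets = tic_normalize(datasets)
    mspec, ref = mean_spectrum(datasets)
    centers = detect_peaks(mspec, ref.axis, smoothing=cfg.smoothing,
                           snr_floor=cfg.snr_floor)
    fm = align_peaks(datasets, centers, halfwidth=cfg.align_halfwidth,
                     aggregation=cfg.aggregation)
    fm.to_csv(p["features"])
    return [p["features"]]


def stage_annotate(cfg: RunConfig, out: Path) -> list[Path]:
    p = _paths(out)
    fm = FeatureMatrix.from_csv(p["features"])
    marker_mzs = list(cfg.marker_mzs)
    if not marker_mzs:
        marker_mzs = load_truth(p["truth"]).annotation_marker_mzs
    rule = MarkerRule(marker_mzs=marker_mzs,
                      min_marker_correlation=cfg.min_marker_correlation,
                      tic_floor_fraction=cfg.tic_floor_fraction)
    ann = annotate_from_markers(fm, rule)
    auc, pval = validate_roi_contrast(fm, ann, marker_mzs[0])
    if not (auc < cfg.marker_auc_max and pval < cfg.marker_p_max):
        raise ValueError(
            f"annotation marker fails acceptance: AUC {auc:.3f} "
            f"(need < {cfg.marker_auc_max}), p {pval:.2e} "
            f"(need < {cfg.marker_p_max})")
    ann.table.to_csv(p["annotation"], index=False)
    _annotation_png(ann, p["annotation_png"])
    return [p["annotation"], p["annotation_png"]]


def _annotation_png(ann: RegionAnnotation, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sections = ann.table["section"].unique()
    codes = {"off_tissue": 0, "tm": 1, "tam": 2}
    fig, axes = plt.subplots(1, len(sections),
                             figsize=(3 * len(sections), 3), squeeze=False)
    for ax, sid in zip(axes[0], sections):
        t = ann.table[ann.table["section"] == sid]
        img = np.zeros((t["pixel_y"].max() + 1, t["pixel_x"].max() + 1))
        img[t["pixel_y"], t["pixel_x"]] = [codes[r] for r in t["region"]]
        ax.imshow(img, interpolation="nearest")
        ax.set_title(sid, fontsize=8)
        ax.axis("off")
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def _tissue_fm(cfg: RunConfig, out: Path) -> FeatureMatrix:
    p = _paths(out)
    fm = FeatureMatrix.from_csv(p["features"])
    return fm.subset(tissue_mask_from_tic(fm, cfg.tic_floor_fraction))


def stage_segment(cfg: RunConfig, out: Path) -> list[Path]:
    p = _paths(out)
    fm = _tissue_fm(cfg, out)
    tree = bisect_kmeans(fm, n_segments=cfg.n_segments,
                         seed=derive_seed(cfg.seed, "segment"),
                         n_atoms=cfg.omp_atoms)
    df = fm.pixel_table.copy()
    for k in range(1, tree.n_levels + 1):
        df[f"segment_level_{k}"] = tree.level_labels(k)
    df.to_csv(p["segmentation"], index=False)
    return [p["segmentation"]]


def stage_decompose(cfg: RunConfig, out: Path) -> list[Path]:
    p = _paths(out)
    fm = _tissue_fm(cfg, out)
    dec = pca(fm, n_components=cfg.n_components)
    scores = fm.pixel_table.copy()
    for i in range(cfg.n_components):
        scores[f"PC{i + 1}"] = dec.scores[:, i]
    scores.to_csv(p["pca_scores"], index=False)
    pd.DataFrame(dec.loadings.T, columns=[f"PC{i + 1}" for i in range(cfg.n_components)],
                 index=pd.Index(dec.column_centers, name="mz")) \
        .assign(explained_pct=np.nan) \
        .pipe(_write_loadings, dec.explained, p["pca_loadings"])
    pl = plsa(fm, n_components=cfg.n_components)
    pscores = fm.pixel_table.copy()
    for i in range(cfg.n_components):
        pscores[f"C{i + 1}"] = pl.scores[:, i]
    pscores.to_csv(p["plsa_scores"], index=False)
    pd.DataFrame(pl.loadings.T, columns=[f"C{i + 1}" for i in range(cfg.n_components)],
                 index=pd.Index(pl.column_centers, name="mz")) \
        .to_csv(p["plsa_loadings"])
    pd.DataFrame({"iteration": np.arange(len(pl.log_likelihood)),
                  "log_likelihood": pl.log_likelihood}) \
        .to_csv(p["plsa_loglik"], index=False)
    return [p["pca_scores"], p["pca_loadings"], p["plsa_scores"],
            p["plsa_loadings"], p["plsa_loglik"]]


def _write_loadings(df: pd.DataFrame, explained, path: Path) -> None:
    df = df.drop(columns=["explained_pct"])
    df.to_csv(path)
    with open(path, "a") as fh:
        fh.write("# explained_pct," +
                 ",".join(f"{e:.4f}" for e in explained) + "\n")


def stage_markers(cfg: RunConfig, out: Path) -> list[Path]:
    p = _paths(out)
    fm = FeatureMatrix.from_csv(p["features"])
    ann = RegionAnnotation(table=pd.read_csv(p["annotation"]),
                           source="marker_based")
    outputs = []
    for region, dest in (("tam", p["markers_tam"]), ("tm", p["markers_tm"])):
        spec = treatment_contrast(region, treated=cfg.treated_group,
                                  control=cfg.control_group,
                                  p_max=cfg.treatment_p_max,
                                  seed=derive_seed(cfg.seed, f"markers/{region}"))
        spec.auc_low, spec.auc_high = cfg.auc_low, cfg.auc_high
        spec.ratio_low, spec.ratio_high = cfg.ratio_low, cfg.ratio_high
        mt = discover_markers(fm, ann, spec)
        mt.to_csv(dest)
        outputs.append(dest)
    return outputs


def _combined_marker_stats(out: Path) -> pd.DataFrame:
    p = _paths(out)
    tam = pd.read_csv(p["markers_tam"])
    tm = pd.read_csv(p["markers_tm"])
    return pd.DataFrame({
        "mz": tam["mz"],
        "ratio_tam": tam["ratio"], "ratio_tm": tm["ratio"],
        "auc_tam": tam["auc"], "auc_tm": tm["auc"],
        "passes_tam": tam["passes"], "passes_tm": tm["passes"],
    })


def stage_match(cfg: RunConfig, out: Path) -> list[Path]:
    p = _paths(out)
    stats = _combined_marker_stats(out)
    passing = stats.loc[stats["passes_tam"] | stats["passes_tm"], "mz"]
    ids = read_peptide_ids(p["ids"])
    report = match_ims_to_lcms(list(passing), ids,
                               tolerance=cfg.match_tolerance_da)
    report.matches.to_csv(p["matches"], index=False)
    report.proteins.to_csv(p["proteins"], index=False)
    return [p["matches"], p["proteins"]]


def stage_report(cfg: RunConfig, out: Path) -> list[Path]:
    p = _paths(out)
    stats = _combined_marker_stats(out)
    passing = stats.loc[stats["passes_tam"] | stats["passes_tm"], "mz"]
    ids = read_peptide_ids(p["ids"])
    match = match_ims_to_lcms(list(passing), ids,
                              tolerance=cfg.match_tolerance_da)
    rep = build_report(match, stats)
    rep.to_csv(p["report"], index=False)
    return [p["report"]]


_STAGE_FUNCS = {
    "simulate": stage_simulate, "preprocess": stage_preprocess,
    "annotate": stage_annotate, "segment": stage_segment,
    "decompose": stage_decompose, "markers": stage_markers,
    "match": stage_match, "report": stage_report,
}


def run_all(cfg: RunConfig, out_dir: str | Path) -> RunManifest:
    """Execute all stages in order; any failure halts with the stage name
    while preserving upstream outputs."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = _paths(out)
    cfg.to_yaml(p["config"])
    manifest = RunManifest(
        config_hash=config_hash(cfg), out_dir=str(out),
        seed_registry={"master": cfg.seed, **{
            s: derive_seed(cfg.seed, s) for s in ("panel", "segment")}},
    )
    for name in STAGES:
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FUNCS[name](cfg, out)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        manifest.add(name, outputs, time.perf_counter() - t0)
    manifest.save(p["manifest"])
    return manifest


def compare_contrasts(out_dir: str | Path) -> dict:
    """Passing-marker counts per contrast and their tam:tm ratio.

    On default synthetic data, where treatment effects are planted only in the
    trauma-adjacent region, the tam contrast must dominate.
    """
    p = _paths(Path(out_dir))
    for key in ("markers_tam", "markers_tm"):
        if not p[key].exists():
            raise FileNotFoundError(f"missing contrast table {p[key]}")
    tam = pd.read_csv(p["markers_tam"])
    tm = pd.read_csv(p["markers_tm"])
    n_tam = int(tam["passes"].sum()) if len(tam) else 0
    n_tm = int(tm["passes"].sum()) if len(tm) else 0
    return {
        "tam_passing": n_tam,
        "tm_passing": n_tm,
        "tam_to_tm_ratio": float("inf") if n_tm == 0 and n_tam > 0
        else (n_tam / n_tm if n_tm else 0.0),
        "tam_mzs": list(tam.loc[tam["passes"], "mz"]) if len(tam) else [],
        "tm_mzs": list(tm.loc[tm["passes"], "mz"]) if len(tm) else [],
    }
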