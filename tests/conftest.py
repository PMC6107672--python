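"""Shared fixtures: a default study-shaped synthetic run, reused by the
module suites and the acceptance suite so the heavy simulation happens once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from msiregio import RunConfig, run_all
from msiregio.pipeline import load_truth, _paths

#: canonical master seed for the default study-shaped batch
MASTER_SEED = 1


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig(seed=MASTER_SEED)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory, default_config):
    """Full pipeline run on the default synthetic batch (2 groups x 2
    sections, 40x40 grid, 50 peaks, 10 region + 5 treatment markers)."""
    out = tmp_path_factory.mktemp("default_run")
    manifest = run_all(default_config, out)
    return out, manifest


@pytest.fixture(scope="session")
def default_truth(default_run):
    out, _ = default_run
    return load_truth(_paths(out)["truth"])


@pytest.fixture(scope="session")
def ground_truth_table(default_run, default_truth) -> pd.DataFrame:
    """Ground-truth per-pixel labels of the default batch, with group."""
    import json
    out, _ = default_run
    sections = json.loads((_paths(out)["data"] / "manifest.json").read_text())
    groups = {e["section_id"]: e["group"] for e in sections["sections"]}
    return default_truth.to_annotation(groups).table


@pytest.fixture(scope="session")
def default_features(default_run):
    from msiregio import FeatureMatrix
    out, _ = default_run
    return FeatureMatrix.from_csv(_paths(out)["features"])


def merge_truth(df: pd.DataFrame, gt: pd.DataFrame) -> pd.DataFrame:
    """Attach ground-truth region/group labels to a pixel-keyed frame."""
    gt = gt.rename(columns={"region": "true_region", "group": "true_group"})
    return df.merge(gt, on=["pixel_x", "pixel_y", "section"], how="left")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
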