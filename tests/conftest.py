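"""Shared fixtures: the default synthetic scene and its pipeline products.

The default 64-leaf scene is expensive enough to render and segment that the
suite builds it once per session; everything downstream (feature tables with
and without scatter correction) is derived from it here.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import leafspec as ls


@pytest.fixture(scope="session")
def default_cfg() -> ls.SceneConfig:
    return ls.SceneConfig()


@pytest.fixture(scope="session")
def default_scene(default_cfg):
    img, gt = ls.render_scene(default_cfg)
    return SimpleNamespace(cfg=default_cfg, img=img, gt=gt)


@pytest.fixture(scope="session")
def segmented(default_scene):
    cfg = default_scene.cfg
    cal = ls.calibrate(default_scene.img, cfg.panel_region, cfg.panel_reflectance)
    leaves = ls.segment_leaves(cal, exclude_region=cfg.panel_region)
    mapping, agreement, aligned = ls.match_labels(
        leaves, default_scene.gt.label_map, default_scene.gt.table)
    return SimpleNamespace(cal=cal, leaves=leaves, mapping=mapping,
                           agreement=agreement, aligned=aligned)


@pytest.fixture(scope="session")
def tables(segmented):
    """Normalized 32-column feature tables from leaf-mean spectra: OS and MSC."""
    ideal = ls.ideal_spectrum(segmented.leaves, segmented.cal)
    corrected = ls.msc_correct(segmented.leaves.spectra, ideal)
    norm_os = ls.normalize(ls.build_feature_table(segmented.leaves.spectra,
                                                  segmented.aligned))
    norm_msc = ls.normalize(ls.build_feature_table(corrected, segmented.aligned))
    return SimpleNamespace(os=norm_os, msc=norm_msc, ideal=ideal)


def make_toy_table(X: np.ndarray, y: np.ndarray, names=None,
                   target: str = "chl_ab") -> ls.FeatureTable:
    """A small already-normalized FeatureTable for selection/modeling tests."""
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"v{i}" for i in range(X.shape[1])]
    Xdf = pd.DataFrame(X, columns=list(names))
    mu, sd = Xdf.mean(), Xdf.std(ddof=1)
    ydf = pd.DataFrame({target: np.asarray(y, dtype=float)})
    return ls.FeatureTable(X=(Xdf - mu) / sd, y=ydf, normalized=True,
                           norm_means=mu, norm_sds=sd, raw_X=Xdf.copy())
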