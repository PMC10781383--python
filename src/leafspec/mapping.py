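"""Pixel-wise pigment mapping and per-layer reporting.

A model fitted on per-leaf mean spectra is applied to every leaf pixel of a
(typically MSC-corrected) reflectance image: the model's variable subset is
evaluated on the pixel's band vector, normalized with the training
parameters, and predicted.  Pixels whose features are undefined (masked
denominators) or whose prediction falls outside the training target range
widened by 20% of its span are flagged as outliers — flagged, never
silently dropped — emulating the removal of saturated/specular patches in
real imagery.

Layer summaries compare, per canopy layer, the mean predicted pigment over
all non-outlier pixels (the "green line") with the mean laboratory value of
that layer's leaves (the "red line"), plus a 50-bin frequency histogram of
the pixel predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import apply_normalization, compute_features
from .imaging import LeafSet, MultibandImage
from .modeling import FittedModel

__all__ = ["PigmentMap", "LayerSummary", "predict_map", "summarize_layers"]


@dataclass
class PigmentMap:
    """Per-pixel predicted pigment content (NaN outside leaves)."""

    values: np.ndarray           # H x W float32, NaN where undefined
    outlier_mask: np.ndarray     # H x W bool, True where flagged
    target: str
    model_id: str

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values) & ~self.outlier_mask


@dataclass
class LayerSummary:
    """One canopy layer: histogram plus the green-line/red-line statistics."""

    layer: str
    bin_edges: np.ndarray
    counts: np.ndarray
    pixel_mean: float            # mean prediction over non-outlier pixels
    lab_mean: float              # mean laboratory value of the layer's leaves
    n_pixels: int


def predict_map(img: MultibandImage, leaves: LeafSet, model: FittedModel,
                outlier_margin: float = 0.2) -> PigmentMap:
    """Apply a fitted model to every leaf pixel of a reflectance image.

    Pure function of its inputs: identical inputs give a bit-identical map.
    Predictions outside [y_min - m*range, y_max + m*range] of the training
    target (m = ``outlier_margin``) are flagged as outliers, as are pixels
    with any masked feature.
    """
    if img.kind != "reflectance":
        raise ValueError("predict_map expects a reflectance image")
    H, W, _ = img.shape
    mask = leaves.label_map > 0
    values = np.full((H, W), np.nan, dtype=np.float32)
    outliers = np.zeros((H, W), dtype=bool)
    bands = img.data[mask]
    feats = compute_features(bands, model.subset, mode=model.mode)
    defined = ~feats.isna().any(axis=1).to_numpy()
    Xn = apply_normalization(feats.loc[defined], model.norm_means, model.norm_sds)
    preds = model.predict(Xn)
    rows, cols = np.nonzero(mask)
    values[rows[defined], cols[defined]] = preds
    outliers[rows[~defined], cols[~defined]] = True
    span = model.y_max - model.y_min
    lo = model.y_min - outlier_margin * span
    hi = model.y_max + outlier_margin * span
    out_of_range = (preds < lo) | (preds > hi)
    outliers[rows[defined][out_of_range], cols[defined][out_of_range]] = True
    model_id = f"{model.family}:{model.target}"
    return PigmentMap(values=values, outlier_mask=outliers, target=model.target,
                      model_id=model_id)


def summarize_layers(pmap: PigmentMap, leaves: LeafSet, lab: pd.DataFrame,
                     n_bins: int = 50) -> list[LayerSummary]:
    """Per-layer pixel histograms and pixel-mean vs lab-mean statistics.

    ``lab`` must carry leaf_id (in segmented-label order is not required —
    leaf_id must match the segmentation labels), layer, and the target
    column (chl_ab or car).  Empty layers are omitted with a warning.
    """
    if leaves.layers is None:
        raise ValueError("LeafSet has no layer labels; match against ground truth first")
    target_col = pmap.target
    if target_col not in lab.columns:
        raise ValueError(f"lab table lacks a {target_col!r} column")
    layers_per_leaf = np.asarray(leaves.layers)
    summaries: list[LayerSummary] = []
    valid = pmap.valid_mask
    for layer in dict.fromkeys(leaves.layers):      # preserve first-seen order
        leaf_ids = np.flatnonzero(layers_per_leaf == layer) + 1
        px = valid & np.isin(leaves.label_map, leaf_ids)
        vals = pmap.values[px]
        if vals.size == 0:
            warnings.warn(f"layer {layer!r} has no valid pixels; omitted")
            continue
        counts, edges = np.histogram(vals, bins=n_bins)
        lab_rows = lab.loc[lab["layer"] == layer, target_col]
        summaries.append(LayerSummary(
            layer=layer, bin_edges=edges, counts=counts,
            pixel_mean=float(vals.mean()), lab_mean=float(lab_rows.mean()),
            n_pixels=int(vals.size)))
    return summaries
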