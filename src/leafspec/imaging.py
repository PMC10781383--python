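"""Radiometric calibration, leaf segmentation and per-leaf spectra.

Raw multiband counts become reflectance by ratio to a reference panel of
known reflectance (flat-field panel calibration).  Leaves are then segmented
on the 840-nm band — photosynthetic pigments do not absorb in the NIR, so
leaf pixels sit far above the black background there — with a reflectance
threshold of 0.25, labelled by 8-connected components, and summarised as
per-leaf mean spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from skimage import measure

__all__ = ["BAND_CENTERS", "BAND_NAMES", "MultibandImage", "LeafSet",
           "calibrate", "segment_leaves", "match_labels",
           "read_multiband_tiff", "write_leaf_spectra"]

BAND_CENTERS: tuple[int, ...] = (450, 555, 660, 720, 750, 840)
BAND_NAMES: tuple[str, ...] = ("Blue", "Green", "Red", "Edge1", "Edge2", "NIR")
NIR_INDEX = 5


@dataclass
class MultibandImage:
    """H x W x 6 raster plus band metadata.

    ``kind`` is "counts" (sensor units, within [0, 65535]) or "reflectance"
    (fractions; may exceed 1 or go negative after MSC).
    """

    data: np.ndarray
    band_centers: tuple[int, ...] = BAND_CENTERS
    kind: str = "counts"
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 6:
            raise ValueError(f"expected an H x W x 6 array, got {self.data.shape}")
        if self.kind not in ("counts", "reflectance"):
            raise ValueError(f"unknown image kind {self.kind!r}")
        if self.kind == "counts":
            if self.data.min() < 0 or self.data.max() > 2 ** self.bit_depth - 1:
                raise ValueError("counts outside the sensor range")
        elif not np.all(np.isfinite(self.data)):
            raise ValueError("reflectance must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LeafSet:
    """Segmentation result: label map plus per-leaf summaries.

    Labels are contiguous 1..K in order of decreasing pixel area; ``spectra``
    is K x 6 (mean reflectance per band), ``areas`` the pixel counts, and
    ``layers`` an optional canopy-layer label per leaf (filled in by
    :func:`match_labels` against a ground-truth table).
    """

    label_map: np.ndarray
    spectra: np.ndarray
    areas: np.ndarray
    layers: list[str] | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.areas)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.spectra, columns=[f"R{c}" for c in BAND_CENTERS])
        df.insert(0, "leaf_id", np.arange(1, self.n_leaves + 1))
        df.insert(1, "area_px", self.areas)
        if self.layers is not None:
            df["layer"] = self.layers
        return df


def calibrate(img: MultibandImage, panel_region: tuple[int, int, int, int],
              panel_reflectance=0.99) -> MultibandImage:
    """Panel-ratio calibration: R = counts / mean(panel counts) * panel reflectance.

    ``panel_region`` is (r0, r1, c0, c1); ``panel_reflectance`` is a scalar or
    per-band sequence.  Invariant to any global illumination scaling of the
    counts, since the panel scales with the scene.
    """
    if img.kind != "counts":
        raise ValueError("calibrate expects a counts image")
    r0, r1, c0, c1 = panel_region
    H, W, _ = img.shape
    if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
        raise ValueError("panel_region empty or outside the image")
    panel_mean = img.data[r0:r1, c0:c1, :].mean(axis=(0, 1))
    if np.any(panel_mean <= 0):
        raise ValueError("panel mean counts are zero in at least one band")
    refl = img.data / panel_mean * np.broadcast_to(np.asarray(panel_reflectance, dtype=float), (6,))
    return MultibandImage(data=refl, band_centers=img.band_centers, kind="reflectance")


def segment_leaves(img: MultibandImage, threshold: float = 0.25,
                   min_area: int = 50,
                   exclude_region: tuple[int, int, int, int] | None = None) -> LeafSet:
    """Threshold the 840-nm band, label 8-connected components, summarise.

    Pixels strictly above ``threshold`` are foreground; components smaller
    than ``min_area`` pixels are removed; surviving components are renumbered
    by decreasing area.  ``exclude_region`` (r0, r1, c0, c1) masks out the
    reference panel, which is otherwise bright enough to segment as a leaf.
    """
    if img.kind != "reflectance":
        raise ValueError("segment_leaves expects a reflectance image")
    mask = img.data[:, :, NIR_INDEX] > threshold
    if exclude_region is not None:
        r0, r1, c0, c1 = exclude_region
        mask[r0:r1, c0:c1] = False
    raw = measure.label(mask, connectivity=2)
    n_raw = raw.max()
    if n_raw == 0:
        warnings.warn("empty segmentation mask: no leaves found")
        return LeafSet(label_map=np.zeros_like(raw), spectra=np.empty((0, 6)),
                       areas=np.empty(0, dtype=int))
    areas = np.bincount(raw.ravel())[1:]
    keep = np.flatnonzero(areas >= min_area) + 1
    # renumber by descending area (ties: original label order)
    order = keep[np.argsort(-areas[keep - 1], kind="stable")]
    remap = np.zeros(n_raw + 1, dtype=np.int32)
    remap[order] = np.arange(1, len(order) + 1)
    label_map = remap[raw]
    K = len(order)
    spectra = np.empty((K, 6))
    flat = label_map.ravel()
    for b in range(6):
        sums = np.bincount(flat, weights=img.data[:, :, b].ravel(), minlength=K + 1)
        spectra[:, b] = sums[1:K + 1]
    counts = np.bincount(flat, minlength=K + 1)[1:K + 1]
    spectra /= counts[:, None]
    return LeafSet(label_map=label_map, spectra=spectra, areas=counts)


def match_labels(leaves: LeafSet, ref_label_map: np.ndarray,
                 ref_table: pd.DataFrame | None = None
                 ) -> tuple[dict[int, int], float, pd.DataFrame | None]:
    """Match segmented labels to reference labels by majority pixel overlap.

    Returns ``(mapping, agreement, aligned_table)`` where ``mapping`` sends a
    segmented label to the reference label covering most of its pixels,
    ``agreement`` is the fraction of reference leaf pixels whose segmented
    label maps back to the right reference leaf, and ``aligned_table`` (when
    ``ref_table`` with columns leaf_id/layer/chl_ab/car is given) is that
    table reordered to segmented-label order; ``leaves.layers`` is filled in.
    """
    seg = leaves.label_map
    mapping: dict[int, int] = {}
    for lab in range(1, leaves.n_leaves + 1):
        refs = ref_label_map[seg == lab]
        refs = refs[refs > 0]
        mapping[lab] = int(np.bincount(refs).argmax()) if refs.size else 0
    ref_mask = ref_label_map > 0
    remap = np.zeros(leaves.n_leaves + 1, dtype=int)
    for k, v in mapping.items():
        remap[k] = v
    agree = float(np.mean(remap[seg[ref_mask]] == ref_label_map[ref_mask]))
    aligned = None
    if ref_table is not None:
        idx = ref_table.set_index("leaf_id")
        aligned = idx.loc[[mapping[lab] for lab in range(1, leaves.n_leaves + 1)]].reset_index()
        leaves.layers = aligned["layer"].tolist()
    return mapping, agree, aligned


def read_multiband_tiff(path, kind: str = "counts") -> MultibandImage:
    arr = tifffile.imread(path)
    if arr.ndim == 3 and arr.shape[0] == 6 and arr.shape[2] != 6:
        arr = np.moveaxis(arr, 0, -1)
    return MultibandImage(data=np.asarray(arr, dtype=float), kind=kind)


def write_leaf_spectra(leaves: LeafSet, path) -> None:
    leaves.to_frame().to_csv(path, index=False)
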