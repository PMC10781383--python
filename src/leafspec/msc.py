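"""Multiplicative scatter correction (MSC) of 6-band leaf spectra.

Scatter from specular reflection and leaf inclination acts, to first order,
as an affine distortion of each spectrum: s' = b*s + a.  MSC estimates
(a, b) by ordinary least squares of each spectrum on a reference "ideal
spectrum" — here the mean over all leaf pixels of the group image — and
inverts the fit: corrected = (s - a) / b.  Any affine distortion with
positive gain is removed exactly; applying the correction twice against the
same ideal is a no-op.

The same routine serves leaf-mean spectra (modelling) and whole pixel cubes
(pigment mapping); corrected reflectance may legitimately leave [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import MultibandImage, LeafSet

__all__ = ["IdealSpectrum", "ideal_spectrum", "msc_correct", "msc_correct_image"]

_MIN_GAIN = 1e-8


@dataclass(frozen=True)
class IdealSpectrum:
    """MSC reference spectrum: mean over all leaf pixels of a group image."""

    values: np.ndarray           # 6 bands
    group_id: str = "scene"
    n_pixels: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (6,) or not np.all(np.isfinite(v)):
            raise ValueError("ideal spectrum must be 6 finite values")
        if v.std() == 0:
            raise ValueError("ideal spectrum is constant across bands")
        object.__setattr__(self, "values", v)


def ideal_spectrum(leaves: LeafSet, img: MultibandImage,
                   group_id: str = "scene") -> IdealSpectrum:
    """Mean spectrum over all labelled leaf pixels of the image."""
    mask = leaves.label_map > 0
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no leaf pixels: cannot form an ideal spectrum")
    return IdealSpectrum(values=img.data[mask].mean(axis=0), group_id=group_id,
                         n_pixels=n)


def msc_correct(spectra: np.ndarray, ideal: IdealSpectrum) -> np.ndarray:
    """OLS of each spectrum on the ideal across the 6 bands, then invert.

    ``spectra`` is (6,) or (N, 6); returns the same shape.  Spectra whose
    fitted gain magnitude is below 1e-8 (uncorrelated with the ideal) raise.
    """
    s = np.atleast_2d(np.asarray(spectra, dtype=float))
    if s.shape[1] != 6:
        raise ValueError("spectra must have 6 bands")
    m = ideal.values
    mc = m - m.mean()
    denom = float(mc @ mc)
    b = (s - s.mean(axis=1, keepdims=True)) @ mc / denom
    if np.any(np.abs(b) < _MIN_GAIN):
        raise ValueError("degenerate MSC fit: spectrum uncorrelated with the ideal")
    a = s.mean(axis=1) - b * m.mean()
    out = (s - a[:, None]) / b[:, None]
    return out[0] if np.asarray(spectra).ndim == 1 else out


def msc_correct_image(img: MultibandImage, leaves: LeafSet,
                      ideal: IdealSpectrum | None = None) -> MultibandImage:
    """Per-pixel MSC of all leaf pixels against the group ideal.

    Background and panel pixels pass through unchanged.  The default ideal is
    recomputed from this image, matching the per-scene convention.
    """
    if ideal is None:
        ideal = ideal_spectrum(leaves, img)
    mask = leaves.label_map > 0
    out = img.data.copy()
    out[mask] = msc_correct(img.data[mask], ideal)
    return MultibandImage(data=out, band_centers=img.band_centers, kind="reflectance")
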