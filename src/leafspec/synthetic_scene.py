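"""Seeded synthetic multiband leaf scenes with ground truth.

No public image/pigment dataset accompanies the study system this package
models, so this module generates one with the same statistical structure:
64 poplar leaves from three canopy layers tiled on a black background,
imaged in six broad bands (450/555/660/720/750/840 nm) next to a reference
panel, with laboratory pigment values per leaf.

What is emulated
----------------
* Per-leaf total chlorophyll (Chl_a+b) and carotenoid (Car) contents drawn
  from truncated normals matching the reference distribution
  (Chl_a+b 2.35-54.25 ug/cm^2, mean 26.96, SD 13.02; Car 2.12-9.54, mean
  6.10, SD 2.05; correlation 0.8), with mean-balanced layer shifts so
  upper-canopy leaves carry less pigment than lower-canopy leaves.
* A pigment->reflectance law: R_b = Rinf_b * exp(-(kChl_b*chl + kCar_b*car)),
  decreasing at 555/660/720 nm with pigment and flat in the NIR.  This law
  and its coefficients are a rendering fixture, not a radiative-transfer
  model; they are chosen so band-pigment correlations order the red-edge and
  green indices first, as observed on real leaves.
* Per-leaf affine scatter distortion (gain ~ LogNormal(0, scatter_sd),
  offset ~ N(0, offset_sd)) emulating specular reflection and leaf
  inclination — exactly the distortion family MSC is designed to remove —
  plus per-pixel Gaussian sensor noise.
* Within-leaf structure: a smooth radial pigment gradient and a darker main
  vein, so pixel maps show the leaf/vein contrast seen in real images.

Counts are kept as float64 clipped to [0, 65535]; quantisation to uint16
happens only on TIFF export, so exact-inversion invariants hold in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.stats import norm, truncnorm

from .imaging import MultibandImage, BAND_CENTERS
from .pigment_lab import ExtractContext, absorbances_from_contents, LAB_TABLE_COLUMNS

__all__ = ["SceneConfig", "GroundTruth", "sample_pigments", "reflectance_model",
           "render_scene", "write_scene"]


@dataclass(frozen=True)
class SceneConfig:
    """Configuration of one rendered leaf scene (a "group image")."""

    n_leaves: int = 64
    image_size: tuple[int, int] = (360, 480)          # (H, W) pixels
    layers: tuple[str, ...] = ("upper", "middle", "lower")
    layer_chl_shift: tuple[float, ...] = (-6.0, 0.0, 6.0)   # ug/cm^2
    layer_car_shift: tuple[float, ...] = (-0.8, 0.0, 0.8)
    chl_mean: float = 26.96
    chl_sd: float = 13.02
    chl_range: tuple[float, float] = (2.35, 54.25)
    car_mean: float = 6.10
    car_sd: float = 2.05
    car_range: tuple[float, float] = (2.12, 9.54)
    chl_car_corr: float = 0.8
    band_centers: tuple[int, ...] = BAND_CENTERS
    plateau: tuple[float, ...] = (0.10, 0.55, 0.50, 0.60, 0.62, 0.62)
    k_chl: tuple[float, ...] = (0.010, 0.030, 0.045, 0.020, 0.0, 0.0)
    k_car: tuple[float, ...] = (0.060, 0.010, 0.0, 0.0, 0.0, 0.0)
    panel_reflectance: float = 0.99
    panel_region: tuple[int, int, int, int] = (6, 42, 6, 96)  # r0, r1, c0, c1
    background_reflectance: float = 0.03
    illum_gain: float = 40000.0          # counts at unit reflectance, per band
    scatter_sd: float = 0.15             # per-leaf multiplicative log-scale SD
    offset_sd: float = 0.02              # per-leaf additive reflectance SD
    noise_sd: float = 0.005              # per-pixel sensor SD, reflectance units
    vein_contrast: float = 0.85          # reflectance factor on vein pixels (1 = off)
    gradient_amplitude: float = 0.10     # within-leaf pigment gradient (0 = off)
    seed: int = 20230217

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")
        if len(self.band_centers) != 6:
            raise ValueError("exactly 6 bands are expected")
        for name in ("scatter_sd", "offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for mean, (lo, hi), label in ((self.chl_mean, self.chl_range, "chl"),
                                      (self.car_mean, self.car_range, "car")):
            if not lo < hi:
                raise ValueError(f"infeasible {label} truncation bounds ({lo}, {hi})")
        if len(self.layers) != len(self.layer_chl_shift) or len(self.layers) != len(self.layer_car_shift):
            raise ValueError("layer shift tuples must match the layer labels")


@dataclass
class GroundTruth:
    """Per-pixel pigment maps, the leaf label map and the per-leaf table."""

    chl_map: np.ndarray          # H x W, ug/cm^2, 0 outside leaves
    car_map: np.ndarray
    label_map: np.ndarray        # H x W int, 0 = background, 1..K = leaves
    table: pd.DataFrame          # leaf_id, layer, chl_ab, car


def _calibrate_parent(target_mean: float, target_sd: float, lo: float, hi: float,
                      shifts: np.ndarray) -> tuple[np.ndarray, float]:
    """Parent (per-layer loc, scale) whose truncated pooled moments hit the target.

    The reference mean/SD are sample statistics of bounded data; truncation
    strictly shrinks a parent normal's SD, so the parent is inflated (and its
    location nudged) by fixed-point iteration on the exact truncated moments
    until the pooled truncated mean/SD across layers match the targets.
    """
    shifts = np.asarray(shifts, dtype=float)
    delta, sigma = 0.0, target_sd
    for _ in range(80):
        locs = target_mean + shifts + delta
        a = (lo - locs) / sigma
        b = (hi - locs) / sigma
        m, v = truncnorm.stats(a, b, loc=locs, scale=sigma, moments="mv")
        m, v = np.atleast_1d(m), np.atleast_1d(v)
        pooled_m = m.mean()
        pooled_sd = np.sqrt(v.mean() + m.var())
        delta -= 0.8 * (pooled_m - target_mean)
        sigma *= (target_sd / pooled_sd) ** 0.8
    return target_mean + shifts + delta, sigma


def sample_pigments(cfg: SceneConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the per-leaf pigment table.

    Chl_a+b and Car each follow a truncated normal over the reference range,
    coupled through a Gaussian copula with correlation ``cfg.chl_car_corr``.
    Because the reference mean/SD are sample statistics of bounded data, the
    parent normals are calibrated (:func:`_calibrate_parent`) so the
    *realized* pooled mean and SD match the reference values.  Layer shifts
    are mean-balanced, so the pooled mean stays on target while upper leaves
    run low and lower leaves run high.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_leaves
    layer_of = np.concatenate([
        np.full(len(chunk), i)
        for i, chunk in enumerate(np.array_split(np.arange(n), len(cfg.layers)))
    ])
    lo_c, hi_c = cfg.chl_range
    lo_k, hi_k = cfg.car_range
    raw_mu_c = cfg.chl_mean + np.asarray(cfg.layer_chl_shift)
    raw_mu_k = cfg.car_mean + np.asarray(cfg.layer_car_shift)
    if np.any(raw_mu_c <= lo_c) or np.any(raw_mu_c >= hi_c) or \
       np.any(raw_mu_k <= lo_k) or np.any(raw_mu_k >= hi_k):
        raise ValueError("layer-shifted mean falls outside the truncation bounds")
    locs_c, sd_c = _calibrate_parent(cfg.chl_mean, cfg.chl_sd, lo_c, hi_c,
                                     cfg.layer_chl_shift)
    locs_k, sd_k = _calibrate_parent(cfg.car_mean, cfg.car_sd, lo_k, hi_k,
                                     cfg.layer_car_shift)
    # Gaussian copula: correlated uniforms pushed through the two truncated
    # marginals, so marginal moments are exact and the dependence is r
    r = cfg.chl_car_corr
    z1 = rng.standard_normal(n)
    z2 = r * z1 + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
    u1 = norm.cdf(z1)
    u2 = norm.cdf(z2)
    mu_c = locs_c[layer_of]
    mu_k = locs_k[layer_of]
    chl = truncnorm.ppf(u1, (lo_c - mu_c) / sd_c, (hi_c - mu_c) / sd_c,
                        loc=mu_c, scale=sd_c)
    car = truncnorm.ppf(u2, (lo_k - mu_k) / sd_k, (hi_k - mu_k) / sd_k,
                        loc=mu_k, scale=sd_k)
    return pd.DataFrame({
        "leaf_id": np.arange(1, n + 1),
        "layer": [cfg.layers[j] for j in layer_of],
        "chl_ab": chl,
        "car": car,
    })


def reflectance_model(chl, car, cfg: SceneConfig | None = None) -> np.ndarray:
    """Six-band reflectance of a leaf element with the given pigment contents.

    ``R_b = Rinf_b * exp(-(kChl_b*chl + kCar_b*car))``; broadcasts over any
    leading shape of chl/car and returns shape ``(..., 6)`` in (0, 1].
    """
    if cfg is None:
        cfg = SceneConfig()
    chl = np.asarray(chl, dtype=float)[..., None]
    car = np.asarray(car, dtype=float)[..., None]
    if np.any(chl < 0) or np.any(car < 0):
        raise ValueError("pigment contents must be >= 0")
    plateau = np.asarray(cfg.plateau)
    return plateau * np.exp(-(np.asarray(cfg.k_chl) * chl + np.asarray(cfg.k_car) * car))


def _leaf_grid(cfg: SceneConfig) -> tuple[int, int, int]:
    """Grid geometry below the panel strip: (row0, cell_h, cell_w) and counts."""
    H, W = cfg.image_size
    row0 = cfg.panel_region[1] + 4
    avail_h = H - row0
    ncols = int(np.ceil(np.sqrt(cfg.n_leaves * W / max(avail_h, 1))))
    ncols = max(1, min(ncols, cfg.n_leaves))
    nrows = int(np.ceil(cfg.n_leaves / ncols))
    cell_h = avail_h // nrows
    cell_w = W // ncols
    if min(cell_h, cell_w) < 20:
        raise ValueError("image too small for the requested number of leaves")
    return row0, nrows, ncols, cell_h, cell_w


def render_scene(cfg: SceneConfig | None = None) -> tuple[MultibandImage, GroundTruth]:
    """Render one scene: 16-bit-range count image plus ground truth.

    Leaves are rotated ellipses placed one per grid cell (never touching, and
    never overlapping the panel), each with a smooth radial pigment gradient
    normalised so the masked map mean equals the leaf's table value exactly,
    and a darker main vein.  Reflectance -> counts uses a per-band
    illumination gain; per-leaf affine scatter distortion and per-pixel
    Gaussian noise are applied in reflectance units.
    """
    if cfg is None:
        cfg = SceneConfig()
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.image_size
    r0p, r1p, c0p, c1p = cfg.panel_region
    if not (0 <= r0p < r1p <= H and 0 <= c0p < c1p <= W):
        raise ValueError("panel_region outside the image")

    pigments = sample_pigments(cfg, rng)
    row0, nrows, ncols, cell_h, cell_w = _leaf_grid(cfg)

    label_map = np.zeros((H, W), dtype=np.int32)
    chl_map = np.zeros((H, W))
    car_map = np.zeros((H, W))
    vein = np.ones((H, W))
    mincell = min(cell_h, cell_w)

    for i in range(cfg.n_leaves):
        gr, gc = divmod(i, ncols)
        cy = row0 + gr * cell_h + cell_h / 2 + rng.uniform(-0.05, 0.05) * cell_h
        cx = gc * cell_w + cell_w / 2 + rng.uniform(-0.05, 0.05) * cell_w
        a = rng.uniform(0.30, 0.40) * mincell          # semi-major axis
        b = rng.uniform(0.55, 0.80) * a                # semi-minor axis
        theta = rng.uniform(0, np.pi)
        rr0 = max(int(cy - a) - 1, 0)
        rr1 = min(int(cy + a) + 2, H)
        cc0 = max(int(cx - a) - 1, 0)
        cc1 = min(int(cx + a) + 2, W)
        yy, xx = np.mgrid[rr0:rr1, cc0:cc1]
        dx, dy = xx - cx, yy - cy
        u = (dx * np.cos(theta) + dy * np.sin(theta)) / a
        v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b
        r2 = u * u + v * v
        inside = r2 <= 1.0
        if inside.sum() == 0:  # pragma: no cover
            raise RuntimeError("degenerate leaf ellipse")
        sub = (slice(rr0, rr1), slice(cc0, cc1))
        label_map[sub][inside] = i + 1
        # radial pigment gradient, normalised to masked mean 1
        g = 1.0 + cfg.gradient_amplitude * (0.5 - r2[inside])
        g /= g.mean()
        chl_map[sub][inside] = pigments["chl_ab"].iat[i] * g
        car_map[sub][inside] = pigments["car"].iat[i] * g
        # main vein along the major axis
        if cfg.vein_contrast != 1.0:
            vein_px = inside & (np.abs(v * b) <= 1.0)
            vein[sub][vein_px] = cfg.vein_contrast

    if np.any(label_map[r0p:r1p, c0p:c1p] > 0):
        raise ValueError("panel region overlaps a leaf")

    # reflectance cube
    refl = np.full((H, W, 6), cfg.background_reflectance)
    leaf_mask = label_map > 0
    refl[leaf_mask] = reflectance_model(chl_map[leaf_mask], car_map[leaf_mask], cfg)
    refl[leaf_mask] *= vein[leaf_mask][:, None]
    refl[r0p:r1p, c0p:c1p, :] = cfg.panel_reflectance

    # per-leaf affine scatter distortion (specular reflection / inclination)
    gains = np.exp(rng.normal(0.0, cfg.scatter_sd, cfg.n_leaves)) if cfg.scatter_sd > 0 \
        else np.ones(cfg.n_leaves)
    offsets = rng.normal(0.0, cfg.offset_sd, cfg.n_leaves) if cfg.offset_sd > 0 \
        else np.zeros(cfg.n_leaves)
    lbl = label_map[leaf_mask]
    refl[leaf_mask] = refl[leaf_mask] * gains[lbl - 1][:, None] + offsets[lbl - 1][:, None]

    if cfg.noise_sd > 0:
        refl = refl + rng.normal(0.0, cfg.noise_sd, refl.shape)

    counts = np.clip(refl * cfg.illum_gain, 0.0, 65535.0)
    img = MultibandImage(data=counts, band_centers=cfg.band_centers, kind="counts")
    gt = GroundTruth(chl_map=chl_map, car_map=car_map, label_map=label_map,
                     table=pigments)
    return img, gt


def make_lab_table(pigments: pd.DataFrame,
                   ctx: ExtractContext | None = None) -> pd.DataFrame:
    """Emulated wet-lab table: absorbances consistent with the true contents.

    Inverts the pigment equations so that running the forward conversion on
    the emitted absorbances reproduces chl_ab/car exactly.
    """
    if ctx is None:
        ctx = ExtractContext()
    a665, a649, a470 = absorbances_from_contents(
        pigments["chl_ab"].to_numpy(), pigments["car"].to_numpy(), ctx)
    return pd.DataFrame({
        "sample_id": pigments["leaf_id"],
        "layer": pigments["layer"],
        "A665": a665, "A649": a649, "A470": a470,
        "V_mL": ctx.V, "n": ctx.n, "leaf_area_cm2": ctx.leaf_area,
        "chl_ab_ug_cm2": pigments["chl_ab"],
        "car_ug_cm2": pigments["car"],
    })[LAB_TABLE_COLUMNS]


def write_scene(outdir, cfg: SceneConfig, img: MultibandImage, gt: GroundTruth) -> None:
    """Export a scene: counts TIFF (uint16), ground-truth TIFF, lab CSV, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "scene.tif",
                     np.rint(img.data).astype(np.uint16), photometric="minisblack")
    truth = np.stack([gt.chl_map, gt.car_map], axis=-1).astype(np.float32)
    tifffile.imwrite(outdir / "ground_truth.tif", truth, photometric="minisblack")
    tifffile.imwrite(outdir / "labels.tif", gt.label_map.astype(np.uint16),
                     photometric="minisblack")
    make_lab_table(gt.table).to_csv(outdir / "lab_table.csv", index=False)
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"scene_config": asdict(cfg)}, fh)
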