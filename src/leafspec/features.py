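"""The 32-variable "pseudo-hyper-spectrum": 6 bands + 26 vegetation indices.

Six broadband reflectances (450, 555, 660, 720, 750, 840 nm; aliased B1-B6
in wavelength order) are augmented with 26 published vegetation indices to
form the fixed 32-column feature table used for pigment modelling.

Each index carries two formula modes:

* ``as_printed`` — the formulation as tabulated in applied summaries,
  reproduced literally including its transcription idiosyncrasies (MSR and
  MSRre without square roots, RDVI identical to NDVI, CVI with Blue^2 in
  the denominator, GRNDVI with Blue).  This is the default, for fidelity.
* ``canonical`` — the originally published forms (MSR/MSRre with sqrt in the
  denominator, RDVI with sqrt(NIR+Red), CVI = NIR*Red/Green^2, GRNDVI with
  Red).

All printed formulas except MSRre are invariant to a common positive scaling
of the band vector; printed MSRre mixes a reflectance difference with the
constant 1 and is not (documented, not "fixed").  Divisions whose
denominator magnitude falls below 1e-9 yield NaN ("masked") rather than
infinities; sqrt of a negative ratio likewise masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .imaging import BAND_NAMES

__all__ = ["VI_REGISTRY", "BAND_ALIASES", "FEATURE_NAMES", "compute_vi",
           "compute_features", "FeatureTable", "build_feature_table",
           "normalize", "apply_normalization", "rank_by_correlation",
           "export_registry_yaml"]

_EPS = 1e-9

BAND_ALIASES = {f"B{i + 1}": name for i, name in enumerate(BAND_NAMES)}


def _div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.where(np.abs(den) < _EPS, np.nan, num / np.where(np.abs(den) < _EPS, 1.0, den))
    return out


def _sqrt(x):
    x = np.asarray(x, dtype=float)
    return np.where(x < 0, np.nan, np.sqrt(np.abs(x)))


@dataclass(frozen=True)
class _VI:
    name: str
    long_name: str
    printed: callable
    printed_str: str
    canonical: callable = None
    canonical_str: str = None
    citation: str = ""

    def __post_init__(self):
        if self.canonical is None:
            object.__setattr__(self, "canonical", self.printed)
            object.__setattr__(self, "canonical_str", self.printed_str)


def _registry() -> dict[str, _VI]:
    B, G, R, E1, E2, N = BAND_NAMES
    entries = [
        _VI("BGI", "Blue green pigment index",
            lambda d: _div(d[B], d[G]), "Blue/Green", citation="Zarco-Tejada 2005"),
        _VI("CIg", "Chlorophyll index (green)",
            lambda d: _div(d[N], d[G]) - 1, "(NIR/Green) - 1", citation="Gitelson 2003"),
        _VI("CIre", "Chlorophyll index (red edge)",
            lambda d: _div(d[N], d[E1]) - 1, "(NIR/Edge1) - 1", citation="Gitelson 2003"),
        _VI("CVI", "Chlorophyll vegetation index",
            lambda d: _div(d[N] * d[R], d[B] ** 2), "NIR * Red / Blue^2",
            lambda d: _div(d[N] * d[R], d[G] ** 2), "NIR * Red / Green^2",
            citation="Vincini 2008"),
        _VI("Datt", "Datt index",
            lambda d: _div(d[N] - d[E1], d[N] - d[R]), "(NIR - Edge1)/(NIR - Red)",
            citation="Datt 1999"),
        _VI("GLI", "Green leaf index",
            lambda d: _div(2 * d[G] - d[R] - d[B], 2 * d[G] + d[R] + d[B]),
            "(2*Green - Red - Blue)/(2*Green + Red + Blue)", citation="Louhaichi 2001"),
        _VI("GNDVI", "Green normalized difference vegetation index",
            lambda d: _div(d[N] - d[G], d[N] + d[G]), "(NIR - Green)/(NIR + Green)",
            citation="Gitelson 1996"),
        _VI("GRNDVI", "Green-red NDVI",
            lambda d: _div(d[N] - d[G] - d[B], d[N] + d[G] + d[B]),
            "(NIR - Green - Blue)/(NIR + Green + Blue)",
            lambda d: _div(d[N] - d[G] - d[R], d[N] + d[G] + d[R]),
            "(NIR - Green - Red)/(NIR + Green + Red)", citation="Wang 2007"),
        _VI("LCI", "Leaf chlorophyll index",
            lambda d: _div(d[N] - d[E1], d[N] + d[R]), "(NIR - Edge1)/(NIR + Red)",
            citation="Datt 1999"),
        _VI("mNDVI", "Modified NDVI",
            lambda d: _div(d[N] - d[R], d[N] + d[R] - 2 * d[B]),
            "(NIR - Red)/(NIR + Red - 2*Blue)", citation="Sims & Gamon 2002"),
        _VI("MSR", "Modified simple ratio",
            lambda d: _div(_div(d[N], d[R]) - 1, _div(d[N], d[R]) + 1),
            "((NIR/Red) - 1)/((NIR/Red) + 1)",
            lambda d: _div(_div(d[N], d[R]) - 1, _sqrt(_div(d[N], d[R])) + 1),
            "((NIR/Red) - 1)/(sqrt(NIR/Red) + 1)", citation="Chen 1996"),
        _VI("MSRre", "Modified red-edge simple ratio",
            lambda d: _div(d[N] - d[E1] - 1, d[N] - d[E1] + 1),
            "(NIR - Edge1 - 1)/(NIR - Edge1 + 1)",
            lambda d: _div(_div(d[N], d[E1]) - 1, _sqrt(_div(d[N], d[E1])) + 1),
            "((NIR/Edge1) - 1)/(sqrt(NIR/Edge1) + 1)", citation="Chen 1996"),
        _VI("MTCI", "MERIS terrestrial chlorophyll index",
            lambda d: _div(d[E2] - d[E1], d[E1] - d[R]), "(Edge2 - Edge1)/(Edge1 - Red)",
            citation="Dash & Curran 2004"),
        _VI("NDRE", "Normalized difference red edge index",
            lambda d: _div(d[N] - d[E1], d[N] + d[E1]), "(NIR - Edge1)/(NIR + Edge1)",
            citation="Barnes 2000"),
        _VI("NDVI", "Normalized difference vegetation index",
            lambda d: _div(d[N] - d[R], d[N] + d[R]), "(NIR - Red)/(NIR + Red)",
            citation="Rouse 1974"),
        _VI("NDVIg", "Green NDVI (750/555)",
            lambda d: _div(d[E2] - d[G], d[E2] + d[G]), "(Edge2 - Green)/(Edge2 + Green)",
            citation="Gitelson 1996"),
        _VI("NGRDI", "Normalized green-red difference index",
            lambda d: _div(d[G] - d[R], d[G] + d[R]), "(Green - Red)/(Green + Red)",
            citation="Tucker 1979"),
        _VI("NPCI", "Normalized pigment chlorophyll index",
            lambda d: _div(d[R] - d[B], d[R] + d[B]), "(Red - Blue)/(Red + Blue)",
            citation="Penuelas 1994"),
        _VI("PPR", "Plant pigment ratio",
            lambda d: _div(d[G] - d[B], d[G] + d[B]), "(Green - Blue)/(Green + Blue)",
            citation="Metternicht 2003"),
        _VI("PSSR", "Pigment specific simple ratio",
            lambda d: _div(d[N], d[R]), "NIR/Red", citation="Blackburn 1998"),
        _VI("RDVI", "Renormalized difference vegetation index",
            lambda d: _div(d[N] - d[R], d[N] + d[R]), "(NIR - Red)/(NIR + Red)",
            lambda d: _div(d[N] - d[R], _sqrt(d[N] + d[R])),
            "(NIR - Red)/sqrt(NIR + Red)", citation="Roujean & Breon 1995"),
        _VI("RENDVI", "Red edge NDVI",
            lambda d: _div(d[E2] - d[E1], d[E2] + d[E1]),
            "(Edge2 - Edge1)/(Edge2 + Edge1)", citation="Gitelson 1994"),
        _VI("SIPI2", "Structure insensitive pigment index 2",
            lambda d: _div(d[N] - d[B], d[N] - d[R]), "(NIR - Blue)/(NIR - Red)",
            citation="Penuelas 1995"),
        _VI("SR450_660", "Simple ratio 450/660",
            lambda d: _div(d[B], d[R]), "Blue/Red", citation="Penuelas 1994"),
        _VI("SR750_555", "Simple ratio 750/555",
            lambda d: _div(d[E2], d[G]), "Edge2/Green", citation="Gitelson 2003"),
        _VI("VOG1", "Vogelmann red edge index 1",
            lambda d: _div(d[E2], d[E1]), "Edge2/Edge1", citation="Vogelmann 1993"),
    ]
    return {e.name: e for e in entries}


VI_REGISTRY: dict[str, _VI] = _registry()
VI_NAMES: tuple[str, ...] = tuple(VI_REGISTRY)
FEATURE_NAMES: tuple[str, ...] = tuple(BAND_ALIASES) + VI_NAMES
assert len(VI_NAMES) == 26 and len(FEATURE_NAMES) == 32

# printed MSRre mixes a reflectance difference with the constant 1, so it is
# the one printed formula not invariant to a common positive band scaling;
# canonical RDVI divides by sqrt(NIR+Red) and scales as sqrt(c)
NOT_SCALE_INVARIANT_PRINTED: frozenset = frozenset({"MSRre"})
NOT_SCALE_INVARIANT_CANONICAL: frozenset = frozenset({"RDVI"})


def compute_vi(name: str, bands, mode: str = "as_printed"):
    """Evaluate one vegetation index on a band vector or (N, 6) array."""
    if name not in VI_REGISTRY:
        raise KeyError(f"unknown vegetation index {name!r}")
    if mode not in ("as_printed", "canonical"):
        raise ValueError(f"unknown formula mode {mode!r}")
    arr = np.atleast_2d(np.asarray(bands, dtype=float))
    d = {bn: arr[:, i] for i, bn in enumerate(BAND_NAMES)}
    entry = VI_REGISTRY[name]
    out = entry.printed(d) if mode == "as_printed" else entry.canonical(d)
    return out[0] if np.asarray(bands).ndim == 1 else out


def compute_features(bands, names=FEATURE_NAMES, mode: str = "as_printed") -> pd.DataFrame:
    """Evaluate the named features (bands and/or VIs) on an (N, 6) band array."""
    arr = np.atleast_2d(np.asarray(bands, dtype=float))
    cols = {}
    for name in names:
        if name in BAND_ALIASES:
            cols[name] = arr[:, list(BAND_ALIASES).index(name)]
        else:
            cols[name] = compute_vi(name, arr, mode=mode)
    return pd.DataFrame(cols)


@dataclass
class FeatureTable:
    """Samples x 32 feature matrix with targets and normalization state.

    ``X`` keeps the fixed registry column order (B1..B6 then the 26 VI
    abbreviations); ``y`` holds the chl_ab and car targets (ug/cm^2).  After
    :func:`normalize`, ``norm_means``/``norm_sds`` store the z-score
    parameters (sample SD, n-1) and ``raw_X`` retains the unnormalized
    matrix for procedures that re-normalize inside resampling folds.
    """

    X: pd.DataFrame
    y: pd.DataFrame
    mode: str = "as_printed"
    normalized: bool = False
    norm_means: pd.Series | None = None
    norm_sds: pd.Series | None = None
    raw_X: pd.DataFrame | None = None
    n_dropped: int = 0

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def raw(self) -> pd.DataFrame:
        return self.X if self.raw_X is None else self.raw_X

    def to_csv(self, path) -> None:
        pd.concat([self.X, self.y], axis=1).to_csv(path, index=False)


def build_feature_table(band_vectors, targets: pd.DataFrame,
                        mode: str = "as_printed") -> FeatureTable:
    """Assemble the 32-column table from per-leaf spectra and lab targets.

    ``band_vectors`` is (n, 6) in band order 450..840 nm; ``targets`` must
    carry chl_ab and car columns aligned row-for-row.  Rows with any masked
    (NaN) index are dropped; the count is recorded on the result.
    """
    arr = np.atleast_2d(np.asarray(band_vectors, dtype=float))
    if len(arr) != len(targets):
        raise ValueError(f"{len(arr)} spectra but {len(targets)} target rows")
    X = compute_features(arr, FEATURE_NAMES, mode=mode)
    y = targets.loc[:, ["chl_ab", "car"]].reset_index(drop=True)
    ok = ~X.isna().any(axis=1)
    n_dropped = int((~ok).sum())
    return FeatureTable(X=X.loc[ok].reset_index(drop=True),
                        y=y.loc[ok.to_numpy()].reset_index(drop=True),
                        mode=mode, n_dropped=n_dropped)


def normalize(table: FeatureTable) -> FeatureTable:
    """Z-score every feature column (mean 0, sample SD 1)."""
    if len(table.X) < 2:
        raise ValueError("need at least 2 samples to normalize")
    means = table.X.mean()
    sds = table.X.std(ddof=1)
    zero = sds.index[sds < _EPS].tolist()
    if zero:
        raise ValueError(f"zero-variance feature columns: {zero}")
    return FeatureTable(X=(table.X - means) / sds, y=table.y, mode=table.mode,
                        normalized=True, norm_means=means, norm_sds=sds,
                        raw_X=table.raw.copy(), n_dropped=table.n_dropped)


def apply_normalization(X: pd.DataFrame, means: pd.Series, sds: pd.Series) -> pd.DataFrame:
    """Apply stored z-score parameters to new rows (e.g. map pixels)."""
    cols = X.columns
    return (X - means[cols]) / sds[cols]


def rank_by_correlation(table: FeatureTable, target: str) -> pd.DataFrame:
    """Rank all features by |Pearson r| against a pigment target.

    Ties keep registry order (stable sort).  Returns a DataFrame with
    columns variable, r, abs_r, rank (1 = most correlated).
    """
    if target not in table.y.columns:
        raise ValueError(f"unknown target {target!r}")
    if len(table.X) < 3:
        raise ValueError("need at least 3 samples for a correlation ranking")
    yv = table.y[target].to_numpy(dtype=float)
    if yv.std() < _EPS:
        raise ValueError("zero-variance target")
    r = np.array([np.corrcoef(table.X[c].to_numpy(dtype=float), yv)[0, 1]
                  for c in table.X.columns])
    order = np.argsort(-np.abs(r), kind="stable")
    out = pd.DataFrame({"variable": np.asarray(table.X.columns)[order],
                        "r": r[order], "abs_r": np.abs(r)[order]})
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def export_registry_yaml(path, mode: str = "as_printed") -> None:
    """Machine-readable dump of the VI registry (name, formula, citation)."""
    entries = []
    for e in VI_REGISTRY.values():
        entries.append({"name": e.name, "long_name": e.long_name, "mode": mode,
                        "formula": e.printed_str if mode == "as_printed" else e.canonical_str,
                        "citation": e.citation})
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)
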