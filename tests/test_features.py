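"""The 32-variable feature set: VI formulas, normalization, correlation ranking.

The VI formulas are checked against an independent oracle written here as
plain scalar arithmetic, separate from the registry's vectorized
implementations.
"""

import math

import numpy as np
import pandas as pd
import pytest

import leafspec as ls
from leafspec import features as ft

# ---------------------------------------------------------------------------
# independent scalar oracle: (printed, canonical) per index, on a 6-tuple
# (Blue, Green, Red, Edge1, Edge2, NIR)
# ---------------------------------------------------------------------------


def _oracle(name, mode, B, G, R, E1, E2, N):
    printed = {
        "BGI": lambda: B / G,
        "CIg": lambda: N / G - 1,
        "CIre": lambda: N / E1 - 1,
        "CVI": lambda: N * R / B ** 2,
        "Datt": lambda: (N - E1) / (N - R),
        "GLI": lambda: (2 * G - R - B) / (2 * G + R + B),
        "GNDVI": lambda: (N - G) / (N + G),
        "GRNDVI": lambda: (N - G - B) / (N + G + B),
        "LCI": lambda: (N - E1) / (N + R),
        "mNDVI": lambda: (N - R) / (N + R - 2 * B),
        "MSR": lambda: (N / R - 1) / (N / R + 1),
        "MSRre": lambda: (N - E1 - 1) / (N - E1 + 1),
        "MTCI": lambda: (E2 - E1) / (E1 - R),
        "NDRE": lambda: (N - E1) / (N + E1),
        "NDVI": lambda: (N - R) / (N + R),
        "NDVIg": lambda: (E2 - G) / (E2 + G),
        "NGRDI": lambda: (G - R) / (G + R),
        "NPCI": lambda: (R - B) / (R + B),
        "PPR": lambda: (G - B) / (G + B),
        "PSSR": lambda: N / R,
        "RDVI": lambda: (N - R) / (N + R),
        "RENDVI": lambda: (E2 - E1) / (E2 + E1),
        "SIPI2": lambda: (N - B) / (N - R),
        "SR450_660": lambda: B / R,
        "SR750_555": lambda: E2 / G,
        "VOG1": lambda: E2 / E1,
    }
    canonical = dict(printed)
    canonical.update({
        "CVI": lambda: N * R / G ** 2,
        "GRNDVI": lambda: (N - G - R) / (N + G + R),
        "MSR": lambda: (N / R - 1) / (math.sqrt(N / R) + 1),
        "MSRre": lambda: (N / E1 - 1) / (math.sqrt(N / E1) + 1),
        "RDVI": lambda: (N - R) / math.sqrt(N + R),
    })
    return (printed if mode == "as_printed" else canonical)[name]()


def _random_bands(n, seed=0):
    rng = np.random.default_rng(seed)
    # realistic leaf reflectances, bounded away from masked denominators
    lo = np.array([0.02, 0.10, 0.05, 0.25, 0.45, 0.45])
    hi = np.array([0.12, 0.45, 0.40, 0.60, 0.70, 0.70])
    return lo + (hi - lo) * rng.random((n, 6))


class TestRegistry:
    def test_counts(self):
        assert len(ft.VI_REGISTRY) == 26
        assert len(ft.FEATURE_NAMES) == 32
        assert ft.FEATURE_NAMES[:6] == ("B1", "B2", "B3", "B4", "B5", "B6")

    def test_unknown_index_rejected(self):
        with pytest.raises(KeyError):
            ls.compute_vi("NOPE", np.ones(6))
        with pytest.raises(ValueError):
            ls.compute_vi("NDVI", np.ones(6), mode="freestyle")

    @pytest.mark.parametrize("name, bands, expected", [
        ("NDVI", dict(NIR=0.5, Red=0.1), 0.4 / 0.6),
        ("NDVI", dict(NIR=0.3, Red=0.3), 0.0),
        ("MTCI", dict(Edge2=0.4, Edge1=0.3, Red=0.1), 0.5),
        ("VOG1", dict(Edge2=0.36, Edge1=0.3), 1.2),
        ("CIg", dict(NIR=0.6, Green=0.2), 2.0),
        ("CIre", dict(NIR=0.6, Edge1=0.3), 1.0),
    ])
    def test_worked_examples(self, name, bands, expected):
        vec = np.full(6, 0.2)
        for bname, val in bands.items():
            vec[ft.BAND_NAMES.index(bname)] = val
        assert ls.compute_vi(name, vec) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("mode", ["as_printed", "canonical"])
    def test_all_formulas_match_oracle(self, mode):
        """Every registry formula equals independent direct arithmetic."""
        bands = _random_bands(1000, seed=1)
        for name in ft.VI_NAMES:
            got = ls.compute_vi(name, bands, mode=mode)
            want = np.array([_oracle(name, mode, *row) for row in bands])
            np.testing.assert_allclose(got, want, atol=1e-12, err_msg=f"{name}/{mode}")

    @pytest.mark.parametrize("mode", ["as_printed", "canonical"])
    def test_scale_invariance(self, mode):
        """Band-ratio indices are invariant to a common positive scaling.

        Printed MSRre mixes a reflectance difference with the constant 1 and
        is the documented exception.
        """
        bands = _random_bands(200, seed=2)
        exceptions = (ft.NOT_SCALE_INVARIANT_PRINTED if mode == "as_printed"
                      else ft.NOT_SCALE_INVARIANT_CANONICAL)
        for name in ft.VI_NAMES:
            if name in exceptions:
                base = ls.compute_vi(name, bands, mode=mode)
                scaled = ls.compute_vi(name, 2.0 * bands, mode=mode)
                assert np.abs(base - scaled).max() > 1e-6
                continue
            for c in (0.5, 3.0):
                np.testing.assert_allclose(
                    ls.compute_vi(name, c * bands, mode=mode),
                    ls.compute_vi(name, bands, mode=mode),
                    rtol=1e-9, atol=1e-9, err_msg=f"{name} x{c}")

    def test_masked_denominator_yields_nan(self):
        vec = np.full(6, 0.3)            # NIR == Red -> Datt/SIPI2 masked
        assert np.isnan(ls.compute_vi("Datt", vec))
        assert np.isnan(ls.compute_vi("SIPI2", vec))


class TestFeatureTable:
    def test_shape_and_order(self, tables):
        assert tables.os.X.shape[1] == 32
        assert list(tables.os.X.columns) == list(ft.FEATURE_NAMES)
        assert tables.os.X.shape[0] == 64

    def test_band_columns_passthrough(self, segmented):
        tab = ls.build_feature_table(segmented.leaves.spectra, segmented.aligned)
        np.testing.assert_allclose(tab.X["B6"], segmented.leaves.spectra[:, 5])

    def test_masked_rows_dropped_and_counted(self):
        spectra = np.array([
            [0.05, 0.2, 0.15, 0.35, 0.6, 0.6],
            [0.05, 0.2, 0.60, 0.35, 0.6, 0.6],   # NIR == Red: Datt masked
        ])
        targets = pd.DataFrame({"chl_ab": [10.0, 20.0], "car": [3.0, 4.0]})
        tab = ls.build_feature_table(spectra, targets)
        assert len(tab.X) == 1
        assert tab.n_dropped == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ls.build_feature_table(np.ones((3, 6)),
                                   pd.DataFrame({"chl_ab": [1.0], "car": [1.0]}))


class TestNormalize:
    def test_mean_zero_sd_one(self, tables):
        assert np.abs(tables.os.X.mean()).max() < 1e-12
        assert np.abs(tables.os.X.std(ddof=1) - 1).max() < 1e-12

    def test_two_sample_column_sample_sd(self):
        """{0, 2} standardizes to +-1/sqrt(2) under the n-1 convention."""
        tab = ls.FeatureTable(X=pd.DataFrame({"v": [0.0, 2.0]}),
                              y=pd.DataFrame({"chl_ab": [1.0, 2.0]}))
        norm = ls.normalize(tab)
        np.testing.assert_allclose(norm.X["v"], [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_stored_parameters_reproduce(self, tables):
        again = ft.apply_normalization(tables.os.raw, tables.os.norm_means,
                                       tables.os.norm_sds)
        np.testing.assert_allclose(again, tables.os.X, atol=1e-12)

    def test_zero_variance_rejected(self):
        tab = ls.FeatureTable(X=pd.DataFrame({"v": [1.0, 1.0, 1.0]}),
                              y=pd.DataFrame({"chl_ab": [1.0, 2.0, 3.0]}))
        with pytest.raises(ValueError, match="zero-variance.*v"):
            ls.normalize(tab)


class TestCorrelationRanking:
    def test_oracle_equivalence(self, tables):
        """Ranking equals brute-force recomputation of all 32 correlations."""
        ranking = ls.rank_by_correlation(tables.os, "chl_ab")
        y = tables.os.y["chl_ab"].to_numpy()
        for _, row in ranking.iterrows():
            x = tables.os.X[row["variable"]].to_numpy()
            r = float(np.sum((x - x.mean()) * (y - y.mean())) /
                      np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
            assert row["r"] == pytest.approx(r, abs=1e-10)
        assert sorted(ranking["rank"]) == list(range(1, 33))
        assert (np.diff(ranking["abs_r"]) <= 1e-12).all()

    def test_perfect_feature_ranks_first(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=50)
        X = pd.DataFrame({"a": rng.normal(size=50), "b": y.copy(),
                          "c": -y, "d": rng.normal(size=50)})
        tab = ls.FeatureTable(X=X, y=pd.DataFrame({"chl_ab": y}), normalized=True)
        ranking = ls.rank_by_correlation(tab, "chl_ab")
        top_two = set(ranking.head(2)["variable"])
        assert top_two == {"b", "c"}          # sign-invariant |r| = 1
        assert ranking.head(2)["abs_r"].min() == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self, tables):
        with pytest.raises(ValueError):
            ls.rank_by_correlation(tables.os, "not_a_target")
        tab = ls.FeatureTable(X=pd.DataFrame({"v": [1.0, 2.0, 3.0]}),
                              y=pd.DataFrame({"chl_ab": [5.0, 5.0, 5.0]}))
        with pytest.raises(ValueError, match="zero-variance target"):
            ls.rank_by_correlation(tab, "chl_ab")


def test_registry_yaml_export(tmp_path):
    import yaml
    path = tmp_path / "registry.yaml"
    ft.export_registry_yaml(path)
    entries = yaml.safe_load(path.read_text())
    assert len(entries) == 26
    assert {e["name"] for e in entries} == set(ft.VI_NAMES)
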