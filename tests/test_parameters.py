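import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soyspec import (
    DUAL_BAND_NAMES,
    EMPIRICAL_NAMES,
    FULL_GRID,
    TRILATERAL_NAMES,
    SpectrumSet,
    dual_band_value,
    empirical_indices,
    first_derivative,
    parameter_matrix,
    trilateral_parameters,
)
from conftest import random_spectra

refl = st.floats(0.01, 1.0, allow_nan=False)


def spectrum_with_bands(values: dict[int, float], fill: float = 0.5) -> SpectrumSet:
    """Single spectrum with specified reflectance at named wavelengths."""
    r = np.full(FULL_GRID.size, fill)
    for nm, v in values.items():
        r[nm - 350] = v
    return SpectrumSet(FULL_GRID.copy(), r[None, :], ["a"])


class TestEmpiricalIndices:
    def test_osavi_hand_example(self):
        s = spectrum_with_bands({800: 0.5, 670: 0.05})
        out = empirical_indices(s)
        expected = 1.16 * (0.5 - 0.05) / (0.5 + 0.05 + 0.16)
        assert out["OSAVI"].iloc[0] == pytest.approx(expected, abs=1e-12)
        assert out["OSAVI"].iloc[0] == pytest.approx(0.7352, abs=1e-4)

    def test_ndni_hand_example_and_base_invariance(self):
        s = spectrum_with_bands({1510: 0.1, 1680: 0.2})
        out = empirical_indices(s)
        ln = (math.log(1 / 0.1) - math.log(1 / 0.2)) / (
            math.log(1 / 0.1) + math.log(1 / 0.2)
        )
        lg = (math.log10(1 / 0.1) - math.log10(1 / 0.2)) / (
            math.log10(1 / 0.1) + math.log10(1 / 0.2)
        )
        assert ln == pytest.approx(lg, abs=1e-12)  # base invariance is algebraic
        assert out["NDNI"].iloc[0] == pytest.approx(ln, abs=1e-12)
        assert out["NDNI"].iloc[0] == pytest.approx(0.17718, abs=1e-5)

    def test_dd_hand_example(self):
        s = spectrum_with_bands({749: 0.5, 720: 0.4, 701: 0.2, 672: 0.15})
        out = empirical_indices(s)
        assert out["DD"].iloc[0] == pytest.approx(0.05, abs=1e-12)

    def test_ratio_800_680(self):
        s = spectrum_with_bands({800: 0.5, 680: 0.1})
        out = empirical_indices(s)
        assert out["D800/680"].iloc[0] == pytest.approx(5.0, abs=1e-12)

    def test_ipvi_product_vs_literature(self):
        s = spectrum_with_bands({800: 0.5, 670: 0.05})
        product = empirical_indices(s)["IPVI"].iloc[0]
        lit = empirical_indices(s, ipvi_literature=True)["IPVI"].iloc[0]
        assert product == pytest.approx(0.5 * 0.55, abs=1e-12)
        assert lit == pytest.approx(0.5 / 0.55, abs=1e-12)

    def test_avi_readings(self):
        s = spectrum_with_bands({800: 0.5, 1100: 0.4, 600: 0.1, 700: 0.2})
        ratio = empirical_indices(s)
        assert ratio["AVI"].iloc[0] == pytest.approx(2 * 0.5 / 0.4 - 0.1 / 0.2)
        assert ratio["DVI_MSS"].iloc[0] == pytest.approx(2.4 * 0.5 / 0.4 - 0.1 / 0.2)
        prod = empirical_indices(s, ratio_reading=False)
        assert prod["AVI"].iloc[0] == pytest.approx(2 * 0.5 * 0.4 - 0.1 * 0.2)

    def test_zero_reflectance_gives_nan_sentinel(self):
        s = spectrum_with_bands({500: 0.0})
        out = empirical_indices(s)
        assert np.isnan(out["D678/500"].iloc[0])

    def test_all_ten_columns(self, smoothed):
        out = empirical_indices(smoothed)
        assert list(out.columns) == EMPIRICAL_NAMES
        assert len(out) == smoothed.n_samples


class TestTrilateralParameters:
    def test_telescoping_areas(self, smoothed):
        out = trilateral_parameters(smoothed)
        for name, (lo, hi) in [
            ("S_b", (490, 530)),
            ("S_y", (462, 642)),
            ("S_r", (670, 760)),
        ]:
            expected = smoothed.band(hi) - smoothed.band(lo)
            np.testing.assert_allclose(out[name], expected, atol=1e-12)

    def test_monotone_spectrum(self):
        ramp = np.linspace(0.1, 0.9, FULL_GRID.size)
        s = SpectrumSet(FULL_GRID.copy(), ramp[None, :], ["a"])
        out = trilateral_parameters(s)
        assert out["D_b"].iloc[0] > 0
        assert out["D_y"].iloc[0] > 0
        assert out["D_r"].iloc[0] > 0
        assert out["R_g"].iloc[0] == pytest.approx(ramp[560 - 350])
        assert out["R_r"].iloc[0] == pytest.approx(ramp[650 - 350])

    def test_ndd_zero_when_equal_amplitudes(self):
        flat = np.full(FULL_GRID.size, 0.4)
        s = SpectrumSet(FULL_GRID.copy(), flat[None, :], ["a"])
        out = trilateral_parameters(s)
        # D_r = D_b = 0 on a constant spectrum -> normalized forms undefined
        assert np.isnan(out["NDD_rb"].iloc[0])
        ramp = np.linspace(0.1, 0.9, FULL_GRID.size)
        out2 = trilateral_parameters(SpectrumSet(FULL_GRID.copy(), ramp[None, :], ["a"]))
        # constant-slope ramp: D_r == D_b exactly -> NDD = 0
        assert out2["NDD_rb"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_yellow_edge_overlaps_blue(self, smoothed):
        # the 462-642 nm yellow window contains the blue edge entirely
        out = trilateral_parameters(smoothed)
        assert (out["D_y"] >= out["D_b"] - 1e-15).all()

    def test_all_ten_columns(self, smoothed):
        out = trilateral_parameters(smoothed)
        assert list(out.columns) == TRILATERAL_NAMES


class TestDualBandFormulas:
    def test_vi6_hand_example(self):
        assert dual_band_value("VI6", 0.5, 0.25) == pytest.approx(-2.0, abs=1e-12)

    def test_tvi_hand_example(self):
        v = dual_band_value("TVI", 0.5, 0.2, r_550=0.1)
        assert v == pytest.approx(14.0, abs=1e-12)

    def test_mndi_hand_example(self):
        v = dual_band_value("mNDI", 0.5, 0.3, r_455=0.1)
        assert v == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert v == pytest.approx(0.3333, abs=1e-4)

    def test_savi_matches_closed_form(self):
        v = dual_band_value("SAVI", 0.5, 0.05)
        assert v == pytest.approx(1.16 * 0.45 / 0.71, abs=1e-12)

    @pytest.mark.parametrize("fid", ["DI", "NDVI", "VI6"])
    def test_zero_at_equal_bands(self, fid):
        assert dual_band_value(fid, 0.4, 0.4) == pytest.approx(0.0, abs=1e-12)

    @given(refl, refl)
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry_and_symmetry(self, ri, rj):
        for fid in ("DI", "NDVI", "VI6"):
            a = dual_band_value(fid, ri, rj)
            b = dual_band_value(fid, rj, ri)
            assert a == pytest.approx(-b, rel=1e-9, abs=1e-12)
        assert dual_band_value("PI", ri, rj) == dual_band_value("PI", rj, ri)
        assert dual_band_value("SI", ri, rj) == dual_band_value("SI", rj, ri)
        ratio = dual_band_value("RI", ri, rj) * dual_band_value("RI", rj, ri)
        assert ratio == pytest.approx(1.0, rel=1e-9)

    @given(refl, refl)
    @settings(max_examples=50, deadline=None)
    def test_ndvi_bounded(self, ri, rj):
        assert -1.0 <= dual_band_value("NDVI", ri, rj) <= 1.0

    @given(
        st.floats(0.2, 1.0), st.floats(0.2, 1.0), st.floats(0.001, 0.19)
    )
    @settings(max_examples=50, deadline=None)
    def test_mndi_bounded_when_r455_below_bands(self, ri, rj, r455):
        v = dual_band_value("mNDI", ri, rj, r_455=r455)
        assert -1.0 - 1e-12 <= v <= 1.0 + 1e-12

    def test_singularities_are_nan(self):
        assert np.isnan(dual_band_value("RI", 0.5, 0.0))
        assert np.isnan(dual_band_value("mSR", 0.5, 0.1, r_455=0.1))
        assert np.isnan(dual_band_value("mNDI", 0.3, 0.1, r_455=0.2))
        assert np.isnan(dual_band_value("VI6", 0.0, 0.5))

    def test_unknown_formula(self):
        with pytest.raises(KeyError):
            dual_band_value("XYZ", 0.5, 0.5)


@pytest.fixture(scope="module")
def pairs():
    return {fid: (700, 800) for fid in DUAL_BAND_NAMES}


class TestParameterMatrix:
    def test_shape_48_by_30(self, smoothed, pairs):
        pm = parameter_matrix(smoothed, pairs)
        assert pm.values.shape == (48, 30)
        assert pm.columns_of("empirical") == EMPIRICAL_NAMES
        assert pm.columns_of("trilateral") == TRILATERAL_NAMES
        assert pm.columns_of("dualband") == DUAL_BAND_NAMES

    def test_deterministic(self, smoothed, pairs):
        a = parameter_matrix(smoothed, pairs)
        b = parameter_matrix(smoothed, pairs)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_permuting_samples_permutes_rows(self, smoothed, pairs):
        perm = list(reversed(smoothed.sample_ids))
        reordered = smoothed.select_samples(perm)
        a = parameter_matrix(smoothed, pairs)
        b = parameter_matrix(reordered, pairs)
        pd.testing.assert_frame_equal(a.values.loc[perm], b.values)

    def test_missing_pair_rejected(self, smoothed):
        with pytest.raises(ValueError, match="missing wavelength pairs"):
            parameter_matrix(smoothed, {"VI6": (700, 800)})

    def test_csv_roundtrip(self, smoothed, pairs, tmp_path):
        pm = parameter_matrix(smoothed, pairs)
        path = tmp_path / "params.csv"
        pm.to_csv(path)
        back = type(pm).read_csv(path)
        pd.testing.assert_frame_equal(pm.values, back.values, atol=1e-12)
        assert back.class_tags == pm.class_tags

    def test_undefined_sentinel_propagates(self, pairs):
        spectra = random_spectra(10, seed=1)
        spectra.reflectance[0, 700 - 350] = 0.0  # kills RI/VI6 at i=700
        pm = parameter_matrix(spectra, pairs)
        counts = pm.undefined_counts()
        assert counts["VI6"] == 1
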