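"""Spectral I/O, smoothing, probe extraction and normalization."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ureafold.spectra import (
    DenaturationSeries,
    Spectrum,
    build_denaturation_series,
    cd_ratio_222_208,
    extract_signal,
    flag_high_urea,
    lambda_max,
    molar_ellipticity,
    moving_average,
    normalize_kinetics,
    normalize_series,
    rayleigh_scatter,
    read_spectrum_table,
    read_series_csv,
    write_series_csv,
)
from ureafold.synth import exponential_trace


def make_spectrum(values, start=300.0, probe="fluorescence", urea=0.0):
    values = np.asarray(values, dtype=float)
    wl = start + np.arange(values.size)
    return Spectrum(wl, values, probe=probe, urea=urea)


class TestReadSpectrumTable:
    def test_reads_two_column_table_with_header(self, tmp_path):
        wl = np.arange(300, 451)
        vals = np.exp(-0.5 * ((wl - 335) / 18.0) ** 2)
        path = tmp_path / "em.csv"
        path.write_text(
            "# fluorescence emission\nwavelength_nm,counts\n"
            + "\n".join(f"{w},{v}" for w, v in zip(wl, vals))
        )
        s = read_spectrum_table(path, probe="fluorescence", urea=1.5)
        assert len(s.wavelengths) == 151
        assert s.urea == 1.5
        np.testing.assert_allclose(s.values, vals)

    def test_out_of_order_rows_sorted(self, tmp_path):
        path = tmp_path / "shuffled.csv"
        rows = [(302, 3.0), (300, 1.0), (301, 2.0)]
        path.write_text("\n".join(f"{w},{v}" for w, v in rows))
        s = read_spectrum_table(path, probe="cd", urea=0)
        np.testing.assert_array_equal(s.wavelengths, [300, 301, 302])
        np.testing.assert_array_equal(s.values, [1.0, 2.0, 3.0])

    def test_duplicate_wavelength_is_parse_error_naming_line(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("334,1.0\n335,2.0\n335,2.1\n336,3.0")
        with pytest.raises(ValueError, match="335.*line 3|line 3.*335"):
            read_spectrum_table(path, probe="fluorescence", urea=0)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_spectrum_table(tmp_path / "nope.csv", probe="cd", urea=0)

    def test_corrupt_row_mid_table(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("300,1.0\n301,oops\n302,2.0")
        with pytest.raises(ValueError, match="line 2"):
            read_spectrum_table(path, probe="cd", urea=0)


class TestMovingAverage:
    def test_constant_spectrum_invariant(self):
        s = make_spectrum(np.full(51, 7.0))
        np.testing.assert_array_equal(moving_average(s, 5.0).values, 7.0)

    def test_unit_spike_spreads_over_window(self):
        vals = np.zeros(41)
        vals[20] = 11.0
        sm = moving_average(make_spectrum(vals), 5.0)
        expected = np.zeros(41)
        expected[15:26] = 1.0  # 11 points within +/-5 nm share the mass
        np.testing.assert_allclose(sm.values, expected)

    def test_truncated_window_at_edge(self):
        vals = np.arange(20.0)
        sm = moving_average(make_spectrum(vals), 5.0)
        assert sm.values[0] == pytest.approx(np.mean(vals[:6]))
        assert sm.values[-1] == pytest.approx(np.mean(vals[-6:]))

    def test_nonuniform_grid_rejected(self):
        s = Spectrum(np.array([300.0, 301.0, 303.0]), np.zeros(3), "cd", 0.0)
        with pytest.raises(ValueError, match="uniform"):
            moving_average(s, 5.0)

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=15, max_size=60))
    def test_smoothing_preserves_total_mean_on_interior(self, values):
        """Interior windows are full boxcars, so the mean over any stretch that
        excludes the edges is preserved for periodic-like content; here we
        assert the weaker, always-true property that smoothing never escapes
        the data range."""
        s = make_spectrum(values)
        sm = moving_average(s, 5.0)
        assert sm.values.min() >= np.min(values) - 1e-9
        assert sm.values.max() <= np.max(values) + 1e-9


class TestExtraction:
    def test_extract_at_grid_point(self):
        vals = np.zeros(151)
        vals[35] = 42.0
        s = make_spectrum(vals)
        assert extract_signal(s, 335.0) == 42.0

    def test_nearest_point_rule(self):
        vals = np.zeros(151)
        vals[35] = 42.0
        assert extract_signal(make_spectrum(vals), 335.4) == 42.0

    def test_out_of_range(self):
        with pytest.raises(ValueError, match="outside"):
            extract_signal(make_spectrum(np.zeros(151)), 299.0)

    def test_lambda_max_of_gaussian(self):
        wl = np.arange(300.0, 451.0)
        s = Spectrum(wl, np.exp(-0.5 * ((wl - 335) / 10) ** 2), "fluorescence", 0.0)
        assert lambda_max(s) == 335.0

    def test_lambda_max_tie_breaks_low(self):
        vals = np.zeros(151)
        vals[40:45] = 5.0  # plateau 340-344
        assert lambda_max(make_spectrum(vals)) == 340.0

    def test_lambda_max_monotone_spectrum_is_first_point(self):
        assert lambda_max(make_spectrum(np.arange(151, 0, -1.0))) == 300.0

    def test_row_order_invariance(self, tmp_path):
        wl = np.arange(300, 451)
        vals = np.exp(-0.5 * ((wl - 340) / 9.0) ** 2)
        rows = list(zip(wl, vals))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        p1.write_text("\n".join(f"{w},{v}" for w, v in rows))
        rng = np.random.default_rng(0)
        p2.write_text("\n".join(f"{rows[i][0]},{rows[i][1]}" for i in rng.permutation(len(rows))))
        s1 = read_spectrum_table(p1, "fluorescence", 0)
        s2 = read_spectrum_table(p2, "fluorescence", 0)
        assert lambda_max(s1) == lambda_max(s2)
        assert extract_signal(s1, 335) == extract_signal(s2, 335)


class TestRayleighScatter:
    def test_constant_window(self):
        s = make_spectrum(np.full(31, 100.0), start=290.0, probe="scattering")
        assert rayleigh_scatter(s) == 100.0

    def test_identity_values_average_to_center(self):
        wl = np.arange(290.0, 321.0)
        s = Spectrum(wl, wl.copy(), "scattering", 0.0)
        assert rayleigh_scatter(s) == 300.0

    def test_odd_perturbation_averages_to_center_value(self):
        # deviations antisymmetric about 300 nm cancel over the window
        wl = np.arange(290.0, 311.0)
        s = Spectrum(wl, 1000.0 + (wl - 300.0) ** 3, "scattering", 0.0)
        assert rayleigh_scatter(s) == pytest.approx(1000.0)

    def test_window_not_covered(self):
        s = make_spectrum(np.zeros(30), start=301.0, probe="scattering")
        with pytest.raises(ValueError, match="window"):
            rayleigh_scatter(s)


class TestCdRatio:
    def make_cd(self, v208, v222):
        wl = np.arange(190.0, 251.0)
        vals = np.zeros(wl.size)
        vals[wl == 208.0] = v208
        vals[wl == 222.0] = v222
        return Spectrum(wl, vals, "cd", 0.0)

    def test_equal_signals_give_unity(self):
        assert cd_ratio_222_208(self.make_cd(-10.0, -10.0)) == pytest.approx(1.0)

    def test_coiled_coil_ratio_above_one(self):
        assert cd_ratio_222_208(self.make_cd(-10.0, -11.0)) == pytest.approx(1.1)

    def test_zero_208_flagged_unusable(self):
        with pytest.raises(ZeroDivisionError, match="unusable"):
            cd_ratio_222_208(self.make_cd(0.0, -11.0))

    def test_high_urea_flagging(self):
        series = build_denaturation_series(
            [(u, [1.1 - 0.1 * u]) for u in np.arange(0, 7.5, 0.5)], "ratio222_208"
        )
        flagged = flag_high_urea(series)
        assert flagged.flagged[flagged.urea > 4.5].all()
        assert not flagged.flagged[flagged.urea <= 4.5].any()


class TestDenaturationSeries:
    def test_replicate_mean_and_sd(self):
        s = build_denaturation_series([(0.0, [1.0, 2.0, 3.0])], "I335")
        assert s.mean[0] == 2.0
        assert s.sd[0] == pytest.approx(1.0)  # sample SD
        assert s.n_rep[0] == 3

    def test_single_replicate_records_zero_sd(self):
        s = build_denaturation_series([(1.0, [5.0])], "I335")
        assert s.sd[0] == 0.0
        assert s.n_rep[0] == 1

    def test_output_sorted_by_urea(self):
        s = build_denaturation_series([(3.0, [1.0]), (0.5, [2.0]), (1.0, [3.0])], "x")
        np.testing.assert_array_equal(s.urea, [0.5, 1.0, 3.0])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_denaturation_series([], "x")

    def test_csv_round_trip(self, tmp_path):
        s = build_denaturation_series(
            [(u, [1.0 + u, 1.2 + u]) for u in (0.0, 1.0, 2.0)], "I335"
        )
        path = tmp_path / "series.csv"
        write_series_csv(s, path)
        back = read_series_csv(path)
        np.testing.assert_allclose(back.urea, s.urea)
        np.testing.assert_allclose(back.mean, s.mean)
        np.testing.assert_allclose(back.sd, s.sd)


class TestNormalization:
    def series(self, means):
        return build_denaturation_series(
            [(u, [m]) for u, m in zip(np.arange(0, 7.5, 0.5), means)], "I335"
        )

    def test_linear_map(self):
        means = np.full(15, 10.0)
        means[-2:] = 2.0
        means[7] = 6.0
        n = normalize_series(self.series(means))
        assert n.mean[7] == pytest.approx(0.5)
        assert n.mean[0] == pytest.approx(1.0)

    def test_equal_plateaus_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            normalize_series(self.series(np.full(15, 3.0)))

    def test_out_of_band_values_flagged_not_dropped(self):
        means = np.full(15, 10.0)
        means[-2:] = 2.0
        means[1] = 10.8  # above the native plateau
        n = normalize_series(self.series(means))
        assert n.mean[1] > 1
        assert n.flagged[1]
        assert len(n) == 15

    @settings(derandomize=True, max_examples=25)
    @given(
        st.lists(st.floats(-100, 100), min_size=15, max_size=15).filter(
            lambda v: abs(np.mean(v[:2]) - np.mean(v[-2:])) > 1e-3
        )
    )
    def test_inverse_affine_map_recovers_input(self, means):
        s = self.series(np.asarray(means))
        n = normalize_series(s, native_range=(0, 0.5), unfolded_range=(6.5, 7))
        native = s.mean[:2].mean()
        unfolded = s.mean[-2:].mean()
        back = n.mean * (native - unfolded) + unfolded
        np.testing.assert_allclose(back, s.mean, atol=1e-9 * max(1, np.abs(s.mean).max()))


class TestKinetics:
    def test_affine_map(self):
        trace = exponential_trace(4.0)
        n = normalize_kinetics(trace)
        i0 = np.argmin(np.abs(trace.time - 0.006))
        i1 = np.argmin(np.abs(trace.time - 100.0))
        assert n.values[i0] == pytest.approx(1.0)
        assert n.values[i1] == pytest.approx(0.0)
        mid = (trace.values[i0] + trace.values[i1]) / 2
        k = np.argmin(np.abs(trace.values - mid))
        assert n.values[k] == pytest.approx(0.5, abs=0.02)

    def test_idempotent_on_normalized_trace(self):
        n1 = normalize_kinetics(exponential_trace(4.0))
        n2 = normalize_kinetics(n1)
        np.testing.assert_allclose(n2.values, n1.values, atol=1e-12)

    def test_equal_anchor_values_rejected(self):
        trace = exponential_trace(4.0, amplitude=0.0)
        with pytest.raises(ValueError, match="anchor"):
            normalize_kinetics(trace)


def test_molar_ellipticity_scaling():
    # doubling pathlength halves the mean-residue ellipticity
    a = molar_ellipticity(100.0, 3.2e-6, 0.1, 260)
    b = molar_ellipticity(100.0, 3.2e-6, 0.2, 260)
    assert a == pytest.approx(2 * b)
    with pytest.raises(ValueError):
        molar_ellipticity(100.0, 0.0, 0.1, 260)
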