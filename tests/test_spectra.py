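"""Spectrum simulation: multiplet construction, Lorentzian areas,
inversion-recovery series, determinism and file round trips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qnmrquant import (
    AcquisitionParams,
    InvalidParameterError,
    IntegrationRegion,
    ParseError,
    Spectrum,
    integrate_regions,
    multiplet_pattern,
    read_spectrum,
    simulate_inversion_recovery,
    simulate_spectrum,
    write_spectrum,
)


class TestMultipletPattern:
    def test_singlet_identity(self):
        assert multiplet_pattern(6.16, [], 400.132) == [(6.16, 1.0)]
        assert multiplet_pattern(9.77, [], 400.132) == [(9.77, 1.0)]

    def test_equal_couplings_merge_to_triplet(self):
        lines = multiplet_pattern(6.16, [4.0, 4.0], 400.132)
        assert len(lines) == 3
        assert [round(i, 12) for _, i in lines] == [0.25, 0.5, 0.25]
        # outer lines sit one full J from each other side of the centre
        assert lines[1][0] == pytest.approx(6.16)
        assert lines[2][0] - lines[0][0] == pytest.approx(2 * 4.0 / 400.132)

    def test_doublet_of_doublets_positions(self):
        j1, j2 = 5.7, 1.5
        lines = multiplet_pattern(7.50, [j1, j2], 400.132)
        assert len(lines) == 4
        spread = (j1 + j2) / 400.132
        assert lines[-1][0] - lines[0][0] == pytest.approx(spread)

    @given(
        couplings=st.lists(st.floats(0.0, 20.0), max_size=4),
        center=st.floats(-2.0, 12.0),
    )
    @settings(deadline=None, derandomize=True)
    def test_intensities_always_sum_to_one(self, couplings, center):
        lines = multiplet_pattern(center, couplings, 400.132)
        assert sum(i for _, i in lines) == pytest.approx(1.0)

    def test_rejects_nonpositive_frequency(self):
        with pytest.raises(InvalidParameterError):
            multiplet_pattern(6.16, [5.7], 0.0)


class TestSimulateSpectrum:
    def test_empty_mixture_is_flat_zero(self):
        spec = simulate_spectrum([], AcquisitionParams(n_points=256), noise_sd=0.0)
        assert np.all(spec.intensities == 0.0)

    def test_lorentzian_area_conservation(self, singlet_analyte, fine_params):
        # 114.10 mg of the probe is 1 mmol -> unit analytic total area
        spec = simulate_spectrum([(singlet_analyte, 114.10)], fine_params)
        gamma = 1.0 / fine_params.spectrometer_frequency
        w = 80 * gamma
        region = IntegrationRegion("s", 6.16 - w, 6.16 + w)
        area = integrate_regions(spec, [region]).raw["s"]
        assert area == pytest.approx(1.0, rel=5e-3)
        # and it matches the analytic truncated-Lorentzian area much tighter
        truncated = (2 / math.pi) * math.atan(w / (gamma / 2))
        assert area == pytest.approx(truncated, rel=5e-4)

    def test_mole_ratio_of_areas(self, fx, fine_params):
        spec = simulate_spectrum(
            [(fx.furanone, 25.22), (fx.vanillin, 11.84)], fine_params
        )
        table = integrate_regions(
            spec,
            [IntegrationRegion("H2", 5.9, 6.4), IntegrationRegion("CHO", 9.5, 10.0)],
        )
        expected = (25.22 * 0.98 / 114.10) / (11.84 * 0.99 / 152.15)
        assert table.raw["H2"] / table.raw["CHO"] == pytest.approx(expected, rel=1e-2)

    def test_seed_determinism_and_variation(self, singlet_analyte):
        params = AcquisitionParams(n_points=2048)
        a = simulate_spectrum([(singlet_analyte, 5.0)], params, noise_sd=0.1, seed=7)
        b = simulate_spectrum([(singlet_analyte, 5.0)], params, noise_sd=0.1, seed=7)
        c = simulate_spectrum([(singlet_analyte, 5.0)], params, noise_sd=0.1, seed=8)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_out_of_window_signal_warns(self, singlet_analyte):
        params = AcquisitionParams(n_points=256, spectral_width=400.0, center_ppm=0.0)
        with pytest.warns(UserWarning, match="outside spectral window"):
            simulate_spectrum([(singlet_analyte, 5.0)], params)

    def test_saturation_factor_scales_areas(self, fx, fine_params):
        sat = simulate_spectrum(
            [(fx.furanone, 25.0), (fx.vanillin, 12.0)], fine_params, saturation=True
        )
        free = simulate_spectrum(
            [(fx.furanone, 25.0), (fx.vanillin, 12.0)], fine_params, saturation=False
        )
        regions = [IntegrationRegion("H2", 5.9, 6.4), IntegrationRegion("CHO", 9.5, 10.0)]
        rs, rf = integrate_regions(sat, regions), integrate_regions(free, regions)
        from qnmrquant import SteadyStateQuery, steady_state_mz

        tr, alpha = fine_params.total_recycle_time, fine_params.flip_angle
        factor = steady_state_mz(SteadyStateQuery(0.5, tr, alpha)) / steady_state_mz(
            SteadyStateQuery(0.9, tr, alpha)
        )
        ratio_sat = rs.raw["H2"] / rs.raw["CHO"]
        ratio_free = rf.raw["H2"] / rf.raw["CHO"]
        assert ratio_sat / ratio_free == pytest.approx(factor, rel=1e-2)


class TestInversionRecovery:
    def test_zero_crossing_at_t1_ln2(self):
        series = simulate_inversion_recovery(1, -2, 0.5, [0.3466, 1, 2, 3])
        assert series.intensities[0] == pytest.approx(0.0, abs=1e-4)

    def test_full_recovery_at_long_tau(self):
        series = simulate_inversion_recovery(1, -2, 0.5, [0.1, 0.2, 0.3, 50.0])
        assert series.intensities[-1] == pytest.approx(1.0)

    def test_rejects_nonpositive_t1(self):
        with pytest.raises(InvalidParameterError):
            simulate_inversion_recovery(1, -2, 0.0, [0.1, 0.2, 0.3, 0.4])

    def test_needs_four_points(self):
        with pytest.raises(InvalidParameterError):
            simulate_inversion_recovery(1, -2, 0.5, [0.1, 0.2, 0.3])


class TestSpectrumIO:
    def test_csv_round_trip_bitwise(self, tmp_path, singlet_analyte):
        spec = simulate_spectrum(
            [(singlet_analyte, 3.0)], AcquisitionParams(n_points=512),
            noise_sd=0.05, seed=3,
        )
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_spectrum(spec, p1)
        again = read_spectrum(p1)
        write_spectrum(again, p2)
        assert p1.read_bytes() == p2.read_bytes()
        np.testing.assert_array_equal(spec.ppm_axis, again.ppm_axis)

    def test_ascending_axis_normalized_with_flag(self, tmp_path):
        p = tmp_path / "asc.csv"
        p.write_text("ppm,intensity\n1.0,0.1\n2.0,0.2\n3.0,0.3\n")
        spec = read_spectrum(p)
        assert spec.original_ascending
        assert spec.ppm_axis[0] > spec.ppm_axis[-1]  # stored high->low
        assert spec.intensities[0] == 0.3

    def test_jcamp_round_trip(self, tmp_path, singlet_analyte):
        spec = simulate_spectrum(
            [(singlet_analyte, 3.0)], AcquisitionParams(n_points=512),
            noise_sd=0.05, seed=3,
        )
        p = tmp_path / "a.jdx"
        write_spectrum(spec, p, format="jcamp_subset")
        again = read_spectrum(p, format="jcamp_subset")
        np.testing.assert_allclose(again.ppm_axis, spec.ppm_axis, rtol=1e-9)
        np.testing.assert_allclose(again.intensities, spec.intensities, rtol=1e-9)

    def test_jcamp_unsupported_data_class_errors(self, tmp_path):
        p = tmp_path / "bad.jdx"
        p.write_text(
            "##TITLE=x\n##FIRSTX=10\n##LASTX=0\n##NPOINTS=2\n"
            "##XYDATA=(XY..XY)\n10 1\n0 2\n##END=\n"
        )
        with pytest.raises(ParseError, match="unsupported XYDATA class"):
            read_spectrum(p, format="jcamp_subset")

    def test_malformed_csv_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("ppm,intensity\n1.0,0.1\noops\n")
        with pytest.raises(ParseError, match=":3"):
            read_spectrum(p)

    def test_non_uniform_axis_rejected(self, tmp_path):
        p = tmp_path / "warp.csv"
        p.write_text("ppm,intensity\n3.0,0\n2.0,0\n0.5,0\n")
        with pytest.raises(InvalidParameterError, match="uniform"):
            read_spectrum(p)


class TestSpectrumType:
    def test_rejects_non_monotonic_axis(self):
        with pytest.raises(InvalidParameterError):
            Spectrum(np.array([1.0, 3.0, 2.0]), np.zeros(3))

    def test_rejects_length_mismatch(self):
        with pytest.raises(InvalidParameterError):
            Spectrum(np.array([1.0, 2.0, 3.0]), np.zeros(2))
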