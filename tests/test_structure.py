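"""CD, synchronous-fluorescence, EEM and voltammetry metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quenchlab import (
    Spectrum,
    ValidationError,
    cd_analysis,
    dpv_series_metrics,
    eem_peak_table,
    find_peak,
    helix_fraction,
    mre_from_ellipticity,
    shift_and_quench_table,
)
from quenchlab.simulate import simulate_cd, simulate_eem, simulate_voltammogram


class TestCD:
    def test_mre_zero_and_scaling(self):
        assert mre_from_ellipticity(0.0, 0.2, 0.1) == 0.0
        one = mre_from_ellipticity(-10.0, 0.2, 0.1)
        assert mre_from_ellipticity(-10.0, 0.4, 0.1) == pytest.approx(one / 2)

    def test_mre_conversion_hand_arithmetic(self):
        # -36.56 mdeg at 0.1995 mg/mL (3 uM of a 66.5 kDa protein), 0.1 cm
        mre = mre_from_ellipticity(-36.56, 0.1995, 0.1, 110.0)
        assert mre == pytest.approx(-20159.0, abs=5.0)

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValidationError):
            mre_from_ellipticity(-10.0, 0.0, 0.1)

    @pytest.mark.parametrize(
        "mre_208,expected",
        [(-33000.0, 100.0), (-4000.0, 0.0), (-22183.0, 62.7), (-7422.0, 11.8)],
    )
    def test_helix_fraction_values(self, mre_208, expected):
        clamped, raw = helix_fraction(mre_208)
        assert clamped == pytest.approx(expected, abs=0.05)

    def test_helix_fraction_clamps_but_keeps_raw(self):
        clamped, raw = helix_fraction(-40000.0)
        assert clamped == 100.0 and raw > 100.0
        clamped, raw = helix_fraction(-1000.0)
        assert clamped == 0.0 and raw < 0.0

    @given(st.floats(-40000, 0), st.floats(1e-6, 5000))
    @settings(deadline=None)
    def test_helix_fraction_strictly_decreasing_in_mre(self, mre, d):
        _, raw_lo = helix_fraction(mre)
        _, raw_hi = helix_fraction(mre + d)
        assert raw_lo > raw_hi

    @pytest.mark.parametrize("fraction", [0.0, 0.118, 0.627, 1.0])
    def test_cd_simulation_round_trip(self, fraction):
        spec = simulate_cd(fraction, conc=0.1995, path_length=0.1)
        rec = cd_analysis(spec, 0.1995, 0.1, 110.0)
        assert rec.helix_pct == pytest.approx(100.0 * fraction, abs=1e-9)


class TestFindPeak:
    def test_gaussian_voltammetric_peak_located(self):
        vg = simulate_voltammogram(E_p=0.95, I_p=8.0, width=0.05, step=0.002)
        pk = find_peak(vg, refine=True)
        assert pk.position == pytest.approx(0.95, abs=0.002)

    def test_constant_signal_ties_break_to_first_point(self):
        spec = Spectrum([1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0])
        pk = find_peak(spec)
        assert pk.position == 1.0

    def test_parabolic_refinement_symmetric_vertex(self):
        spec = Spectrum([1.0, 2.0, 3.0], [1.0, 4.0, 1.0])
        pk = find_peak(spec, refine=True)
        assert pk.position == pytest.approx(2.0, abs=1e-12)
        assert pk.method == "parabolic"

    def test_empty_window_rejected(self):
        spec = Spectrum([1.0, 2.0, 3.0], [1.0, 4.0, 1.0])
        with pytest.raises(ValidationError):
            find_peak(spec, window=(10.0, 20.0))


class TestShiftTable:
    @staticmethod
    def _band(center, height, grid=None):
        grid = np.arange(250.0, 360.0, 0.5) if grid is None else grid
        return Spectrum(grid, height * np.exp(-0.5 * ((grid - center) / 10.0) ** 2))

    def test_engineered_blue_shift_and_quench(self):
        # final band: 4 nm blue shift, height down to 12.75% of initial
        series = [self._band(285.0, 100.0), self._band(281.0, 12.75)]
        table = shift_and_quench_table(series)
        assert table[-1]["shift"] == pytest.approx(-4.0, abs=0.5)
        assert table[-1]["percent_change"] == pytest.approx(-87.25, abs=0.01)

    def test_identical_spectra_no_shift_no_change(self):
        series = [self._band(285.0, 100.0)] * 3
        for row in shift_and_quench_table(series):
            assert row["shift"] == 0.0
            assert row["percent_change"] == 0.0

    def test_doubled_height_positive_change(self):
        series = [self._band(285.0, 50.0), self._band(285.0, 100.0)]
        table = shift_and_quench_table(series)
        assert table[-1]["percent_change"] == pytest.approx(100.0)
        assert table[-1]["shift"] == 0.0

    def test_single_spectrum_rejected(self):
        with pytest.raises(ValidationError):
            shift_and_quench_table([self._band(285.0, 100.0)])


class TestEEM:
    def test_fixture_peaks_recovered_with_rayleigh_masked(self):
        eem = simulate_eem(
            [(280.0, 350.0, 248.0, 12.0, 18.0), (230.0, 343.0, 198.0, 10.0, 16.0)],
            rayleigh=True,
        )
        peaks = eem_peak_table(eem, rayleigh_halfwidth=15.0)
        assert len(peaks) >= 2
        top = peaks[0]
        assert (top.excitation, top.emission) == (280.0, 350.0)
        assert top.intensity == pytest.approx(248.0, rel=0.01)
        second = peaks[1]
        assert abs(second.excitation - 230.0) <= 5.0  # one excitation grid step
        assert abs(second.emission - 343.0) <= 1.0
        assert second.intensity == pytest.approx(198.0, rel=0.01)

    def test_zero_eem_has_no_peaks(self):
        eem = simulate_eem([], rayleigh=False)
        assert eem_peak_table(eem) == []

    def test_peak_on_first_order_ridge_is_masked(self):
        eem = simulate_eem([(300.0, 300.0, 500.0, 8.0, 8.0)], rayleigh=False)
        peaks = eem_peak_table(eem, rayleigh_halfwidth=15.0)
        assert all(abs(p.emission - p.excitation) > 15.0 for p in peaks)
        assert not any(p.intensity > 400.0 for p in peaks)

    def test_all_masked_rejected(self):
        eem = simulate_eem([], rayleigh=False)
        with pytest.raises(ValidationError):
            eem_peak_table(eem, rayleigh_halfwidth=1e6)


class TestDPV:
    def test_peak_potential_shift(self):
        series = [
            simulate_voltammogram(E_p=0.95, label="0"),
            simulate_voltammogram(E_p=1.08, label="12"),
        ]
        metrics = dpv_series_metrics(series)
        assert metrics["delta_E_p"] == pytest.approx(0.13, abs=0.004)

    def test_monotone_current_loss_flagged(self):
        series = [
            simulate_voltammogram(E_p=0.95, I_p=I, label=f"{i}")
            for i, I in enumerate([10.0, 7.0, 5.0, 3.0])
        ]
        metrics = dpv_series_metrics(series)
        assert metrics["I_p_strictly_decreasing"]
        assert metrics["delta_I_p"] < 0

    def test_single_voltammogram_rejected(self):
        with pytest.raises(ValidationError):
            dpv_series_metrics([simulate_voltammogram()])
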