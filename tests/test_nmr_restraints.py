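"""Observable -> restraint conversions: PRE, RDC, relaxation, hetNOE,
temperature coefficients, NOE class bounds."""

import math

import numpy as np
import pytest

from flexfold.nmr_restraints import (
    DistanceRestraint,
    PeakRecord,
    PREParams,
    RelaxationSeries,
    compute_hetnoe,
    fit_relaxation_rate,
    noes_to_restraints,
    pre_distance,
    pre_table_to_restraints,
    r2sp_from_distance,
    r2sp_from_ratio,
    ratio_from_r2sp,
    rdc_from_ipap,
    read_restraints,
    temperature_coefficient,
    write_restraints,
)

R2_GRID = np.array([16, 32, 64, 96, 128, 192, 320, 640]) * 1e-3


class TestRelaxationFit:
    @pytest.mark.parametrize("rate", [0.1, 2.0, 50.0])
    def test_noiseless_exact_recovery(self, rate):
        series = RelaxationSeries(1, R2_GRID, 100.0 * np.exp(-rate * R2_GRID))
        res = fit_relaxation_rate(series)
        assert res.converged
        assert res.rate == pytest.approx(rate, rel=1e-8)
        assert res.amplitude == pytest.approx(100.0, rel=1e-8)

    def test_constant_intensities_fail_flag(self):
        series = RelaxationSeries(1, R2_GRID, np.full(len(R2_GRID), 42.0))
        res = fit_relaxation_rate(series)
        assert not res.converged
        assert math.isnan(res.rate)

    def test_noisy_replicates_unbiased(self):
        """Simulation oracle: mean fitted rate within 2 standard errors of truth."""
        rng = np.random.default_rng(0)
        rates = []
        for _ in range(500):
            noisy = 100.0 * np.exp(-2.0 * R2_GRID) + rng.normal(scale=2.0,
                                                                size=len(R2_GRID))
            res = fit_relaxation_rate(RelaxationSeries(1, R2_GRID, noisy))
            if res.converged:
                rates.append(res.rate)
        mean = np.mean(rates)
        sem = np.std(rates, ddof=1) / math.sqrt(len(rates))
        assert abs(mean - 2.0) < 2 * sem + 1e-3


class TestHetNoe:
    def test_equal_intensities(self):
        r = compute_hetnoe(PeakRecord(1, "saturated", 70.0),
                           PeakRecord(1, "unsaturated", 70.0))
        assert r.noe == pytest.approx(1.0)

    def test_negative_noe_fast_motion_sign(self):
        r = compute_hetnoe(PeakRecord(1, "saturated", -30.0),
                           PeakRecord(1, "unsaturated", 100.0))
        assert r.noe == pytest.approx(-0.3)

    def test_error_propagation(self):
        r = compute_hetnoe(PeakRecord(1, "saturated", 50.0, noise_sigma=5.0),
                           PeakRecord(1, "unsaturated", 100.0, noise_sigma=5.0))
        assert r.noe == pytest.approx(0.5)
        assert r.sigma == pytest.approx(0.5 * math.sqrt(0.01 + 0.0025), abs=1e-4)

    def test_zero_unsaturated_rejected(self):
        with pytest.raises(ValueError):
            compute_hetnoe(PeakRecord(1, "saturated", 1.0),
                           PeakRecord(1, "unsaturated", 0.0))


class TestTemperatureCoefficient:
    def _series(self, slope_ppb_per_k, t_celsius=(25, 30, 35, 40, 45)):
        return [
            (273.15 + t,
             PeakRecord(7, f"temperature:{273.15 + t}", 100.0,
                        shift_h=8.0 + slope_ppb_per_k * (t - 25) * 1e-3))
            for t in t_celsius
        ]

    def test_linear_slope_recovered_and_flagged(self):
        # 8.000 ppm at 25 °C to 7.940 ppm at 45 °C: -3 ppb/K
        res = temperature_coefficient(self._series(-3.0))
        assert res.coefficient == pytest.approx(-3.0, abs=1e-9)
        assert res.hbond_flag

    def test_steep_slope_not_flagged(self):
        res = temperature_coefficient(self._series(-6.0))
        assert res.coefficient == pytest.approx(-6.0, abs=1e-9)
        assert not res.hbond_flag

    def test_temperature_independent_flags_true(self):
        res = temperature_coefficient(self._series(0.0))
        assert res.coefficient == pytest.approx(0.0, abs=1e-12)
        assert res.hbond_flag

    @pytest.mark.parametrize("slope,expected", [(-4.4, True), (-4.6, False),
                                                (4.4, True), (4.6, False)])
    def test_flag_depends_only_on_magnitude(self, slope, expected):
        assert temperature_coefficient(self._series(slope)).hbond_flag is expected

    def test_insufficient_span_rejected(self):
        with pytest.raises(ValueError):
            temperature_coefficient(self._series(-3.0, t_celsius=(25, 28, 31)))


class TestPreInversion:
    def test_ratio_one_gives_zero(self):
        assert r2sp_from_ratio(1.0, 20.0, 0.01) == 0.0

    def test_forward_inverse_round_trip(self):
        # R2dia = 50 s^-1 (linewidth 50/pi), t = 10 ms, true R2sp = 50
        lw = 50.0 / math.pi
        ratio = ratio_from_r2sp(50.0, lw, 0.01)
        assert ratio == pytest.approx(0.3033, abs=2e-4)
        assert r2sp_from_ratio(ratio, lw, 0.01) == pytest.approx(50.0, abs=1e-6)

    def test_monotone_decreasing_in_ratio(self):
        vals = [r2sp_from_ratio(r, 20.0, 0.01) for r in np.linspace(0.05, 0.99, 25)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_unphysical_inputs_rejected(self):
        with pytest.raises(ValueError):
            r2sp_from_ratio(1.2, 20.0, 0.01)
        with pytest.raises(ValueError):
            r2sp_from_ratio(0.0, 20.0, 0.01)


class TestPreDistance:
    params = PREParams()

    @pytest.mark.parametrize("r", np.linspace(8.0, 35.0, 10))
    def test_distance_rate_round_trip(self, r):
        assert pre_distance(r2sp_from_distance(r, self.params),
                            self.params) == pytest.approx(r, abs=1e-9)

    def test_doubling_rate_scales_by_sixth_root(self):
        r1 = pre_distance(40.0, self.params)
        r2 = pre_distance(80.0, self.params)
        assert r2 / r1 == pytest.approx(2 ** (-1 / 6), rel=1e-12)

    def test_vanishing_correlation_time_limit(self):
        # r -> 0 as tau_c -> 0 for fixed rate (monotone in the sixth root)
        r_tiny = pre_distance(50.0, PREParams(tau_c=1e-15))
        r_small = pre_distance(50.0, PREParams(tau_c=1e-12))
        r_default = pre_distance(50.0, PREParams())
        assert r_tiny < r_small < r_default
        assert r_tiny < 2.0

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            pre_distance(0.0, self.params)


class TestPreTable:
    params = PREParams()

    def _pair(self, residue, ratio):
        return (PeakRecord(residue, "paramagnetic", ratio * 100.0, linewidth=20.0),
                PeakRecord(residue, "diamagnetic", 100.0, linewidth=20.0))

    def test_high_ratio_gives_lower_bound_only(self):
        (r,) = pre_table_to_restraints([self._pair(5, 0.95)], (1, "LABEL", 0),
                                       self.params)
        assert r.lower == self.params.r_max_bound
        assert not np.isfinite(r.upper)

    def test_vanished_peak_gives_upper_bound_only(self):
        (r,) = pre_table_to_restraints([self._pair(5, 0.02)], (1, "LABEL", 0),
                                       self.params)
        assert r.upper == self.params.r_min_bound
        assert r.lower == 0.0

    def test_known_distances_recovered_in_range(self):
        """Forward-model round trip for 20 residues at 12-28 Å."""
        truth = np.linspace(12.5, 28.0, 20)
        table = []
        for i, d in enumerate(truth):
            rate = r2sp_from_distance(d, self.params)
            table.append(self._pair(i + 1, ratio_from_r2sp(rate, 20.0,
                                                           self.params.t_evol)))
        restraints = pre_table_to_restraints(table, (50, "LABEL", 0), self.params)
        for r, d in zip(restraints, truth):
            if r.two_sided:
                assert abs(r.d0 - d) < 1.0

    def test_unmatched_pair_skipped(self):
        table = [(PeakRecord(1, "paramagnetic", 50.0, linewidth=20.0),
                  PeakRecord(2, "diamagnetic", 100.0, linewidth=20.0))]
        assert pre_table_to_restraints(table, (9, "LABEL", 0), self.params) == []


class TestRdc:
    def _quartet(self, residue, split_para_hz, split_dia_hz, field=700.0):
        n_freq = field * 0.10136767
        mk = lambda cond, hz: PeakRecord(residue, cond, 100.0,
                                         shift_n=120.0 + hz / n_freq)
        return (mk("inphase", split_para_hz / 2), mk("antiphase", -split_para_hz / 2),
                mk("inphase", split_dia_hz / 2), mk("antiphase", -split_dia_hz / 2))

    def test_difference_definition(self):
        rec = rdc_from_ipap(*self._quartet(3, 95.0, 93.0))
        assert rec.d_hz == pytest.approx(2.0, abs=1e-9)

    def test_identical_spectra_give_zero(self):
        rec = rdc_from_ipap(*self._quartet(3, 93.0, 93.0))
        assert rec.d_hz == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_residues_rejected(self):
        q = list(self._quartet(3, 95.0, 93.0))
        q[1] = PeakRecord(4, "antiphase", 100.0, shift_n=119.0)
        with pytest.raises(ValueError):
            rdc_from_ipap(*q)


class TestNoeRestraints:
    def test_class_bounds(self):
        rs = noes_to_restraints([(10, 14, "strong"), (2, 9, "medium"),
                                 (1, 30, "weak")])
        assert [r.upper for r in rs] == [3.5, 4.5, 6.0]
        assert all(r.lower == 1.8 and r.potential == "flat-bottom" for r in rs)

    def test_empty_input(self):
        assert noes_to_restraints([]) == []

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            noes_to_restraints([(1, 2, "huge")])


def test_restraint_tsv_round_trip(tmp_path):
    rs = [
        DistanceRestraint((1, "LABEL", 0), (7, "H", 0), 15.0, 11.0, 19.0,
                          "PRE", 1.0, "sigmoid"),
        DistanceRestraint((3, "LABEL", 0), (3, "LABEL", 1), 23.5, 17.5, 29.5,
                          "DEER", 0.25, "harmonic"),
    ]
    path = tmp_path / "r.tsv"
    write_restraints(rs, path)
    back = read_restraints(path)
    assert back == rs


def test_peak_table_tsv_round_trip(tmp_path):
    from flexfold.nmr_restraints import peaks_to_frame, read_peak_table

    records = [
        PeakRecord(3, "paramagnetic", 55.0, linewidth=20.0, noise_sigma=1.5),
        PeakRecord(3, "diamagnetic", 100.0, linewidth=20.0, noise_sigma=1.5),
        PeakRecord(4, "temperature:298.15", 80.0, shift_h=8.21),
    ]
    path = tmp_path / "peaks.tsv"
    peaks_to_frame(records).to_csv(path, sep="\t", index=False)
    back = read_peak_table(path)
    assert back == records


def test_restraint_bound_invariant():
    with pytest.raises(ValueError):
        DistanceRestraint((1, "CA", 0), (2, "CA", 0), 5.0, 6.0, 7.0, "NOE")
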