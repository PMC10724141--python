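"""Labelling, cross-correlation, enrichment functions, cycle durations."""

import numpy as np
import pytest

import celledge as ce
from celledge.containers import SignalMap, VelocityMap
from celledge.errors import (
    DegenerateControlError,
    DimensionError,
    EmptyRegionWarning,
    ParameterError,
)
from celledge.morpho import NEITHER, PROTRUSION, RETRACTION


def vmap(values, dt=40.0):
    return VelocityMap(np.asarray(values, dtype=float), 0.26, dt)


def smap(values, wcm=None, dt=40.0):
    values = np.asarray(values, dtype=float)
    return SignalMap(values, band_depth=3.0,
                     whole_cell_mean=values.mean() if wcm is None else wcm,
                     frame_interval=dt)


class TestLabelling:
    def test_zero_map_is_all_neither(self):
        labels = ce.label_protrusion_retraction(vmap(np.zeros((4, 5))))
        assert np.all(labels.labels == NEITHER)

    def test_hand_labelled_toy_matrix(self):
        labels = ce.label_protrusion_retraction(
            vmap([[0.1, -0.1], [0.05, 0.2]])
        )
        expected = np.array([[PROTRUSION, RETRACTION], [NEITHER, PROTRUSION]])
        np.testing.assert_array_equal(labels.labels, expected)

    def test_threshold_value_itself_is_neither(self):
        labels = ce.label_protrusion_retraction(vmap([[0.075, -0.075]]))
        assert np.all(labels.labels == NEITHER)

    def test_misordered_thresholds_rejected(self):
        with pytest.raises(ParameterError, match="v_retraction"):
            ce.label_protrusion_retraction(vmap([[0.0]]), v_protrusion=-0.1,
                                           v_retraction=0.1)


def brute_force_pearson(signal, velocity, lag):
    """Explicit double-loop Pearson r at one lag; independent of the library."""
    xs, ys = [], []
    n_p, n_t = velocity.shape
    n_s = signal.shape[1]
    for p in range(n_p):
        for t in range(n_t):
            ts = t + lag
            if 0 <= ts < n_s:
                xs.append(signal[p, ts])
                ys.append(velocity[p, t])
    xs, ys = np.array(xs), np.array(ys)
    return np.mean((xs - xs.mean()) * (ys - ys.mean())) / (xs.std() * ys.std())


class TestCrossCorrelation:
    def test_identical_maps_have_unit_correlation_at_zero_lag(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(6, 12))
        cc = ce.crosscorrelate_maps(smap(np.column_stack([v, v[:, -1]])),
                                    vmap(v), max_lag=0)
        # at lag 0 the overlapping columns are numerically equal
        assert cc.r[0] == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(6, 12))
        cc = ce.crosscorrelate_maps(smap(-np.column_stack([v, v[:, -1]])),
                                    vmap(v), max_lag=0)
        assert cc.r[0] == pytest.approx(-1.0)

    def test_toy_lag_recovered_and_matches_brute_force(self):
        sig, vel = ce.generate_toy_maps(8, 40, 4, gain=0.6, noise_sd=0.02,
                                        seed=2)
        cc = ce.crosscorrelate_maps(sig, vel, max_lag=9)
        assert cc.extremum_lag == 4
        for i, lag in enumerate(cc.lags):
            ref = brute_force_pearson(sig.values, vel.values, int(lag))
            assert cc.r[i] == pytest.approx(ref, abs=1e-12)

    def test_zero_variance_reported_missing_with_warning(self):
        sig = smap(np.ones((4, 6)))
        vel = vmap(np.random.default_rng(3).normal(size=(4, 5)))
        with pytest.warns(EmptyRegionWarning):
            cc = ce.crosscorrelate_maps(sig, vel, max_lag=1)
        assert np.all(np.isnan(cc.r))
        with pytest.raises(ParameterError):
            cc.extremum_lag

    def test_position_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            ce.crosscorrelate_maps(smap(np.ones((3, 6))),
                                   vmap(np.zeros((4, 5))), 1)


def brute_force_enrichment(signal, wcm, labels, shift):
    """Explicit double loop over the labelled entries; independent oracle."""
    out = []
    for target in (PROTRUSION, RETRACTION):
        acc, n = 0.0, 0
        for p in range(labels.shape[0]):
            for t in range(labels.shape[1]):
                ts = t + shift
                if labels[p, t] == target and 0 <= ts < signal.shape[1]:
                    acc += signal[p, ts]
                    n += 1
        out.append((acc / n / wcm - 1.0) * 100.0 if n else np.nan)
    return tuple(out)


class TestEnrichment:
    def test_uniform_signal_has_zero_enrichment_everywhere(self):
        sig = smap(np.full((5, 8), 3.0))
        vel = vmap(np.random.default_rng(4).normal(0, 1, size=(5, 7)))
        ef = ce.enrichment_function(sig, vel, range(-3, 4))
        np.testing.assert_allclose(ef.protrusion_enrichment, 0.0, atol=1e-12)
        np.testing.assert_allclose(ef.retraction_enrichment, 0.0, atol=1e-12)

    def test_doubled_signal_in_protrusions_is_plus_hundred_percent(self):
        vel = vmap([[1.0, -1.0], [1.0, -1.0]])
        sig_vals = np.array([[2.0, 0.5, 9.9], [2.0, 0.5, 9.9]])
        labels = ce.label_protrusion_retraction(vel)
        prot, retr = ce.enrichment_at_shift(smap(sig_vals, wcm=1.0), labels, 0)
        assert prot == pytest.approx(100.0)
        assert retr == pytest.approx(-50.0)

    def test_shift_beyond_map_is_an_error(self):
        vel = vmap(np.ones((2, 3)))
        labels = ce.label_protrusion_retraction(vel)
        with pytest.raises(ParameterError, match="shift"):
            ce.enrichment_at_shift(smap(np.ones((2, 4))), labels, 10)

    def test_empty_class_gives_nan_with_warning(self):
        vel = vmap(np.full((2, 3), 1.0))  # protrusion only
        labels = ce.label_protrusion_retraction(vel)
        with pytest.warns(EmptyRegionWarning, match="retraction"):
            prot, retr = ce.enrichment_at_shift(
                smap(np.ones((2, 4))), labels, 0
            )
        assert np.isnan(retr) and not np.isnan(prot)

    @pytest.mark.parametrize("shift", [-3, -1, 0, 2, 5])
    def test_matches_brute_force_oracle_on_small_random_maps(self, shift):
        rng = np.random.default_rng(10 + shift)
        sig = smap(rng.uniform(0.5, 2.0, size=(7, 10)))
        vel = vmap(rng.normal(0, 0.5, size=(7, 9)))
        labels = ce.label_protrusion_retraction(vel)
        got = ce.enrichment_at_shift(sig, labels, shift)
        ref = brute_force_enrichment(sig.values, sig.whole_cell_mean,
                                     labels.labels, shift)
        np.testing.assert_allclose(got, ref, atol=1e-12)

    def test_negating_velocity_swaps_protrusion_and_retraction(self):
        rng = np.random.default_rng(11)
        sig = smap(rng.uniform(0.5, 2.0, size=(6, 8)))
        v = rng.normal(0, 0.5, size=(6, 7))
        p1, r1 = ce.enrichment_at_shift(
            sig, ce.label_protrusion_retraction(vmap(v)), 0
        )
        p2, r2 = ce.enrichment_at_shift(
            sig, ce.label_protrusion_retraction(vmap(-v)), 0
        )
        assert p1 == r2 and r1 == p2

    def test_toy_lag_appears_as_enrichment_peak(self):
        sig, vel = ce.generate_toy_maps(10, 60, 4, gain=0.5, noise_sd=0.0,
                                        seed=7)
        ef = ce.enrichment_function(sig, vel, range(-10, 11))
        assert ef.peak_shift == 4
        sig0, vel0 = ce.generate_toy_maps(10, 60, 0, gain=0.5, noise_sd=0.0,
                                          seed=8)
        assert ce.enrichment_function(sig0, vel0, range(-10, 11)).peak_shift == 0


class TestControlNormalization:
    def grid(self, prot, retr):
        n = len(prot)
        return ce.EnrichmentFunction(
            shifts=np.arange(n) - n // 2,
            protrusion_enrichment=np.asarray(prot, dtype=float),
            retraction_enrichment=np.asarray(retr, dtype=float),
            frame_interval=40.0,
        )

    def test_zero_control_is_identity(self):
        sensor = self.grid([10.0, 20.0, 5.0], [-5.0, -1.0, 0.0])
        control = self.grid([0.0, 0.0, 0.0], [0.0, 0.0, 0.0])
        out = ce.normalize_enrichment_to_control(sensor, control)
        np.testing.assert_allclose(out.protrusion_enrichment,
                                   sensor.protrusion_enrichment)
        assert out.normalized

    def test_ratio_of_ratios_arithmetic(self):
        sensor = self.grid([50.0], [50.0])
        control = self.grid([25.0], [25.0])
        out = ce.normalize_enrichment_to_control(sensor, control)
        assert out.protrusion_enrichment[0] == pytest.approx(20.0)

    def test_sensor_equal_control_gives_zero(self):
        f = self.grid([12.0, -3.0], [4.0, 8.0])
        out = ce.normalize_enrichment_to_control(f, f)
        np.testing.assert_allclose(out.protrusion_enrichment, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.retraction_enrichment, 0.0, atol=1e-12)

    def test_degenerate_control_rejected(self):
        sensor = self.grid([10.0], [0.0])
        control = self.grid([-100.0], [0.0])
        with pytest.raises(DegenerateControlError):
            ce.normalize_enrichment_to_control(sensor, control)


class TestCycleDurations:
    def test_hand_traced_row(self):
        v = vmap([[0.1, 0.1, 0.0, -0.1, 0.1, -0.1]])
        cycles = ce.cycle_durations(v, n_positions=100)
        # every rescaled row repeats the single input row
        assert set(np.unique(cycles.durations)) == {40.0, 120.0}
        assert cycles.mean == pytest.approx(80.0)

    def test_all_protrusion_yields_no_cycles(self):
        cycles = ce.cycle_durations(vmap(np.full((3, 6), 1.0)))
        assert len(cycles.durations) == 0
        assert np.isnan(cycles.mean)

    def test_sinusoid_mean_duration_is_half_period(self):
        # analytic oracle: for v = A sin(2 pi t / T) with |A| >> threshold,
        # the first crossing below -thr follows the first crossing above
        # +thr by exactly T/2, independent of the threshold
        T, dt, A = 600.0, 40.0, 1.0
        rng = np.random.default_rng(12)
        phases = rng.uniform(0, 2 * np.pi, 100)
        t = (np.arange(150) + 0.5) * dt
        v = vmap(A * np.sin(2 * np.pi * t[None, :] / T + phases[:, None]), dt)
        cycles = ce.cycle_durations(v)
        assert abs(cycles.mean - T / 2) <= dt
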