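"""Differential affinity: derivatives, monotone segments, the affinity
formula, and its invariances."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

import dynconn as dc
from dynconn.affinity import bundle_matrix
from dynconn.simulate import TraceSet


def make_traces(x, dt=0.25):
    """Wrap (n_neurons, T) rows as a single-animal TraceSet."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return TraceSet(
        activity=x[None, :, :],
        neuron_ids=[f"n{i:03d}" for i in range(x.shape[0])],
        observed=np.ones((1, x.shape[0]), dtype=bool),
        dt=dt,
    )


class TestSmoothDerivative:
    def test_constant_trace_zero_derivative(self):
        d = dc.smooth_derivative(make_traces(np.full((1, 50), 3.7)), sigma=1.0)
        np.testing.assert_array_equal(d.d, 0.0)

    def test_linear_ramp_exact_slope(self):
        dt = 0.25
        c = -1.7
        t = np.arange(100) * dt
        d = dc.smooth_derivative(make_traces(c * t, dt=dt), sigma=0.0)
        np.testing.assert_allclose(d.d[0, 0, 1:-1], c, rtol=1e-9)

    def test_matches_bruteforce_convolution_oracle(self):
        """Smoothing + central differences equals a naive double-loop
        discrete Gaussian convolution followed by differencing."""
        dt = 0.5
        sigma = 2 * dt
        T = 61
        x = np.sin(np.arange(T) * dt)
        d = dc.smooth_derivative(make_traces(x, dt=dt), sigma=sigma)

        # oracle: reflect-pad, truncated Gaussian kernel as scipy builds it,
        # then the same central differences
        s = sigma / dt
        radius = int(4.0 * s + 0.5)
        k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / s) ** 2)
        k /= k.sum()
        xp = np.concatenate([x[radius - 1 :: -1], x, x[: -radius - 1 : -1]])
        sm = np.array(
            [np.sum(k * xp[i : i + 2 * radius + 1]) for i in range(T)]
        )
        grad = np.gradient(sm, dt)
        np.testing.assert_allclose(d.d[0, 0], grad, atol=1e-10)

    def test_too_few_timepoints(self):
        with pytest.raises(ValueError, match="3 time points"):
            dc.smooth_derivative(make_traces(np.zeros((1, 2))))


class TestMonotoneSegments:
    def test_single_rising_ramp_one_plus_segment(self):
        t = np.arange(80) * 0.25
        d = dc.smooth_derivative(make_traces(2 * t), sigma=0.0)
        segs = dc.monotone_segments(d, zero_band=1e-9)
        ivals = segs.intervals(0, 0)
        assert len(ivals) == 1
        t0, t1, sign = ivals[0]
        assert sign == 1 and t0 == 0 and t1 == 80

    def test_triangle_wave_alternating_segments(self):
        """Run boundaries sit at the apex samples (+/- one sample)."""
        period = 40
        T = 200
        x = np.abs((np.arange(T) % period) - period / 2)
        d = dc.smooth_derivative(make_traces(x), sigma=0.0)
        segs = dc.monotone_segments(d, zero_band=1e-9, min_duration=0.0)
        ivals = segs.intervals(0, 0)
        # oracle: run-length encoding of the sign of the raw gradient
        sign = np.sign(np.gradient(x))
        expected = []
        start = 0
        for t in range(1, T + 1):
            if t == T or sign[t] != sign[start]:
                if sign[start] != 0:
                    expected.append((start, t, int(sign[start])))
                start = t
        assert len(ivals) == len(expected)
        for (a0, a1, s1), (b0, b1, s2) in zip(ivals, expected):
            assert s1 == s2 and abs(a0 - b0) <= 1 and abs(a1 - b1) <= 1

    def test_zero_band_suppresses_flat_noise(self):
        rng = np.random.default_rng(0)
        x = 1e-6 * rng.standard_normal(100)
        d = dc.smooth_derivative(make_traces(x), sigma=0.0)
        segs = dc.monotone_segments(d, zero_band=1.0)
        assert segs.intervals(0, 0) == []

    def test_min_duration_drops_short_runs(self):
        x = np.r_[np.arange(20.0), 19.5, np.arange(19.0, -1.0, -1.0)]
        d = dc.smooth_derivative(make_traces(x), sigma=0.0)
        long = dc.monotone_segments(d, zero_band=1e-9, min_duration=0.0)
        short = dc.monotone_segments(d, zero_band=1e-9, min_duration=10 * 0.25)
        assert len(long.intervals(0, 0)) >= len(short.intervals(0, 0))
        assert all(t1 - t0 >= 10 for t0, t1, _ in short.intervals(0, 0))


class TestDifferentialAffinity:
    def affinity_of(self, rows, kappa, dt=0.25, sigma=0.0, zero_band=1e-9):
        traces = make_traces(rows, dt=dt)
        d = dc.smooth_derivative(traces, sigma=sigma)
        segs = dc.monotone_segments(d, zero_band=zero_band)
        return dc.differential_affinity(d, segs, kappa=kappa)

    def test_identical_traces_saturate_gate(self):
        t = np.arange(100) * 0.25
        x = np.sin(0.3 * t) * 5
        a = self.affinity_of([x, x], kappa=1e-6)
        vals = a.a[0, 0]
        assert vals.max() <= 1.0
        assert (vals[vals > 0] > 1 - 1e-6).all()

    def test_constant_partner_zero_affinity(self):
        t = np.arange(100) * 0.25
        a = self.affinity_of([np.sin(t), np.full(100, 2.0)], kappa=1e-6)
        np.testing.assert_array_equal(a.a[0, 0], 0.0)

    def test_ramp_slope_ratio(self):
        """Slopes 1 and 2 with a tiny kappa give affinity 1/2."""
        t = np.arange(200) * 0.25
        a = self.affinity_of([t, 2 * t], kappa=1e-9)
        interior = a.a[0, 0, 5:-5]
        np.testing.assert_allclose(interior, 0.5, atol=1e-9)

    def test_sign_flip_invariance_exact(self):
        rng = np.random.default_rng(5)
        x = np.cumsum(rng.standard_normal(150))
        y = np.cumsum(rng.standard_normal(150))
        a1 = self.affinity_of([x, y], kappa=0.5, sigma=1.0)
        a2 = self.affinity_of([x, -y], kappa=0.5, sigma=1.0)
        np.testing.assert_array_equal(a1.a, a2.a)

    def test_bounded_and_consistent_with_direct_formula(self):
        rng = np.random.default_rng(1)
        x = np.cumsum(rng.standard_normal(120))
        y = np.cumsum(rng.standard_normal(120))
        kappa = 0.7
        traces = make_traces([x, y])
        d = dc.smooth_derivative(traces, sigma=0.5)
        segs = dc.monotone_segments(d, zero_band=1e-3)
        a = dc.differential_affinity(d, segs, kappa=kappa)
        assert (a.a >= 0).all() and (a.a <= 1).all()
        # straight-from-formula oracle at every frame
        di, dj = np.abs(d.d[0, 0]), np.abs(d.d[0, 1])
        hi = np.maximum(di, dj)
        lo = np.minimum(di, dj)
        both = (segs.sign[0, 0] != 0) & (segs.sign[0, 1] != 0)
        expect = np.where(both & (hi > 0), lo / np.where(hi > 0, hi, 1) * -np.expm1(-hi / kappa), 0)
        np.testing.assert_allclose(a.a[0, 0], expect, atol=1e-12)

    def test_scale_covariance(self):
        """Scaling both traces and kappa by the same constant leaves the
        affinity unchanged (given an equally scaled zero band)."""
        rng = np.random.default_rng(9)
        x = np.cumsum(rng.standard_normal(100))
        y = np.cumsum(rng.standard_normal(100))
        c = 37.0
        a1 = self.affinity_of([x, y], kappa=0.2, zero_band=1e-4)
        a2 = self.affinity_of([c * x, c * y], kappa=0.2 * c, zero_band=1e-4 * c)
        np.testing.assert_allclose(a1.a, a2.a, atol=1e-12)


class TestBundleMatrix:
    def test_symmetric_zero_diagonal(self, two_circuit_spec):
        traces, _ = dc.simulate_traces(two_circuit_spec)
        series = dc.DifferentialAffinity().fit_transform(traces)
        A = bundle_matrix(series, t=100, animal=0)
        np.testing.assert_array_equal(A, A.T)
        np.testing.assert_array_equal(np.diag(A), 0.0)
        assert A.shape == (12, 12)

    def test_unobserved_rows_are_nan(self, single_circuit_spec):
        traces, _ = dc.simulate_traces(single_circuit_spec)
        traces.observed[0, 4] = False
        series = dc.DifferentialAffinity().fit_transform(traces)
        A = bundle_matrix(series, t=100, animal=0)
        assert np.isnan(A[4, :3]).all() and np.isnan(A[:3, 4]).all()
        assert A[4, 4] == 0.0

    def test_round_trip_with_vectorization(self, single_circuit_spec):
        traces, _ = dc.simulate_traces(single_circuit_spec)
        series = dc.DifferentialAffinity().fit_transform(traces)
        A = bundle_matrix(series, t=120, animal=1)
        v = dc.vectorize_matrix(A, series.pair_map)
        np.testing.assert_allclose(v, series.a[1, :, 120], atol=0)
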