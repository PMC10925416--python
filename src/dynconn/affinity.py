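"""Local differential affinity between neural activity traces.

Global similarity measures (correlation, cosine) are misleading for
calcium traces: two mostly-silent neurons look similar everywhere, and
two neurons that reach the same level minutes apart are unlikely to be
interacting.  The signal that matters is *coincident monotonic change*:
two neurons whose activity rises or falls together are plausibly coupled
(directly, or through common input), even when one is inhibited and the
derivatives have opposite sign.

The affinity used here is therefore local in time and built from
absolute smoothed derivatives.  For a pair (i, j) at frame t:

    a_ij(t) = 0                              unless t lies inside a
                                             monotone segment of BOTH traces
    a_ij(t) = min(|d_i|, |d_j|) / max(|d_i|, |d_j|)
              * (1 - exp(-max(|d_i|, |d_j|) / kappa))    otherwise

The min/max ratio compares derivative magnitudes (1 when the traces
change at the same absolute rate, regardless of sign); the gate
1 - exp(-max|d|/kappa) suppresses coincidences between near-flat traces
where the ratio would be dominated by noise.  Values are in [0, 1] and
zero whenever either neuron is unobserved.

A monotone segment is a maximal run of frames over which the smoothed
derivative keeps one sign; derivatives below ``zero_band`` in magnitude
count as sign 0, and runs shorter than ``min_duration`` are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import TraceSet
from .tensor import PairMap, pair_index


@dataclass
class DerivativeField:
    """Smoothed time derivatives, shape (n_animals, n_neurons, n_timepoints)."""

    d: np.ndarray
    smoothing_sigma: float  # seconds
    dt: float
    observed: np.ndarray  # (n_animals, n_neurons)


@dataclass
class MonotoneSegments:
    """Per-frame derivative sign in {-1, 0, +1} after zero-banding and
    minimum-duration filtering; ``sign == 0`` marks frames outside any
    monotone segment."""

    sign: np.ndarray  # (n_animals, n_neurons, n_timepoints) int8
    zero_band: float
    min_duration: float  # seconds
    dt: float

    def intervals(self, animal: int, neuron: int) -> list:
        """Maximal half-open constant-sign intervals [(t0, t1, sign), ...]."""
        s = self.sign[animal, neuron]
        out = []
        start = 0
        for t in range(1, len(s) + 1):
            if t == len(s) or s[t] != s[start]:
                if s[start] != 0:
                    out.append((start, t, int(s[start])))
                start = t
        return out


@dataclass
class AffinitySeries:
    """Pairwise affinities, shape (n_animals, n_pairs, n_timepoints), in [0,1].

    ``pair_observed[w, p]`` is False when either neuron of pair ``p`` is
    unobserved in animal ``w``; affinities there are missing, not zero.
    """

    a: np.ndarray
    pair_map: PairMap
    pair_observed: np.ndarray
    neuron_ids: list
    dt: float
    params: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.pair_map.n


def smooth_derivative(traces: TraceSet, sigma: float | None = None) -> DerivativeField:
    """Gaussian-smooth each trace, then take central differences.

    ``sigma`` is in seconds (default: 4 sampling intervals); ``sigma=0``
    skips smoothing.  Boundaries are handled by reflection.  The operator
    is linear, and derivatives are per second.
    """
    if traces.n_timepoints < 3:
        raise ValueError("need at least 3 time points to differentiate")
    if sigma is None:
        sigma = 4.0 * traces.dt
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    x = traces.activity
    # a kernel much narrower than one sample is numerically the identity
    if sigma / traces.dt > 1e-3:
        x = gaussian_filter1d(x, sigma=sigma / traces.dt, axis=-1, mode="reflect")
    d = np.gradient(x, traces.dt, axis=-1)
    d[~traces.observed] = 0.0
    return DerivativeField(d=d, smoothing_sigma=sigma, dt=traces.dt, observed=traces.observed)


def monotone_segments(
    d: DerivativeField,
    zero_band: float | None = None,
    min_duration: float | None = None,
) -> MonotoneSegments:
    """Maximal constant-sign runs of the derivative.

    ``zero_band`` (default: the 5th percentile of |d| per animal over its
    observed neurons) sets the magnitude below which the sign counts as 0;
    ``min_duration`` (seconds, default 3 samples) drops runs too short to
    be a credible monotone excursion.
    """
    W, N, T = d.d.shape
    absd = np.abs(d.d)
    if zero_band is None:
        zb = np.zeros(W)
        for w in range(W):
            vals = absd[w, d.observed[w]]
            zb[w] = np.percentile(vals, 5) if vals.size else 0.0
        zero_band_arr = zb[:, None, None]
        zero_band_val = float(zb.mean())
    else:
        if zero_band < 0:
            raise ValueError("zero_band must be non-negative")
        zero_band_arr = np.full((W, 1, 1), zero_band)
        zero_band_val = float(zero_band)
    if min_duration is None:
        min_duration = 3 * d.dt
    min_len = max(1, int(np.ceil(min_duration / d.dt)))

    sign = np.sign(d.d).astype(np.int8)
    sign[absd < zero_band_arr] = 0
    sign[~d.observed] = 0

    # drop runs shorter than min_len (run-length over the time axis)
    flat = sign.reshape(-1, T)
    for row in flat:
        start = 0
        for t in range(1, T + 1):
            if t == T or row[t] != row[start]:
                if row[start] != 0 and (t - start) < min_len:
                    row[start:t] = 0
                start = t
    return MonotoneSegments(
        sign=flat.reshape(W, N, T),
        zero_band=zero_band_val,
        min_duration=min_duration,
        dt=d.dt,
    )


def differential_affinity(
    d: DerivativeField,
    segs: MonotoneSegments,
    kappa: float | None = None,
    neuron_ids: list | None = None,
) -> AffinitySeries:
    """Evaluate the differential affinity for every pair, animal, frame.

    ``kappa`` (default: median |d| over observed data) sets the derivative
    magnitude at which the gate reaches 1 - 1/e.  The output is bounded in
    [0, 1], symmetric in (i, j), and invariant to flipping the sign of
    either trace.
    """
    W, N, T = d.d.shape
    absd = np.abs(d.d)
    if kappa is None:
        vals = absd[d.observed]
        kappa = float(np.median(vals)) if vals.size else 1.0
        if kappa <= 0:
            kappa = 1.0
    if kappa <= 0:
        raise ValueError("kappa must be positive")

    pm = pair_index(N)
    i_idx, j_idx = pm.i_idx, pm.j_idx
    di = absd[:, i_idx, :]
    dj = absd[:, j_idx, :]
    lo = np.minimum(di, dj)
    hi = np.maximum(di, dj)
    active = (segs.sign[:, i_idx, :] != 0) & (segs.sign[:, j_idx, :] != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(hi > 0, lo / np.where(hi > 0, hi, 1.0), 0.0)
    gate = -np.expm1(-hi / kappa)
    a = np.where(active & (hi > 0), ratio * gate, 0.0)

    pair_observed = d.observed[:, i_idx] & d.observed[:, j_idx]
    a[~pair_observed] = 0.0
    if neuron_ids is None:
        neuron_ids = [f"n{i:03d}" for i in range(N)]
    return AffinitySeries(
        a=a,
        pair_map=pm,
        pair_observed=pair_observed,
        neuron_ids=list(neuron_ids),
        dt=d.dt,
        params={
            "kappa": kappa,
            "zero_band": segs.zero_band,
            "min_duration": segs.min_duration,
            "smoothing_sigma": d.smoothing_sigma,
        },
    )


def bundle_matrix(a: AffinitySeries, t: int, animal: int = 0) -> np.ndarray:
    """The symmetric affinity matrix A^(t) for one animal at frame ``t``.

    Zero diagonal; rows/columns of unobserved neurons are NaN (missing,
    not zero).
    """
    n = a.n_neurons
    if not (0 <= t < a.a.shape[2]):
        raise IndexError(f"time index {t} out of range")
    A = np.zeros((n, n))
    A[a.pair_map.i_idx, a.pair_map.j_idx] = a.a[animal, :, t]
    A = A + A.T
    obs_neuron = np.zeros(n, dtype=bool)
    # a neuron is observed iff any of its pairs is observed (n >= 2 always)
    obs_neuron[a.pair_map.i_idx[a.pair_observed[animal]]] = True
    obs_neuron[a.pair_map.j_idx[a.pair_observed[animal]]] = True
    A[~obs_neuron, :] = np.nan
    A[:, ~obs_neuron] = np.nan
    np.fill_diagonal(A, 0.0)
    return A


class DifferentialAffinity(BaseEstimator, TransformerMixin):
    """Transformer: TraceSet -> AffinitySeries.

    Data-dependent defaults (``zero_band_``, ``kappa_``) are resolved in
    :meth:`fit`; :meth:`transform` then evaluates the affinity with those
    resolved values, so a single parameterization can be applied to
    held-out traces.

    Parameters
    ----------
    sigma : float or None
        Derivative smoothing scale in seconds (None: 4 sampling intervals).
    zero_band : float or None
        Derivative magnitude treated as sign 0 (None: per-animal 5th
        percentile of |d|).
    min_duration : float or None
        Minimum monotone-segment duration in seconds (None: 3 samples).
    kappa : float or None
        Magnitude-gate scale (None: median |d| over observed data).
    """

    def __init__(self, sigma=None, zero_band=None, min_duration=None, kappa=None):
        self.sigma = sigma
        self.zero_band = zero_band
        self.min_duration = min_duration
        self.kappa = kappa

    def fit(self, traces: TraceSet, y=None):
        d = smooth_derivative(traces, self.sigma)
        absd = np.abs(d.d)
        if self.kappa is None:
            vals = absd[d.observed]
            self.kappa_ = float(np.median(vals)) if vals.size else 1.0
            if self.kappa_ <= 0:
                self.kappa_ = 1.0
        else:
            self.kappa_ = float(self.kappa)
        segs = monotone_segments(d, self.zero_band, self.min_duration)
        self.zero_band_ = segs.zero_band
        self.min_duration_ = segs.min_duration
        self.sigma_ = d.smoothing_sigma
        return self

    def transform(self, traces: TraceSet) -> AffinitySeries:
        d = smooth_derivative(traces, self.sigma_ if hasattr(self, "sigma_") else self.sigma)
        segs = monotone_segments(d, getattr(self, "zero_band_", self.zero_band),
                                 getattr(self, "min_duration_", self.min_duration))
        return differential_affinity(
            d, segs, getattr(self, "kappa_", self.kappa), neuron_ids=traces.neuron_ids
        )
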