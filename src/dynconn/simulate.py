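"""Synthetic multi-animal trace sets with planted transient circuits.

Real recordings of this kind are brain-wide calcium traces from several
animals exposed to the same stimulus protocol: different groups of neurons
("circuits") become co-active during different stimulus windows, while the
rest of the time each neuron drifts idiosyncratically.  The generator
emulates exactly that structure so every downstream stage (affinity,
tensor factorization, community detection) can be tested against known
ground truth without any data download.

Each planted circuit has a member set, a half-open active time window, a
set of participating animals, an amplitude, and a per-member polarity
(+1/-1).  During the window all members of a circuit follow one shared
smooth latent drive -- a sum of calcium-like double-exponential bumps --
scaled by ``amplitude * polarity``, on top of a baseline that is frozen
for the duration of the window so that, noise-free, member traces are
exact affine copies of the drive (up to sign).  Outside windows neurons
follow independent low-amplitude drift plus observation noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d


@dataclass(frozen=True)
class PlantedCircuit:
    """A transient functional circuit planted in the simulation.

    Parameters
    ----------
    members : tuple of int
        Neuron indices belonging to the circuit (at least 2).
    window : (int, int)
        Half-open frame interval ``[t0, t1)`` during which the circuit is
        active.
    animals : tuple of int or None
        Animal indices in which the circuit is expressed; ``None`` means
        all animals.
    amplitude : float
        Peak scale of the shared latent drive.
    polarity : tuple of int or None
        Per-member sign in {+1, -1}; ``None`` assigns -1 to the last
        member and +1 to the rest, so anti-correlated members are always
        exercised.
    """

    members: tuple
    window: tuple
    animals: tuple | None = None
    amplitude: float = 1.0
    polarity: tuple | None = None

    def resolved_polarity(self) -> np.ndarray:
        if self.polarity is not None:
            pol = np.asarray(self.polarity, dtype=float)
            if pol.shape != (len(self.members),) or not np.all(np.abs(pol) == 1):
                raise ValueError("polarity must be one of {+1,-1} per member")
            return pol
        pol = np.ones(len(self.members))
        if len(self.members) >= 2:
            pol[-1] = -1.0
        return pol


@dataclass(frozen=True)
class SimSpec:
    n_neurons: int
    n_animals: int
    n_timepoints: int
    circuits: tuple = ()
    noise_sd: float = 0.05
    baseline_drift_sd: float = 0.02
    dt: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_neurons < 2:
            raise ValueError("need at least 2 neurons")
        if self.n_animals < 1:
            raise ValueError("need at least 1 animal")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 time points")
        if self.noise_sd < 0 or self.baseline_drift_sd < 0:
            raise ValueError("noise levels must be non-negative")
        for c in self.circuits:
            if len(c.members) < 2:
                raise ValueError("circuit needs at least 2 members")
            if not all(0 <= m < self.n_neurons for m in c.members):
                raise ValueError("circuit member index out of range")
            t0, t1 = c.window
            if not (0 <= t0 < t1 <= self.n_timepoints):
                raise ValueError(f"invalid circuit window {c.window}")
            if c.animals is not None and not all(
                0 <= w < self.n_animals for w in c.animals
            ):
                raise ValueError("circuit animal index out of range")
            c.resolved_polarity()


@dataclass
class TraceSet:
    """Per-animal neuron x time activity on a shared neuron namespace.

    ``activity`` has shape (n_animals, n_neurons, n_timepoints); the time
    axis is identical across animals (stimulus-locked recordings).
    ``observed[w, i]`` is False when neuron ``i`` was not recorded in
    animal ``w``; activity there is meaningless (set to 0).
    """

    activity: np.ndarray
    neuron_ids: list
    observed: np.ndarray
    dt: float = 0.25

    @property
    def n_animals(self) -> int:
        return self.activity.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.activity.shape[2]

    def validate(self) -> None:
        w, n, t = self.activity.shape
        if len(self.neuron_ids) != n or self.observed.shape != (w, n):
            raise ValueError("inconsistent TraceSet shapes")
        if not np.isfinite(self.activity[self.observed]).all():
            raise ValueError("non-finite activity at observed entries")


@dataclass
class GroundTruth:
    """What was planted: memberships, windows, animal sets, overlaps."""

    circuits: tuple
    n_neurons: int
    overlapping_pairs: list = field(default_factory=list)

    def membership_indicator(self, circuit_idx: int) -> np.ndarray:
        """Binary labels: 1 for members of circuit ``circuit_idx``, else 0."""
        lab = np.zeros(self.n_neurons, dtype=int)
        lab[list(self.circuits[circuit_idx].members)] = 1
        return lab

    def window_indicator(self, circuit_idx: int, n_timepoints: int) -> np.ndarray:
        t0, t1 = self.circuits[circuit_idx].window
        ind = np.zeros(n_timepoints)
        ind[t0:t1] = 1.0
        return ind

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_neurons": self.n_neurons,
                "overlapping_pairs": self.overlapping_pairs,
                "circuits": [
                    {
                        "members": list(c.members),
                        "window": list(c.window),
                        "animals": None if c.animals is None else list(c.animals),
                        "amplitude": c.amplitude,
                        "polarity": c.resolved_polarity().tolist(),
                    }
                    for c in self.circuits
                ],
            },
            indent=2,
        )


def latent_drive(
    window: tuple,
    n_timepoints: int,
    dt: float,
    rng: np.random.Generator,
    segment_dur: tuple = (3.5, 7.0),
    min_step: float = 0.3,
) -> np.ndarray:
    """Shared circuit drive: jittered ramp excursions filling a window.

    The drive is piecewise linear between random activity levels in
    [0, 1], rising from 0 at the window start and returning to 0 at the
    end.  Ramp durations are uniform in ``segment_dur`` seconds and
    consecutive levels differ by at least ``min_step``, so the slope
    magnitude stays bounded away from zero: the monotone rise/fall
    segments the affinity measure relies on tile (almost) the entire
    window, with only brief turning points between them.
    """
    t0, t1 = window
    span = (t1 - t0) * dt
    # vertex times across the window
    times = [0.0]
    while times[-1] < span:
        times.append(times[-1] + rng.uniform(*segment_dur))
    times[-1] = span
    if len(times) < 3:
        times = [0.0, span / 2, span]
    # levels: endpoints 0, interior alternating with a minimum excursion
    levels = [0.0]
    for _ in range(len(times) - 2):
        for _ in range(20):
            cand = rng.uniform(0.0, 1.0)
            if abs(cand - levels[-1]) >= min_step:
                break
        else:
            cand = 1.0 - levels[-1]
        levels.append(cand)
    levels.append(0.0)
    if abs(levels[-2]) < min_step:  # avoid a near-flat final ramp
        levels[-2] = min_step + (1.0 - min_step) * rng.random()

    drive = np.zeros(n_timepoints)
    tt = (np.arange(t0, t1) - t0) * dt
    drive[t0:t1] = np.interp(tt, times, levels)
    return drive


def simulate_traces(spec: SimSpec) -> tuple:
    """Generate a (TraceSet, GroundTruth) pair from a simulation spec.

    Noise-free (``noise_sd=0``), member traces inside a circuit window are
    exact affine copies of the circuit's latent drive up to polarity.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    W, N, T = spec.n_animals, spec.n_neurons, spec.n_timepoints

    # idiosyncratic slow baseline drift per (animal, neuron)
    if spec.baseline_drift_sd > 0:
        drift = rng.normal(0.0, spec.baseline_drift_sd, size=(W, N, T))
        drift = gaussian_filter1d(drift, sigma=8.0, axis=-1, mode="reflect")
        drift = np.cumsum(drift, axis=-1) * 0.1
    else:
        drift = np.zeros((W, N, T))
    activity = drift.copy()

    # plant circuits: freeze the baseline over the window, add shared drive
    overlaps = []
    claimed: dict = {}
    for k, c in enumerate(spec.circuits):
        t0, t1 = c.window
        animals = range(W) if c.animals is None else c.animals
        pol = c.resolved_polarity()
        for m in c.members:
            for t in range(t0, t1):
                prev = claimed.get((m, t))
                if prev is not None and prev != k:
                    pair = sorted((prev, k))
                    if pair not in overlaps:
                        overlaps.append(pair)
                claimed[(m, t)] = k
        # one drive realization per animal: worms respond to the same
        # stimulus window with similar but not identical dynamics; members
        # within an animal share the realization exactly
        for w in animals:
            drive = latent_drive(c.window, T, spec.dt, rng)
            for m, p in zip(c.members, pol):
                base = activity[w, m, t0]
                activity[w, m, t0:t1] = base + p * c.amplitude * drive[t0:t1]

    if spec.noise_sd > 0:
        activity = activity + rng.normal(0.0, spec.noise_sd, size=(W, N, T))

    traces = TraceSet(
        activity=activity,
        neuron_ids=[f"n{i:03d}" for i in range(N)],
        observed=np.ones((W, N), dtype=bool),
        dt=spec.dt,
    )
    truth = GroundTruth(
        circuits=tuple(spec.circuits), n_neurons=N, overlapping_pairs=overlaps
    )
    return traces, truth


# ---------------------------------------------------------------------------
# File I/O: one CSV per animal (rows = time, columns = neuron IDs, first
# column "time"), plus a JSON manifest.  Missing neurons are absent columns.
# ---------------------------------------------------------------------------

def write_traces(traces: TraceSet, outdir) -> Path:
    """Write a TraceSet as per-animal CSV tables plus a JSON manifest.

    Returns the manifest path.  Values are written with 17 significant
    digits so a round-trip is exact to double precision.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = np.arange(traces.n_timepoints) * traces.dt
    animals = []
    for w in range(traces.n_animals):
        present = np.flatnonzero(traces.observed[w])
        cols = {"time": t}
        for i in present:
            cols[traces.neuron_ids[i]] = traces.activity[w, i]
        fname = f"animal_{w:03d}.csv"
        pd.DataFrame(cols).to_csv(outdir / fname, index=False, float_format="%.17g")
        missing = [traces.neuron_ids[i] for i in np.flatnonzero(~traces.observed[w])]
        animals.append({"id": f"animal_{w:03d}", "file": fname, "missing": missing})
    manifest = {"dt": traces.dt, "neuron_ids": list(traces.neuron_ids), "animals": animals}
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def read_traces(manifest_path) -> TraceSet:
    """Read a TraceSet from a manifest written by :func:`write_traces`.

    Neuron columns may appear in any order per animal; they are
    canonicalized to the manifest's (or the sorted union's) neuron order.
    Neurons absent from an animal's table get ``observed=False``.
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    dt = float(manifest["dt"])

    tables = []
    for a in manifest["animals"]:
        df = pd.read_csv(base / a["file"])
        if "time" not in df.columns:
            raise ValueError(f"animal {a['id']}: table lacks a 'time' column")
        for col in df.columns:
            if not pd.api.types.is_numeric_dtype(df[col]):
                row = int(pd.to_numeric(df[col], errors="coerce").isna().idxmax())
                raise ValueError(
                    f"animal {a['id']}: non-numeric cell at row {row}, column {col!r}"
                )
        tables.append((a["id"], df))

    if "neuron_ids" in manifest:
        neuron_ids = list(manifest["neuron_ids"])
    else:
        union: set = set()
        for _, df in tables:
            union |= set(df.columns) - {"time"}
        neuron_ids = sorted(union)
    id_pos = {nid: i for i, nid in enumerate(neuron_ids)}

    n_time = {aid: len(df) for aid, df in tables}
    if len(set(n_time.values())) > 1:
        raise ValueError(f"animals disagree on time axis length: {n_time}")
    T = len(tables[0][1])
    W, N = len(tables), len(neuron_ids)
    activity = np.zeros((W, N, T))
    observed = np.zeros((W, N), dtype=bool)
    for w, (aid, df) in enumerate(tables):
        for col in df.columns:
            if col == "time":
                continue
            if col not in id_pos:
                raise ValueError(
                    f"animal {aid}: neuron {col!r} not in the shared namespace"
                )
            i = id_pos[col]
            activity[w, i] = df[col].to_numpy(dtype=float)
            observed[w, i] = True
    ts = TraceSet(activity=activity, neuron_ids=neuron_ids, observed=observed, dt=dt)
    ts.validate()
    return ts
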