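"""End-to-end orchestration: traces -> affinities -> tensor -> communities.

One resolved :class:`PipelineConfig` plus a master seed fully determines
every output file, so any artifact can be regenerated from the config
alone.  Stage seeds are derived from the master seed by stage name, so
results are stable under configuration changes elsewhere in the run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from ._util import derive_seed
from .affinity import DifferentialAffinity
from .benchmark import nmi
from .communities import (
    Partition,
    WeightedSBM,
    community_report,
    graph_from_matrix,
)
from .simulate import GroundTruth, SimSpec, PlantedCircuit, read_traces, simulate_traces
from .tensor import NonnegativeCP, build_tensor, factor_to_matrix

log = logging.getLogger("dynconn")


@dataclass
class PipelineConfig:
    """Fully-resolved parameters of one pipeline run (JSON-serializable)."""

    # input: either a manifest path or a simulation spec dict
    manifest: str | None = None
    simulate: dict | None = None
    # affinity stage
    sigma: float | None = None
    zero_band: float | None = None
    min_duration: float | None = None
    kappa: float | None = None
    # tensor stage
    rank: int = 2
    n_restarts: int = 10
    max_iter: int = 500
    tol: float = 1e-7
    # community stage
    w_min: float = 0.0
    burnin: int = 200
    sweeps: int = 800
    beta_max: float = 5.0
    # global
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


def _sim_spec_from_dict(d: dict, seed: int) -> SimSpec:
    circuits = tuple(
        PlantedCircuit(
            members=tuple(c["members"]),
            window=tuple(c["window"]),
            animals=None if c.get("animals") is None else tuple(c["animals"]),
            amplitude=float(c.get("amplitude", 1.0)),
            polarity=None if c.get("polarity") is None else tuple(c["polarity"]),
        )
        for c in d.get("circuits", [])
    )
    return SimSpec(
        n_neurons=d["n_neurons"],
        n_animals=d["n_animals"],
        n_timepoints=d["n_timepoints"],
        circuits=circuits,
        noise_sd=float(d.get("noise_sd", 0.05)),
        baseline_drift_sd=float(d.get("baseline_drift_sd", 0.02)),
        dt=float(d.get("dt", 0.25)),
        seed=d.get("seed", derive_seed(seed, "simulate")),
    )


@dataclass
class PipelineResult:
    traces: object
    affinities: object
    tensor: object
    cp: NonnegativeCP
    partitions: list
    reports: list
    ground_truth: GroundTruth | None = None
    outdir: Path | None = None


def _fmt_array(a: np.ndarray) -> list:
    return np.asarray(a).round(12).tolist()


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute all three stages; optionally write artifacts under ``outdir``.

    Artifacts: resolved config, factor tables (CSV), per-component
    partition JSON (labels + description length), community reports, and
    a MANIFEST recording per-stage status.  Deterministic given the seed.
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "version": __version__, "failed": None}

    def stage(name):
        t0 = time.perf_counter()

        def done():
            manifest["stages"].append(
                {"name": name, "seconds": round(time.perf_counter() - t0, 3)}
            )
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)

        return done

    try:
        done = stage("input")
        truth = None
        if config.simulate is not None:
            spec = _sim_spec_from_dict(config.simulate, config.seed)
            traces, truth = simulate_traces(spec)
        elif config.manifest is not None:
            traces = read_traces(config.manifest)
        else:
            raise ValueError("config needs either 'manifest' or 'simulate'")
        done()

        done = stage("affinity")
        aff = DifferentialAffinity(
            sigma=config.sigma,
            zero_band=config.zero_band,
            min_duration=config.min_duration,
            kappa=config.kappa,
        )
        series = aff.fit_transform(traces)
        tensor = build_tensor(series)
        done()

        done = stage("factorize")
        cp = NonnegativeCP(
            rank=config.rank,
            n_restarts=config.n_restarts,
            max_iter=config.max_iter,
            tol=config.tol,
            random_state=derive_seed(config.seed, "factorize"),
        ).fit(tensor)
        done()

        done = stage("communities")
        partitions, reports = [], []
        for r in range(cp.model_.rank):
            A = factor_to_matrix(cp.factors_[2][:, r], tensor.pair_map)
            graph = graph_from_matrix(A, config.w_min, node_ids=tensor.neuron_ids)
            sbm = WeightedSBM(
                w_min=config.w_min,
                burnin=config.burnin,
                sweeps=config.sweeps,
                beta_max=config.beta_max,
                random_state=derive_seed(config.seed, f"communities-{r}"),
            ).fit(graph)
            part = Partition(labels=sbm.labels_, dl=sbm.description_length_)
            partitions.append(part)
            reports.append(
                community_report(graph, part, model=cp.model_, component=r, traces=traces)
            )
        done()

        if outdir is not None:
            _write_artifacts(outdir, config, traces, cp, partitions, reports, truth, tensor)
        manifest_ok = True
    except Exception as exc:
        manifest["failed"] = f"{type(exc).__name__}: {exc}"
        if outdir is not None:
            (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        raise
    if outdir is not None:
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(
        traces=traces,
        affinities=series,
        tensor=tensor,
        cp=cp,
        partitions=partitions,
        reports=reports,
        ground_truth=truth,
        outdir=outdir,
    )


def _write_artifacts(outdir, config, traces, cp, partitions, reports, truth, tensor):
    import pandas as pd

    (outdir / "config.json").write_text(config.to_json())
    model = cp.model_
    names = [f"c{r}" for r in range(model.rank)]
    for fname, mat in [
        ("factor_temporal.csv", model.temporal),
        ("factor_animal.csv", model.animal),
        ("factor_affinity.csv", model.affinity),
    ]:
        pd.DataFrame(mat, columns=names).to_csv(outdir / fname, index=False,
                                                float_format="%.12g")
    (outdir / "cp_meta.json").write_text(
        json.dumps(
            {
                "rank": model.rank,
                "lambdas": _fmt_array(model.lambdas),
                "objective": round(model.objective, 12),
                "n_iter": model.n_iter,
                "seed": model.seed,
            },
            indent=2,
        )
    )
    for r, (part, rep) in enumerate(zip(partitions, reports)):
        (outdir / f"partition_c{r}.json").write_text(
            json.dumps(
                {
                    "labels": {
                        nid: int(lab)
                        for nid, lab in zip(traces.neuron_ids, part.labels)
                    },
                    "description_length": round(part.dl, 9),
                    "n_communities": part.n_communities,
                },
                indent=2,
                sort_keys=True,
            )
        )
        slim = {k: v for k, v in rep.items() if k != "component"}
        comp = rep.get("component")
        if comp is not None:
            slim["component"] = {k: v for k, v in comp.items() if k != "trace_snippets"}
        (outdir / f"report_c{r}.json").write_text(json.dumps(slim, indent=2, sort_keys=True))
    if truth is not None:
        (outdir / "ground_truth.json").write_text(truth.to_json())


def evaluate_recovery(result: PipelineResult) -> dict:
    """Score a simulated run against its ground truth.

    Components are matched to planted circuits by correlating each
    temporal factor with each circuit's window indicator (greedy best
    match).  Returns per-circuit temporal correlation and the NMI between
    the matched component's partition and the circuit's binary
    membership.
    """
    truth = result.ground_truth
    if truth is None:
        raise ValueError("pipeline was not run on simulated data")
    model = result.cp.model_
    T = result.traces.n_timepoints
    n_circ = len(truth.circuits)
    corr = np.zeros((model.rank, n_circ))
    for r in range(model.rank):
        f = model.temporal[:, r]
        for k in range(n_circ):
            ind = truth.window_indicator(k, T)
            denom = f.std() * ind.std()
            corr[r, k] = float(np.corrcoef(f, ind)[0, 1]) if denom > 0 else 0.0
    from scipy.optimize import linear_sum_assignment

    rows, cols = linear_sum_assignment(-corr)
    out = {"matches": [], "min_temporal_corr": None, "min_membership_nmi": None}
    tcs, nmis = [], []
    for r, k in zip(rows, cols):
        part = result.partitions[r]
        score = nmi(part.labels, truth.membership_indicator(k))
        out["matches"].append(
            {"component": int(r), "circuit": int(k),
             "temporal_corr": float(corr[r, k]), "membership_nmi": float(score)}
        )
        tcs.append(corr[r, k])
        nmis.append(score)
    out["min_temporal_corr"] = float(min(tcs)) if tcs else 0.0
    out["min_membership_nmi"] = float(min(nmis)) if nmis else 0.0
    return out
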