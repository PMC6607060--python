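"""Reproducible experiment driver: config in, CSV/JSON reports out.

An :class:`ExperimentConfig` captures everything needed to re-run an
analysis (kind, sigma_hat, sample size, seed, protocol and solver
settings, parameter overrides).  All randomness flows from the single
config seed; saved sample matrices and QOI tables round-trip through CSV
at full double precision, so a re-run with the same config reproduces
them bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import gsa, mcf, tissue, uq
from .features import QOI_NAMES
from .parameters import PARAM_NAMES, ParameterSet
from .protocols import (SolverSettings, StimulusProtocol, dynamic_restitution,
                        find_threshold, pace, simulate_ap)

__all__ = ["ExperimentConfig", "run_experiment", "make_qoi_evaluator"]

log = logging.getLogger("cardiouq")

_KINDS = ("simulate", "threshold", "pace", "restitution", "propagate",
          "sobol", "morris", "mcfilter", "strand")


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully serializable description of one experiment run."""

    kind: str
    sigma_hat: float = 0.01
    n: int = 1000
    seed: int = 0
    qoi: str = "apd"
    behavior: str = "1"
    base_n: int = 1024
    n_trajectories: int = 50
    bcl: float = 1000.0
    n_beats: int = 10
    duration: float = 1000.0
    stim_multiple: float = 1.1
    fixed_at_nominal: tuple[str, ...] = ()
    param_overrides: dict[str, float] = field(default_factory=dict)
    rtol: float = 1e-6
    atol: float = 1e-8
    out_dir: str = "."
    screen_first: bool = False
    bcl_list: tuple[float, ...] = (1000.0, 800.0, 600.0, 500.0, 400.0, 300.0)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}; "
                             f"expected one of {_KINDS}")
        unknown = set(self.param_overrides) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter overrides: {sorted(unknown)}")
        unknown = set(self.fixed_at_nominal) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown fixed_at_nominal names: "
                             f"{sorted(unknown)}")

    # -- serialization ----------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fixed_at_nominal" in raw:
            raw["fixed_at_nominal"] = tuple(raw["fixed_at_nominal"])
        if "bcl_list" in raw:
            raw["bcl_list"] = tuple(raw["bcl_list"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["fixed_at_nominal"] = list(self.fixed_at_nominal)
        d["bcl_list"] = list(self.bcl_list)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    # -- derived objects --------------------------------------------------
    @property
    def solver(self) -> SolverSettings:
        return SolverSettings(rtol=self.rtol, atol=self.atol)

    def parameters(self) -> ParameterSet:
        return ParameterSet.nominal(**self.param_overrides)

    def uncertainty(self) -> uq.UncertaintySpec:
        return uq.build_distributions(self.parameters(), self.sigma_hat,
                                      overrides=self.fixed_at_nominal)


def make_qoi_evaluator(qoi: str, horizon: float = 1000.0,
                       solver: SolverSettings = SolverSettings()):
    """A callable mapping an (n, 36) parameter matrix to one QOI column.

    Runs the full threshold + AP pipeline per row; undefined QOIs and
    failed rows come back as NaN.
    """
    if qoi not in QOI_NAMES:
        raise ValueError(f"unknown QOI {qoi!r}; expected one of {QOI_NAMES}")

    def evaluate(values: np.ndarray) -> np.ndarray:
        table = uq.evaluate_rows(values, horizon=horizon, solver=solver,
                                 classify=False)
        return table[qoi].to_numpy(dtype=float)

    return evaluate


def _write_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")


def run_experiment(cfg: ExperimentConfig) -> dict[str, str]:
    """Execute one experiment and write its report files.

    Returns a mapping of artifact names to file paths.  Depending on the
    kind, writes a sample matrix CSV, a QOI table CSV, and a summary JSON
    (moments, CoVs, behavior fractions, index or filtering tables), plus a
    log line with the seed and failure counts.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = cfg.parameters()
    artifacts: dict[str, str] = {}
    summary: dict = {"kind": cfg.kind, "seed": cfg.seed,
                     "sigma_hat": cfg.sigma_hat}

    if cfg.kind == "simulate":
        thr = find_threshold(params, solver=cfg.solver)
        stim = StimulusProtocol(amplitude=cfg.stim_multiple * thr)
        trace = simulate_ap(params, stim, duration=cfg.duration,
                            solver=cfg.solver)
        path = out / "trace.csv"
        trace.to_frame(include_currents=True).to_csv(path, index=False)
        artifacts["trace"] = str(path)
        summary["threshold"] = thr

    elif cfg.kind == "threshold":
        summary["threshold"] = find_threshold(params, solver=cfg.solver)

    elif cfg.kind == "pace":
        beats = pace(params, bcl=cfg.bcl, n_beats=cfg.n_beats,
                     solver=cfg.solver)
        path = out / "paced_last_beat.csv"
        beats[-1].to_frame(include_currents=True).to_csv(path, index=False)
        artifacts["last_beat"] = str(path)

    elif cfg.kind == "restitution":
        table = dynamic_restitution(params, cfg.bcl_list, solver=cfg.solver)
        path = out / "restitution.csv"
        table.to_csv(path, index=False)
        artifacts["restitution"] = str(path)

    elif cfg.kind == "propagate":
        spec = cfg.uncertainty()
        samples = uq.sample_parameters(spec, cfg.n, cfg.seed)
        res = uq.propagate(spec, cfg.n, cfg.seed, samples=samples,
                           solver=cfg.solver)
        samples.to_csv(out / "samples.csv")
        res.table.to_csv(out / "qois.csv", index=False)
        behaviors = uq.behavior_probabilities(spec, cfg.n, cfg.seed,
                                              table=res.table)
        summary["qois"] = json.loads(res.summary.to_json(orient="index"))
        summary["behaviors"] = json.loads(
            behaviors.to_json(orient="index"))
        summary["n_failed"] = res.n_failed
        artifacts["samples"] = str(out / "samples.csv")
        artifacts["qois"] = str(out / "qois.csv")

    elif cfg.kind == "morris":
        spec = cfg.uncertainty()
        ev = make_qoi_evaluator(cfg.qoi, solver=cfg.solver)
        mres = gsa.morris_screen(spec, ev, n_trajectories=cfg.n_trajectories,
                                 seed=cfg.seed, qoi=cfg.qoi)
        mres.table.to_csv(out / "morris.csv")
        artifacts["morris"] = str(out / "morris.csv")
        summary["influential"] = list(mres.influential)
        summary["excluded"] = list(mres.excluded)

    elif cfg.kind == "sobol":
        spec = cfg.uncertainty()
        ev = make_qoi_evaluator(cfg.qoi, solver=cfg.solver)
        subset = None
        if cfg.screen_first:
            mres = gsa.morris_screen(spec, ev,
                                     n_trajectories=cfg.n_trajectories,
                                     seed=cfg.seed, qoi=cfg.qoi)
            subset = mres.influential
            summary["screened_out"] = list(mres.excluded)
        design = gsa.saltelli_design(spec, cfg.base_n, cfg.seed,
                                     param_subset=subset)
        y = ev(design.matrix.values)
        sres = gsa.sobol_indices(design, y, qoi=cfg.qoi, seed=cfg.seed)
        sres.table.to_csv(out / "sobol.csv")
        artifacts["sobol"] = str(out / "sobol.csv")
        summary["top_total_index"] = sres.ranked("ST").index[0]

    elif cfg.kind == "mcfilter":
        spec = cfg.uncertainty()
        samples = uq.sample_parameters(spec, cfg.n, cfg.seed)
        table = uq.evaluate_rows(samples.values, solver=cfg.solver)
        fres = mcf.mc_filter(samples, table["behavior"].fillna("failed"),
                             cfg.behavior)
        samples.to_csv(out / "samples.csv")
        table.to_csv(out / "qois.csv", index=False)
        fres.table.to_csv(out / "filtering.csv")
        artifacts["filtering"] = str(out / "filtering.csv")
        cdf_frames = []
        for name in fres.top(4):
            df = mcf.cdf_pair(samples, table["behavior"].fillna("failed"),
                              cfg.behavior, name)
            df.insert(0, "parameter", name)
            cdf_frames.append(df)
        pd.concat(cdf_frames, ignore_index=True).to_csv(
            out / "cdf_pairs.csv", index=False)
        artifacts["cdf_pairs"] = str(out / "cdf_pairs.csv")
        summary["highly_influential"] = list(fres.highly_influential)
        summary["influential"] = list(fres.influential)
        summary["n_behavior"] = fres.n_behavior
        summary["n_failed"] = int(table["sim_failed"].sum())

    elif cfg.kind == "strand":
        sol = tissue.solve_strand(params, duration=cfg.duration)
        cv = tissue.conduction_velocity(sol)
        field_df = pd.DataFrame({
            "x": sol.x, "activation_time": sol.activation_times})
        field_df.to_csv(out / "activation.csv", index=False)
        artifacts["activation"] = str(out / "activation.csv")
        summary["conduction_velocity_cm_per_s"] = cv
        summary["propagated"] = sol.propagated

    _write_json(summary, out / "summary.json")
    artifacts["summary"] = str(out / "summary.json")
    log.info("experiment %s done (seed=%d): %s", cfg.kind, cfg.seed,
             {k: v for k, v in summary.items() if not isinstance(v, dict)})
    return artifacts
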