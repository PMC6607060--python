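"""Parameter uncertainty: hyper-parameter-controlled distributions, Monte
Carlo sampling, and uncertainty propagation through the AP pipeline.

A single hyper-parameter sigma_hat scales the uncertainty of every sampled
parameter.  Half-(in)activation voltages are normal,

    p ~ N(p_nom, (sigma_hat * R)^2),        R = 100 mV reference range,

so that voltages near zero are not artificially pinned; all positive
parameters (conductances, slope factors, time constants, delta_h) are
lognormal,

    p ~ Lognormal(log(p_nom) - sigma_hat^2 / 2, sigma_hat^2),

which has mean exactly p_nom and standard deviation ~ sigma_hat * p_nom.
The Nernst potentials are environmental and stay fixed; additional
parameters can be pinned at nominal to probe their influence.

Propagation: for each sampled parameter set, find the threshold stimulus
by bisection, fire a 0.5 ms pulse at 1.1x threshold, extract QOIs from the
1000 ms trace, classify the behavior.  Summaries report per-QOI moments
over the rows where the QOI is defined, the undefined fraction, and a
convergence flag comparing estimates from N and N/2 samples (mean to three
significant figures, sd to two).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import QOI_NAMES, classify_behavior, extract_qois
from .parameters import (
    FIXED_NAMES,
    LOGNORMAL_NAMES,
    NORMAL_NAMES,
    N_PARAMS,
    PARAM_NAMES,
    ParameterSet,
    SAMPLED_NAMES,
)
from .protocols import (
    SolverError,
    SolverSettings,
    StimulusProtocol,
    ThresholdError,
    find_threshold,
    simulate_ap,
)

__all__ = [
    "UncertaintySpec",
    "SampleMatrix",
    "build_distributions",
    "sample_parameters",
    "evaluate_rows",
    "propagate",
    "behavior_probabilities",
    "PropagationResult",
    "BEHAVIOR_LABELS",
]

#: Default reference range for voltage parameters, mV.
REFERENCE_RANGE = 100.0

BEHAVIOR_LABELS = ("1", "2", "3", "4", "3A", "3B", "3C")


@dataclass(frozen=True)
class UncertaintySpec:
    """Sampling law for the 36-entry parameter vector.

    family maps each parameter name to 'normal', 'lognormal' or 'fixed';
    `fixed_at_nominal` lists normally-sampled parameters pinned to their
    nominal value for a fixed-parameter experiment.
    """

    sigma_hat: float
    nominal: ParameterSet
    R: float = REFERENCE_RANGE
    fixed_at_nominal: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.sigma_hat < 0:
            raise ValueError("sigma_hat must be non-negative")
        unknown = self.fixed_at_nominal - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")

    def family(self, name: str) -> str:
        if name in FIXED_NAMES or name in self.fixed_at_nominal:
            return "fixed"
        if name in NORMAL_NAMES:
            return "normal"
        return "lognormal"

    @property
    def free_names(self) -> tuple[str, ...]:
        """Parameters actually varied under this spec."""
        return tuple(n for n in SAMPLED_NAMES
                     if n not in self.fixed_at_nominal)

    def mean(self, name: str) -> float:
        return self.nominal[name]

    def sd(self, name: str) -> float:
        fam = self.family(name)
        p_nom = self.nominal[name]
        if fam == "fixed" or self.sigma_hat == 0.0:
            return 0.0
        if fam == "normal":
            return self.sigma_hat * self.R
        s2 = self.sigma_hat ** 2
        return abs(p_nom) * math.sqrt((math.exp(s2) - 1.0))

    def ppf(self, name: str, q) -> np.ndarray:
        """Quantile function of one parameter's distribution."""
        q = np.asarray(q, dtype=float)
        p_nom = self.nominal[name]
        fam = self.family(name)
        if fam == "fixed" or self.sigma_hat == 0.0:
            out = np.full_like(q, p_nom)
        elif fam == "normal":
            out = stats.norm.ppf(q, loc=p_nom, scale=self.sigma_hat * self.R)
        else:
            mu = math.log(p_nom) - 0.5 * self.sigma_hat ** 2
            out = np.exp(stats.norm.ppf(q, loc=mu, scale=self.sigma_hat))
        return float(out) if out.ndim == 0 else out

    def interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Equal-tailed interval of one parameter's distribution."""
        alpha = 0.5 * (1.0 - level)
        return (float(self.ppf(name, alpha)), float(self.ppf(name, 1 - alpha)))


@dataclass(frozen=True)
class SampleMatrix:
    """n x 36 matrix of sampled parameter vectors plus provenance."""

    values: np.ndarray
    sigma_hat: float
    seed: int | None
    scheme: str  # simple-MC | saltelli | morris
    columns: tuple[str, ...] = PARAM_NAMES

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != N_PARAMS:
            raise ValueError(f"values must be (n, {N_PARAMS})")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def row(self, i: int) -> ParameterSet:
        return ParameterSet(self.values[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.columns))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sigma_hat=float("nan"), seed=None,
                 scheme="loaded") -> "SampleMatrix":
        df = pd.read_csv(path, float_precision="round_trip")
        if list(df.columns) != list(PARAM_NAMES):
            raise ValueError("CSV columns do not match the canonical "
                             "36-parameter order")
        return cls(values=df.to_numpy(dtype=float), sigma_hat=sigma_hat,
                   seed=seed, scheme=scheme)


def build_distributions(nominal: ParameterSet, sigma_hat: float,
                        overrides: Iterable[str] = (),
                        R: float = REFERENCE_RANGE) -> UncertaintySpec:
    """Construct the sampling law for a given hyper-parameter sigma_hat.

    `overrides` names parameters to hold fixed at their nominal values (in
    addition to the always-fixed Nernst potentials).
    """
    if sigma_hat < 0:
        raise ValueError("sigma_hat must be non-negative")
    return UncertaintySpec(sigma_hat=sigma_hat, nominal=nominal, R=R,
                           fixed_at_nominal=frozenset(overrides))


def sample_parameters(spec: UncertaintySpec, n: int,
                      seed: int | None = None) -> SampleMatrix:
    """Draw n independent parameter vectors.

    One root seed spawns an independent child stream per parameter, in
    canonical column order, so adding output processing never shifts the
    draws of another parameter.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    root = np.random.SeedSequence(seed)
    children = root.spawn(N_PARAMS)
    out = np.empty((n, N_PARAMS))
    for j, name in enumerate(PARAM_NAMES):
        rng = np.random.default_rng(children[j])
        fam = spec.family(name)
        p_nom = spec.nominal[name]
        if fam == "fixed" or spec.sigma_hat == 0.0:
            out[:, j] = p_nom
            # keep the stream advanced identically either way
            rng.standard_normal(n)
        elif fam == "normal":
            out[:, j] = p_nom + spec.sigma_hat * spec.R * rng.standard_normal(n)
        else:
            mu = math.log(p_nom) - 0.5 * spec.sigma_hat ** 2
            out[:, j] = np.exp(mu + spec.sigma_hat * rng.standard_normal(n))
    return SampleMatrix(values=out, sigma_hat=spec.sigma_hat, seed=seed,
                        scheme="simple-MC")


# ---------------------------------------------------------------------------
# Propagation pipeline
# ---------------------------------------------------------------------------

def evaluate_rows(values: np.ndarray,
                  horizon: float = 1000.0,
                  dt_out: float = 0.05,
                  stim_multiple: float = 1.1,
                  stim_duration: float = 0.5,
                  solver: SolverSettings = SolverSettings(),
                  classify: bool = True,
                  qoi_names: Sequence[str] = QOI_NAMES) -> pd.DataFrame:
    """Run the AP pipeline for every row of an (n, 36) parameter matrix.

    Per row: bisect the threshold stimulus, fire a 0.5 ms pulse at
    `stim_multiple` x threshold, extract QOIs over `horizon` ms, classify
    the behavior.  Individual failures are recorded (sim_failed = True,
    QOIs NaN) and never abort the batch.
    """
    values = np.asarray(values, dtype=float)
    rows = []
    for i in range(values.shape[0]):
        rec: dict[str, object] = {"row": i, "sim_failed": False}
        try:
            params = ParameterSet(values[i])
            thr = find_threshold(params, stim_duration=stim_duration,
                                 solver=solver)
            stim = StimulusProtocol(amplitude=stim_multiple * thr,
                                    onset=0.0, duration=stim_duration)
            trace = simulate_ap(params, stim, duration=horizon,
                                dt_out=dt_out, solver=solver)
            qois = extract_qois(trace, threshold=thr)
            rec.update(qois.as_dict())
            if classify:
                label = classify_behavior(trace)
                rec["behavior"] = str(label)
                rec["behavior_major"] = label.major
        except (SolverError, ThresholdError, ValueError) as exc:
            rec["sim_failed"] = True
            rec["error"] = type(exc).__name__
            for name in qoi_names:
                rec[name] = float("nan")
                rec[f"{name}_defined"] = False
            if classify:
                rec["behavior"] = None
                rec["behavior_major"] = -1
        rows.append(rec)
    df = pd.DataFrame(rows)
    return df


def _sig_figs(x: float, k: int) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    return float(f"{x:.{k}g}")


def _converged(values: np.ndarray) -> bool:
    """N-vs-N/2 rule: mean to 3 significant figures, sd to 2."""
    v = values[np.isfinite(values)]
    if v.size < 4:
        return False
    half = v[: v.size // 2]
    mean_ok = _sig_figs(float(np.mean(v)), 3) == _sig_figs(
        float(np.mean(half)), 3)
    sd_ok = _sig_figs(float(np.std(v, ddof=1)), 2) == _sig_figs(
        float(np.std(half, ddof=1)), 2)
    return bool(mean_ok and sd_ok)


@dataclass
class PropagationResult:
    """QOI table plus per-QOI summary statistics."""

    table: pd.DataFrame
    summary: pd.DataFrame
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]
    n_failed: int
    sigma_hat: float
    seed: int | None

    def cov(self, qoi: str) -> float:
        """Coefficient of variation of a QOI, percent."""
        return float(self.summary.loc[qoi, "cov_pct"])


def summarize_qois(table: pd.DataFrame, sigma_hat: float = float("nan"),
                   seed: int | None = None,
                   qoi_names: Sequence[str] = QOI_NAMES,
                   n_bins: int = 50) -> PropagationResult:
    """Per-QOI moments, undefined fractions, histograms, convergence flags.

    Histograms use `n_bins` bins spanning mean +- 40% of the mean (the
    fixed-axis convention that makes QOI spreads comparable).
    """
    n_total = len(table)
    rows = []
    hists: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name in qoi_names:
        x = table[name].to_numpy(dtype=float)
        ok = np.isfinite(x)
        xd = x[ok]
        mean = float(np.mean(xd)) if xd.size else float("nan")
        sd = float(np.std(xd, ddof=1)) if xd.size > 1 else float("nan")
        cov = 100.0 * sd / abs(mean) if xd.size > 1 and mean != 0 else float("nan")
        rows.append({
            "qoi": name,
            "mean": mean,
            "sd": sd,
            "cov_pct": cov,
            "n_defined": int(xd.size),
            "frac_undefined": 1.0 - xd.size / n_total if n_total else float("nan"),
            "converged": _converged(x),
        })
        if xd.size and np.isfinite(mean) and mean != 0:
            lo, hi = mean - 0.4 * abs(mean), mean + 0.4 * abs(mean)
            counts, edges = np.histogram(xd, bins=n_bins, range=(lo, hi))
            hists[name] = (counts, edges)
    summary = pd.DataFrame(rows).set_index("qoi")
    n_failed = int(table["sim_failed"].sum()) if "sim_failed" in table else 0
    return PropagationResult(table=table, summary=summary, histograms=hists,
                             n_failed=n_failed, sigma_hat=sigma_hat,
                             seed=seed)


def propagate(spec: UncertaintySpec, n: int, seed: int | None = None,
              horizon: float = 1000.0,
              solver: SolverSettings = SolverSettings(),
              samples: SampleMatrix | None = None) -> PropagationResult:
    """Monte Carlo uncertainty propagation through the AP pipeline.

    Draws n samples (or reuses `samples`), runs the pipeline on each, and
    summarizes the QOIs.  The stimulus is 1.1x the per-sample threshold.
    """
    if horizon < 1000.0:
        raise ValueError("horizon must be >= 1000 ms for classification")
    if samples is None:
        samples = sample_parameters(spec, n, seed)
    table = evaluate_rows(samples.values, horizon=horizon, solver=solver)
    for j, name in enumerate(PARAM_NAMES):
        table[name] = samples.values[:, j]
    return summarize_qois(table, sigma_hat=spec.sigma_hat, seed=seed)


def behavior_probabilities(spec: UncertaintySpec, n: int,
                           seed: int | None = None,
                           table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fractions of each AP behavior label, with binomial standard errors.

    Either draws and evaluates n samples or reuses a pipeline `table`.
    Major labels 1/2/3/4 partition the sample; 3A/3B/3C partition label 3.
    """
    if table is None:
        if n < 1000:
            raise ValueError("behavior probabilities need n >= 1000")
        samples = sample_parameters(spec, n, seed)
        table = evaluate_rows(samples.values)
    ok = table[~table["sim_failed"]]
    m = len(ok)
    rows = []
    for label in BEHAVIOR_LABELS:
        if label in ("1", "2", "3", "4"):
            count = int((ok["behavior_major"] == int(label)).sum())
        else:
            count = int((ok["behavior"] == label).sum())
        frac = count / m if m else float("nan")
        se = math.sqrt(frac * (1 - frac) / m) if m else float("nan")
        rows.append({"behavior": label, "count": count, "fraction": frac,
                     "se": se})
    out = pd.DataFrame(rows).set_index("behavior")
    out.attrs["n_evaluated"] = m
    out.attrs["n_failed"] = int(table["sim_failed"].sum())
    return out
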