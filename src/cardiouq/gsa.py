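"""Variance-based global sensitivity analysis and Morris screening.

First-order and total Sobol indices are estimated with the Saltelli
pick-freeze design: two quasi-random base matrices A and B (halves of one
scrambled Sobol sequence in 2k dimensions) plus the k matrices AB_i equal
to A with column i taken from B, for a total of base_n * (k + 2) model
evaluations.  Estimators:

    S1_i = mean(f(B) * (f(AB_i) - f(A))) / V        (Saltelli et al. 2010)
    ST_i = mean((f(A) - f(AB_i))^2) / (2 V)         (Jansen 1999)

with V the variance of f over the pooled A and B samples.  Uncertainty in
each index is a bootstrap half-width (resampling base-sample indices).

Morris elementary-effects screening ranks parameters by mu*, the mean
absolute one-at-a-time effect along randomized trajectories on a p-level
grid in the unit hypercube (mapped through each parameter's quantile
function).  It is used to exclude clearly non-influential parameters
before spending a full Saltelli design on an expensive QOI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .parameters import N_PARAMS, PARAM_NAMES, ParameterSet
from .uq import SampleMatrix, UncertaintySpec

__all__ = [
    "SaltelliDesign",
    "SobolResult",
    "MorrisResult",
    "saltelli_design",
    "sobol_indices",
    "morris_design",
    "morris_screen",
]

#: Parameters with mu* below this fraction of the largest mu* are screened
#: out as non-influential.
MORRIS_EXCLUDE_FRACTION = 0.01


@dataclass(frozen=True)
class SaltelliDesign:
    """Pick-freeze design: rows ordered A, B, AB_1 ... AB_k."""

    matrix: SampleMatrix
    param_subset: tuple[str, ...]
    base_n: int

    @property
    def k(self) -> int:
        return len(self.param_subset)

    @property
    def n_rows(self) -> int:
        return self.base_n * (self.k + 2)

    def blocks(self, y: np.ndarray):
        """Split evaluations y into (f_A, f_B, f_AB[k, base_n])."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_rows,):
            raise ValueError(
                f"expected {self.n_rows} evaluations, got {y.shape}")
        f_A = y[: self.base_n]
        f_B = y[self.base_n: 2 * self.base_n]
        f_AB = y[2 * self.base_n:].reshape(self.k, self.base_n)
        return f_A, f_B, f_AB


@dataclass
class SobolResult:
    """First-order (S1) and total (ST) indices with bootstrap errors."""

    table: pd.DataFrame  # index: parameter; columns S1, S1_err, ST, ST_err
    qoi: str
    base_n: int
    variance: float

    def ranked(self, by: str = "ST") -> pd.DataFrame:
        return self.table.sort_values(by, ascending=False)


@dataclass
class MorrisResult:
    """Elementary-effects screening summary."""

    table: pd.DataFrame  # index: parameter; columns mu_star, sigma, verdict
    qoi: str
    n_trajectories: int

    @property
    def influential(self) -> tuple[str, ...]:
        t = self.table
        return tuple(t.index[t["verdict"] == "influential"])

    @property
    def excluded(self) -> tuple[str, ...]:
        t = self.table
        return tuple(t.index[t["verdict"] == "excluded"])


def _unit_to_params(spec: UncertaintySpec, U: np.ndarray,
                    subset: Sequence[str]) -> np.ndarray:
    """Map unit-hypercube rows (n, k) to full (n, 36) parameter rows.

    Columns outside `subset` sit at their nominal values.
    """
    n = U.shape[0]
    out = np.tile(spec.nominal.values, (n, 1))
    for j, name in enumerate(subset):
        out[:, PARAM_NAMES.index(name)] = spec.ppf(name, U[:, j])
    return out


def saltelli_design(spec: UncertaintySpec, base_n: int, seed: int | None = None,
                    param_subset: Sequence[str] | None = None
                    ) -> SaltelliDesign:
    """Build the Saltelli pick-freeze design for S1 and ST estimation.

    `param_subset` defaults to every free parameter of the spec.  base_n is
    ideally a power of two (scrambled Sobol sequence balance).  The design
    has base_n * (k + 2) rows; every row satisfies the positivity
    invariants by construction (quantile transforms).
    """
    if param_subset is None:
        param_subset = spec.free_names
    subset = tuple(param_subset)
    if not subset:
        raise ValueError("param_subset must not be empty")
    unknown = set(subset) - set(spec.free_names)
    if unknown:
        raise ValueError(f"not free under this spec: {sorted(unknown)}")
    k = len(subset)
    sampler = qmc.Sobol(d=2 * k, scramble=True, seed=seed)
    base = sampler.random(base_n)
    # clip away exact 0/1 that would map to +-inf through the ppf
    eps = 1e-12
    base = np.clip(base, eps, 1 - eps)
    UA, UB = base[:, :k], base[:, k:]
    rows = [UA, UB]
    for i in range(k):
        UABi = UA.copy()
        UABi[:, i] = UB[:, i]
        rows.append(UABi)
    U = np.vstack(rows)
    values = _unit_to_params(spec, U, subset)
    matrix = SampleMatrix(values=values, sigma_hat=spec.sigma_hat, seed=seed,
                          scheme="saltelli")
    return SaltelliDesign(matrix=matrix, param_subset=subset, base_n=base_n)


def sobol_indices(design: SaltelliDesign, qoi_values: np.ndarray,
                  qoi: str = "", n_bootstrap: int = 100,
                  seed: int | None = None) -> SobolResult:
    """Estimate S1 and ST from evaluations of the design rows.

    Requires a fully defined QOI over the design: variance decomposition
    over a censored sample is meaningless, so any undefined (NaN) value
    raises (use a smaller sigma_hat or a more robust QOI).
    Bootstrap errors are half-widths of the central 95% interval over 100
    resamples of the base-sample indices.
    """
    y = np.asarray(qoi_values, dtype=float)
    n_bad = int(np.sum(~np.isfinite(y)))
    if n_bad:
        raise ValueError(
            f"{n_bad}/{y.size} undefined QOI values in the Sobol design; "
            "variance decomposition needs a fully defined sample -- use a "
            "smaller sigma_hat or a more robust QOI")
    f_A, f_B, f_AB = design.blocks(y)

    def estimate(idx: np.ndarray):
        a, b, ab = f_A[idx], f_B[idx], f_AB[:, idx]
        pooled = np.concatenate([a, b])
        mu = pooled.mean()
        var = pooled.var()
        if var == 0.0:
            return np.zeros(design.k), np.zeros(design.k), 0.0
        s1 = np.mean(b[None, :] * (ab - a[None, :]), axis=1) / var
        st = 0.5 * np.mean((a[None, :] - ab) ** 2, axis=1) / var
        return s1, st, var

    all_idx = np.arange(design.base_n)
    S1, ST, var = estimate(all_idx)
    rng = np.random.default_rng(seed)
    boots_s1 = np.empty((n_bootstrap, design.k))
    boots_st = np.empty((n_bootstrap, design.k))
    for bi in range(n_bootstrap):
        idx = rng.integers(0, design.base_n, design.base_n)
        boots_s1[bi], boots_st[bi], _ = estimate(idx)
    s1_err = 0.5 * (np.percentile(boots_s1, 97.5, axis=0)
                    - np.percentile(boots_s1, 2.5, axis=0))
    st_err = 0.5 * (np.percentile(boots_st, 97.5, axis=0)
                    - np.percentile(boots_st, 2.5, axis=0))
    table = pd.DataFrame(
        {"S1": S1, "S1_err": s1_err, "ST": ST, "ST_err": st_err},
        index=list(design.param_subset))
    table.index.name = "parameter"
    return SobolResult(table=table, qoi=qoi, base_n=design.base_n,
                       variance=float(var))


def morris_design(spec: UncertaintySpec, n_trajectories: int = 50,
                  n_levels: int = 4, seed: int | None = None,
                  param_subset: Sequence[str] | None = None):
    """Randomized Morris trajectories on a p-level grid.

    Returns (matrix, subset, delta): matrix has n_trajectories * (k + 1)
    rows; within a trajectory, consecutive rows differ in exactly one
    parameter by delta = p / (2 (p - 1)) in unit-hypercube coordinates.
    """
    if param_subset is None:
        param_subset = spec.free_names
    subset = tuple(param_subset)
    k = len(subset)
    if k == 0:
        raise ValueError("param_subset must not be empty")
    if n_levels < 2 or n_levels % 2:
        raise ValueError("n_levels must be an even integer >= 2")
    p = n_levels
    delta = p / (2.0 * (p - 1.0))
    rng = np.random.default_rng(seed)
    grid = np.arange(p / 2) / (p - 1.0)  # start levels in [0, 1 - delta]
    rows = []
    for _ in range(n_trajectories):
        x = rng.choice(grid, size=k)
        order = rng.permutation(k)
        signs = rng.choice((-1.0, 1.0), size=k)
        traj = [x.copy()]
        for step, j in enumerate(order):
            x = x.copy()
            d = signs[step] * delta
            if not (0.0 <= x[j] + d <= 1.0):
                d = -d
            x[j] += d
            traj.append(x.copy())
        rows.append(np.vstack(traj))
    U = np.vstack(rows)
    eps = 1e-12
    values = _unit_to_params(spec, np.clip(U, eps, 1 - eps), subset)
    matrix = SampleMatrix(values=values, sigma_hat=spec.sigma_hat, seed=seed,
                          scheme="morris")
    return matrix, subset, delta


def morris_screen(spec: UncertaintySpec,
                  evaluate: Callable[[np.ndarray], np.ndarray],
                  n_trajectories: int = 50, n_levels: int = 4,
                  seed: int | None = None,
                  param_subset: Sequence[str] | None = None,
                  qoi: str = "") -> MorrisResult:
    """Elementary-effects screening of the spec's free parameters.

    `evaluate` maps an (n, 36) parameter matrix to n QOI values (NaN for
    undefined).  A trajectory containing any undefined value is discarded
    (with a count in the result table attrs).  Verdict: parameters with
    mu* below 1% of the largest mu* are 'excluded', the rest
    'influential'.
    """
    if n_trajectories < 20:
        raise ValueError("use at least 20 trajectories")
    matrix, subset, delta = morris_design(spec, n_trajectories, n_levels,
                                          seed, param_subset)
    k = len(subset)
    y = np.asarray(evaluate(matrix.values), dtype=float)
    col_of = {name: PARAM_NAMES.index(name) for name in subset}
    effects: dict[str, list[float]] = {name: [] for name in subset}
    n_discarded = 0
    step = k + 1
    for tr in range(n_trajectories):
        sl = slice(tr * step, (tr + 1) * step)
        ytr = y[sl]
        vals = matrix.values[sl]
        if not np.all(np.isfinite(ytr)):
            n_discarded += 1
            continue
        for i in range(k):
            diff = vals[i + 1] - vals[i]
            changed = np.nonzero(diff)[0]
            if changed.size != 1:
                continue
            col = int(changed[0])
            name = subset[next(s for s, nm in enumerate(subset)
                               if col_of[nm] == col)]
            # elementary effect in unit-hypercube coordinates
            u_hi = _param_to_unit(spec, name, vals[i + 1][col])
            u_lo = _param_to_unit(spec, name, vals[i][col])
            du = u_hi - u_lo
            effects[name].append((ytr[i + 1] - ytr[i]) / du)
    mu_star = np.array([np.mean(np.abs(effects[nm])) if effects[nm]
                        else np.nan for nm in subset])
    sigma = np.array([np.std(effects[nm], ddof=1)
                      if len(effects[nm]) > 1 else np.nan for nm in subset])
    cutoff = MORRIS_EXCLUDE_FRACTION * np.nanmax(mu_star)
    verdict = np.where(mu_star < cutoff, "excluded", "influential")
    table = pd.DataFrame({"mu_star": mu_star, "sigma": sigma,
                          "verdict": verdict}, index=list(subset))
    table.index.name = "parameter"
    table.attrs["n_discarded_trajectories"] = n_discarded
    table.attrs["delta"] = delta
    return MorrisResult(table=table, qoi=qoi,
                        n_trajectories=n_trajectories - n_discarded)


def _param_to_unit(spec: UncertaintySpec, name: str, value: float) -> float:
    """Inverse of the per-parameter quantile transform (CDF)."""
    from scipy import stats
    import math

    fam = spec.family(name)
    p_nom = spec.nominal[name]
    if fam == "fixed" or spec.sigma_hat == 0.0:
        return 0.5
    if fam == "normal":
        return float(stats.norm.cdf(value, loc=p_nom,
                                    scale=spec.sigma_hat * spec.R))
    mu = math.log(p_nom) - 0.5 * spec.sigma_hat ** 2
    return float(stats.norm.cdf(math.log(value), loc=mu,
                                scale=spec.sigma_hat))
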