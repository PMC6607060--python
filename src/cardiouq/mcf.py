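"""Monte Carlo filtering (regionalized sensitivity analysis).

After sampling M parameter vectors and classifying each simulated AP, the
sample is split into the rows that exhibit a target behavior and those
that do not.  For each parameter, the two conditional empirical CDFs are
compared with the two-sample Kolmogorov-Smirnov test: a large gap D_stat
means the parameter shapes whether the behavior occurs.

Categories (per parameter): highly influential if D_stat > 0.2;
influential if D_stat <= 0.2 but p < 0.01; not influential otherwise.
P-values use the asymptotic two-sample KS distribution, appropriate for
the M ~ 10,000 samples these analyses use.

Behavior-conditioned pairwise correlations (with delta_h entering on a log
scale, matching its lognormal sampling law) quantify the parameter
combinations that the surviving, normally-behaving sample prefers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import PARAM_NAMES, SAMPLED_NAMES
from .uq import SampleMatrix

__all__ = [
    "FilteringResult",
    "ks_two_sample",
    "cdf_pair",
    "mc_filter",
    "conditional_correlations",
    "D_STAT_HIGH",
    "ALPHA",
]

#: D_stat above this is 'highly influential'.
D_STAT_HIGH = 0.2
#: Significance level for 'influential'.
ALPHA = 0.01
#: Minimum split-set size for the KS asymptotics.
MIN_SPLIT = 10


@dataclass
class FilteringResult:
    """Per-parameter KS statistics and influence categories."""

    table: pd.DataFrame       # index: parameter; D_stat, p_value, category
    behavior: str
    n_total: int
    n_behavior: int

    @property
    def highly_influential(self) -> tuple[str, ...]:
        t = self.table
        return tuple(t.index[t["category"] == "highly-influential"])

    @property
    def influential(self) -> tuple[str, ...]:
        t = self.table
        return tuple(t.index[t["category"] == "influential"])

    def top(self, n: int = 5) -> tuple[str, ...]:
        """The n parameters with the largest CDF separation."""
        return tuple(self.table.sort_values("D_stat", ascending=False)
                     .index[:n])


def ks_two_sample(a: Sequence[float], b: Sequence[float]
                  ) -> tuple[float, float]:
    """Two-sample KS statistic D = sup |ECDF_a - ECDF_b| and its p-value.

    P-values from the asymptotic two-sample distribution.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def _categorize(d: float, p: float) -> str:
    if d > D_STAT_HIGH:
        return "highly-influential"
    if p < ALPHA:
        return "influential"
    return "not-influential"


def mc_filter(samples: SampleMatrix | np.ndarray,
              labels: Sequence, target_behavior,
              param_names: Sequence[str] = SAMPLED_NAMES
              ) -> FilteringResult:
    """Monte Carlo filtering of one behavior against all others.

    `labels` holds one behavior label per sample row (compared against
    `target_behavior` by string equality, so major classes can be passed
    as 1/'1' and sub-classes as '3C'; a major class matches its
    sub-classes' rows via their leading character).
    """
    values = samples.values if isinstance(samples, SampleMatrix) else \
        np.asarray(samples, dtype=float)
    lab = np.asarray([str(l) for l in labels])
    if lab.shape[0] != values.shape[0]:
        raise ValueError("labels and samples must have equal length")
    target = str(target_behavior)
    if len(target) == 1:
        in_set = np.char.startswith(lab, target)
    else:
        in_set = lab == target
    n_in, n_out = int(in_set.sum()), int((~in_set).sum())
    if min(n_in, n_out) < MIN_SPLIT:
        raise ValueError(
            f"split sets too small ({n_in} vs {n_out}); need >= {MIN_SPLIT} "
            "each -- use a larger M or a sigma_hat that produces the "
            "behavior more often")
    rows = []
    for name in param_names:
        col = values[:, PARAM_NAMES.index(name)]
        d, p = ks_two_sample(col[in_set], col[~in_set])
        rows.append({"parameter": name, "D_stat": d, "p_value": p,
                     "category": _categorize(d, p)})
    table = pd.DataFrame(rows).set_index("parameter")
    return FilteringResult(table=table, behavior=target,
                           n_total=values.shape[0], n_behavior=n_in)


def cdf_pair(samples: SampleMatrix | np.ndarray, labels: Sequence,
             target_behavior, param: str) -> pd.DataFrame:
    """The two conditional ECDFs of one parameter, for plotting.

    Returns a long-format frame (value, ecdf, conditioned) with
    conditioned in {'behavior', 'not-behavior'}; right-continuous step
    convention (ecdf at a value counts draws <= value).
    """
    values = samples.values if isinstance(samples, SampleMatrix) else \
        np.asarray(samples, dtype=float)
    lab = np.asarray([str(l) for l in labels])
    target = str(target_behavior)
    if len(target) == 1:
        in_set = np.char.startswith(lab, target)
    else:
        in_set = lab == target
    col = values[:, PARAM_NAMES.index(param)]
    frames = []
    for name, mask in (("behavior", in_set), ("not-behavior", ~in_set)):
        x = np.sort(col[mask])
        if x.size == 0:
            raise ValueError(f"no rows in the {name!r} split")
        frames.append(pd.DataFrame({
            "value": x,
            "ecdf": np.arange(1, x.size + 1) / x.size,
            "conditioned": name,
        }))
    return pd.concat(frames, ignore_index=True)


def conditional_correlations(samples: SampleMatrix | np.ndarray,
                             labels: Sequence,
                             param_subset: Sequence[str],
                             condition_behavior="4",
                             min_rows: int = 100) -> pd.DataFrame:
    """Pearson correlations among `param_subset` on a behavior-conditioned
    subset of the sample.

    delta_h enters as log(delta_h) (its sampling law is lognormal, so the
    log scale is where linear correlation is meaningful); the output names
    it 'log_delta_h'.
    """
    values = samples.values if isinstance(samples, SampleMatrix) else \
        np.asarray(samples, dtype=float)
    lab = np.asarray([str(l) for l in labels])
    target = str(condition_behavior)
    if len(target) == 1:
        mask = np.char.startswith(lab, target)
    else:
        mask = lab == target
    n = int(mask.sum())
    if n < min_rows:
        raise ValueError(
            f"only {n} rows with behavior {target}; need >= {min_rows}")
    cols = {}
    for name in param_subset:
        col = values[mask, PARAM_NAMES.index(name)]
        if name == "delta_h":
            cols["log_delta_h"] = np.log(col)
        else:
            cols[name] = col
    df = pd.DataFrame(cols)
    corr = df.corr(method="pearson")
    corr.attrs["n_rows"] = n
    corr.attrs["behavior"] = target
    return corr
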