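"""Per-condition net growth rates and the death-rate vs CTL-density scaling.

For each CTL concentration E (optionally per desired tumor concentration Ta)
the net growth rate r_net is the least-squares slope of ln T against time in
days over all available time points; with two time points this reduces to the
difference of mean ln counts over the interval. The no-CTL rate r0 anchors
the CTL-attributable death rate K(E) = r0 - r_net(E), and the scaling of K
with E is summarized by an ordinary least-squares fit of ln K on ln E, i.e.
K = c * E^n. Under mass-action killing the exponent n is 1; a sublinear
exponent indicates that the apparent per-CTL efficacy falls with CTL density
(or, as in the suppression-in-growth model, that low CTL densities already
suppress growth non-lytically).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from gelkill.models import HOURS_PER_DAY

__all__ = ["NetRateEstimate", "DeathRateCurve", "net_growth_rates", "death_rate_power_fit"]


@dataclass(frozen=True)
class NetRateEstimate:
    """Net exponential growth rate of one (E [, Ta]) condition."""

    ctl_conc: float
    desired_tumor_conc: float | None  # None when pooled over Ta
    r_net: float  # per day
    stderr: float  # per day
    n_obs: int


@dataclass
class DeathRateCurve:
    """CTL-attributable death rates K(E) = r0 - r_net(E) and their power fit."""

    r0: float
    points: pd.DataFrame  # columns: E, r_net, K
    exponent: float
    intercept: float  # c in K = c * E^exponent
    exponent_stderr: float
    n_excluded_nonpositive: int


def _slope(t_days: np.ndarray, ln_t: np.ndarray) -> tuple[float, float]:
    X = sm.add_constant(t_days)
    res = sm.OLS(ln_t, X).fit()
    return float(res.params[1]), float(res.bse[1]) if len(res.bse) > 1 else math.nan


def net_growth_rates(data: pd.DataFrame, pool_over_ta: bool = True) -> list[NetRateEstimate]:
    """Estimate r_net per CTL concentration (averaged over Ta when pooling).

    Conditions with a single time point are skipped with a warning. Requires
    positive measured concentrations (filter zero-count gels upstream).
    """
    if np.any(data["b16_measured"] <= 0):
        raise ValueError("net growth rates need positive counts; filter zeros first")
    per_condition: list[NetRateEstimate] = []
    for (e, ta), grp in data.groupby(["otl_conc", "b16_desired"]):
        t = grp["time_h"].to_numpy(dtype=float) / HOURS_PER_DAY
        if np.unique(t).size < 2:
            warnings.warn(
                f"condition E={e:g}, Ta={ta:g} has a single time point; skipped",
                stacklevel=2,
            )
            continue
        slope, se = _slope(t, np.log(grp["b16_measured"].to_numpy(dtype=float)))
        per_condition.append(NetRateEstimate(e, ta, slope, se, len(grp)))
    if not pool_over_ta:
        return per_condition
    pooled = []
    by_e: dict[float, list[NetRateEstimate]] = {}
    for est in per_condition:
        by_e.setdefault(est.ctl_conc, []).append(est)
    for e in sorted(by_e):
        ests = by_e[e]
        rates = np.array([x.r_net for x in ests])
        ses = np.array([x.stderr for x in ests])
        pooled.append(
            NetRateEstimate(
                ctl_conc=e,
                desired_tumor_conc=None,
                r_net=float(rates.mean()),
                stderr=float(np.sqrt(np.nansum(ses**2)) / len(ests)),
                n_obs=int(sum(x.n_obs for x in ests)),
            )
        )
    return pooled


def death_rate_power_fit(rates: list[NetRateEstimate], r0: float) -> DeathRateCurve:
    """Fit K = c * E^n by OLS of ln K on ln E over positive-E conditions.

    Conditions with K = r0 - r_net <= 0 (apparent growth faster than the
    no-CTL control) cannot enter the log regression and are excluded with a
    count in the result.
    """
    rows = [
        {"E": x.ctl_conc, "r_net": x.r_net, "K": r0 - x.r_net}
        for x in rates
        if x.ctl_conc > 0
    ]
    points = pd.DataFrame(rows)
    usable = points[points["K"] > 0]
    n_excluded = len(points) - len(usable)
    if len(usable) < 2:
        raise ValueError("need at least two positive-E conditions with K > 0")
    X = sm.add_constant(np.log(usable["E"].to_numpy()))
    res = sm.OLS(np.log(usable["K"].to_numpy()), X).fit()
    return DeathRateCurve(
        r0=r0,
        points=points,
        exponent=float(res.params[1]),
        intercept=float(math.exp(res.params[0])),
        exponent_stderr=float(res.bse[1]),
        n_excluded_nonpositive=n_excluded,
    )
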