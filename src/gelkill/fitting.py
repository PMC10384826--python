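"""Least-squares fitting of gel models on ln counts, with model selection.

Models are fit by minimizing the sum of squared differences between the
natural log of measured B16 concentrations and the model's log prediction,
jointly over all (Ta, E, t) conditions with shared parameters. Scale
parameters spanning many orders of magnitude (k, h, g2, a1, a2) are optimized
on log10 scale; optimization is multistarted from Latin-hypercube draws
within bounds plus a fixed domain-informed default start, and is
deterministic given the seed.

Model comparison uses AIC computed from the residual sum of squares,

    AIC = n ln(SSR/n) + 2 (K + 1),

where K counts the model's parameters (the +1 is the error variance). The
additive constant is convention-dependent; differences between models fit to
the same data are not, and all selection here rests on those differences and
the Akaike weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2).
``constant="gaussian"`` adds n(ln 2*pi + 1), the full Gaussian log-likelihood
constant used by some tools.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from scipy.stats import qmc

from gelkill.models import LOG_SCALE_PARAMS, Model

__all__ = [
    "FitResult",
    "ModelComparison",
    "fit_model",
    "compute_aic",
    "akaike_weights",
    "compare_models",
    "nested_f_test",
    "nested_lr_test",
    "lack_of_fit_test",
    "residual_diagnostics",
    "confidence_intervals",
]

#: Domain-informed default start: recovery fraction ~1/3 (alpha ~ 3), growth
#: about one division per day, mass-action kill rate ~1e-6 /(cell/mL)/day,
#: half-saturation constants at mid-experimental CTL densities.
_DEFAULT_START = {
    "alpha": 3.0,
    "r": 0.5,
    "g0": 0.3,
    "g1": 0.5,
    "g2": 1e4,
    "k": 1e-6,
    "h": 1e6,
    "n": 1.0,
    "fd": 0.5,
    "d": 1.0,
    "tprime": 0.5,
    "a1": 1e-8,
    "a2": 1e-8,
}


class FitError(RuntimeError):
    """No optimization start converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass
class FitResult:
    """Outcome of a least-squares model fit on ln-scale counts."""

    model: Model
    params: dict[str, float]
    ssr: float
    n_obs: int
    n_params: int
    aic: float
    residuals: np.ndarray
    converged: bool
    n_starts_used: int
    seed: int
    boundary_warning: bool
    ci95: dict[str, tuple[float, float]] | None
    jacobian: np.ndarray | None = None
    data: pd.DataFrame | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [f"{self.model.name}: SSR={self.ssr:.4g}, AIC={self.aic:.2f}, n={self.n_obs}"]
        for p, v in self.params.items():
            ci = f" (95% CI {self.ci95[p][0]:.4g}-{self.ci95[p][1]:.4g})" if self.ci95 else ""
            lines.append(f"  {p} = {v:.6g}{ci}")
        return "\n".join(lines)


@dataclass
class ModelComparison:
    """AIC comparison of several fits of the same data."""

    fits: list[FitResult]
    delta: dict[str, float]
    weights: dict[str, float]
    best: str


def _internal(values: np.ndarray, names: Sequence[str]) -> np.ndarray:
    out = values.copy()
    for j, p in enumerate(names):
        if p in LOG_SCALE_PARAMS:
            out[j] = math.log10(values[j])
    return out


def _natural(values: np.ndarray, names: Sequence[str]) -> np.ndarray:
    out = values.copy()
    for j, p in enumerate(names):
        if p in LOG_SCALE_PARAMS:
            out[j] = 10.0 ** values[j]
    return out


def _default_start(model: Model) -> np.ndarray:
    vals = []
    for p in model.parameter_names:
        key = p.split("_")[0] if p[-1].isdigit() else p
        if key.startswith("alpha"):
            key = "alpha"
        vals.append(_DEFAULT_START.get(key, 1.0))
    return np.array(vals, dtype=float)


def fit_model(
    data: pd.DataFrame,
    model: Model,
    n_starts: int = 50,
    seed: int = 0,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    x0: Mapping[str, float] | None = None,
    keep_data: bool = True,
) -> FitResult:
    """Fit ``model`` to gel measurements by least squares on ln counts.

    ``data`` is a canonical gel DataFrame with all measured concentrations
    positive (exclude or impute zero-count gels upstream). The fit is jointly
    over all conditions with shared parameters; the best of ``n_starts``
    optimizations (one fixed default start plus Latin-hypercube draws within
    bounds, seeded by ``seed``) is returned.
    """
    names = model.parameter_names
    K = len(names)
    if np.any(data["b16_measured"] <= 0):
        raise ValueError("all measured concentrations must be > 0; filter zero-count gels first")
    if len(data) < K + 1:
        raise ValueError(f"need at least {K + 1} observations to fit {model.name}")

    Ta = data["b16_desired"].to_numpy(dtype=float)
    E = data["otl_conc"].to_numpy(dtype=float)
    t_h = data["time_h"].to_numpy(dtype=float)
    y = np.log(data["b16_measured"].to_numpy(dtype=float))

    all_bounds = dict(model.bounds)
    if bounds:
        all_bounds.update(bounds)
    lb = _internal(np.array([all_bounds[p][0] for p in names]), names)
    ub = _internal(np.array([all_bounds[p][1] for p in names]), names)

    def resid(theta_int: np.ndarray) -> np.ndarray:
        theta = _natural(theta_int, names)
        return model.predict_log(dict(zip(names, theta)), Ta, E, t_h) - y

    starts = [_internal(np.clip(_default_start(model), *zip(*[all_bounds[p] for p in names])), names)]
    if x0 is not None:
        starts.insert(0, _internal(np.array([x0[p] for p in names]), names))
    starts = starts[: max(n_starts, 1)]
    if n_starts > len(starts):
        sampler = qmc.LatinHypercube(d=K, seed=seed)
        draws = qmc.scale(sampler.random(n_starts - len(starts)), lb, ub)
        starts.extend(draws)

    best = None
    diagnostics = []
    for s in starts:
        try:
            res = least_squares(
                resid, np.clip(s, lb, ub), bounds=(lb, ub), method="trf",
                x_scale="jac", max_nfev=2000,
            )
        except Exception as exc:  # pragma: no cover - solver-internal failures
            diagnostics.append({"start": s, "error": str(exc)})
            continue
        diagnostics.append({"start": s, "cost": res.cost, "status": res.status})
        if res.status > 0 and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError(f"no start converged for {model.name}", diagnostics)

    theta_nat = _natural(best.x, names)
    params = dict(zip(names, theta_nat))
    residuals = best.fun
    ssr = float(residuals @ residuals)
    near_bound = np.any(
        (best.x - lb < 1e-6 * (ub - lb)) | (ub - best.x < 1e-6 * (ub - lb))
    )
    if near_bound:
        warnings.warn(
            f"{model.name}: estimate pinned at a parameter bound", stacklevel=2
        )

    # Jacobian w.r.t. natural parameters (chain rule through the log10 map)
    jac = best.jac.copy()
    for j, p in enumerate(names):
        if p in LOG_SCALE_PARAMS:
            jac[:, j] /= theta_nat[j] * math.log(10.0)

    fit = FitResult(
        model=model,
        params=params,
        ssr=ssr,
        n_obs=len(y),
        n_params=K,
        aic=compute_aic(ssr, len(y), K),
        residuals=residuals,
        converged=True,
        n_starts_used=len(starts),
        seed=seed,
        boundary_warning=bool(near_bound),
        ci95=None,
        jacobian=jac,
        data=data.reset_index(drop=True) if keep_data else None,
    )
    try:
        fit.ci95 = confidence_intervals(fit)
    except np.linalg.LinAlgError:
        fit.ci95 = None
    return fit


def compute_aic(ssr: float, n_obs: int, n_params: int, constant: str = "ssr") -> float:
    """AIC from a least-squares fit: n ln(SSR/n) + 2(K+1).

    ``constant="gaussian"`` adds n(ln 2*pi + 1); differences between models on
    the same data are identical under either convention.
    """
    if n_obs <= n_params:
        raise ValueError("need n_obs > n_params")
    if ssr <= 0:
        warnings.warn("SSR is zero; AIC is -inf", stacklevel=2)
        return -math.inf
    aic = n_obs * math.log(ssr / n_obs) + 2 * (n_params + 1)
    if constant == "gaussian":
        aic += n_obs * (math.log(2 * math.pi) + 1.0)
    elif constant != "ssr":
        raise ValueError(f"unknown AIC constant convention {constant!r}")
    return aic


def akaike_weights(aics: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """AIC differences Delta_i = AIC_i - min AIC and Akaike weights."""
    aics = np.asarray(aics, dtype=float)
    if aics.size < 2:
        raise ValueError("need at least two AIC values")
    delta = aics - np.min(aics)
    rel = np.exp(-delta / 2.0)
    return delta, rel / rel.sum()


def compare_models(fits: Sequence[FitResult]) -> ModelComparison:
    """Rank fits of the same data by AIC; ties go to fewer parameters."""
    ns = {f.n_obs for f in fits}
    if len(ns) != 1:
        raise ValueError("fits must be on identical data")
    delta, weights = akaike_weights([f.aic for f in fits])
    order = sorted(range(len(fits)), key=lambda i: (fits[i].aic, fits[i].n_params))
    return ModelComparison(
        fits=list(fits),
        delta={f.model.name: float(d) for f, d in zip(fits, delta)},
        weights={f.model.name: float(w) for f, w in zip(fits, weights)},
        best=fits[order[0]].model.name,
    )


def nested_f_test(fit_reduced: FitResult, fit_full: FitResult):
    """F-test for nested least-squares fits on the same data.

    F = ((SSR_r - SSR_f)/(K_f - K_r)) / (SSR_f/(n - K_f)), with p from the
    F(K_f - K_r, n - K_f) distribution.
    """
    if fit_reduced.n_obs != fit_full.n_obs:
        raise ValueError("fits must be on the same data")
    df1 = fit_full.n_params - fit_reduced.n_params
    if df1 <= 0:
        raise ValueError("full model must have more parameters than reduced")
    if fit_reduced.ssr < fit_full.ssr - 1e-9 * fit_full.ssr:
        raise ValueError("reduced SSR below full SSR: full-model optimizer failed")
    df2 = fit_full.n_obs - fit_full.n_params
    num = max(fit_reduced.ssr - fit_full.ssr, 0.0) / df1
    den = fit_full.ssr / df2
    F = num / den
    return F, (df1, df2), float(stats.f.sf(F, df1, df2))


def nested_lr_test(fit_reduced: FitResult, fit_full: FitResult):
    """Likelihood-ratio chi-square for the same nested comparison.

    chi2 = n ln(SSR_r/SSR_f) on K_f - K_r degrees of freedom (Gaussian errors).
    """
    if fit_reduced.n_obs != fit_full.n_obs:
        raise ValueError("fits must be on the same data")
    df = fit_full.n_params - fit_reduced.n_params
    chi2 = fit_full.n_obs * math.log(max(fit_reduced.ssr, 1e-300) / fit_full.ssr)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def lack_of_fit_test(fit: FitResult, data: pd.DataFrame | None = None):
    """Lack-of-fit F-test against pure replicate error.

    Groups observations by unique (Ta, E, t) condition, decomposes the fit's
    SSR into pure error (within-group scatter about group means) and lack of
    fit, and returns F = (SS_lof/df_lof)/(SS_pe/df_pe) with
    df_lof = G - K and df_pe = n - G for G groups.
    """
    if data is None:
        data = fit.data
    if data is None:
        raise ValueError("fit carries no data; pass the fitted measurements")
    y = np.log(data["b16_measured"].to_numpy(dtype=float))
    groups = data.groupby(["b16_desired", "otl_conc", "time_h"], sort=False)
    if not (groups.size() > 1).any():
        raise ValueError("lack-of-fit test needs at least one replicated condition")
    group_mean = groups["b16_measured"].transform(lambda s: np.mean(np.log(s)))
    ss_pe = float(np.sum((y - group_mean.to_numpy()) ** 2))
    G = groups.ngroups
    df_pe = fit.n_obs - G
    df_lof = G - fit.n_params
    if df_lof <= 0 or df_pe <= 0:
        raise ValueError("not enough groups/replicates for the lack-of-fit test")
    ss_lof = max(fit.ssr - ss_pe, 0.0)
    F = (ss_lof / df_lof) / (ss_pe / df_pe)
    return F, (df_lof, df_pe), float(stats.f.sf(F, df_lof, df_pe))


def residual_diagnostics(fit: FitResult) -> dict:
    """Shapiro-Wilk normality check and residual summaries on ln scale."""
    r = np.asarray(fit.residuals, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 residuals")
    out: dict = {"n": int(r.size), "mean": float(r.mean()), "sd": float(r.std(ddof=1))}
    if np.ptp(r) == 0:
        out.update({"shapiro_w": math.nan, "shapiro_p": math.nan, "degenerate": True})
    else:
        w, p = stats.shapiro(r)
        out.update({"shapiro_w": float(w), "shapiro_p": float(p), "degenerate": False})
    if fit.data is not None:
        df = fit.data.assign(residual=r)
        out["by_time"] = df.groupby("time_h")["residual"].mean()
        out["by_condition"] = df.groupby(["b16_desired", "otl_conc"])["residual"].mean()
    return out


def confidence_intervals(
    fit: FitResult,
    method: str = "linearized",
    n_boot: int = 200,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """95% confidence intervals for the fitted parameters.

    ``linearized`` (default): t intervals from the Jacobian at the optimum,
    est +- t(0.975, n-K) * se with se from SSR/(n-K) * diag((J'J)^-1).
    ``bootstrap``: resample ln-scale residuals, refit from the estimate, take
    the percentile interval — for when the curvature is singular or the
    linearization is suspect.
    """
    names = fit.model.parameter_names
    if method == "linearized":
        if fit.jacobian is None:
            raise ValueError("fit carries no Jacobian")
        J = fit.jacobian
        dof = fit.n_obs - fit.n_params
        sigma2 = fit.ssr / dof
        cov = sigma2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        tq = stats.t.ppf(0.975, dof)
        est = np.array([fit.params[p] for p in names])
        return {p: (float(e - tq * s), float(e + tq * s)) for p, e, s in zip(names, est, se)}
    if method == "bootstrap":
        if fit.data is None:
            raise ValueError("bootstrap CIs need the fitted data on the FitResult")
        rng = np.random.default_rng(seed)
        yhat = np.log(fit.data["b16_measured"].to_numpy(dtype=float)) - fit.residuals
        samples = {p: [] for p in names}
        for _ in range(n_boot):
            boot = fit.data.copy()
            boot["b16_measured"] = np.exp(
                yhat + rng.choice(fit.residuals, size=fit.n_obs, replace=True)
            )
            bf = fit_model(
                boot, fit.model, n_starts=1, seed=seed, x0=fit.params, keep_data=False
            )
            for p in names:
                samples[p].append(bf.params[p])
        return {
            p: tuple(np.percentile(samples[p], [2.5, 97.5]).tolist()) for p in names
        }
    raise ValueError(f"unknown CI method {method!r}")
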