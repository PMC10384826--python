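"""Growth/killing models for B16 tumor cells co-inoculated with CTLs.

All models share the skeleton

    dT/dt = (fg(E) - fk(E)) T,    T(0) = Ta / alpha,

where T is the tumor concentration (cell/mL), Ta the desired inoculum,
1/alpha the effective recovery fraction of the counting assay, E the CTL
concentration (cell/mL), fg the per-capita growth rate and fk the per-capita
kill rate (both per day). With E constant the log solution is linear in time,

    ln T(t) = ln(Ta/alpha) + (fg(E) - fk(E)) t,

so each closed-form model is fully specified by its (fg, fk) pair:

================  =======================  =====================
model             fg(E)                    fk(E)
================  =======================  =====================
EG                r                        0
MA                r                        k E
Sat               r                        k E / (h + E)
Power             r                        k E^n
SiGMA             g0 + g1/(1 + E/g2)       k E
SiGMA_ratio       g0 + g1/(1 + E/g2)       k E/(1 + a1 T + a2 E)
================  =======================  =====================

SiGMA is "suppression-in-growth with mass-action killing": CTLs reduce the
tumor growth rate non-lytically (half effect at E = g2) in addition to killing
at rate kE; the CTL-free growth rate is the derived quantity r = g0 + g1.
SiGMA_ratio makes killing ratio-dependent, so its solution requires numerical
integration. Two further forms describe CTL-free early dynamics that is not a
single exponential: Alt1 integrates an algebraic-sigmoid per-capita rate that
switches from negative to positive around time t' (days),

    ln T(t) = ln(Ta/alpha) + r (sqrt(1 + (t - t')^2) - sqrt(1 + t'^2)),

and Alt2 splits the inoculum into a dying fraction fd (rate d) and a growing
remainder,

    T(t) = (Ta/alpha) (fd e^{-d t} + (1 - fd) e^{r t}).

``EG_vr`` fits one growth rate per desired-concentration level (density-
dependent growth); ``*_var_alpha`` variants fit one alpha per level.

Internal rate units are per day; every public time argument is hours and is
converted with :data:`HOURS_PER_DAY` in exactly one place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

#: Hours-to-days conversion, fixed in one place.
HOURS_PER_DAY = 24.0

LN10 = math.log(10.0)

#: Sentinel for "the tumor population is never reduced 90% at this E".
NEVER = math.inf

CLOSED_FORM = ("EG", "MA", "Sat", "Power", "SiGMA", "Alt1", "Alt2")


class UnsupportedModelError(ValueError):
    """Operation not defined for this model form."""


def _bounds_for(name: str) -> tuple[float, float]:
    """Default fitting bounds per parameter name (natural scale)."""
    if name.startswith("alpha"):
        return (1.0, 20.0)
    if name in ("k", "h", "g2", "a1", "a2"):
        return (1e-12, 1e12)
    if name == "n":
        return (0.05, 5.0)
    if name == "fd":
        return (0.0, 1.0)
    if name == "tprime":
        return (0.0, 4.0)
    if name == "d":
        return (0.0, 10.0)
    if name.startswith("r"):
        # growth rates may be negative (density-dependent fits find declining
        # high-inoculum conditions)
        return (-5.0, 10.0)
    if name in ("g0", "g1"):
        return (0.0, 10.0)
    raise KeyError(name)


#: Parameters optimized on log10 scale (ranges span many orders of magnitude).
LOG_SCALE_PARAMS = frozenset({"k", "h", "g2", "a1", "a2"})


@dataclass(frozen=True)
class Model:
    """An evaluable model form.

    ``ta_levels`` is only used by the per-level variants (``EG_vr`` and
    ``*_var_alpha``): it fixes the ordered desired-concentration levels that
    index the per-level parameters.
    """

    name: str
    base: str  # family providing fg/fk: EG, MA, Sat, Power, SiGMA, Alt1, Alt2, SiGMA_ratio
    parameter_names: tuple[str, ...]
    var_alpha: bool = False
    var_r: bool = False
    ta_levels: tuple[float, ...] = ()
    alt1_raw: bool = False

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)

    @property
    def uses_numerical_integration(self) -> bool:
        return self.base == "SiGMA_ratio"

    @property
    def bounds(self) -> dict[str, tuple[float, float]]:
        return {p: _bounds_for(p) for p in self.parameter_names}

    # -- parameter plumbing -------------------------------------------------

    def validate_params(self, params: Mapping[str, float]) -> dict[str, float]:
        """Check completeness and positivity/interval constraints."""
        out = {}
        for p in self.parameter_names:
            if p not in params:
                raise ValueError(f"model {self.name}: missing parameter {p!r}")
            v = float(params[p])
            if p.startswith("alpha") and not v > 0:
                raise ValueError(f"{p} must be > 0")
            if p in ("h", "g2", "n") and not v > 0:
                raise ValueError(f"{p} must be > 0")
            if p in ("k", "d", "a1", "a2") and v < 0:
                raise ValueError(f"{p} must be >= 0")
            if p == "fd" and not (0.0 <= v <= 1.0):
                raise ValueError("fd must lie in [0, 1]")
            out[p] = v
        return out

    def _alpha(self, params: Mapping[str, float], Ta) -> np.ndarray:
        """Alpha per observation (per-level alphas for var_alpha variants)."""
        Ta = np.asarray(Ta, dtype=float)
        if not self.var_alpha:
            return np.full_like(Ta, float(params["alpha"]))
        alphas = np.array([params[f"alpha_{i+1}"] for i in range(len(self.ta_levels))])
        return alphas[self._level_index(Ta)]

    def _level_index(self, Ta: np.ndarray) -> np.ndarray:
        levels = np.asarray(self.ta_levels, dtype=float)
        idx = np.searchsorted(levels, Ta)
        idx = np.clip(idx, 0, len(levels) - 1)
        if not np.allclose(levels[idx], Ta, rtol=1e-6):
            raise ValueError("desired concentration not among the model's ta_levels")
        return idx

    # -- rate functions -----------------------------------------------------

    def growth_rate(self, params: Mapping[str, float], E, Ta=None):
        """Per-capita growth rate fg(E) in 1/day."""
        E = np.asarray(E, dtype=float)
        if np.any(E < 0):
            raise ValueError("CTL concentration must be >= 0")
        if self.base in ("SiGMA", "SiGMA_ratio"):
            return params["g0"] + params["g1"] / (1.0 + E / params["g2"])
        if self.base in ("MA", "Sat", "Power", "EG"):
            if self.var_r:
                if Ta is None:
                    raise ValueError("per-level growth rates require Ta")
                rs = np.array([params[f"r_{i+1}"] for i in range(len(self.ta_levels))])
                return rs[self._level_index(np.asarray(Ta, dtype=float))] + 0.0 * E
            return np.full_like(E, float(params["r"]))
        raise UnsupportedModelError(
            f"{self.name} has no CTL-independent per-capita growth rate (time-dependent form)"
        )

    def kill_rate(self, params: Mapping[str, float], E, T=None):
        """Per-capita kill rate fk(E) in 1/day (fk(E, T) for SiGMA_ratio)."""
        E = np.asarray(E, dtype=float)
        if np.any(E < 0):
            raise ValueError("CTL concentration must be >= 0")
        if self.base in ("MA", "SiGMA"):
            return params["k"] * E
        if self.base == "Sat":
            return params["k"] * E / (params["h"] + E)
        if self.base == "Power":
            return np.where(E > 0, params["k"] * np.power(np.maximum(E, 1e-300), params["n"]), 0.0)
        if self.base == "EG":
            return np.zeros_like(E)
        if self.base == "SiGMA_ratio":
            if T is None:
                raise ValueError("SiGMA_ratio kill rate depends on the tumor concentration T")
            T = np.asarray(T, dtype=float)
            return params["k"] * E / (1.0 + params["a1"] * T + params["a2"] * E)
        raise UnsupportedModelError(f"{self.name} has no static kill rate")

    # -- solution -----------------------------------------------------------

    def predict_log(self, params: Mapping[str, float], Ta, E, time_h):
        """Natural log of the predicted tumor concentration.

        ``time_h`` is hours since inoculation (converted to days internally).
        Inputs broadcast like numpy arrays.
        """
        Ta, E, time_h = np.broadcast_arrays(
            np.asarray(Ta, dtype=float),
            np.asarray(E, dtype=float),
            np.asarray(time_h, dtype=float),
        )
        if np.any(time_h < 0):
            raise ValueError("time must be >= 0")
        t = time_h / HOURS_PER_DAY
        ln0 = np.log(Ta) - np.log(self._alpha(params, Ta))
        if self.base == "Alt1":
            tp = params["tprime"]
            r = params["r"]
            if self.alt1_raw:
                # literal algebraic-sigmoid primitive without re-zeroing at t=0
                return ln0 + r * np.sqrt(1.0 + (t - tp) ** 2)
            return ln0 + r * (np.sqrt(1.0 + (t - tp) ** 2) - math.sqrt(1.0 + tp**2))
        if self.base == "Alt2":
            fd, d, r = params["fd"], params["d"], params["r"]
            with np.errstate(divide="ignore"):
                dying = np.log(fd) - d * t if fd > 0 else np.full_like(t, -np.inf)
                growing = np.log(1.0 - fd) + r * t if fd < 1 else np.full_like(t, -np.inf)
            return ln0 + np.logaddexp(dying, growing)
        if self.base == "SiGMA_ratio":
            return self._integrate_log(params, Ta, E, t, ln0)
        fg = self.growth_rate(params, E, Ta=Ta)
        fk = self.kill_rate(params, E)
        return ln0 + (fg - fk) * t

    def _integrate_log(self, params, Ta, E, t_days, ln0):
        """Numerically integrate the ratio-dependent killing ODE per condition."""
        out = np.empty_like(t_days)
        flat_Ta, flat_E, flat_t = Ta.ravel(), E.ravel(), t_days.ravel()
        flat_ln0, flat_out = ln0.ravel(), out.ravel()
        g0, g1, g2, k, a1, a2 = (params[p] for p in ("g0", "g1", "g2", "k", "a1", "a2"))
        conditions = {}
        for i in range(flat_t.size):
            conditions.setdefault((flat_Ta[i], flat_E[i]), []).append(i)
        for (ta, e), idx in conditions.items():
            idx = np.asarray(idx)
            t0 = math.exp(flat_ln0[idx[0]])
            fg = g0 + g1 / (1.0 + e / g2)

            def rhs(_t, y):
                return fg * y - k * e * y / (1.0 + a1 * y + a2 * e)

            ts = flat_t[idx]
            order = np.argsort(ts)
            t_eval = np.unique(ts[order])
            t_end = max(float(t_eval[-1]), 1e-12)
            sol = solve_ivp(
                rhs,
                (0.0, t_end),
                [t0],
                t_eval=np.clip(t_eval, 0.0, t_end),
                method="LSODA",
                rtol=1e-8,
                atol=1e-12 * max(t0, 1.0),
            )
            if not sol.success:
                raise RuntimeError(
                    f"ODE integration failed for condition Ta={ta}, E={e}: {sol.message}"
                )
            lookup = dict(zip(sol.t, sol.y[0]))
            for i in idx:
                flat_out[i] = math.log(max(lookup[flat_t[i]], 1e-300))
        return out


_BASE_PARAMS = {
    "EG": ("alpha", "r"),
    "MA": ("alpha", "r", "k"),
    "Sat": ("alpha", "r", "k", "h"),
    "Power": ("alpha", "r", "k", "n"),
    "SiGMA": ("alpha", "g0", "g1", "g2", "k"),
    "Alt1": ("alpha", "r", "tprime"),
    "Alt2": ("alpha", "fd", "d", "r"),
    "SiGMA_ratio": ("alpha", "g0", "g1", "g2", "k", "a1", "a2"),
}


def get_model(
    name: str,
    ta_levels: Sequence[float] = (),
    alt1_raw: bool = False,
) -> Model:
    """Build a :class:`Model` by name.

    Names: ``EG, MA, Sat, Power, SiGMA, Alt1, Alt2, SiGMA_ratio``, plus
    ``EG_vr`` (per-level growth rates) and ``<base>_var_alpha`` (per-level
    alphas); the per-level variants require ``ta_levels``, the sorted desired
    B16 concentrations present in the data.
    """
    var_alpha = name.endswith("_var_alpha")
    var_r = name == "EG_vr"
    base = name.removesuffix("_var_alpha")
    if var_r:
        base = "EG"
    if base not in _BASE_PARAMS:
        raise KeyError(f"unknown model {name!r}")
    if (var_alpha or var_r) and not ta_levels:
        raise ValueError(f"model {name} requires ta_levels")
    levels = tuple(sorted(float(x) for x in ta_levels))
    params = list(_BASE_PARAMS[base])
    if var_alpha:
        params.remove("alpha")
        params = [f"alpha_{i+1}" for i in range(len(levels))] + params
    if var_r:
        params.remove("r")
        params = params + [f"r_{i+1}" for i in range(len(levels))]
    return Model(
        name=name,
        base=base,
        parameter_names=tuple(params),
        var_alpha=var_alpha,
        var_r=var_r,
        ta_levels=levels,
        alt1_raw=alt1_raw,
    )


# -- module-level functional surface ---------------------------------------


def growth_rate(model: Model, params: Mapping[str, float], E, Ta=None):
    """fg(E), per day. See :meth:`Model.growth_rate`."""
    return model.growth_rate(model.validate_params(params), E, Ta=Ta)


def kill_rate(model: Model, params: Mapping[str, float], E, T=None):
    """fk(E), per day. See :meth:`Model.kill_rate`."""
    return model.kill_rate(model.validate_params(params), E, T=T)


def log_prediction(model: Model, params: Mapping[str, float], Ta, E, time_h):
    """ln of the predicted tumor concentration at ``time_h`` hours."""
    return model.predict_log(model.validate_params(params), Ta, E, time_h)


def t90(model: Model, params: Mapping[str, float], E):
    """Days to kill 90% of initially present targets at CTL concentration E.

    t90 = ln(10) / (fk(E) - fg(E)); where killing does not exceed growth the
    population is never reduced 90% and :data:`NEVER` (inf) is returned.
    """
    params = model.validate_params(params)
    net = np.asarray(model.kill_rate(params, E) - model.growth_rate(params, E), dtype=float)
    out = np.where(net > 0, LN10 / np.where(net > 0, net, 1.0), NEVER)
    return out if out.ndim else float(out)


def control_concentration(
    model: Model,
    params: Mapping[str, float],
    horizon_days: float = 100.0,
    bracket: tuple[float, float] = (0.0, 1e9),
    rtol: float = 1e-6,
) -> float:
    """Smallest CTL concentration eliminating >=90% of tumors within a horizon.

    Solves fk(E) - fg(E) = ln(10)/horizon by bisection on ``bracket`` (with
    automatic upward expansion); returns ``inf`` when killing saturates below
    the requirement (e.g. the saturated-killing model with k too small).
    Raises if the net rate is not monotone increasing over the bracket.
    """
    if horizon_days <= 0:
        raise ValueError("horizon must be > 0")
    p = model.validate_params(params)
    target = LN10 / horizon_days

    def net(E):
        return float(model.kill_rate(p, E) - model.growth_rate(p, E)) - target

    lo, hi = bracket
    grid = np.geomspace(max(lo, 1.0), hi, 200)
    vals = np.array([net(e) for e in grid])
    if np.any(np.diff(vals) < -1e-9 * np.maximum(np.abs(vals[:-1]), 1.0)):
        raise ValueError(
            "net kill rate is not monotone increasing in E over the bracket; "
            "use a grid search instead"
        )
    for _ in range(6):  # bracket expansion
        if net(hi) >= 0:
            break
        hi *= 10.0
    else:
        return math.inf
    if net(lo) >= 0:
        return lo
    return brentq(net, lo, hi, rtol=rtol)


def efficacy_metrics(
    model: Model,
    params: Mapping[str, float],
    E_grid: Sequence[float],
    Ta_list: Sequence[float] = (1e4, 1e5, 1e6),
):
    """Tabulate CTL-efficacy metrics over a grid of CTL concentrations.

    Per E: the growth rate fg(E), kill rate fk(E), per-capita kill rate
    fk(E)/E; and per (E, Ta): the number of tumor cells killed per day over
    the first 24 h, computed as the difference between growth-only and full
    model predictions at 24 h, plus the same per CTL. Returns a tidy
    DataFrame with one row per (E, Ta).
    """
    import pandas as pd

    p = model.validate_params(params)
    rows = []
    for E in E_grid:
        fg = float(model.growth_rate(p, E))
        fk = float(model.kill_rate(p, E))
        fk_per_E = fk / E if E > 0 else math.nan
        for Ta in Ta_list:
            T0 = Ta / float(model._alpha(p, np.asarray([Ta]))[0])
            growth_only = T0 * math.exp(fg * 1.0)
            with_killing = math.exp(float(model.predict_log(p, Ta, E, HOURS_PER_DAY)))
            killed = growth_only - with_killing
            rows.append(
                {
                    "E": E,
                    "Ta": Ta,
                    "fg_per_day": fg,
                    "fk_per_day": fk,
                    "fk_per_E": fk_per_E,
                    "killed_per_day_24h": killed,
                    "killed_per_day_per_ctl_24h": killed / E if E > 0 else 0.0,
                }
            )
    return pd.DataFrame(rows)


#: Best-fit parameters from the original collagen-fibrin gel study
#: (Datasets 1-4, CTL concentrations <= 1e7 cell/mL, 431 gels). Units:
#: alpha dimensionless; r, g0, g1 per day; g2, h cell/mL; k model-specific
#: (MA/SiGMA per (cell/mL)/day, Sat per day, Power per (cell/mL)^n/day).
STUDY_PARAMS: dict[str, dict[str, float]] = {
    "MA": {"alpha": 2.77, "r": 0.576, "k": 3.79e-7},
    "Sat": {"alpha": 2.81, "r": 0.744, "k": 6.0, "h": 5.34e6},
    "Power": {"alpha": 2.79, "r": 0.744, "k": 2.23e-4, "n": 0.606},
    "SiGMA": {"alpha": 2.71, "g0": 0.12, "g1": 0.64, "g2": 6715.0, "k": 3.29e-7},
}
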