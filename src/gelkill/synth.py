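"""Synthetic gel-experiment generator with the study's statistical structure.

A :class:`DesignSpec` is a grid of (desired B16 concentration, CTL
concentration) conditions crossed with measurement times and replicates.
Data are generated by evaluating a ground-truth model's log prediction on
each design cell and adding ln-scale measurement error, either drawn from a
pool of observed residuals (errors resampled with replacement, independently
per observation) or Gaussian. The built-in designs replicate both the five
historical gel datasets (no-CTL growth; short- and long-term killing; dense
early sampling; one high-CTL-density experiment) and the six hypothetical
designs (D1-D3, Types A/B) evaluated by the power analysis.

The Gaussian surrogate scale :data:`STUDY_LOG_SD` = 0.51 is the root mean
square ln-scale residual of the best 431-gel fit (SSR 112 over 431 gels); it
makes the whole power pipeline runnable without any measured residual pool
and is labeled as a synthetic surrogate wherever it is used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from gelkill.gel_data import COLUMNS
from gelkill.models import Model, STUDY_PARAMS, get_model

__all__ = [
    "DesignSpec",
    "NoiseModel",
    "builtin_designs",
    "build_residual_pool",
    "generate_dataset",
    "generate_study_replica",
    "STUDY_LOG_SD",
]

#: ln-scale SD matching the scatter of the historical 431-gel fit
#: (sqrt(112/431) ~ 0.51); a synthetic Gaussian surrogate for the residual pool.
STUDY_LOG_SD = math.sqrt(112.0 / 431.0)


@dataclass(frozen=True)
class DesignSpec:
    """A gel experiment layout: conditions x time points x replicates.

    ``n_target`` trims the full grid down to a stated observation count
    (the historical datasets lost a few gels to handling); surplus rows are
    dropped at evenly spaced grid positions, deterministically.
    """

    name: str
    conditions: tuple[tuple[float, float], ...]  # (Ta, E) cell/mL
    time_points_h: tuple[float, ...]
    replicates: int = 1
    n_target: int | None = None
    dataset_id: int = 1

    @property
    def total_observations(self) -> int:
        full = len(self.conditions) * len(self.time_points_h) * self.replicates
        return full if self.n_target is None else min(full, self.n_target)

    def grid(self) -> pd.DataFrame:
        """The design grid as rows (before noise), with experiment/replicate ids.

        Replicates cycle through three experimental repeats of duplicate gels,
        mirroring the historical protocol.
        """
        rows = []
        for ta, e in self.conditions:
            for t in self.time_points_h:
                for rep in range(self.replicates):
                    rows.append(
                        (
                            self.dataset_id,
                            (rep // 2) % 3 + 1,
                            rep + 1,
                            ta,
                            e,
                            t,
                            np.nan,
                        )
                    )
        df = pd.DataFrame(rows, columns=list(COLUMNS))
        full = len(df)
        if self.n_target is not None and self.n_target < full:
            surplus = full - self.n_target
            drop = np.unique(np.round(np.linspace(0, full - 1, surplus)).astype(int))
            # np.linspace may collide after rounding; extend from the tail
            extra = [i for i in range(full - 1, -1, -1) if i not in set(drop)]
            drop = np.sort(np.concatenate([drop, extra[: surplus - drop.size]]))
            df = df.drop(index=drop).reset_index(drop=True)
        return df

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "conditions": [list(c) for c in self.conditions],
            "time_points_h": list(self.time_points_h),
            "replicates": self.replicates,
            "n_target": self.n_target,
            "dataset_id": self.dataset_id,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DesignSpec":
        return cls(
            name=d["name"],
            conditions=tuple((float(a), float(b)) for a, b in d["conditions"]),
            time_points_h=tuple(float(t) for t in d["time_points_h"]),
            replicates=int(d.get("replicates", 1)),
            n_target=d.get("n_target"),
            dataset_id=int(d.get("dataset_id", 1)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "DesignSpec":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class NoiseModel:
    """Ln-scale measurement error: residual resampling, Gaussian, or none.

    ``zero_inflation_prob`` is the probability a gel reads zero cells
    (below the detection limit), off by default.
    """

    kind: str = "gaussian"
    pool: tuple[float, ...] | None = None
    sigma: float | None = None
    zero_inflation_prob: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("residual_pool", "gaussian", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind == "residual_pool" and not self.pool:
            raise ValueError("residual_pool noise requires a non-empty pool")
        if self.kind == "gaussian" and (self.sigma is None or self.sigma < 0):
            raise ValueError("gaussian noise requires sigma >= 0")
        if not (0.0 <= self.zero_inflation_prob <= 1.0):
            raise ValueError("zero_inflation_prob must lie in [0, 1]")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return np.zeros(n)
        if self.kind == "gaussian":
            return rng.normal(0.0, self.sigma, size=n)
        return rng.choice(np.asarray(self.pool, dtype=float), size=n, replace=True)


def study_noise() -> NoiseModel:
    """Gaussian surrogate noise at the study-scale ln SD (synthetic stand-in
    for the measured residual pool)."""
    return NoiseModel(kind="gaussian", sigma=STUDY_LOG_SD)


def _grid(tas, es):
    return tuple((float(ta), float(e)) for ta in tas for e in es)


def builtin_designs() -> dict[str, DesignSpec]:
    """Named built-in designs.

    ``D1-A`` .. ``D3-B``: the six hypothetical designs compared by the power
    analysis (48 or 40 observations each). ``dataset1`` .. ``dataset5``:
    replicas of the historical gel experiments, trimmed to their recorded
    non-zero gel counts (70, 175, 96, 90, 7).
    """
    designs = {
        "D1-A": DesignSpec(
            "D1-A",
            _grid([1e3, 1e4, 1e5, 1e6, 1e7, 1e8], [0, 1e5, 1e6, 1e7]),
            (0.0, 24.0),
        ),
        "D1-B": DesignSpec(
            "D1-B",
            _grid([1e5, 1e6, 1e7], [0, 1e5, 1e6, 1e7]),
            (0.0, 24.0, 48.0, 72.0),
        ),
        "D2-A": DesignSpec(
            "D2-A",
            _grid([1e5, 1e6, 1e7], [0, 1e5, 1e6, 1e7]),
            (0.0, 8.0, 16.0, 24.0),
        ),
        "D2-B": DesignSpec(
            "D2-B",
            _grid([1e5, 1e6, 1e7], [0, 1e5, 1e6, 1e7]),
            (0.0, 24.0, 48.0, 72.0),
        ),
        "D3-A": DesignSpec(
            "D3-A",
            _grid([1e5, 1e6], [0, 5e5, 1e6, 5e6, 1e7]),
            (0.0, 24.0, 48.0, 72.0),
        ),
        "D3-B": DesignSpec(
            "D3-B",
            _grid([1e5, 1e6], [0, 1e4, 1e5, 1e6, 1e7]),
            (0.0, 24.0, 48.0, 72.0),
        ),
        "dataset1": DesignSpec(
            "dataset1",
            _grid([1e3, 1e4, 1e5], [0]),
            (0.0, 24.0, 48.0, 72.0),
            replicates=6,
            n_target=70,
            dataset_id=1,
        ),
        "dataset2": DesignSpec(
            "dataset2",
            _grid([1e4, 1e5, 1e6], [0, 1e4, 1e5, 1e6, 1e7]),
            (0.0, 24.0),
            replicates=6,
            n_target=175,
            dataset_id=2,
        ),
        "dataset3": DesignSpec(
            "dataset3",
            _grid([1e6], [0, 1e6, 1e7]),
            (0.0, 24.0, 48.0, 72.0, 96.0),
            replicates=7,
            n_target=96,
            dataset_id=3,
        ),
        "dataset4": DesignSpec(
            "dataset4",
            _grid([1e5], [0, 1e6, 1e7]),
            (0.0, 4.0, 8.0, 12.0, 24.0),
            replicates=6,
            n_target=90,
            dataset_id=4,
        ),
        "dataset5": DesignSpec(
            "dataset5",
            _grid([1e5], [1e8]),
            (0.0, 24.0),
            replicates=4,
            n_target=7,
            dataset_id=5,
        ),
    }
    return designs


def build_residual_pool(data: pd.DataFrame) -> np.ndarray:
    """Ln-scale residuals about per-(condition, time) group means.

    This is the empirical error pool used for residual-resampling noise:
    y_i - mean(y) within each (Ta, E, t) group, on the natural-log scale.
    Singleton groups contribute only zero residuals and are dropped with a
    warning. The pool mean is zero by construction.
    """
    if np.any(data["b16_measured"] <= 0):
        raise ValueError("residual pool needs positive counts; filter zeros first")
    pool = []
    n_singleton = 0
    for _, grp in data.groupby(["b16_desired", "otl_conc", "time_h"]):
        if len(grp) < 2:
            n_singleton += 1
            continue
        y = np.log(grp["b16_measured"].to_numpy(dtype=float))
        pool.append(y - y.mean())
    if n_singleton:
        warnings.warn(
            f"{n_singleton} singleton condition groups contribute no residuals",
            stacklevel=2,
        )
    if not pool:
        raise ValueError("no replicated groups; cannot build a residual pool")
    return np.concatenate(pool)


def generate_dataset(
    design: DesignSpec,
    model: Model,
    params: Mapping[str, float],
    noise: NoiseModel,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate one gel experiment: model surface + ln-scale error.

    For every design cell, ln T = model log prediction + sampled error,
    exponentiated back to cell/mL; with ``zero_inflation_prob`` > 0 a draw is
    replaced by a zero count (below-detection gel) with that probability.
    Deterministic given the seed.
    """
    if seed is None:
        seed = noise.seed
    if seed is None:
        raise ValueError("a seed is required (either argument or NoiseModel.seed)")
    rng = np.random.default_rng(seed)
    df = design.grid()
    p = model.validate_params(params)
    ln_pred = model.predict_log(
        p,
        df["b16_desired"].to_numpy(dtype=float),
        df["otl_conc"].to_numpy(dtype=float),
        df["time_h"].to_numpy(dtype=float),
    )
    df["b16_measured"] = np.exp(ln_pred + noise.draw(len(df), rng))
    if noise.zero_inflation_prob > 0:
        zero = rng.random(len(df)) < noise.zero_inflation_prob
        df.loc[zero, "b16_measured"] = 0.0
    return df


def generate_study_replica(
    seed: int,
    datasets: Sequence[int] = (1, 2, 3, 4, 5),
    model: Model | None = None,
    params: Mapping[str, float] | None = None,
    noise: NoiseModel | None = None,
    n_zero_gels: int = 13,
) -> pd.DataFrame:
    """A synthetic replica of the five historical gel datasets.

    Generates the requested dataset designs from a ground-truth model
    (default: the suppression-in-growth model at its historical best-fit
    parameters, with Gaussian surrogate noise at the study ln-scale SD) and
    appends ``n_zero_gels`` zero-count gels in high-CTL conditions of the
    killing datasets, mirroring the 13 below-detection gels recorded among
    the 451 historical measurements. The default full replica therefore has
    438 positive-count rows (70+175+96+90+7) plus the zero gels.
    """
    model = model or get_model("SiGMA")
    params = params or STUDY_PARAMS[model.name]
    noise = noise or study_noise()
    designs = builtin_designs()
    rng = np.random.default_rng(seed)
    frames = []
    for ds in datasets:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        frames.append(
            generate_dataset(designs[f"dataset{ds}"], model, params, noise, seed=sub_seed)
        )
    df = pd.concat(frames, ignore_index=True)
    killing = df[(df["otl_conc"] >= 1e6) & (df["time_h"] > 0) & df["dataset"].isin([2, 3])]
    if n_zero_gels > 0 and len(killing) > 0:
        picks = killing.sample(
            n=min(n_zero_gels, len(killing)), random_state=int(rng.integers(0, 2**31 - 1))
        )
        zeros = picks.copy()
        zeros["b16_measured"] = 0.0
        zeros["replicate"] = zeros["replicate"] + 100  # distinct gel ids
        df = pd.concat([df, zeros], ignore_index=True)
    return df.reset_index(drop=True)
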