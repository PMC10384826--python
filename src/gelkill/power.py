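"""Simulation-based power analysis for choosing gel experiment designs.

For a candidate design, data are repeatedly simulated from each of the three
distinguishable models (Sat, Power, SiGMA — mass-action is a special case of
all three and is excluded), all three models are fit to every replicate, and
the best model by Akaike weight is tallied. The result is a 3x3
model-recovery matrix whose column j gives the fraction of replicates in
which each model won when model j generated the data; columns sum to one, and
a design that discriminates well has a heavy diagonal.

Two designs A and B are compared through the determinants of their recovery
matrices with the statistic

    |Delta D| = | |det(A)| - |det(B)| |,

the difference in volume of the parallelepipeds spanned by the matrix
columns. Significance is assessed two ways: against a universal null of
random column-stochastic matrices (each column uniform on the probability
simplex), and by a permutation test that re-assigns the six observed columns
between two pseudo-designs. Exceedance is counted with >= so that an observed
statistic of zero yields p = 1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from gelkill.fitting import FitError, compare_models, fit_model
from gelkill.models import STUDY_PARAMS, get_model
from gelkill.synth import DesignSpec, NoiseModel, generate_dataset, study_noise

__all__ = [
    "WeightMatrix",
    "DesignComparisonResult",
    "weight_matrix",
    "delta_D",
    "null_distribution_test",
    "permutation_test",
    "compare_designs",
]

DEFAULT_MODELS = ("Sat", "Power", "SiGMA")


@dataclass
class WeightMatrix:
    """Model-recovery matrix for one design.

    ``entries[i, j]`` is the fraction of replicates in which fitted model i
    was best when generator model j produced the data. Columns sum to 1.
    """

    generator_models: tuple[str, ...]
    fitted_models: tuple[str, ...]
    entries: np.ndarray  # (fitted, generator)
    n_replicates: int
    design: DesignSpec
    seed: int
    n_failures: int = 0

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        if entries.shape != (len(self.fitted_models), len(self.generator_models)):
            raise ValueError("entries shape does not match model lists")
        if np.any(entries < -1e-12) or np.any(entries > 1 + 1e-12):
            raise ValueError("entries must lie in [0, 1]")
        colsums = entries.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-12):
            raise ValueError("each column must sum to 1")
        self.entries = entries

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.entries))


@dataclass
class DesignComparisonResult:
    """Full design comparison: matrices, |Delta D|, and both p-values."""

    matrix_A: WeightMatrix
    matrix_B: WeightMatrix
    det_A: float
    det_B: float
    delta_D_obs: float
    p_null: float
    p_perm: float
    n_null_draws: int
    seed: int

    @property
    def better_design(self) -> str:
        """The design whose matrix has the larger |det| (heavier diagonal)."""
        a, b = abs(self.det_A), abs(self.det_B)
        return self.matrix_A.design.name if a >= b else self.matrix_B.design.name


def weight_matrix(
    design: DesignSpec,
    generator_params: Mapping[str, Mapping[str, float]] | None = None,
    noise: NoiseModel | None = None,
    n_replicates: int = 100,
    seed: int = 0,
    fit_models: Sequence[str] = DEFAULT_MODELS,
    n_starts: int = 8,
) -> WeightMatrix:
    """Build the model-recovery matrix for one design.

    For each generator model, ``n_replicates`` datasets are simulated and all
    ``fit_models`` are fit to each; the winner (highest Akaike weight, ties to
    fewer parameters) is tallied into that generator's column. Replicates on
    which any fit fails are dropped and counted; more than 10% failures is an
    error. Deterministic given ``seed``.
    """
    generator_params = generator_params or {m: STUDY_PARAMS[m] for m in fit_models}
    noise = noise or study_noise()
    names = tuple(fit_models)
    models = {m: get_model(m) for m in names}
    entries = np.zeros((len(names), len(names)))
    n_failures = 0
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(len(names) * n_replicates) % (2**31 - 1)
    for j, gen_name in enumerate(names):
        tally = np.zeros(len(names))
        n_ok = 0
        for rep in range(n_replicates):
            rep_seed = int(rep_seeds[j * n_replicates + rep])
            data = generate_dataset(
                design, models[gen_name], generator_params[gen_name], noise, seed=rep_seed
            )
            try:
                fits = [
                    fit_model(data, models[m], n_starts=n_starts, seed=rep_seed, keep_data=False)
                    for m in names
                ]
            except FitError:
                n_failures += 1
                continue
            comp = compare_models(fits)
            tally[names.index(comp.best)] += 1
            n_ok += 1
        if n_ok < 0.9 * n_replicates:
            raise RuntimeError(
                f"more than 10% of replicates failed for generator {gen_name}"
            )
        entries[:, j] = tally / n_ok
    return WeightMatrix(
        generator_models=names,
        fitted_models=names,
        entries=entries,
        n_replicates=n_replicates,
        design=design,
        seed=seed,
        n_failures=n_failures,
    )


def delta_D(matrix_A: WeightMatrix | np.ndarray, matrix_B: WeightMatrix | np.ndarray) -> float:
    """|Delta D| = | |det A| - |det B| | for two recovery matrices."""
    a = matrix_A.entries if isinstance(matrix_A, WeightMatrix) else np.asarray(matrix_A)
    b = matrix_B.entries if isinstance(matrix_B, WeightMatrix) else np.asarray(matrix_B)
    return abs(abs(float(np.linalg.det(a))) - abs(float(np.linalg.det(b))))


def null_distribution_test(
    delta_D_obs: float, n_draws: int = 100_000, seed: int = 0
) -> float:
    """p-value of |Delta D| against random column-stochastic matrix pairs.

    Draws pairs of 3x3 matrices whose columns are uniform on the probability
    simplex (flat Dirichlet), computes |Delta D| per pair, and returns the
    smoothed exceedance fraction (count(null >= obs) + 1) / (n + 1), which is
    monotone non-increasing in the observed value and never exactly zero.
    """
    if n_draws < 1000:
        raise ValueError("use at least 1000 null draws")
    rng = np.random.default_rng(seed)
    # columns ~ Dirichlet(1,1,1): (n, 2, 3 cols, 3) then det over the 3x3
    cols = rng.dirichlet(np.ones(3), size=(n_draws, 2, 3))
    mats = np.swapaxes(cols, -1, -2)  # columns on the last-but-one axis
    dets = np.abs(np.linalg.det(mats))
    nulls = np.abs(dets[:, 0] - dets[:, 1])
    return float((np.count_nonzero(nulls >= delta_D_obs) + 1) / (n_draws + 1))


def permutation_test(
    matrix_A: WeightMatrix | np.ndarray,
    matrix_B: WeightMatrix | np.ndarray,
    ordered: bool = True,
) -> float:
    """Permutation p-value re-assigning the six observed columns.

    Pools the columns of both matrices and enumerates every split of the six
    into a pseudo-A and pseudo-B triple (C(6,3) = 20 unordered splits; with
    ``ordered=True`` each split is weighted by the 3!*3! within-matrix column
    orderings, under which |det| is invariant, so the two modes agree). The
    p-value is the fraction of arrangements whose |Delta D| is >= the
    observed one; the identity arrangement is included, so p > 0 always.
    """
    a = matrix_A.entries if isinstance(matrix_A, WeightMatrix) else np.asarray(matrix_A, float)
    b = matrix_B.entries if isinstance(matrix_B, WeightMatrix) else np.asarray(matrix_B, float)
    obs = delta_D(a, b)
    columns = np.concatenate([a.T, b.T])  # six columns as rows
    count = total = 0
    for pick in itertools.combinations(range(6), 3):
        rest = tuple(i for i in range(6) if i not in pick)
        da = abs(np.linalg.det(columns[list(pick)].T))
        db = abs(np.linalg.det(columns[list(rest)].T))
        weight = 36 if ordered else 1  # |det| invariant to column order
        total += weight
        if abs(da - db) >= obs - 1e-12:
            count += weight
    return count / total


def compare_designs(
    design_A: DesignSpec,
    design_B: DesignSpec,
    generator_params: Mapping[str, Mapping[str, float]] | None = None,
    noise: NoiseModel | None = None,
    n_replicates: int = 100,
    n_null_draws: int = 100_000,
    seed: int = 0,
    fit_models: Sequence[str] = DEFAULT_MODELS,
    n_starts: int = 8,
) -> DesignComparisonResult:
    """Full design comparison pipeline: matrices, |Delta D|, both p-values."""
    ss = np.random.SeedSequence(seed)
    seed_a, seed_b, seed_null = (int(s) for s in ss.generate_state(3) % (2**31 - 1))
    mat_a = weight_matrix(
        design_A, generator_params, noise, n_replicates, seed_a, fit_models, n_starts
    )
    mat_b = weight_matrix(
        design_B, generator_params, noise, n_replicates, seed_b, fit_models, n_starts
    )
    obs = delta_D(mat_a, mat_b)
    return DesignComparisonResult(
        matrix_A=mat_a,
        matrix_B=mat_b,
        det_A=mat_a.det,
        det_B=mat_b.det,
        delta_D_obs=obs,
        p_null=null_distribution_test(obs, n_null_draws, seed_null),
        p_perm=permutation_test(mat_a, mat_b),
        n_null_draws=n_null_draws,
        seed=seed,
    )
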