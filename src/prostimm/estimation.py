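"""Model calibration by a self-tuning real-coded genetic algorithm.

The 25 rate constants are estimated by minimizing the sum of squared errors
(SSE) between simulated and measured observables over every data box.  The
optimizer is a real-coded genetic algorithm in the Deb tradition — binary
tournament selection, simulated binary crossover (SBX), polynomial mutation
and single-individual elitism — wrapped in a two-stage "modified GA" (MGA):

1. *Hyperparameter selection.*  GA behavior depends strongly on its own
   settings (generations, population size, crossover/mutation probabilities
   and distribution indices).  A grid of candidate settings (243 by default)
   is each run once on the data; the winning level of each setting is picked
   coordinate-wise by smallest median fitting error.
2. *Replicate fits.*  Under the selected settings the fit is repeated with
   independent seeds and the best-objective run is returned.

Identifiability is assessed by a nonparametric bootstrap: replicates are
resampled within each data box, each resample is refit, and a parameter is
flagged non-identifiable when the coefficient of variation (sd/mean) of its
bootstrap estimates exceeds 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    PARAM_NAMES,
    ParameterSet,
    Regimen,
    observe,
    simulate,
    simulate_batch,
)
from .synthetic_data import Dataset

__all__ = [
    "GAConfig",
    "HyperGrid",
    "FitResult",
    "MGAResult",
    "DEFAULT_BOUNDS",
    "sse_objective",
    "dataset_objective",
    "ga_minimize",
    "hypergrid_enumerate",
    "select_hyperparameters",
    "mga_fit",
    "bootstrap_identifiability",
    "spawn_seeds",
]

#: Default calibration search box per rate constant (log-wide, per week).
DEFAULT_BOUNDS = (1e-3, 1e2)

#: Hyperparameter fields in the fixed order used for coordinate-wise selection.
GA_FIELDS = ("generations", "population", "p_crossover", "p_mutation",
             "eta_crossover", "eta_mutation")


def spawn_seeds(master_seed: int, n: int, stage: str = "") -> np.ndarray:
    """Derive ``n`` independent 31-bit seeds from a master seed and a stage
    label, so each pipeline stage gets its own reproducible seed ladder."""
    entropy = [int(master_seed)] + [ord(c) for c in stage]
    ss = np.random.SeedSequence(entropy)
    return ss.generate_state(n, dtype=np.uint32) % (2**31)


@dataclass(frozen=True)
class GAConfig:
    """Settings of one genetic-algorithm run."""

    generations: int = 100
    population: int = 100
    p_crossover: float = 0.9
    p_mutation: float = 1.0 / 25.0
    eta_crossover: float = 10.0
    eta_mutation: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 1 or self.population < 1:
            raise ValueError("generations and population must be >= 1")
        for p in (self.p_crossover, self.p_mutation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.eta_crossover <= 0 or self.eta_mutation <= 0:
            raise ValueError("distribution indices must be positive")


@dataclass
class HyperGrid:
    """Candidate levels per GA setting; the Cartesian product is the
    candidate pool.  The default varies five settings over three levels each
    (3^5 = 243 candidates) and pins the mutation probability at the 1/n
    rule-of-thumb for n = 25 parameters."""

    generations: Sequence[int] = (50, 100, 200)
    population: Sequence[int] = (50, 100, 200)
    p_crossover: Sequence[float] = (0.7, 0.8, 0.9)
    p_mutation: Sequence[float] = (1.0 / 25.0,)
    eta_crossover: Sequence[float] = (2.0, 10.0, 20.0)
    eta_mutation: Sequence[float] = (10.0, 20.0, 50.0)

    @property
    def size(self) -> int:
        return int(np.prod([len(getattr(self, f)) for f in GA_FIELDS]))


@dataclass
class FitResult:
    """One GA run: best point, its objective, and per-generation trace."""

    x: np.ndarray
    objective: float
    config: GAConfig
    seed: int
    trace: np.ndarray

    @property
    def params(self) -> ParameterSet:
        if self.x.shape != (len(PARAM_NAMES),):
            raise ValueError("fit is not over the 25 model parameters")
        return ParameterSet(self.x.copy())

    def to_json_dict(self) -> dict:
        d = {"objective": float(self.objective), "seed": int(self.seed),
             "config": {f: getattr(self.config, f) for f in GA_FIELDS},
             "trace": [float(v) for v in self.trace]}
        if self.x.shape == (len(PARAM_NAMES),):
            d["params"] = dict(zip(PARAM_NAMES, map(float, self.x)))
        else:
            d["x"] = [float(v) for v in self.x]
        return d


@dataclass
class MGAResult:
    """Full provenance of an MGA fit: stage-1 candidate errors, the selected
    configuration, and every stage-3 replicate fit."""

    best: FitResult
    selected: GAConfig
    candidate_errors: dict
    replicate_fits: list

    @property
    def replicate_objectives(self) -> np.ndarray:
        return np.array([f.objective for f in self.replicate_fits])


# ---------------------------------------------------------------------------
# Objective


def sse_objective(params: ParameterSet, ds: Dataset) -> float:
    """Sum of squared errors between model observables and every replicate
    measurement; the t = 0 baseline never contributes.  Invalid trajectories
    score +inf so the optimizer discards them."""
    if len(ds) == 0:
        raise ValueError("dataset has no data boxes")
    total = 0.0
    for cond in ds.conditions:
        traj = simulate(params, Regimen.from_label(cond))
        if not traj.valid:
            return float("inf")
        series = observe(traj)
        for box in ds.boxes:
            if box.condition != cond:
                continue
            model = float(np.interp(box.time_weeks, traj.times,
                                    series[box.observable]))
            total += float(np.sum((model - box.values) ** 2))
    return total


_OBS_STATE_IDX = {"CTL-P": 12, "Treg-P": 13, "CTL-L": 9, "Treg-L": 10}


def dataset_objective(ds: Dataset, n_steps: int = 250) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorized SSE objective: maps an (m, 25) parameter matrix to m SSE
    values, using the fixed-step batch integrator.  This is the objective
    the GA uses; :func:`sse_objective` is the adaptive-solver reference."""
    if len(ds) == 0:
        raise ValueError("dataset has no data boxes")
    # Pre-index the boxes per condition and unique time.
    plan = []
    for cond in ds.conditions:
        boxes = [b for b in ds.boxes if b.condition == cond]
        times = sorted({b.time_weeks for b in boxes})
        entries = [(times.index(b.time_weeks), b.observable, b.values)
                   for b in boxes]
        plan.append((Regimen.from_label(cond), np.array(times), entries))

    def objective(P: np.ndarray) -> np.ndarray:
        P = np.atleast_2d(P)
        sse = np.zeros(P.shape[0])
        ok_all = np.ones(P.shape[0], dtype=bool)
        for regimen, times, entries in plan:
            states, ok = simulate_batch(P, regimen, times, n_steps=n_steps)
            ok_all &= ok
            for ti, obs, values in entries:
                if obs == "Tumor":
                    model = (states[:, ti, 4] + states[:, ti, 5]) / 2.0
                else:
                    model = states[:, ti, _OBS_STATE_IDX[obs]]
                sse += np.sum((model[:, None] - values[None, :]) ** 2, axis=1)
        sse[~ok_all] = np.inf
        return sse

    return objective


# ---------------------------------------------------------------------------
# Genetic algorithm


def _sbx_pairs(parents: np.ndarray, lo: np.ndarray, hi: np.ndarray,
               p_cross: float, eta: float, rng: np.random.Generator) -> np.ndarray:
    """Simulated binary crossover on consecutive parent pairs (bounded,
    per-variable exchange with probability 1/2)."""
    children = parents.copy()
    n, d = parents.shape
    for i in range(0, n - 1, 2):
        if rng.random() >= p_cross:
            continue
        a, b = parents[i].copy(), parents[i + 1].copy()
        do = rng.random(d) < 0.5
        u = rng.random(d)
        beta = np.where(u <= 0.5,
                        (2 * u) ** (1.0 / (eta + 1.0)),
                        (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0)))
        c1 = 0.5 * ((1 + beta) * a + (1 - beta) * b)
        c2 = 0.5 * ((1 - beta) * a + (1 + beta) * b)
        children[i] = np.where(do, np.clip(c1, lo, hi), a)
        children[i + 1] = np.where(do, np.clip(c2, lo, hi), b)
    return children


def _poly_mutation(pop: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                   p_mut: float, eta: float, rng: np.random.Generator) -> np.ndarray:
    """Bounded polynomial mutation, applied per variable with probability
    ``p_mut``."""
    out = pop.copy()
    span = hi - lo
    mask = rng.random(pop.shape) < p_mut
    u = rng.random(pop.shape)
    d1 = (out - lo) / span
    d2 = (hi - out) / span
    mpow = 1.0 / (eta + 1.0)
    dq_lo = (2 * u + (1 - 2 * u) * (1 - d1) ** (eta + 1.0)) ** mpow - 1.0
    dq_hi = 1.0 - (2 * (1 - u) + 2 * (u - 0.5) * (1 - d2) ** (eta + 1.0)) ** mpow
    delta = np.where(u <= 0.5, dq_lo, dq_hi)
    out = np.where(mask, np.clip(out + delta * span, lo, hi), out)
    return out


def ga_minimize(objective: Callable, bounds, cfg: GAConfig,
                init: str = "uniform", vectorized: bool = False) -> FitResult:
    """Minimize ``objective`` over a box with a real-coded GA.

    ``bounds`` is a (lower, upper) pair of arrays (or an (d, 2) array).
    With ``vectorized=True`` the objective maps an (m, d) matrix to m values
    (the fast path used for model calibration); otherwise it is called per
    point.  ``init`` is "uniform" or "loguniform" (positive bounds only).
    Deterministic for a fixed ``cfg`` (including its seed); the returned
    per-generation best-objective trace is non-increasing (elitism).
    """
    lo, hi = (np.asarray(b, dtype=float) for b in
              (bounds if len(bounds) == 2 else np.transpose(bounds)))
    if lo.shape != hi.shape or np.any(lo >= hi):
        raise ValueError("bounds must be a (lower, upper) pair with lower < upper")
    d = lo.size
    rng = np.random.default_rng(cfg.seed)

    if init == "loguniform":
        if np.any(lo <= 0):
            raise ValueError("log-uniform initialization needs positive bounds")
        pop = np.exp(rng.uniform(np.log(lo), np.log(hi),
                                 size=(cfg.population, d)))
    elif init == "uniform":
        pop = rng.uniform(lo, hi, size=(cfg.population, d))
    else:
        raise ValueError(f"unknown init scheme {init!r}")

    def evaluate(P: np.ndarray) -> np.ndarray:
        if vectorized:
            return np.asarray(objective(P), dtype=float)
        return np.array([objective(x) for x in P], dtype=float)

    fit = evaluate(pop)
    fit = np.where(np.isnan(fit), np.inf, fit)
    best_i = int(np.argmin(fit))
    best_x, best_f = pop[best_i].copy(), float(fit[best_i])
    trace = [best_f]

    for _ in range(cfg.generations):
        # binary tournament selection
        idx = rng.integers(cfg.population, size=(cfg.population, 2))
        winners = np.where(fit[idx[:, 0]] <= fit[idx[:, 1]],
                           idx[:, 0], idx[:, 1])
        parents = pop[winners]
        children = _sbx_pairs(parents, lo, hi, cfg.p_crossover,
                              cfg.eta_crossover, rng)
        children = _poly_mutation(children, lo, hi, cfg.p_mutation,
                                  cfg.eta_mutation, rng)
        children[0] = best_x  # elitism: the incumbent survives unchanged
        fit = evaluate(children)
        fit = np.where(np.isnan(fit), np.inf, fit)
        pop = children
        gi = int(np.argmin(fit))
        if fit[gi] < best_f:
            best_x, best_f = pop[gi].copy(), float(fit[gi])
        trace.append(best_f)

    return FitResult(best_x, best_f, cfg, cfg.seed, np.array(trace))


# ---------------------------------------------------------------------------
# Hyperparameter grid and MGA


def hypergrid_enumerate(grid: HyperGrid) -> list[GAConfig]:
    """The full Cartesian product of candidate levels, in deterministic
    order (fields in :data:`GA_FIELDS` order, last field fastest)."""
    levels = [getattr(grid, f) for f in GA_FIELDS]
    return [GAConfig(**dict(zip(GA_FIELDS, combo)))
            for combo in itertools.product(*levels)]


def select_hyperparameters(errors: Mapping[GAConfig, float],
                           grid: HyperGrid) -> GAConfig:
    """Coordinate-wise selection: for each GA setting in fixed order, group
    all candidate runs by that setting's level and keep the level with the
    smallest median error (ties go to the first-listed level)."""
    configs = hypergrid_enumerate(grid)
    missing = [c for c in configs if c not in errors]
    if missing:
        raise ValueError(f"errors missing for {len(missing)} candidate configs")
    chosen = {}
    for fld in GA_FIELDS:
        best_level, best_med = None, np.inf
        for level in getattr(grid, fld):
            vals = [errors[c] for c in configs if getattr(c, fld) == level]
            med = float(np.median(vals))
            if med < best_med:
                best_level, best_med = level, med
        chosen[fld] = best_level
    return GAConfig(**chosen)


def mga_fit(ds: Dataset, grid: HyperGrid | None = None, replicates: int = 20,
            seed: int = 0, bounds=None, n_steps: int = 250,
            full_output: bool = False):
    """Two-stage MGA calibration of the 25 rate constants to a dataset.

    Stage 1 runs the GA once per candidate configuration; stage 2 selects
    the configuration coordinate-wise by median error; stage 3 repeats the
    fit ``replicates`` times with independent seeds under the selected
    configuration and returns the best run (as :class:`FitResult`, or the
    full :class:`MGAResult` with ``full_output=True``).
    """
    if replicates < 1:
        raise ValueError("need at least one replicate fit")
    grid = grid or HyperGrid()
    if bounds is None:
        bounds = (np.full(len(PARAM_NAMES), DEFAULT_BOUNDS[0]),
                  np.full(len(PARAM_NAMES), DEFAULT_BOUNDS[1]))
    objective = dataset_objective(ds, n_steps=n_steps)

    configs = hypergrid_enumerate(grid)
    stage1_seeds = spawn_seeds(seed, len(configs), "hypergrid")
    errors: dict[GAConfig, float] = {}
    stage1_fits = {}
    for cfg, s in zip(configs, stage1_seeds):
        fit = ga_minimize(objective, bounds, replace(cfg, seed=int(s)),
                          init="loguniform", vectorized=True)
        errors[cfg] = fit.objective
        stage1_fits[cfg] = fit

    selected = select_hyperparameters(errors, grid)

    rep_seeds = spawn_seeds(seed, replicates, "replicates")
    fits = [ga_minimize(objective, bounds, replace(selected, seed=int(s)),
                        init="loguniform", vectorized=True)
            for s in rep_seeds]
    best = min(fits, key=lambda f: f.objective)
    if best.objective > stage1_fits[selected].objective:
        best = stage1_fits[selected]
    if full_output:
        return MGAResult(best, selected, errors, fits)
    return best


# ---------------------------------------------------------------------------
# Bootstrap identifiability


def bootstrap_identifiability(ds: Dataset, fit_cfg: GAConfig,
                              n_boot: int = 100, seed: int = 0, bounds=None,
                              n_steps: int = 250,
                              cv_threshold: float = 1.0) -> pd.DataFrame:
    """Bootstrap coefficient-of-variation identifiability analysis.

    Replicates are resampled with replacement within every data box (same
    size, so a resampled box can never be empty; a degenerate resample would
    simply be redrawn), each resampled dataset is refit with a single GA run
    under ``fit_cfg``, and for each parameter the CV (sample sd over mean)
    of its ``n_boot`` estimates is reported.  A parameter is flagged
    non-identifiable when its CV exceeds 1.
    """
    if n_boot < 2:
        raise ValueError("need at least two bootstrap resamples")
    if bounds is None:
        bounds = (np.full(len(PARAM_NAMES), DEFAULT_BOUNDS[0]),
                  np.full(len(PARAM_NAMES), DEFAULT_BOUNDS[1]))
    rng = np.random.default_rng(spawn_seeds(seed, 1, "bootstrap")[0])
    fit_seeds = spawn_seeds(seed, n_boot, "bootstrap-fits")
    estimates = np.empty((n_boot, len(PARAM_NAMES)))
    for b in range(n_boot):
        boxes = []
        for box in ds.boxes:
            vals = rng.choice(box.values, size=box.values.size, replace=True)
            boxes.append(type(box)(box.condition, box.observable,
                                   box.time_weeks, vals))
        resampled = Dataset(boxes)
        objective = dataset_objective(resampled, n_steps=n_steps)
        fit = ga_minimize(objective, bounds,
                          replace(fit_cfg, seed=int(fit_seeds[b])),
                          init="loguniform", vectorized=True)
        estimates[b] = fit.x
    mean = estimates.mean(axis=0)
    sd = estimates.std(axis=0, ddof=1)
    cv = sd / mean
    return pd.DataFrame({
        "parameter": PARAM_NAMES,
        "mean": mean,
        "sd": sd,
        "cv": cv,
        "identifiable": cv <= cv_threshold,
    })
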