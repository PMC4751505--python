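"""Genetic algorithm, objective and MGA calibration tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prostimm import (
    GAConfig,
    HyperGrid,
    ParameterSet,
    Regimen,
    bootstrap_identifiability,
    ga_minimize,
    hypergrid_enumerate,
    mga_fit,
    select_hyperparameters,
    sse_objective,
)
from prostimm.estimation import (
    DEFAULT_BOUNDS,
    GA_FIELDS,
    dataset_objective,
    spawn_seeds,
)
from prostimm.model_core import PARAM_NAMES, observe_at, simulate
from prostimm.synthetic_data import DataBox, Dataset


SPHERE_CENTER = np.array([0.3, 0.7, 0.2, 0.5, 0.9])


def sphere(x):
    return float(np.sum((x - SPHERE_CENTER) ** 2))


SPHERE_BOUNDS = (np.zeros(5), np.ones(5))


# ---------------------------------------------------------------------------
# seeds & config


def test_spawn_seeds_range_and_stage_independence():
    s1 = spawn_seeds(42, 10, "fit")
    s2 = spawn_seeds(42, 10, "fit")
    s3 = spawn_seeds(42, 10, "validate")
    assert np.array_equal(s1, s2)
    assert not np.array_equal(s1, s3)
    assert np.all(s1 < 2**31) and np.all(s1 >= 0)
    assert len(set(s1.tolist())) == 10


def test_gaconfig_validation():
    with pytest.raises(ValueError):
        GAConfig(generations=0)
    with pytest.raises(ValueError):
        GAConfig(p_crossover=1.5)
    with pytest.raises(ValueError):
        GAConfig(eta_mutation=0)


# ---------------------------------------------------------------------------
# GA on a known landscape


def test_ga_converges_on_sphere():
    cfg = GAConfig(generations=150, population=40, p_crossover=0.9,
                   eta_crossover=2, eta_mutation=20, seed=0)
    fit = ga_minimize(sphere, SPHERE_BOUNDS, cfg)
    assert fit.objective < 1e-3
    assert np.allclose(fit.x, SPHERE_CENTER, atol=0.05)


def test_ga_deterministic_per_seed():
    cfg = GAConfig(generations=30, population=20, seed=7)
    a = ga_minimize(sphere, SPHERE_BOUNDS, cfg)
    b = ga_minimize(sphere, SPHERE_BOUNDS, cfg)
    assert np.array_equal(a.x, b.x)
    assert a.objective == b.objective
    assert np.array_equal(a.trace, b.trace)
    c = ga_minimize(sphere, SPHERE_BOUNDS, GAConfig(generations=30,
                                                    population=20, seed=8))
    assert not np.array_equal(a.x, c.x)


def test_ga_trace_monotone_and_bounds_respected():
    cfg = GAConfig(generations=60, population=16, seed=3)
    fit = ga_minimize(sphere, SPHERE_BOUNDS, cfg)
    assert len(fit.trace) == 61
    assert np.all(np.diff(fit.trace) <= 0)
    assert np.all(fit.x >= 0) and np.all(fit.x <= 1)


def test_ga_replicates_min_le_median():
    objs = [ga_minimize(sphere, SPHERE_BOUNDS,
                        GAConfig(generations=25, population=16, seed=s)).objective
            for s in range(7)]
    assert min(objs) <= float(np.median(objs))


def test_ga_vectorized_matches_scalar():
    cfg = GAConfig(generations=20, population=12, seed=5)
    a = ga_minimize(sphere, SPHERE_BOUNDS, cfg)
    b = ga_minimize(lambda P: np.sum((P - SPHERE_CENTER) ** 2, axis=1),
                    SPHERE_BOUNDS, cfg, vectorized=True)
    assert np.array_equal(a.x, b.x)


def test_ga_loguniform_requires_positive_bounds():
    with pytest.raises(ValueError, match="positive bounds"):
        ga_minimize(sphere, (np.zeros(5), np.ones(5)),
                    GAConfig(generations=1, population=4), init="loguniform")
    with pytest.raises(ValueError, match="unknown init"):
        ga_minimize(sphere, SPHERE_BOUNDS,
                    GAConfig(generations=1, population=4), init="sobol")


def test_ga_bad_bounds():
    with pytest.raises(ValueError, match="lower < upper"):
        ga_minimize(sphere, (np.ones(5), np.zeros(5)),
                    GAConfig(generations=1, population=4))


# ---------------------------------------------------------------------------
# hypergrid


def test_default_hypergrid_243():
    grid = HyperGrid()
    assert grid.size == 243
    configs = hypergrid_enumerate(grid)
    assert len(configs) == 243
    assert len(set(configs)) == 243
    assert all(c.p_mutation == pytest.approx(1 / 25) for c in configs)


def test_select_hyperparameters_coordinatewise():
    grid = HyperGrid(generations=(1, 2), population=(3,), p_crossover=(0.5,),
                     p_mutation=(0.04,), eta_crossover=(2.0,),
                     eta_mutation=(10.0, 20.0))
    cfgs = hypergrid_enumerate(grid)
    assert len(cfgs) == 4
    errors = {}
    for c in cfgs:
        errors[c] = {(1, 10.0): 1.0, (1, 20.0): 3.0,
                     (2, 10.0): 2.0, (2, 20.0): 2.5}[
                         (c.generations, c.eta_mutation)]
    sel = select_hyperparameters(errors, grid)
    # generations level 1 has median 2.0 < 2.25; eta_mutation 10 has 1.5 < 2.75
    assert sel.generations == 1
    assert sel.eta_mutation == 10.0
    assert sel.population == 3


def test_select_hyperparameters_requires_full_errors():
    grid = HyperGrid(generations=(1, 2), population=(3,), p_crossover=(0.5,),
                     p_mutation=(0.04,), eta_crossover=(2.0,),
                     eta_mutation=(10.0,))
    with pytest.raises(ValueError, match="missing"):
        select_hyperparameters({}, grid)


# ---------------------------------------------------------------------------
# objectives


def test_sse_zero_at_truth(truth, noise_free_ds):
    assert sse_objective(truth, noise_free_ds) == pytest.approx(0.0, abs=1e-8)


def test_sse_hand_computed_toy(truth):
    boxes = [DataBox("SX", "Tumor", 2.5, [1.0, 2.0]),
             DataBox("SX", "CTL-P", 5.0, [0.5]),
             DataBox("CX", "Tumor", 5.0, [1.5])]
    ds = Dataset(boxes)
    sx = simulate(truth, Regimen.from_label("SX"))
    cx = simulate(truth, Regimen.from_label("CX"))
    expected = ((observe_at(sx, "Tumor", 2.5) - 1.0) ** 2
                + (observe_at(sx, "Tumor", 2.5) - 2.0) ** 2
                + (observe_at(sx, "CTL-P", 5.0) - 0.5) ** 2
                + (observe_at(cx, "Tumor", 5.0) - 1.5) ** 2)
    assert sse_objective(truth, ds) == pytest.approx(expected, rel=1e-12)


def test_sse_empty_dataset_rejected(truth):
    with pytest.raises(ValueError, match="no data boxes"):
        sse_objective(truth, Dataset([]))


def test_dataset_objective_matches_reference(truth, noisy_ds):
    obj = dataset_objective(noisy_ds, n_steps=400)
    fast = obj(truth.values[None, :])[0]
    ref = sse_objective(truth, noisy_ds)
    assert fast == pytest.approx(ref, rel=1e-3, abs=1e-6)


def test_dataset_objective_infinite_on_blowup(truth):
    ds = Dataset([DataBox("SX", "Tumor", 5.0, [1.0])])
    obj = dataset_objective(ds, n_steps=50)
    bad = truth.values.copy()
    bad[PARAM_NAMES.index("alpha_G")] = 1e2
    bad[PARAM_NAMES.index("sigma_I")] = 1e2
    vals = obj(np.vstack([truth.values, bad]))
    assert np.isfinite(vals[0])
    assert np.isinf(vals[1])


# ---------------------------------------------------------------------------
# MGA pipeline (scaled-down smoke tests; the full-scale recovery run lives
# in the acceptance suite)

TINY_GRID = HyperGrid(generations=(15,), population=(16,), p_crossover=(0.9,),
                      p_mutation=(0.04,), eta_crossover=(2.0, 10.0),
                      eta_mutation=(20.0,))


def test_mga_fit_structure_and_determinism(noise_free_ds, truth_bounds):
    res = mga_fit(noise_free_ds, TINY_GRID, replicates=3, seed=11,
                  bounds=truth_bounds, n_steps=50, full_output=True)
    assert len(res.candidate_errors) == 2
    assert len(res.replicate_fits) == 3
    assert res.best.objective <= res.replicate_objectives.min()
    assert res.best.objective <= min(res.candidate_errors.values())
    again = mga_fit(noise_free_ds, TINY_GRID, replicates=3, seed=11,
                    bounds=truth_bounds, n_steps=50)
    assert again.objective == res.best.objective
    assert np.array_equal(again.x, res.best.x)


def test_mga_fit_params_property(noise_free_ds, truth_bounds):
    fit = mga_fit(noise_free_ds, TINY_GRID, replicates=2, seed=0,
                  bounds=truth_bounds, n_steps=50)
    ps = fit.params
    assert isinstance(ps, ParameterSet)
    assert np.all(ps.values >= truth_bounds[0])
    assert np.all(ps.values <= truth_bounds[1])
    d = fit.to_json_dict()
    assert set(d["params"]) == set(PARAM_NAMES)
    assert d["config"]["generations"] == 15


def test_mga_fit_validates_replicates(noise_free_ds):
    with pytest.raises(ValueError, match="replicate"):
        mga_fit(noise_free_ds, TINY_GRID, replicates=0)


def test_parameter_recovery_sigma_005(truth):
    """Calibration on lightly noisy data recovers at least 20 of the 25
    rate constants within 25% relative error from a +/-50% search box."""
    from prostimm import NoiseModel, generate_dataset

    ds = generate_dataset(truth, NoiseModel(sigma=0.05, replicates=5), seed=7)
    obj = dataset_objective(ds, n_steps=100)
    bounds = (truth.values * 0.5, truth.values * 1.5)
    best = None
    for s in range(3):
        cfg = GAConfig(generations=3000, population=32, p_crossover=0.9,
                       eta_crossover=2, eta_mutation=100, seed=s)
        fit = ga_minimize(obj, bounds, cfg, init="loguniform", vectorized=True)
        if best is None or fit.objective < best.objective:
            best = fit
    rel = np.abs(best.x - truth.values) / truth.values
    assert int((rel < 0.25).sum()) >= 20


# ---------------------------------------------------------------------------
# bootstrap identifiability


def test_bootstrap_identifiability_smoke(noisy_ds, truth_bounds):
    cfg = GAConfig(generations=30, population=16, p_crossover=0.9,
                   eta_crossover=2, eta_mutation=20)
    df = bootstrap_identifiability(noisy_ds, cfg, n_boot=4, seed=1,
                                   bounds=truth_bounds, n_steps=50)
    assert list(df.columns) == ["parameter", "mean", "sd", "cv",
                                "identifiable"]
    assert list(df["parameter"]) == list(PARAM_NAMES)
    assert np.all(df["cv"] >= 0)
    assert np.array_equal(df["identifiable"], df["cv"] <= 1.0)
    again = bootstrap_identifiability(noisy_ds, cfg, n_boot=4, seed=1,
                                      bounds=truth_bounds, n_steps=50)
    assert np.array_equal(df["mean"], again["mean"])


def test_bootstrap_identifiability_validates_n_boot(noisy_ds):
    with pytest.raises(ValueError, match="two bootstrap"):
        bootstrap_identifiability(noisy_ds, GAConfig(), n_boot=1)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(1, 30))
def test_spawn_seeds_always_31_bit(seed, n):
    s = spawn_seeds(seed, n, "x")
    assert s.shape == (n,)
    assert np.all(s < 2**31)
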