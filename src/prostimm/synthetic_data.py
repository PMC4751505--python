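"""Synthetic mouse-experiment-like datasets for calibration and validation.

Real calibration data for this model come from cohorts of prostate-specific
Pten-null mice measured under seven treatment conditions (SX, CX, CX + AI,
CX + AR, SX + V, CX + V, CX + V + AR): relative tumor weight and CTL/Treg
populations in prostate and lymphoid tissue, at 2.5 and 5 weeks after
treatment, each relative to a pre-treatment baseline of 1.  This module
generates datasets with exactly that structure — conditions x observables x
time points x replicates — from a known ground-truth parameter set, so every
downstream stage (GA calibration, identifiability, cross-validation,
regimen ranking) can be exercised and checked against the truth.

Noise is multiplicative lognormal with median 1: a replicate is the
noise-free model value times ``exp(sigma * z)`` with standard-normal ``z``.
This keeps measurements positive and makes the noise-free value the median
(not the mean; the mean carries a ``exp(sigma^2 / 2)`` bias) of the
replicate distribution.  Lymphoid measurements are sparse in the real
experiments, which the default missingness pattern mimics by dropping the
lymphoid boxes of the two antibody-only arms (CX + AI and CX + AR).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model_core import ParameterSet, Regimen, observe, simulate

__all__ = [
    "FITTED_CONDITIONS",
    "OBSERVABLES",
    "MEASUREMENT_TIMES",
    "DataBox",
    "Dataset",
    "NoiseModel",
    "default_truth",
    "generate_dataset",
    "read_dataset",
    "write_dataset",
]

#: The seven experimental arms used for model training, in the conventional
#: order ("SX + V" is vaccination without castration).
FITTED_CONDITIONS = (
    "SX", "CX", "CX + AI", "CX + AR", "SX + V", "CX + V", "CX + V + AR",
)

#: Measured observables per condition.
OBSERVABLES = ("Tumor", "CTL-P", "Treg-P", "CTL-L", "Treg-L")

#: Measurement times in weeks post-treatment.
MEASUREMENT_TIMES = (2.5, 5.0)

#: Lymphoid boxes absent by default (sparse lymphoid sampling in the
#: antibody-only arms).
DEFAULT_MISSING = frozenset({
    ("CX + AI", "CTL-L"), ("CX + AI", "Treg-L"),
    ("CX + AR", "CTL-L"), ("CX + AR", "Treg-L"),
})


@dataclass
class DataBox:
    """All replicate measurements of one observable under one condition at
    one time point — the unit of holdout in box-wise cross-validation."""

    condition: str
    observable: str
    time_weeks: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if self.condition not in FITTED_CONDITIONS:
            raise ValueError(f"unknown condition label: {self.condition!r}")
        if self.observable not in OBSERVABLES:
            raise ValueError(f"unknown observable: {self.observable!r}")
        if self.time_weeks not in MEASUREMENT_TIMES:
            raise ValueError(
                f"time must be one of {MEASUREMENT_TIMES}, got {self.time_weeks}")
        if self.values.size < 1:
            raise ValueError("a data box needs at least one replicate")
        if np.any(self.values <= 0) or not np.all(np.isfinite(self.values)):
            raise ValueError(
                f"non-positive or non-finite measurement in box "
                f"({self.condition}, {self.observable}, {self.time_weeks})")

    @property
    def key(self) -> tuple[str, str, float]:
        return (self.condition, self.observable, self.time_weeks)


@dataclass
class Dataset:
    """A collection of data boxes with optional synthetic provenance."""

    boxes: list[DataBox]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [b.key for b in self.boxes]
        if len(keys) != len(set(keys)):
            dup = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate data-box keys: {dup}")

    def __len__(self) -> int:
        return len(self.boxes)

    @property
    def conditions(self) -> tuple[str, ...]:
        seen = dict.fromkeys(b.condition for b in self.boxes)
        return tuple(seen)

    def without_condition(self, condition: str) -> "Dataset":
        return Dataset([b for b in self.boxes if b.condition != condition],
                       dict(self.provenance))

    def without_box(self, key: tuple[str, str, float]) -> "Dataset":
        return Dataset([b for b in self.boxes if b.key != key],
                       dict(self.provenance))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.boxes:
            for rid, v in enumerate(b.values):
                rows.append((b.condition, b.observable, b.time_weeks, rid, v))
        return pd.DataFrame(
            rows, columns=["condition", "observable", "time_weeks",
                           "replicate_id", "value"])


@dataclass
class NoiseModel:
    """Replicate structure of a synthetic experiment: lognormal sigma,
    group size, and which (condition, observable) boxes go unmeasured."""

    sigma: float = 0.15
    replicates: int = 5
    missing: frozenset = DEFAULT_MISSING

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate per box")
        self.missing = frozenset(self.missing)


def default_truth() -> ParameterSet:
    """The packaged ground-truth rate constants (per week).

    Chosen once so that the noise-free model reproduces the qualitative
    biology of the mouse experiments: untreated tumors grow severalfold in
    five weeks; castration shrinks the tumor but leaves a resistant
    population; the lymphoid CTL pool surges then contracts after castration
    while Tregs expand; and the triple arm CX + V + AR yields the lowest
    tumor burden of the seven fitted conditions.
    """
    values = {
        "rho_S": 1.96, "delta_S": 0.115, "lambda_SR": 0.85,
        "rho_R": 0.865, "delta_R": 0.136,
        "eta_S": 1.48, "eta_R": 0.262, "theta_A": 0.5,
        "sigma_Ag": 0.0536, "delta_Ag": 0.931,
        "alpha_D": 0.984, "omega_V": 4.02, "delta_D": 0.583,
        "alpha_Dr": 0.142, "delta_Dr": 2.75,
        "alpha_C": 3.38, "beta_I": 2.37, "xi_C": 1.91,
        "mu_C": 0.0237, "tau_C": 0.309,
        "alpha_G": 0.422, "zeta": 0.217, "mu_G": 0.02, "tau_G": 0.00305,
        "sigma_I": 0.0768,
    }
    return ParameterSet.from_dict(values)


def _truth_hash(truth: ParameterSet) -> str:
    payload = json.dumps(truth.as_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def noise_free_table(truth: ParameterSet) -> dict[tuple[str, str, float], float]:
    """Noise-free model value for every (condition, observable, time) box."""
    table: dict[tuple[str, str, float], float] = {}
    for cond in FITTED_CONDITIONS:
        traj = simulate(truth, Regimen.from_label(cond))
        if not traj.valid:
            raise RuntimeError(f"invalid trajectory under truth for {cond}")
        series = observe(traj)
        for obs in OBSERVABLES:
            for t in MEASUREMENT_TIMES:
                table[(cond, obs, t)] = float(
                    np.interp(t, traj.times, series[obs]))
    return table


def generate_dataset(truth: ParameterSet, noise: NoiseModel | None = None,
                     seed: int = 0) -> Dataset:
    """Simulate all seven fitted conditions and emit noisy replicates.

    Fully reproducible from ``seed``.  Initial (t = 0) values are the
    normalization baseline and are never emitted as data.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    table = noise_free_table(truth)
    boxes = []
    for cond in FITTED_CONDITIONS:
        for obs in OBSERVABLES:
            if (cond, obs) in noise.missing:
                continue
            for t in MEASUREMENT_TIMES:
                mu = table[(cond, obs, t)]
                vals = mu * np.exp(noise.sigma *
                                   rng.standard_normal(noise.replicates))
                boxes.append(DataBox(cond, obs, t, vals))
    prov = {"truth_hash": _truth_hash(truth), "sigma": noise.sigma,
            "replicates": noise.replicates, "seed": int(seed),
            "missing": sorted(map(list, noise.missing))}
    return Dataset(boxes, prov)


# ---------------------------------------------------------------------------
# TSV round trip


def write_dataset(ds: Dataset, path, provenance_path=None) -> None:
    ds.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    if provenance_path is not None:
        with open(provenance_path, "w") as fh:
            json.dump(ds.provenance, fh, indent=1)


def read_dataset(path) -> Dataset:
    """Read a dataset TSV, validating labels, positivity and key uniqueness.

    Errors cite 1-based data-row numbers of the offending lines.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["condition", "observable", "time_weeks", "replicate_id", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"dataset file missing columns: {missing}")
    bad_cond = df.index[~df["condition"].isin(FITTED_CONDITIONS)]
    if len(bad_cond):
        raise ValueError(
            f"unknown condition labels at rows {[i + 1 for i in bad_cond[:5]]}")
    bad_obs = df.index[~df["observable"].isin(OBSERVABLES)]
    if len(bad_obs):
        raise ValueError(
            f"unknown observables at rows {[i + 1 for i in bad_obs[:5]]}")
    bad_val = df.index[~(df["value"] > 0) | ~np.isfinite(df["value"])]
    if len(bad_val):
        raise ValueError(
            f"non-positive values at rows {[i + 1 for i in bad_val[:5]]}")
    boxes = []
    for (cond, obs, t), grp in df.groupby(
            ["condition", "observable", "time_weeks"], sort=False):
        if grp["replicate_id"].duplicated().any():
            raise ValueError(
                f"duplicate replicate ids in box ({cond}, {obs}, {t})")
        grp = grp.sort_values("replicate_id")
        boxes.append(DataBox(cond, obs, float(t), grp["value"].to_numpy()))
    return Dataset(boxes)
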