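"""Regimen outcome prediction, efficacy ranking and Bliss synergy analysis.

With a calibrated parameter set the model predicts tumor outcomes for all
16 regimens (every subset of {CX, V, AI, AR}).  Treatment effect is the
percentage inhibition of the tumor-size outcome relative to the untreated
control, using either the instantaneous 5-week tumor size (type I) or the
0-5 week average (type II).

Synergy between two *disjoint* treatment groups A and B is scored with the
Bliss independence combination index

    CI = (e_A + e_B - e_A * e_B) / e_AB,

the Bliss-expected combined effect over the observed combined effect, so
CI < 1 is synergy, CI = 1 additivity, CI > 1 antagonism.  A group is any
non-empty component subset treated as one unit — "(CX + V) + AR" is a
two-group combination, distinct from the three-way "CX + V + AR" to which
the pairwise index does not apply.  Local sensitivity of the two outcome
types to each rate constant (5% perturbation by default) quantifies how
stable the predictions are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import (
    COMPONENTS,
    PARAM_NAMES,
    ParameterSet,
    Regimen,
    enumerate_regimens,
    outcome_average,
    outcome_instantaneous,
    percent_inhibition,
    simulate,
    simulate_batch,
)
from .synthetic_data import FITTED_CONDITIONS

__all__ = [
    "TreatmentGroup",
    "CIMatrix",
    "predict_all_regimens",
    "rank_regimens",
    "component_rank_table",
    "local_sensitivity",
    "bliss_ci",
    "ci_matrix",
    "pearson_r",
    "t_test",
    "component_summary",
]


@dataclass(frozen=True)
class TreatmentGroup:
    """A non-empty subset of {CX, V, AI, AR} treated as one unit when
    forming pairwise combinations."""

    components: tuple[str, ...]

    def __post_init__(self) -> None:
        comp = tuple(c for c in COMPONENTS if c in set(self.components))
        if not comp or set(self.components) - set(COMPONENTS):
            raise ValueError(f"invalid treatment group: {self.components}")
        object.__setattr__(self, "components", comp)

    @property
    def label(self) -> str:
        lab = " + ".join(self.components)
        return f"({lab})" if len(self.components) > 1 else lab

    @property
    def regimen_label(self) -> str:
        return " + ".join(self.components)

    def disjoint(self, other: "TreatmentGroup") -> bool:
        return not set(self.components) & set(other.components)

    def union(self, other: "TreatmentGroup") -> "TreatmentGroup":
        return TreatmentGroup(self.components + other.components)


def all_groups() -> list[TreatmentGroup]:
    """The 15 non-empty component subsets, by size then component order
    (singles CX, V, AI, AR first)."""
    return [TreatmentGroup(c)
            for k in range(1, len(COMPONENTS) + 1)
            for c in combinations(COMPONENTS, k)]


@dataclass
class CIMatrix:
    """Symmetric Bliss-CI matrix over treatment-group pairs; NaN marks
    inapplicable (overlapping) pairs and the diagonal."""

    groups: list
    values: np.ndarray
    outcome_type: str

    def to_frame(self) -> pd.DataFrame:
        labels = [g.label for g in self.groups]
        return pd.DataFrame(self.values, index=labels, columns=labels)

    def get(self, a: TreatmentGroup, b: TreatmentGroup) -> float:
        return float(self.values[self.groups.index(a), self.groups.index(b)])


# ---------------------------------------------------------------------------
# Outcome prediction and ranking


def predict_all_regimens(params: ParameterSet, grid: float = 0.05) -> pd.DataFrame:
    """Simulate every regimen and tabulate both tumor outcomes plus their
    inhibition percentage relative to the SX control."""
    rows = []
    for reg in enumerate_regimens():
        traj = simulate(params, reg, grid=grid)
        if not traj.valid:
            raise RuntimeError(f"invalid trajectory for regimen {reg.label}")
        rows.append({"regimen": reg.label, "n_components": reg.n_components,
                     "fitted": reg.label in
                     {Regimen.from_label(c).label for c in FITTED_CONDITIONS},
                     "type_I": outcome_instantaneous(traj),
                     "type_II": outcome_average(traj)})
    df = pd.DataFrame(rows)
    sx = df.loc[df["regimen"] == "SX"].iloc[0]
    df["inhibition_I"] = [percent_inhibition(v, sx["type_I"])
                          for v in df["type_I"]]
    df["inhibition_II"] = [percent_inhibition(v, sx["type_II"])
                           for v in df["type_II"]]
    return df


def rank_regimens(outcomes: pd.DataFrame, outcome_type: str = "I") -> pd.DataFrame:
    """Rank regimens by descending inhibition (1 = most effective), breaking
    exact ties by label so the ordering is deterministic; tied rows are
    flagged."""
    col = f"inhibition_{outcome_type}"
    if col not in outcomes.columns:
        raise ValueError(f"unknown outcome type {outcome_type!r}")
    df = outcomes.sort_values([col, "regimen"],
                              ascending=[False, True]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["tied"] = df[col].duplicated(keep=False)
    return df


def component_rank_table(outcomes: pd.DataFrame,
                         outcome_type: str = "I") -> dict[str, dict[int, list[int]]]:
    """For each treatment component, its regimens' ranks *within* each
    combination-size class (singles, pairs, triples) — the layout used to
    ask whether e.g. Treg depletion consistently outranks IL-2
    neutralization."""
    col = f"inhibition_{outcome_type}"
    table: dict[str, dict[int, list[int]]] = {c: {} for c in COMPONENTS}
    for size in (1, 2, 3):
        sub = outcomes[outcomes["n_components"] == size]
        sub = sub.sort_values([col, "regimen"], ascending=[False, True])
        labels = list(sub["regimen"])
        for comp in COMPONENTS:
            table[comp][size] = [i + 1 for i, lab in enumerate(labels)
                                 if comp in Regimen.from_label(lab).components]
    return table


# ---------------------------------------------------------------------------
# Local sensitivity


def local_sensitivity(params: ParameterSet, perturbation: float = 0.05,
                      conditions=FITTED_CONDITIONS,
                      n_steps: int = 500) -> pd.DataFrame:
    """Percent response of both tumor outcomes to a one-at-a-time relative
    increase of each rate constant, per condition:
    ``100 * (Y_perturbed - Y) / Y``."""
    if perturbation <= 0:
        raise ValueError("perturbation must be positive")
    params.validate()
    base = params.values
    P = np.vstack([base] + [params.perturbed(n, perturbation).values
                            for n in PARAM_NAMES])
    times = np.linspace(0.0, 5.0, 101)
    rows = []
    for cond in conditions:
        reg = Regimen.from_label(cond)
        states, ok = simulate_batch(P, reg, times, n_steps=n_steps)
        tumor = (states[:, :, 4] + states[:, :, 5]) / 2.0
        y1 = tumor[:, -1]
        y2 = np.trapezoid(tumor, times, axis=1) / 5.0
        for j, name in enumerate(PARAM_NAMES):
            for typ, y in (("I", y1), ("II", y2)):
                valid = bool(ok[0] and ok[j + 1]) and y[0] > 0
                rows.append({
                    "parameter": name, "index": j + 1, "condition": cond,
                    "outcome_type": typ,
                    "sensitivity": 100.0 * (y[j + 1] - y[0]) / y[0]
                    if valid else np.nan,
                    "valid": valid,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bliss combination index


def _clip_effect(e: float) -> float:
    if e < 0:
        warnings.warn("negative inhibition treated as zero effect",
                      stacklevel=3)
        return 0.0
    return min(e, 0.999)


def bliss_ci(effect_a: float, effect_b: float, effect_ab: float) -> float:
    """Bliss combination index of two disjoint treatments from their
    individual and combined inhibition fractions.  NaN when the combined
    effect is not positive (index undefined)."""
    e_a, e_b = _clip_effect(effect_a), _clip_effect(effect_b)
    if effect_ab <= 0:
        return float("nan")
    e_ab = min(effect_ab, 0.999)
    return (e_a + e_b - e_a * e_b) / e_ab


def ci_matrix(outcomes: pd.DataFrame, outcome_type: str = "I") -> CIMatrix:
    """Bliss CI for every disjoint pair of treatment groups.

    Effects are the inhibition fractions from :func:`predict_all_regimens`;
    the matrix is symmetric with NaN on the diagonal and on overlapping
    pairs (a component cannot combine with itself).
    """
    col = f"inhibition_{outcome_type}"
    if col not in outcomes.columns:
        raise ValueError(f"unknown outcome type {outcome_type!r}")
    eff = {Regimen.from_label(lab).label: v / 100.0
           for lab, v in zip(outcomes["regimen"], outcomes[col])}
    groups = all_groups()
    n = len(groups)
    values = np.full((n, n), np.nan)
    for i, a in enumerate(groups):
        for j, b in enumerate(groups):
            if j <= i or not a.disjoint(b):
                continue
            e_ab = eff[Regimen.from_label(a.union(b).regimen_label).label]
            ci = bliss_ci(eff[Regimen.from_label(a.regimen_label).label],
                          eff[Regimen.from_label(b.regimen_label).label],
                          e_ab)
            values[i, j] = values[j, i] = ci
    return CIMatrix(groups, values, outcome_type)


# ---------------------------------------------------------------------------
# Summary statistics


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def t_test(group_a, group_b, tails: str = "two") -> tuple[float, float]:
    """Unpaired Student t-test with pooled variance.

    ``tails="two"`` tests for any difference; ``tails="one"`` tests the
    directional alternative mean(a) > mean(b).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    alternative = "greater" if tails == "one" else "two-sided"
    res = stats.ttest_ind(a, b, equal_var=True, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def component_summary(outcomes: pd.DataFrame,
                      ci_matrices: dict[str, CIMatrix]) -> pd.DataFrame:
    """Per-component efficacy and synergy summaries.

    For each of CX, V, AI and AR: the mean inhibition over the 8 regimens
    containing it, and two synergy means over CI-matrix rows restricted to
    synergistic (CI < 1) entries — the "unmixed" mean over the component's
    singleton row and the "mixed" mean over every row whose group contains
    the component.  NaN when a row has no synergistic entry.
    """
    rows = []
    for comp in COMPONENTS:
        rec: dict = {"component": comp}
        mask = outcomes["regimen"].map(
            lambda lab: comp in Regimen.from_label(lab).components)
        for typ in ("I", "II"):
            rec[f"mean_inhibition_{typ}"] = float(
                outcomes.loc[mask, f"inhibition_{typ}"].mean())
        for typ, cim in ci_matrices.items():
            idx = [i for i, g in enumerate(cim.groups)
                   if g.components == (comp,)]
            row = cim.values[idx[0]]
            syn = row[np.isfinite(row) & (row < 1.0)]
            rec[f"unmixed_ci_{typ}"] = float(syn.mean()) if syn.size else np.nan
            ridx = [i for i, g in enumerate(cim.groups)
                    if comp in g.components]
            allrows = cim.values[ridx].ravel()
            syn_all = allrows[np.isfinite(allrows) & (allrows < 1.0)]
            rec[f"mixed_ci_{typ}"] = (float(syn_all.mean())
                                      if syn_all.size else np.nan)
        rows.append(rec)
    return pd.DataFrame(rows)
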