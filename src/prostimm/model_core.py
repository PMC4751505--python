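"""Two-compartment tumor-immune ODE model of prostate cancer therapy.

The model tracks fifteen state variables split between a prostate and a
lymphoid compartment:

* four treatment inputs — androgen ``A`` (castration drives its exponential
  decay), vaccine stimulus ``V``, anti-IL-2 antibody ``B_I`` and anti-Treg
  antibody ``B_R``, all first-order decaying;
* the tumor — castration-sensitive (``S``, CSPC) and castration-resistant
  (``R``, CRPC) cell populations sharing a logistic carrying capacity, plus a
  tumor-antigen pool ``Ag`` shed by dying tumor cells;
* the immune response — functional (``D_L``) and regulatory (``Dr_L``)
  dendritic cells, cytotoxic T lymphocytes, regulatory T cells and IL-2 in
  the lymphoid compartment (``C_L``, ``G_L``, ``I_L``) and, after
  trafficking, in the prostate (``C_P``, ``G_P``, ``I_P``).

CSPC proliferation is gated by androgen through a saturating Hill factor
``h(A) = A / (theta_A + A)``; androgen deprivation both slows CSPC growth and
drives the CSPC-to-CRPC transition.  CTLs kill both tumor populations,
antigen and vaccine activate dendritic cells, dendritic cells prime CTLs
(boosted by IL-2), IL-2 secreted by CTLs expands Tregs, and Tregs suppress
CTLs — the feedback loop that Treg depletion (AR) and IL-2 neutralization
(AI) are designed to break.

Time is measured in weeks post-treatment; all populations are relative to
their pre-treatment baseline, so every biological state starts at 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "STATE_NAMES",
    "PARAM_NAMES",
    "FIXED_CONSTANTS",
    "COMPONENTS",
    "Regimen",
    "ParameterSet",
    "Trajectory",
    "OutcomePair",
    "enumerate_regimens",
    "rhs",
    "simulate",
    "simulate_batch",
    "observe",
    "outcome_instantaneous",
    "outcome_average",
    "outcomes",
    "percent_inhibition",
]

#: State ordering used everywhere a state vector appears.
STATE_NAMES = (
    "A", "V", "B_I", "B_R",
    "S", "R", "Ag",
    "D_L", "Dr_L", "C_L", "G_L", "I_L",
    "C_P", "G_P", "I_P",
)

#: The 25 estimated rate constants, in their canonical 1-based ordering
#: (position 4 = CRPC proliferation, position 5 = CRPC apoptosis).
PARAM_NAMES = (
    "rho_S",     # 1  CSPC proliferation
    "delta_S",   # 2  CSPC apoptosis
    "lambda_SR", # 3  deprivation-driven CSPC -> CRPC transition
    "rho_R",     # 4  CRPC proliferation
    "delta_R",   # 5  CRPC apoptosis
    "eta_S",     # 6  CTL kill rate on CSPC
    "eta_R",     # 7  CTL kill rate on CRPC
    "theta_A",   # 8  androgen half-saturation
    "sigma_Ag",  # 9  antigen shedding per dying tumor cell
    "delta_Ag",  # 10 antigen clearance
    "alpha_D",   # 11 functional-DC activation
    "omega_V",   # 12 vaccine potency
    "delta_D",   # 13 functional-DC turnover
    "alpha_Dr",  # 14 regulatory-DC induction
    "delta_Dr",  # 15 regulatory-DC turnover
    "alpha_C",   # 16 CTL priming by DC
    "beta_I",    # 17 IL-2 boost on CTL priming
    "xi_C",      # 18 Treg suppression of CTL
    "mu_C",      # 19 CTL death
    "tau_C",     # 20 CTL trafficking lymphoid -> prostate
    "alpha_G",   # 21 IL-2-driven Treg expansion
    "zeta",      # 22 regulatory-DC-driven Treg induction
    "mu_G",      # 23 Treg death
    "tau_G",     # 24 Treg trafficking lymphoid -> prostate
    "sigma_I",   # 25 IL-2 secretion by CTL
)

#: Constants fixed by convention (per week unless dimensionless): treatment
#: decay rates, tumor carrying capacity (relative units), antibody
#: efficiencies and IL-2 clearance.  Only the 25 rates above are estimated.
FIXED_CONSTANTS: Mapping[str, float] = {
    "delta_A": 2.0,    # androgen decay under castration
    "delta_V": 1.0,    # vaccine stimulus decay
    "delta_BI": 1.0,   # anti-IL-2 antibody decay
    "delta_BR": 1.0,   # anti-Treg antibody decay
    "kappa": 20.0,     # tumor carrying capacity (relative to baseline = 2)
    "kappa_AI": 1.0,   # IL-2 neutralization efficiency
    "kappa_AR": 1.0,   # Treg depletion efficiency
    "delta_I": 1.0,    # IL-2 clearance
}

#: Treatment components in canonical display order.
COMPONENTS = ("CX", "V", "AI", "AR")

_STATE_CEILING = 1e7  # above this a trajectory is treated as blown up

# ---------------------------------------------------------------------------
# Regimen


@dataclass(frozen=True, order=True)
class Regimen:
    """A treatment regimen: any subset of {CX, V, AI, AR}.

    The empty subset is the sham-castrated, untreated control "SX".
    """

    cx: bool = False
    v: bool = False
    ai: bool = False
    ar: bool = False

    @property
    def components(self) -> tuple[str, ...]:
        out = []
        if self.cx:
            out.append("CX")
        if self.v:
            out.append("V")
        if self.ai:
            out.append("AI")
        if self.ar:
            out.append("AR")
        return tuple(out)

    @property
    def label(self) -> str:
        return " + ".join(self.components) if self.components else "SX"

    @property
    def n_components(self) -> int:
        return sum((self.cx, self.v, self.ai, self.ar))

    @classmethod
    def from_components(cls, components: Iterable[str]) -> "Regimen":
        comp = set(components)
        unknown = comp - set(COMPONENTS) - {"SX"}
        if unknown:
            raise ValueError(f"unknown treatment components: {sorted(unknown)}")
        return cls(cx="CX" in comp, v="V" in comp, ai="AI" in comp, ar="AR" in comp)

    @classmethod
    def from_label(cls, label: str) -> "Regimen":
        """Parse labels like "CX + V + AR"; a leading "SX" token is the
        sham-castration control and carries no treatment ("SX + V" == "V")."""
        tokens = [t.strip() for t in label.split("+") if t.strip()]
        return cls.from_components(t for t in tokens if t != "SX")

    def initial_state(self) -> np.ndarray:
        """Regimen-determined initial condition: androgen always 1, treatment
        inputs 1 iff their flag is on, every biological state 1."""
        y0 = np.ones(len(STATE_NAMES))
        y0[1] = 1.0 if self.v else 0.0
        y0[2] = 1.0 if self.ai else 0.0
        y0[3] = 1.0 if self.ar else 0.0
        return y0


def enumerate_regimens() -> list[Regimen]:
    """All 16 regimens: SX first, then by component count, then by label."""
    regs = [Regimen.from_components(c)
            for k in range(len(COMPONENTS) + 1)
            for c in combinations(COMPONENTS, k)]
    return sorted(regs, key=lambda r: (r.n_components, r.label))


# ---------------------------------------------------------------------------
# ParameterSet


@dataclass
class ParameterSet:
    """The 25 estimated rate constants with their search bounds.

    ``values`` follows :data:`PARAM_NAMES`; bounds default to the log-wide
    search box [1e-3, 1e2] used for calibration.
    """

    values: np.ndarray
    lower: np.ndarray = field(default=None)  # type: ignore[assignment]
    upper: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(PARAM_NAMES),):
            raise ValueError(
                f"expected {len(PARAM_NAMES)} parameters, got {self.values.shape}")
        if self.lower is None:
            self.lower = np.full(len(PARAM_NAMES), 1e-3)
        if self.upper is None:
            self.upper = np.full(len(PARAM_NAMES), 1e2)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not np.all(np.isfinite(self.values)):
            bad = PARAM_NAMES[int(np.flatnonzero(~np.isfinite(self.values))[0])]
            raise ValueError(f"non-finite parameter value: {bad}")

    def __getitem__(self, name: str) -> float:
        return float(self.values[PARAM_NAMES.index(name)])

    def validate(self) -> None:
        """Raise if any value is non-positive or outside its bounds."""
        for i, name in enumerate(PARAM_NAMES):
            v = self.values[i]
            if v <= 0:
                raise ValueError(f"parameter {name} must be strictly positive, got {v}")
            if not (self.lower[i] <= v <= self.upper[i]):
                raise ValueError(
                    f"parameter {name}={v} outside bounds "
                    f"[{self.lower[i]}, {self.upper[i]}]")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES, map(float, self.values)))

    @classmethod
    def from_dict(cls, d: Mapping[str, float], lower=None, upper=None) -> "ParameterSet":
        missing = set(PARAM_NAMES) - set(d)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")
        return cls(np.array([d[n] for n in PARAM_NAMES]), lower, upper)

    def perturbed(self, name: str, fraction: float) -> "ParameterSet":
        """Copy with one parameter scaled by (1 + fraction); bounds untouched."""
        v = self.values.copy()
        v[PARAM_NAMES.index(name)] *= 1.0 + fraction
        return ParameterSet(v, self.lower.copy(), self.upper.copy())

    # -- flat file round trip: symbol -> {value, lower, upper, estimated, order}

    def to_file(self, path) -> None:
        rec: dict[str, dict] = {}
        for i, name in enumerate(PARAM_NAMES):
            rec[name] = {"value": float(self.values[i]),
                         "lower": float(self.lower[i]),
                         "upper": float(self.upper[i]),
                         "estimated": True, "order": i + 1}
        for name, v in FIXED_CONSTANTS.items():
            rec[name] = {"value": float(v), "estimated": False}
        path = str(path)
        if path.endswith((".yaml", ".yml")):
            import yaml
            with open(path, "w") as fh:
                yaml.safe_dump(rec, fh, sort_keys=False)
        else:
            with open(path, "w") as fh:
                json.dump(rec, fh, indent=1)

    @classmethod
    def from_file(cls, path) -> "ParameterSet":
        path = str(path)
        if path.endswith((".yaml", ".yml")):
            import yaml
            with open(path) as fh:
                rec = yaml.safe_load(fh)
        else:
            with open(path) as fh:
                rec = json.load(fh)
        est = {k: v for k, v in rec.items() if v.get("estimated")}
        ordered = sorted(est, key=lambda k: est[k]["order"])
        if tuple(ordered) != PARAM_NAMES:
            raise ValueError("parameter file does not match the canonical 25-entry layout")
        return cls(
            np.array([est[k]["value"] for k in PARAM_NAMES]),
            np.array([est[k].get("lower", 1e-3) for k in PARAM_NAMES]),
            np.array([est[k].get("upper", 1e2) for k in PARAM_NAMES]),
        )


# ---------------------------------------------------------------------------
# Right-hand side


def rhs(state: Sequence[float], t: float, params: ParameterSet,
        regimen: Regimen) -> np.ndarray:
    """Time derivative of the 15-dimensional state.

    Treatment inputs decay exponentially (androgen only under castration);
    CSPC growth is androgen-gated and logistic jointly with CRPC; antigen is
    shed in proportion to tumor cell death; both dendritic cell types are
    driven by antigen plus vaccine; CTLs are primed by functional DCs with an
    IL-2 boost, suppressed by Tregs, and traffic to the prostate; Tregs
    expand on IL-2 and regulatory DCs; antibodies remove IL-2 (AI) or Tregs
    (AR) mass-action style.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (15,):
        raise ValueError(f"state must have 15 components, got {y.shape}")
    if not np.all(np.isfinite(y)):
        bad = STATE_NAMES[int(np.flatnonzero(~np.isfinite(y))[0])]
        raise ValueError(f"non-finite state component: {bad}")
    p = params.values
    if not np.all(np.isfinite(p)):
        bad = PARAM_NAMES[int(np.flatnonzero(~np.isfinite(p))[0])]
        raise ValueError(f"non-finite parameter: {bad}")

    (rho_S, delta_S, lam, rho_R, delta_R, eta_S, eta_R, theta_A,
     sigma_Ag, delta_Ag, alpha_D, omega_V, delta_D, alpha_Dr, delta_Dr,
     alpha_C, beta_I, xi_C, mu_C, tau_C, alpha_G, zeta, mu_G, tau_G,
     sigma_I) = p
    c = FIXED_CONSTANTS
    A, V, B_I, B_R, S, R, Ag, D_L, Dr_L, C_L, G_L, I_L, C_P, G_P, I_P = y

    chi_cx = 1.0 if regimen.cx else 0.0
    h = A / (theta_A + A)               # androgen gating of CSPC growth
    crowd = 1.0 - (S + R) / c["kappa"]  # shared logistic crowding
    kill_S = eta_S * C_P * S
    kill_R = eta_R * C_P * R
    stim = Ag + omega_V * V             # DC activation signal

    return np.array([
        -c["delta_A"] * chi_cx * A,
        -c["delta_V"] * V,
        -c["delta_BI"] * B_I,
        -c["delta_BR"] * B_R,
        rho_S * h * S * crowd - delta_S * S - lam * (1.0 - h) * S - kill_S,
        rho_R * R * crowd - delta_R * R + lam * (1.0 - h) * S - kill_R,
        sigma_Ag * (delta_S * S + delta_R * R + kill_S + kill_R) - delta_Ag * Ag,
        alpha_D * stim - delta_D * D_L,
        alpha_Dr * stim * G_L - delta_Dr * Dr_L,
        alpha_C * D_L * (1.0 + beta_I * I_L) - xi_C * G_L * C_L - mu_C * C_L
        - tau_C * C_L,
        alpha_G * I_L * G_L + zeta * Dr_L - mu_G * G_L - tau_G * G_L
        - c["kappa_AR"] * B_R * G_L,
        sigma_I * C_L - c["delta_I"] * I_L - c["kappa_AI"] * B_I * I_L,
        tau_C * C_L - xi_C * G_P * C_P - mu_C * C_P,
        tau_G * G_L + alpha_G * I_P * G_P - mu_G * G_P - c["kappa_AR"] * B_R * G_P,
        sigma_I * C_P - c["delta_I"] * I_P - c["kappa_AI"] * B_I * I_P,
    ])


# ---------------------------------------------------------------------------
# Trajectories


@dataclass
class Trajectory:
    """A solved time course: ``states[i, j]`` is state ``STATE_NAMES[j]`` at
    ``times[i]``.  ``valid`` is False when the solver failed or blew up."""

    times: np.ndarray
    states: np.ndarray
    regimen: Regimen
    params: ParameterSet
    valid: bool = True

    def state(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def at(self, name: str, t: float) -> float:
        tmax = self.times[-1]
        if t > tmax + 1e-9:
            raise ValueError(f"time {t} beyond trajectory horizon {tmax}")
        return float(np.interp(t, self.times, self.state(name)))

    def to_frame(self):
        """Tidy (time, state, value, regimen) table."""
        import pandas as pd
        nt = len(self.times)
        return pd.DataFrame({
            "time": np.repeat(self.times, len(STATE_NAMES)),
            "state": np.tile(STATE_NAMES, nt),
            "value": self.states.ravel(),
            "regimen": self.regimen.label,
        })


@dataclass(frozen=True)
class OutcomePair:
    """Tumor-size outcomes: instantaneous at 5 weeks (type I) and averaged
    over weeks 0-5 (type II)."""

    type_I: float
    type_II: float


def simulate(params: ParameterSet, regimen: Regimen, horizon: float = 5.0,
             grid: float = 0.05) -> Trajectory:
    """Integrate the model with LSODA (rtol 1e-6, atol 1e-8) on a uniform
    grid of step ``grid`` covering [0, horizon]; states are floored at 0."""
    n = int(round(horizon / grid))
    times = np.linspace(0.0, horizon, n + 1)
    y0 = regimen.initial_state()

    def f(t, y):
        return rhs(np.maximum(y, 0.0), t, params, regimen)

    sol = solve_ivp(f, (0.0, horizon), y0, method="LSODA", t_eval=times,
                    rtol=1e-6, atol=1e-8)
    if not sol.success or not np.all(np.isfinite(sol.y)) \
            or np.max(sol.y) > _STATE_CEILING:
        return Trajectory(times, np.full((len(times), 15), np.nan),
                          regimen, params, valid=False)
    return Trajectory(times, np.maximum(sol.y.T, 0.0), regimen, params)


def simulate_batch(param_matrix: np.ndarray, regimen: Regimen,
                   times: Sequence[float], n_steps: int = 250,
                   horizon: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Integrate many parameter sets at once with fixed-step RK4.

    Vectorized over the first axis of ``param_matrix`` (shape (m, 25)); used
    by the genetic-algorithm objective where millions of model evaluations
    are needed and per-solve adaptive stepping would dominate runtime.  The
    calibrated system is non-stiff on the 0-5 week horizon, and 250 steps
    reproduce the adaptive reference solution to ~1e-5.

    Returns ``(states, valid)`` with states of shape (m, len(times), 15)
    evaluated by linear interpolation of the step grid, and a boolean
    validity mask (False where the solution left the finite range).
    """
    P = np.atleast_2d(np.asarray(param_matrix, dtype=float))
    if _numba_rk4 is not None:
        consts = np.array([FIXED_CONSTANTS[k] for k in
                           ("delta_A", "delta_V", "delta_BI", "delta_BR",
                            "kappa", "kappa_AI", "kappa_AR", "delta_I")])
        traj = _numba_rk4(np.ascontiguousarray(P),
                          1.0 if regimen.cx else 0.0,
                          regimen.initial_state(), consts,
                          horizon / n_steps, n_steps, _STATE_CEILING * 10)
        return _sample_times(traj, np.asarray(times, dtype=float),
                             horizon, n_steps)
    return _simulate_batch_numpy(P, regimen, times, n_steps, horizon)


def _sample_times(traj: np.ndarray, times: np.ndarray, horizon: float,
                  n_steps: int) -> tuple[np.ndarray, np.ndarray]:
    grid_t = np.linspace(0.0, horizon, n_steps + 1)
    dt = horizon / n_steps
    valid = np.all(traj < _STATE_CEILING, axis=(1, 2))
    out = np.empty((traj.shape[0], len(times), 15))
    for j, t in enumerate(times):
        idx = min(max(int(np.searchsorted(grid_t, t)), 1), n_steps)
        w = (t - grid_t[idx - 1]) / dt
        out[:, j] = (1 - w) * traj[:, idx - 1] + w * traj[:, idx]
    return out, valid


def _simulate_batch_numpy(P: np.ndarray, regimen: Regimen,
                          times: Sequence[float], n_steps: int,
                          horizon: float) -> tuple[np.ndarray, np.ndarray]:
    """Pure-numpy batch RK4 (reference path; also the fallback when the
    jitted kernel is unavailable)."""
    m = P.shape[0]
    (rho_S, delta_S, lam, rho_R, delta_R, eta_S, eta_R, theta_A,
     sigma_Ag, delta_Ag, alpha_D, omega_V, delta_D, alpha_Dr, delta_Dr,
     alpha_C, beta_I, xi_C, mu_C, tau_C, alpha_G, zeta, mu_G, tau_G,
     sigma_I) = (P[:, i] for i in range(25))
    c = FIXED_CONSTANTS
    chi = 1.0 if regimen.cx else 0.0

    def f(y):
        A, V, B_I, B_R, S, R, Ag, D_L, Dr_L, C_L, G_L, I_L, C_P, G_P, I_P = (
            y[:, i] for i in range(15))
        h = A / (theta_A + A)
        crowd = 1.0 - (S + R) / c["kappa"]
        kill_S = eta_S * C_P * S
        kill_R = eta_R * C_P * R
        stim = Ag + omega_V * V
        return np.stack([
            -c["delta_A"] * chi * A,
            -c["delta_V"] * V,
            -c["delta_BI"] * B_I,
            -c["delta_BR"] * B_R,
            rho_S * h * S * crowd - delta_S * S - lam * (1 - h) * S - kill_S,
            rho_R * R * crowd - delta_R * R + lam * (1 - h) * S - kill_R,
            sigma_Ag * (delta_S * S + delta_R * R + kill_S + kill_R)
            - delta_Ag * Ag,
            alpha_D * stim - delta_D * D_L,
            alpha_Dr * stim * G_L - delta_Dr * Dr_L,
            alpha_C * D_L * (1 + beta_I * I_L) - (xi_C * G_L + mu_C + tau_C) * C_L,
            alpha_G * I_L * G_L + zeta * Dr_L
            - (mu_G + tau_G + c["kappa_AR"] * B_R) * G_L,
            sigma_I * C_L - (c["delta_I"] + c["kappa_AI"] * B_I) * I_L,
            tau_C * C_L - (xi_C * G_P + mu_C) * C_P,
            tau_G * G_L + alpha_G * I_P * G_P
            - (mu_G + c["kappa_AR"] * B_R) * G_P,
            sigma_I * C_P - (c["delta_I"] + c["kappa_AI"] * B_I) * I_P,
        ], axis=1)

    dt = horizon / n_steps
    grid_t = np.linspace(0.0, horizon, n_steps + 1)
    y = np.tile(regimen.initial_state(), (m, 1))
    traj = np.empty((m, n_steps + 1, 15))
    traj[:, 0] = y
    with np.errstate(all="ignore"):
        for k in range(n_steps):
            k1 = f(y)
            k2 = f(np.maximum(y + 0.5 * dt * k1, 0.0))
            k3 = f(np.maximum(y + 0.5 * dt * k2, 0.0))
            k4 = f(np.maximum(y + dt * k3, 0.0))
            y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            y = np.clip(np.nan_to_num(y, nan=np.inf, posinf=np.inf,
                                      neginf=0.0), 0.0, _STATE_CEILING * 10)
            traj[:, k + 1] = y
    return _sample_times(traj, np.asarray(times, dtype=float),
                         horizon, n_steps)


def _build_numba_rk4():
    """JIT-compiled RK4 kernel over a population of parameter sets; returns
    None when numba is unavailable so the numpy path takes over."""
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is an optional speedup
        return None

    @njit(cache=True)
    def kernel(P, chi_cx, y0, c, dt, n_steps, ceiling):
        m = P.shape[0]
        traj = np.empty((m, n_steps + 1, 15))
        d_A, d_V, d_BI, d_BR, kappa, k_AI, k_AR, d_I = (
            c[0], c[1], c[2], c[3], c[4], c[5], c[6], c[7])
        k1 = np.empty(15)
        k2 = np.empty(15)
        k3 = np.empty(15)
        k4 = np.empty(15)
        yt = np.empty(15)
        for i in range(m):
            (rho_S, delta_S, lam, rho_R, delta_R, eta_S, eta_R, theta_A,
             sigma_Ag, delta_Ag, alpha_D, omega_V, delta_D, alpha_Dr,
             delta_Dr, alpha_C, beta_I, xi_C, mu_C, tau_C, alpha_G, zeta,
             mu_G, tau_G, sigma_I) = (
                P[i, 0], P[i, 1], P[i, 2], P[i, 3], P[i, 4], P[i, 5],
                P[i, 6], P[i, 7], P[i, 8], P[i, 9], P[i, 10], P[i, 11],
                P[i, 12], P[i, 13], P[i, 14], P[i, 15], P[i, 16], P[i, 17],
                P[i, 18], P[i, 19], P[i, 20], P[i, 21], P[i, 22], P[i, 23],
                P[i, 24])
            y = y0.copy()
            traj[i, 0] = y

            def deriv(y, out):
                A, V, B_I, B_R = y[0], y[1], y[2], y[3]
                S, R, Ag = y[4], y[5], y[6]
                D_L, Dr_L, C_L, G_L, I_L = y[7], y[8], y[9], y[10], y[11]
                C_P, G_P, I_P = y[12], y[13], y[14]
                h = A / (theta_A + A)
                crowd = 1.0 - (S + R) / kappa
                kill_S = eta_S * C_P * S
                kill_R = eta_R * C_P * R
                stim = Ag + omega_V * V
                out[0] = -d_A * chi_cx * A
                out[1] = -d_V * V
                out[2] = -d_BI * B_I
                out[3] = -d_BR * B_R
                out[4] = (rho_S * h * S * crowd - delta_S * S
                          - lam * (1.0 - h) * S - kill_S)
                out[5] = (rho_R * R * crowd - delta_R * R
                          + lam * (1.0 - h) * S - kill_R)
                out[6] = (sigma_Ag * (delta_S * S + delta_R * R
                                      + kill_S + kill_R) - delta_Ag * Ag)
                out[7] = alpha_D * stim - delta_D * D_L
                out[8] = alpha_Dr * stim * G_L - delta_Dr * Dr_L
                out[9] = (alpha_C * D_L * (1.0 + beta_I * I_L)
                          - (xi_C * G_L + mu_C + tau_C) * C_L)
                out[10] = (alpha_G * I_L * G_L + zeta * Dr_L
                           - (mu_G + tau_G + k_AR * B_R) * G_L)
                out[11] = sigma_I * C_L - (d_I + k_AI * B_I) * I_L
                out[12] = tau_C * C_L - (xi_C * G_P + mu_C) * C_P
                out[13] = (tau_G * G_L + alpha_G * I_P * G_P
                           - (mu_G + k_AR * B_R) * G_P)
                out[14] = sigma_I * C_P - (d_I + k_AI * B_I) * I_P

            for s in range(n_steps):
                deriv(y, k1)
                for j in range(15):
                    yt[j] = max(y[j] + 0.5 * dt * k1[j], 0.0)
                deriv(yt, k2)
                for j in range(15):
                    yt[j] = max(y[j] + 0.5 * dt * k2[j], 0.0)
                deriv(yt, k3)
                for j in range(15):
                    yt[j] = max(y[j] + dt * k3[j], 0.0)
                deriv(yt, k4)
                blown = False
                for j in range(15):
                    v = y[j] + (dt / 6.0) * (k1[j] + 2.0 * k2[j]
                                             + 2.0 * k3[j] + k4[j])
                    if not np.isfinite(v):
                        v = ceiling
                    y[j] = min(max(v, 0.0), ceiling)
                    if y[j] >= ceiling:
                        blown = True
                traj[i, s + 1] = y
                if blown:
                    for rest in range(s + 2, n_steps + 1):
                        traj[i, rest] = y
                    break
        return traj

    return kernel


_numba_rk4 = _build_numba_rk4()


# ---------------------------------------------------------------------------
# Observables and outcomes

#: Measured observables: relative tumor size and the four T-cell populations.
OBSERVABLE_STATES = {
    "CTL-P": "C_P",
    "Treg-P": "G_P",
    "CTL-L": "C_L",
    "Treg-L": "G_L",
}


def observe(traj: Trajectory) -> dict[str, np.ndarray]:
    """The five measured series along ``traj.times``.

    Tumor is the total tumor population (CSPC + CRPC) relative to its
    initial value; the T-cell observables are already relative populations.
    """
    if not traj.valid:
        raise ValueError("cannot observe an invalid trajectory")
    total = traj.state("S") + traj.state("R")
    if total[0] <= 0:
        raise ValueError("initial tumor population must be positive")
    out = {"Tumor": total / total[0]}
    for obs, st in OBSERVABLE_STATES.items():
        out[obs] = traj.state(st)
    return out


def observe_at(traj: Trajectory, observable: str, t: float) -> float:
    series = observe(traj)[observable]
    return float(np.interp(t, traj.times, series))


def outcome_instantaneous(traj: Trajectory) -> float:
    """Type-I outcome: relative tumor size at 5 weeks post-treatment."""
    if not traj.valid:
        raise ValueError("invalid trajectory has no outcome")
    if traj.times[-1] < 5.0 - 1e-9:
        raise ValueError("trajectory horizon shorter than 5 weeks")
    series = observe(traj)["Tumor"]
    return float(np.interp(5.0, traj.times, series))


def outcome_average(traj: Trajectory) -> float:
    """Type-II outcome: relative tumor size averaged over weeks 0-5
    (trapezoid rule on the solution grid)."""
    if not traj.valid:
        raise ValueError("invalid trajectory has no outcome")
    if traj.times[-1] < 5.0 - 1e-9:
        raise ValueError("trajectory horizon shorter than 5 weeks")
    series = observe(traj)["Tumor"]
    mask = traj.times <= 5.0 + 1e-12
    return float(np.trapezoid(series[mask], traj.times[mask]) / 5.0)


def outcomes(traj: Trajectory) -> OutcomePair:
    return OutcomePair(outcome_instantaneous(traj), outcome_average(traj))


def percent_inhibition(outcome_regimen: float, outcome_control: float) -> float:
    """Treatment effect: percentage reduction of the tumor-size outcome
    relative to the untreated control (negative if the treatment worsens it)."""
    if outcome_control <= 0:
        raise ValueError("control outcome must be strictly positive")
    return 100.0 * (1.0 - outcome_regimen / outcome_control)
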