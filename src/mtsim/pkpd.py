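"""Semi-mechanistic PK/PD model of 6-mercaptopurine myelosuppression.

The model couples a linear three-compartment pharmacokinetic cascade for oral
6MP (gut amount, plasma 6MP, active metabolite 6-TGN) to a Friberg-type
transit-compartment model of neutrophil maturation: a proliferating pool,
three transit compartments, and circulating mature neutrophils (the observed
absolute neutrophil count, ANC).  The drug acts through a linear inhibition
``E_drug = slope * x_6tgn`` of the feedback-regulated proliferation rate
``k_tr * (Base / x_ma)**gamma``; 6-TGN clearance scales with body surface
area as ``cl_coef * BSA**cl_exp``.

All rates are per day; cell states are in G/L (1e9 cells/L); drug amounts in
mg (6-TGN on the mg/L scale of the published clearance).  Oral doses enter as
impulses of ``F * amount`` into the gut compartment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._kernels import simulate_states

__all__ = [
    "STATE_NAMES",
    "PKConstants",
    "IndividualParameters",
    "DoseSchedule",
    "SimulationGrid",
    "Trajectory",
    "clearance_6tgn",
    "drug_effect",
    "steady_state_init",
    "rhs",
    "simulate",
]

#: Order of the state vector components.
STATE_NAMES = ("x_6mpgut", "x_6mp", "x_6tgn",
               "x_pr", "x_tr1", "x_tr2", "x_tr3", "x_ma")

#: Number of transit compartments between the proliferating pool and blood;
#: the mean maturation time is ``N_TRANSIT / k_tr``.
N_TRANSIT = 3


@dataclass(frozen=True)
class PKConstants:
    """Published fixed constants of the 6MP pharmacokinetic model.

    Defaults are the literature values used throughout: bioavailability
    F = 0.22, absorption 31.2/day, elimination 12.72/day, fraction 0.019 of
    the metabolic rate 9.9216/day transformed to 6-TGN, 6-TGN clearance
    0.219 * BSA**1.16 per day, and mature-neutrophil death rate 2.3765/day.
    """

    F: float = 0.22
    k_a: float = 31.2
    k_20: float = 12.72
    FM3: float = 0.019
    k_me: float = 9.9216
    cl_coef: float = 0.219
    cl_exp: float = 1.16
    k_ma: float = 2.3765

    def __post_init__(self) -> None:
        for name in ("F", "k_a", "k_20", "FM3", "k_me", "cl_coef", "cl_exp", "k_ma"):
            if not getattr(self, name) > 0:
                raise ValueError(f"PKConstants.{name} must be strictly positive")
        if self.F > 1:
            raise ValueError("bioavailability F must not exceed 1")
        if self.FM3 > 1:
            raise ValueError("metabolic fraction FM3 must not exceed 1")

    @property
    def k_met(self) -> float:
        """Effective 6MP -> 6-TGN transformation rate (FM3 * k_me, 1/day)."""
        return self.FM3 * self.k_me


@dataclass(frozen=True)
class IndividualParameters:
    """Per-patient pharmacodynamic parameters.

    Base
        Neutrophil baseline (untreated steady state), G/L.
    k_tr
        Transit/maturation rate, 1/day.
    gamma
        Exponent of the feedback term ``(Base / x_ma)**gamma``.
    slope
        Linear drug-effect coefficient on the 6-TGN scale (1 / (mg/L)).
    """

    Base: float
    k_tr: float
    gamma: float
    slope: float

    def __post_init__(self) -> None:
        for name in ("Base", "k_tr", "gamma", "slope"):
            if not getattr(self, name) > 0:
                raise ValueError(f"IndividualParameters.{name} must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.Base, self.k_tr, self.gamma, self.slope])

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "IndividualParameters":
        return cls(Base=float(a[0]), k_tr=float(a[1]),
                   gamma=float(a[2]), slope=float(a[3]))

    def scaled(self, eta: Sequence[float]) -> "IndividualParameters":
        """Apply log-normal random effects: parameter * exp(eta)."""
        e = np.asarray(eta, dtype=float)
        return IndividualParameters(self.Base * math.exp(e[0]),
                                    self.k_tr * math.exp(e[1]),
                                    self.gamma * math.exp(e[2]),
                                    self.slope * math.exp(e[3]))


@dataclass(frozen=True)
class DoseSchedule:
    """Ordered impulse oral doses: administration times (day) and amounts (mg)."""

    times: np.ndarray
    amounts: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amounts, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and amounts must be 1-d arrays of equal length")
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("dose times must be nondecreasing")
        if np.any(a < 0):
            raise ValueError("dose amounts must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amounts", a)

    def __len__(self) -> int:
        return self.times.size

    @classmethod
    def empty(cls) -> "DoseSchedule":
        return cls(np.empty(0), np.empty(0))

    @classmethod
    def daily(cls, amount: float, start: float = 0.0, n_days: int = 1) -> "DoseSchedule":
        t = start + np.arange(n_days, dtype=float)
        return cls(t, np.full(n_days, float(amount)))

    def scaled(self, factor: float) -> "DoseSchedule":
        return DoseSchedule(self.times.copy(), self.amounts * factor)


@dataclass(frozen=True)
class SimulationGrid:
    """Output grid: window [t0, tf] and sorted sample times inside it."""

    t0: float
    tf: float
    output_times: np.ndarray

    def __post_init__(self) -> None:
        ot = np.asarray(self.output_times, dtype=float)
        if ot.ndim != 1 or ot.size == 0:
            raise ValueError("output_times must be a nonempty 1-d array")
        if np.any(np.diff(ot) < 0):
            raise ValueError("output_times must be sorted")
        if not (self.t0 <= ot[0] and ot[-1] <= self.tf):
            raise ValueError("output_times must lie within [t0, tf]")
        object.__setattr__(self, "output_times", ot)

    @classmethod
    def regular(cls, t0: float, tf: float, dt: float = 1.0) -> "SimulationGrid":
        return cls(t0, tf, np.arange(t0, tf + 0.5 * dt, dt))


class Trajectory:
    """Sampled state trajectory of one simulated patient."""

    def __init__(self, times: np.ndarray, states: np.ndarray):
        self.times = np.asarray(times, dtype=float)
        self.states = np.asarray(states, dtype=float)
        if self.states.shape != (self.times.size, len(STATE_NAMES)):
            raise ValueError("states must be (n_times, 8)")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    @property
    def anc(self) -> np.ndarray:
        """Circulating mature neutrophils x_ma (the model's ANC), G/L."""
        return self.states[:, 7]

    @property
    def ok(self) -> bool:
        return not np.any(np.isnan(self.states))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.states, columns=list(STATE_NAMES),
                            index=pd.Index(self.times, name="time"))

    def to_tidy(self, patient_id) -> "pd.DataFrame":  # noqa: F821
        """Long-format export (patient_id, time, state, value) for plotting."""
        df = self.to_frame().reset_index().melt(
            id_vars="time", var_name="state", value_name="value")
        df.insert(0, "patient_id", patient_id)
        return df


def clearance_6tgn(bsa: float, consts: PKConstants = PKConstants()) -> float:
    """BSA-dependent 6-TGN clearance ``cl_coef * BSA**cl_exp`` (per day)."""
    if bsa < 0:
        raise ValueError("BSA must be nonnegative")
    return consts.cl_coef * bsa ** consts.cl_exp


def drug_effect(slope: float, x_6tgn: float) -> float:
    """Linear PD effect ``E_drug = slope * x_6tgn`` (dimensionless).

    Values >= 1 shut proliferation down entirely (net kill); they are
    deliberately not clipped.
    """
    if slope < 0 or np.any(np.asarray(x_6tgn) < 0):
        raise ValueError("slope and x_6tgn must be nonnegative")
    return slope * x_6tgn


def steady_state_init(params: IndividualParameters,
                      consts: PKConstants = PKConstants()) -> np.ndarray:
    """Drug-free equilibrium: zero drug states, proliferating/transit pools at
    ``Base * k_ma / k_tr`` and circulating neutrophils at ``Base``."""
    pool = params.Base * consts.k_ma / params.k_tr
    return np.array([0.0, 0.0, 0.0, pool, pool, pool, pool, params.Base])


def rhs(t: float, x: np.ndarray, params: IndividualParameters,
        consts: PKConstants, bsa: float) -> np.ndarray:
    """Continuous right-hand side of the 8-state system (dosing impulses are
    handled outside).  Reference implementation used by tests and oracles;
    simulation goes through the compiled kernel."""
    x = np.asarray(x, dtype=float)
    if x[7] <= 0:
        raise FloatingPointError("x_ma <= 0: feedback term undefined")
    cl = clearance_6tgn(bsa, consts)
    e_drug = params.slope * x[2]
    fb = (params.Base / x[7]) ** params.gamma
    dx = np.empty(8)
    dx[0] = -consts.k_a * x[0]
    dx[1] = consts.k_a * x[0] - consts.k_20 * x[1]
    dx[2] = consts.k_met * x[1] - cl * x[2]
    dx[3] = params.k_tr * x[3] * (1.0 - e_drug) * fb - params.k_tr * x[3]
    dx[4] = params.k_tr * (x[3] - x[4])
    dx[5] = params.k_tr * (x[4] - x[5])
    dx[6] = params.k_tr * (x[5] - x[6])
    dx[7] = params.k_tr * x[6] - consts.k_ma * x[7]
    return dx


class IntegrationError(RuntimeError):
    """Raised when a trajectory leaves the admissible region (x_ma <= 0)."""


def simulate(params: IndividualParameters,
             consts: PKConstants,
             bsa: float,
             doses: DoseSchedule,
             grid: SimulationGrid,
             x0="steady-state",
             step: float = 0.05) -> Trajectory:
    """Simulate the model under impulse oral dosing.

    ``x0`` is either the string ``"steady-state"`` (drug-free equilibrium) or
    an explicit nonnegative 8-vector.  ``step`` is the maximum RK4 step (day)
    for the myelosuppression subsystem; the PK cascade is exact regardless.
    """
    if doses.times.size and (doses.times[0] < grid.t0 or doses.times[-1] > grid.tf):
        raise ValueError("dose times must lie within [t0, tf]")
    if isinstance(x0, str):
        if x0 != "steady-state":
            raise ValueError(f"unknown x0 spec {x0!r}")
        x0v = steady_state_init(params, consts)
    else:
        x0v = np.asarray(x0, dtype=float)
        if x0v.shape != (8,) or np.any(x0v < 0):
            raise ValueError("x0 must be a nonnegative 8-vector")
    cl = clearance_6tgn(bsa, consts)
    states = simulate_states(
        np.asarray(grid.output_times, dtype=float),
        doses.times, doses.amounts, x0v, float(grid.t0),
        params.Base, params.k_tr, params.gamma, params.slope,
        consts.F, consts.k_a, consts.k_20, consts.k_met, cl, consts.k_ma,
        float(step))
    if np.any(np.isnan(states)):
        bad = grid.output_times[np.isnan(states[:, 7])]
        raise IntegrationError(
            f"x_ma reached zero; first failed output time {bad[0]:.3f}")
    return Trajectory(grid.output_times, states)
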