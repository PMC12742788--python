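"""Hybrid dynamics of the powered simplest walker.

The model is a planar biped with rigid massless legs, a point hip mass and
infinitesimal foot masses, walking on level ground.  The stance leg behaves
as an inverted pendulum; the swing leg is driven by one of two hip springs
(stiffness ``k1`` while the inter-leg angle phi is positive, ``k2`` once it
crosses zero).  A step ends when the swing foot reaches the ground away from
the scuff configuration; an impulsive push-off ``P`` directed along the
stance leg is applied just before the perfectly inelastic heel-strike
collision, and the composite transition swaps the legs.

All quantities are dimensionless: masses are scaled by the total mass M,
lengths by the leg length l, and time by sqrt(l / g).

Conventions
-----------
The stance angle theta is measured from vertical and the swing angle phi
from the stance leg.  A nominal step starts just after a collision at
theta = +theta0 with theta_dot < 0, passes mid-stance (theta = 0) and ends
in a new collision at theta = -theta0; phi runs from +2 theta0 through zero
(where the active spring switches) to -2 theta0.  At every valid contact
phi = 2 theta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernel
from ._kernel import COMPLETED, FELL, NO_CONTACT, STEP_FAIL

__all__ = [
    "WalkerState", "ActuationInput", "StepResult", "ScalingConstants",
    "swing_derivatives", "heelstrike_map", "swing_foot_height",
    "expand_state", "simulate_step", "step_map", "IntegrationError",
    "DEFAULT_TOL", "DEFAULT_T_MAX", "DEFAULT_GUARD",
]

DEFAULT_TOL = 1e-13
DEFAULT_T_MAX = 50.0
DEFAULT_GUARD = 1e-6

_OUTCOME_NAMES = {COMPLETED: "completed", FELL: "fell",
                  NO_CONTACT: "no_contact"}


class IntegrationError(RuntimeError):
    """The adaptive integrator failed (distinct from a fall / no contact)."""


@dataclass(frozen=True)
class WalkerState:
    """Instantaneous continuous state of the walker (dimensionless)."""

    theta: float
    theta_dot: float
    phi: float
    phi_dot: float

    def as_array(self) -> np.ndarray:
        return np.array([self.theta, self.theta_dot, self.phi, self.phi_dot])

    @staticmethod
    def from_array(y) -> "WalkerState":
        return WalkerState(float(y[0]), float(y[1]), float(y[2]), float(y[3]))

    def reduced(self) -> np.ndarray:
        """Independent states (theta, theta_dot) at a step start."""
        return np.array([self.theta, self.theta_dot])


@dataclass(frozen=True)
class ActuationInput:
    """Once-per-step controls: push-off impulse and the two hip stiffnesses.

    ``P`` is applied along the stance leg just before contact and must be
    non-negative.  Single-spring operation is represented by k1 == k2.
    """

    P: float
    k1: float
    k2: float

    def __post_init__(self):
        if self.P < 0.0:
            raise ValueError(f"push-off impulse must be non-negative, got {self.P}")

    @staticmethod
    def single(P: float, k: float) -> "ActuationInput":
        return ActuationInput(P, k, k)

    def as_array(self) -> np.ndarray:
        return np.array([self.P, self.k1, self.k2])


@dataclass(frozen=True)
class ScalingConstants:
    """Physical scales used to convert dimensionless results to SI units."""

    l: float = 1.0
    g: float = 9.81
    M: float = 1.0

    @property
    def time_scale(self) -> float:
        return np.sqrt(self.l / self.g)

    @property
    def frequency_scale(self) -> float:
        return np.sqrt(self.g / self.l)

    @property
    def velocity_scale(self) -> float:
        return np.sqrt(self.g * self.l)


@dataclass
class StepResult:
    """Outcome of simulating a single walking step."""

    outcome: str
    end_state_pre_collision: Optional[WalkerState] = None
    start_state_next: Optional[WalkerState] = None
    step_time: float = np.nan
    step_length: float = np.nan
    step_frequency: float = np.nan
    trajectory: Optional[pd.DataFrame] = None

    @property
    def completed(self) -> bool:
        return self.outcome == "completed"


def swing_derivatives(state: WalkerState, u: ActuationInput) -> np.ndarray:
    """Time derivatives (theta_dot, theta_ddot, phi_dot, phi_ddot).

    The stance leg is an inverted pendulum, theta_ddot = sin(theta).  The
    swing leg feels the stance acceleration, a centrifugal term, gravity and
    the active hip spring torque -k * phi with k = k1 for phi > 0 and k2
    otherwise.
    """
    k = u.k1 if state.phi > 0.0 else u.k2
    out = np.empty(4)
    _kernel._rhs(state.as_array(), k, out)
    return out


def swing_foot_height(state: WalkerState) -> float:
    """Vertical swing-foot clearance, cos(theta) - cos(theta - phi).

    Zero both at the scuff configuration (phi = 0) and at contact
    (phi = 2 theta).
    """
    return float(_kernel.swing_foot_height(state.theta, state.phi))


def heelstrike_map(pre: WalkerState, P: float) -> WalkerState:
    """Instantaneous push-off + heel-strike transition.

    Applied at a contact state (phi = 2 theta).  Rows for theta and phi are
    impulse-independent: theta+ = -theta-, phi+ = -2 theta-.  The stance
    rate maps through the collision geometry,
    theta_dot+ = cos(2 theta) theta_dot- + sin(2 theta) P, and the new swing
    rate is (1 - cos(2 theta)) theta_dot+.
    """
    if P < 0.0:
        raise ValueError(f"push-off impulse must be non-negative, got {P}")
    out = np.empty(4)
    _kernel.heelstrike(pre.as_array(), P, out)
    return WalkerState.from_array(out)


def expand_state(x) -> WalkerState:
    """Expand the reduced step-start state (theta, theta_dot) to full state.

    The swing states just after a collision are determined by the stance
    states through the transition structure: phi = 2 theta and
    phi_dot = (1 - cos(2 theta)) theta_dot.
    """
    theta, theta_dot = float(x[0]), float(x[1])
    return WalkerState(theta, theta_dot, 2.0 * theta,
                       (1.0 - np.cos(2.0 * theta)) * theta_dot)


def simulate_step(start: WalkerState, u: ActuationInput,
                  tol: float = DEFAULT_TOL, t_max: float = DEFAULT_T_MAX,
                  guard: float = DEFAULT_GUARD,
                  record_trajectory: bool = False) -> StepResult:
    """Simulate one step from a post-collision state.

    Integrates the swing-phase ODEs with event detection on the contact
    function phi - 2 theta, accepting only crossings with phi < -guard and
    a descending swing foot (the function is also zero at step start, and
    the point foot scuffs the ground at phi = 0).  The active hip spring
    switches whenever phi crosses zero.  On an accepted contact the push-off
    + heel-strike transition with the commanded impulse is applied.

    Falls (|theta| >= pi/2, or the stance rate reversing before mid-stance)
    and missing contact before ``t_max`` are reported through
    ``StepResult.outcome``; a genuine integrator failure raises
    :class:`IntegrationError`.
    """
    traj_buf = np.empty((40000, 6)) if record_trajectory else np.empty((1, 6))
    status, t_c, y_pre, nrec, _ = _kernel.integrate_swing(
        start.as_array(), u.k1, u.k2, tol, t_max, guard,
        traj_buf, record_trajectory)
    if status == STEP_FAIL:
        raise IntegrationError(
            f"adaptive integration stalled at t={t_c:.6g} from state {start}")
    traj = None
    if record_trajectory:
        traj = pd.DataFrame(
            traj_buf[:nrec],
            columns=["time", "theta", "theta_dot", "phi", "phi_dot",
                     "active_spring"])
    if status != COMPLETED:
        return StepResult(outcome=_OUTCOME_NAMES[status], trajectory=traj)
    pre = WalkerState.from_array(y_pre)
    nxt = heelstrike_map(pre, u.P)
    return StepResult(
        outcome="completed",
        end_state_pre_collision=pre,
        start_state_next=nxt,
        step_time=t_c,
        step_length=2.0 * abs(np.sin(pre.theta)),
        step_frequency=1.0 / t_c,
        trajectory=traj,
    )


def step_map(x, u: ActuationInput, tol: float = DEFAULT_TOL,
             t_max: float = DEFAULT_T_MAX, guard: float = DEFAULT_GUARD):
    """Reduced step-to-step return map F and step outputs.

    Maps the reduced state x = (theta, theta_dot) at one step start to the
    next, returning ``(x_next, y, status)`` where y = (SL, SF) are the step
    length and step frequency realized by the executed step.  On a fall or
    missed contact ``x_next`` and ``y`` are None and ``status`` names the
    outcome.
    """
    status, th2, thd2, sl, sf, _, _ = _kernel.step_reduced(
        float(x[0]), float(x[1]), u.P, u.k1, u.k2, tol, t_max, guard)
    if status == STEP_FAIL:
        raise IntegrationError(f"integration failed from reduced state {x}")
    if status != COMPLETED:
        return None, None, _OUTCOME_NAMES[status]
    return np.array([th2, thd2]), np.array([sl, sf]), "completed"
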