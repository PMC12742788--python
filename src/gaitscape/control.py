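"""Once-per-step deadbeat feedback control of periodic gaits.

For each gait the local controller adjusts the three actuations once per
step in proportion to the state error at the step start,

    u_i = u_n - K (x_i - x_n),

so the closed-loop deviation dynamics are dx_{i+1} = (A - B K) dx_i.
Deadbeat control places both closed-loop eigenvalues at zero, eliminating
small perturbations in a single step.  With three inputs and two states the
gain is non-unique; the minimum-norm choice K = pinv(B) A makes A - B K
vanish exactly whenever B has full row rank.

The module also measures two performance quantities used throughout the
package: the maximum tolerable perturbation (MTP) — the largest radius in
(SL, SF) gait space such that the walker, started from every neighboring
gait's initial conditions inside it, walks 100 steps without falling and
converges back to the target gait — and the settling (response) time, the
number of steps until the tracked quantity's error stays below 5% of its
initial deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernel
from .dynamics import (ActuationInput, DEFAULT_GUARD, DEFAULT_T_MAX,
                       DEFAULT_TOL)
from .limit_cycle import GaitCache, GaitGrid, LimitCycleGait
from .linearization import LinearizedMaps, controllability_test, linearize_gait

__all__ = [
    "LocalController", "RolloutResult", "PerturbationResult",
    "deadbeat_gains", "closed_loop_matrix", "build_controller",
    "control_step", "run_steps", "mtp_search", "mtp_survey",
    "settling_time", "response_time_experiment", "UncontrollableGaitError",
]

MTP_STEPS = 100
DEFAULT_CONV_TOL = 1e-6
DEFAULT_EARLY_EXIT_TOL = 1e-10


class UncontrollableGaitError(RuntimeError):
    """Deadbeat synthesis was requested for an uncontrollable pair (A, B)."""


@dataclass
class LocalController:
    """Per-gait once-per-step feedback law u = u_n - K (x - x_n)."""

    K_gain: np.ndarray          # m x 2
    x_nominal: np.ndarray       # (theta, theta_dot) fixed point
    u_nominal: ActuationInput
    gait_key: Tuple[float, float]   # (SL, SF)


def deadbeat_gains(maps: LinearizedMaps,
                   rank_tol: float = 1e-8) -> np.ndarray:
    """Minimum-norm deadbeat gain: K = pinv(B) A.

    All eigenvalues of the closed-loop matrix A - B K are placed at zero.
    Raises :class:`UncontrollableGaitError` when [B, AB] is rank deficient
    (the single-spring walker on its zero-boundary).
    """
    rep = controllability_test(maps, rank_tol)
    if not rep.controllable:
        key = None if maps.gait is None else (maps.gait.SL, maps.gait.SF)
        raise UncontrollableGaitError(
            f"gait {key}: controllability matrix rank {rep.rank} < 2")
    return np.linalg.pinv(maps.B) @ maps.A


def closed_loop_matrix(maps: LinearizedMaps, K: np.ndarray) -> np.ndarray:
    """Closed-loop deviation matrix A - B K under the feedback law above."""
    return maps.A - maps.B @ K


def build_controller(gait: LimitCycleGait, maps: LinearizedMaps = None,
                     integration_tol: float = DEFAULT_TOL
                     ) -> LocalController:
    if maps is None:
        maps = linearize_gait(gait, mode="double",
                              integration_tol=integration_tol)
    K = deadbeat_gains(maps)
    return LocalController(K_gain=K, x_nominal=gait.x_star.copy(),
                           u_nominal=gait.u_nominal,
                           gait_key=(gait.SL, gait.SF))


def control_step(x, ctrl: LocalController) -> ActuationInput:
    """Evaluate the once-per-step law at a step-start state.

    Negative push-off requests are clamped to zero (the impulse is
    unilateral); the hip stiffness corrections are unconstrained.
    """
    dx = np.asarray(x, float) - ctrl.x_nominal
    u = np.array([ctrl.u_nominal.P, ctrl.u_nominal.k1,
                  ctrl.u_nominal.k2]) - ctrl.K_gain @ dx
    return ActuationInput(max(u[0], 0.0), u[1], u[2])


@dataclass
class RolloutResult:
    """Multi-step walk outcome with per-step realized gait variables."""

    outcome: str               # converged | not_converged | fell | failed
    steps: int
    step_lengths: np.ndarray
    step_frequencies: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray
    final_error: float

    @property
    def fell(self) -> bool:
        return self.outcome == "fell"


_ROLLOUT_NAMES = {_kernel.CONVERGED: "converged",
                  _kernel.NOT_CONVERGED: "not_converged",
                  _kernel.ROLLOUT_FELL: "fell",
                  _kernel.ROLLOUT_FAIL: "failed"}

_K_ZERO = np.zeros((3, 2))


def run_steps(x0, n_steps: int, controller: Optional[LocalController] = None,
              u_const: Optional[ActuationInput] = None,
              x_ref=None, conv_tol: float = DEFAULT_CONV_TOL,
              early_exit_tol: float = 0.0,
              integration_tol: float = DEFAULT_TOL) -> RolloutResult:
    """Walk up to ``n_steps`` from reduced state ``x0``.

    Exactly one of ``controller`` (closed loop) or ``u_const`` (open loop,
    constant actuations) must be given.  Convergence is measured against
    ``x_ref`` (default: the controller's nominal state) with the max-norm.
    A positive ``early_exit_tol`` declares convergence as soon as the error
    drops below it: the step map is deterministic, so a state that tight on
    the fixed point repeats the target cycle for the remaining steps.
    """
    if (controller is None) == (u_const is None):
        raise ValueError("give exactly one of controller / u_const")
    if controller is not None:
        K = np.asarray(controller.K_gain, float)
        un = controller.u_nominal
        xn = controller.x_nominal
        use_fb = True
    else:
        K = _K_ZERO
        un = u_const
        xn = np.zeros(2)
        use_fb = False
    if x_ref is None:
        if controller is None:
            raise ValueError("x_ref is required for open-loop rollouts")
        x_ref = controller.x_nominal
    x_ref = np.asarray(x_ref, float)
    sl = np.empty(n_steps)
    sf = np.empty(n_steps)
    th = np.empty(n_steps)
    thd = np.empty(n_steps)
    code, steps, err = _kernel.rollout(
        float(x0[0]), float(x0[1]), n_steps,
        K, float(xn[0]), float(xn[1]), un.P, un.k1, un.k2, use_fb,
        float(x_ref[0]), float(x_ref[1]), conv_tol, early_exit_tol,
        early_exit_tol > 0.0,
        integration_tol, DEFAULT_T_MAX, DEFAULT_GUARD,
        sl, sf, th, thd)
    return RolloutResult(outcome=_ROLLOUT_NAMES[code], steps=int(steps),
                         step_lengths=sl[:steps].copy(),
                         step_frequencies=sf[:steps].copy(),
                         theta=th[:steps].copy(),
                         theta_dot=thd[:steps].copy(),
                         final_error=float(err))


@dataclass
class PerturbationResult:
    """Maximum-tolerable-perturbation search outcome for one target gait."""

    gait_key: Tuple[float, float]
    mtp_radius: float
    controlled: bool
    outcomes: pd.DataFrame      # per-neighbor: dSL, dSF, radius, outcome

    def __repr__(self):
        return (f"PerturbationResult(gait={self.gait_key}, "
                f"mtp={self.mtp_radius:.4g}, controlled={self.controlled})")


def _neighbor_rings(increment: float, cap_radius: float):
    """Lattice offsets grouped by increasing Euclidean distance."""
    n = int(math.ceil(cap_radius / increment))
    by_dist = {}
    for di in range(-n, n + 1):
        for dj in range(-n, n + 1):
            if di == 0 and dj == 0:
                continue
            d = increment * math.hypot(di, dj)
            if d > cap_radius + 1e-12:
                continue
            by_dist.setdefault(round(d, 9), []).append((di, dj))
    return sorted(by_dist.items())


def mtp_search(target: LimitCycleGait, cache: GaitCache,
               controlled: bool,
               controller: Optional[LocalController] = None,
               n_steps: int = MTP_STEPS,
               conv_tol: float = DEFAULT_CONV_TOL,
               early_exit_tol: float = DEFAULT_EARLY_EXIT_TOL,
               cap_radius: float = 0.15,
               integration_tol: float = DEFAULT_TOL) -> PerturbationResult:
    """Layered maximum-tolerable-perturbation search around a target gait.

    Neighboring gaits on the fine lattice are visited in rings of
    increasing radius.  The walker starts from each neighbor's limit-cycle
    initial conditions and must complete ``n_steps`` steps without falling
    and converge back to the target gait — under the target's deadbeat
    controller when ``controlled``, otherwise holding the target's nominal
    actuations.  The MTP is the largest radius whose enclosed neighbors all
    converge; the first failing ring stops the search.  Lattice cells
    outside the gait-space bounds are not gaits and are skipped.

    Early exit is only used where the remaining steps are provably
    repetitive: always under deadbeat control, and open loop only when the
    target is open-loop stable.
    """
    if controlled and controller is None:
        controller = build_controller(target,
                                      integration_tol=integration_tol)
    allow_early = controlled
    if not controlled:
        from .linearization import finite_difference_A
        A = finite_difference_A(target, integration_tol=integration_tol)
        allow_early = bool(np.max(np.abs(np.linalg.eigvals(A))) < 1.0)
    early = early_exit_tol if allow_early else 0.0
    rows = []
    mtp = 0.0
    for dist, cells in _neighbor_rings(cache.increment, cap_radius):
        ring_ok = True
        tested_any = False
        for di, dj in cells:
            neighbor = cache.gait_at(di, dj)
            if neighbor is None:
                spec = cache.spec_at(di, dj)
                if spec is None:
                    continue            # outside the gait space
                rows.append({"dSL": di * cache.increment,
                             "dSF": dj * cache.increment, "radius": dist,
                             "outcome": "neighbor_unsolved"})
                ring_ok = False
                continue
            tested_any = True
            if controlled:
                res = run_steps(neighbor.x_star, n_steps,
                                controller=controller, conv_tol=conv_tol,
                                early_exit_tol=early,
                                integration_tol=integration_tol)
            else:
                res = run_steps(neighbor.x_star, n_steps,
                                u_const=target.u_nominal,
                                x_ref=target.x_star, conv_tol=conv_tol,
                                early_exit_tol=early,
                                integration_tol=integration_tol)
            rows.append({"dSL": di * cache.increment,
                         "dSF": dj * cache.increment, "radius": dist,
                         "outcome": res.outcome})
            if res.outcome != "converged":
                ring_ok = False
        if not ring_ok:
            break
        if tested_any:
            mtp = dist
    return PerturbationResult(gait_key=(target.SL, target.SF),
                              mtp_radius=mtp, controlled=controlled,
                              outcomes=pd.DataFrame(rows))


def mtp_survey(grid: GaitGrid, stride: int, controlled: bool,
               increment: float = 0.01, cap_radius: float = 0.15,
               integration_tol: float = DEFAULT_TOL,
               solver_tol: float = 1e-11) -> pd.DataFrame:
    """MTP at every ``stride``-th converged grid gait.

    Each target gets its own fine-lattice gait cache (increment 0.01 by
    default, matching the full gait-space grid) seeded from the stored
    solution.  Unconverged targets are reported with NaN radius.
    """
    rows = []
    for i in range(0, grid.shape[0], stride):
        for j in range(0, grid.shape[1], stride):
            sl, sf = grid.sl_axis[i], grid.sf_axis[j]
            if not grid.converged[i, j]:
                rows.append({"SL": sl, "SF": sf, "mtp": np.nan})
                continue
            target = grid.gait(i, j)
            cache = GaitCache(target, increment=increment,
                              tol=solver_tol,
                              integration_tol=integration_tol)
            try:
                res = mtp_search(target, cache, controlled,
                                 cap_radius=cap_radius,
                                 integration_tol=integration_tol)
                rows.append({"SL": sl, "SF": sf, "mtp": res.mtp_radius})
            except UncontrollableGaitError:
                rows.append({"SL": sl, "SF": sf, "mtp": np.nan})
    return pd.DataFrame(rows)


def settling_time(errors: Sequence[float], initial_error: float,
                  threshold_frac: float = 0.05) -> float:
    """Steps until the error stays below 5% of the initial difference.

    ``errors`` are the per-step deviations e_1, e_2, ... of the tracked
    quantity from its target; the initial deviation e_0 is prepended.  The
    settling step is counted from the final threshold crossing (an error
    that dips below 5% and re-exceeds it has not settled), refined to a
    fractional step by linear interpolation between the bracketing steps.
    Returns NaN when the series never settles.
    """
    e0 = abs(float(initial_error))
    if e0 == 0.0:
        return 0.0
    thr = threshold_frac * e0
    series = np.abs(np.concatenate([[e0], np.asarray(errors, float)]))
    above = series >= thr
    if above[-1]:
        return np.nan
    if not above.any():
        return 0.0
    last = int(np.where(above)[0][-1])
    e_hi, e_lo = series[last], series[last + 1]
    if e_hi == e_lo:
        return float(last + 1)
    frac = (e_hi - thr) / (e_hi - e_lo)
    return float(last + min(max(frac, 0.0), 1.0))


def response_time_experiment(target: LimitCycleGait,
                             controller: LocalController,
                             perturbed: LimitCycleGait, axis: str,
                             n_steps: int = 40,
                             count_initial_stride: bool = False,
                             integration_tol: float = DEFAULT_TOL) -> dict:
    """Settling time of the local controller after a gait-space perturbation.

    The walker starts from the perturbed gait's limit-cycle state and walks
    under the target gait's controller; the error series is the realized
    step length (axis 'SL') or step frequency ('SF') relative to the
    target's value, with the commanded perturbation as the initial error.

    ``count_initial_stride`` switches to the counting convention in which
    the perturbed starting stride is stride one (adding one step to the
    interpolated crossing); both counts are returned either way.
    """
    res = run_steps(perturbed.x_star, n_steps, controller=controller,
                    conv_tol=DEFAULT_CONV_TOL,
                    integration_tol=integration_tol)
    target_val = target.SL if axis == "SL" else target.SF
    pert_val = perturbed.SL if axis == "SL" else perturbed.SF
    realized = (res.step_lengths if axis == "SL"
                else res.step_frequencies)
    t_raw = (settling_time(realized - target_val, pert_val - target_val)
             if not res.fell else np.nan)
    t_settle = t_raw + 1.0 if (count_initial_stride
                               and np.isfinite(t_raw)) else t_raw
    return {"axis": axis, "initial_error": pert_val - target_val,
            "settling_steps": t_settle, "settling_steps_from_zero": t_raw,
            "outcome": res.outcome, "rollout": res}
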