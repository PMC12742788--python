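"""Gain-scheduled feedback policy over the gait space.

The per-gait deadbeat controllers are generalized to arbitrary (possibly
off-grid, time-varying) target gaits by piecewise-bilinear interpolation of
the six feedback gains together with the nominal state (2 numbers) and
nominal actuations (3 numbers) over the solved gait grid — 11 quantities
per grid node.  To track a target path, each step interpolates the policy
at the next target gait, evaluates the once-per-step law at the current
state, and simulates one step.

Two performance experiments are provided: the optimal response time to
±15% single-axis perturbations (tracking exponential reference paths whose
shared time constant is optimized), and sinusoidal gait-space paths in
which step length oscillates at twice the step-frequency rate with equal
amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .dynamics import ActuationInput, DEFAULT_TOL, step_map
from .limit_cycle import (GaitGrid, GaitSpec, LimitCycleGait,
                          solve_limit_cycle)
from .linearization import linearize_gait
from .control import LocalController, control_step, settling_time
from .control import UncontrollableGaitError, deadbeat_gains

__all__ = [
    "GainGrid", "TargetPath", "TrackingRun", "build_gain_grid",
    "interpolate_policy", "track_path", "exponential_reference",
    "optimize_response_time", "sine_path", "min_path_length",
    "OutOfHullError", "OptimalResponse",
]


class OutOfHullError(ValueError):
    """A target gait lies outside the solved gait-space hull."""


@dataclass
class GainGrid:
    """Deadbeat gains and nominals tabulated over a gait grid.

    ``data[i, j]`` holds, in order: the six gains K (row-major, inputs
    (P, k1, k2) by states (theta, theta_dot)), the nominal state
    (theta, theta_dot), and the nominal actuations (P, k1, k2).  Cells
    where the gait or its linearization is unavailable are invalid.
    """

    sl_axis: np.ndarray
    sf_axis: np.ndarray
    data: np.ndarray            # (n_sl, n_sf, 11)
    valid: np.ndarray           # (n_sl, n_sf) bool
    meta: dict = field(default_factory=dict)

    @property
    def hull(self) -> Tuple[float, float, float, float]:
        return (float(self.sl_axis[0]), float(self.sl_axis[-1]),
                float(self.sf_axis[0]), float(self.sf_axis[-1]))

    def contains(self, sl: float, sf: float) -> bool:
        lo_sl, hi_sl, lo_sf, hi_sf = self.hull
        return (lo_sl - 1e-12 <= sl <= hi_sl + 1e-12
                and lo_sf - 1e-12 <= sf <= hi_sf + 1e-12)

    def to_dataframe(self) -> pd.DataFrame:
        names = (["K_P_theta", "K_P_thetadot", "K_k1_theta",
                  "K_k1_thetadot", "K_k2_theta", "K_k2_thetadot",
                  "theta_n", "thetadot_n", "P_n", "k1_n", "k2_n"])
        ii, jj = np.meshgrid(np.arange(len(self.sl_axis)),
                             np.arange(len(self.sf_axis)), indexing="ij")
        df = pd.DataFrame({"SL": self.sl_axis[ii.ravel()],
                           "SF": self.sf_axis[jj.ravel()],
                           "valid": self.valid.ravel()})
        flat = self.data.reshape(-1, 11)
        for c, name in enumerate(names):
            df[name] = flat[:, c]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def build_gain_grid(grid: GaitGrid, delta: float = 1e-7,
                    integration_tol: float = DEFAULT_TOL) -> GainGrid:
    """Synthesize the deadbeat controller at every converged grid cell."""
    nsl, nsf = grid.shape
    data = np.full((nsl, nsf, 11), np.nan)
    valid = np.zeros((nsl, nsf), bool)
    for i in range(nsl):
        for j in range(nsf):
            if not grid.converged[i, j]:
                continue
            gait = grid.gait(i, j)
            try:
                maps = linearize_gait(gait, delta, "double", integration_tol)
                K = deadbeat_gains(maps)
            except (UncontrollableGaitError, Exception) as exc:
                if isinstance(exc, KeyboardInterrupt):
                    raise
                continue
            data[i, j, :6] = K.ravel()
            data[i, j, 6:8] = gait.x_star
            data[i, j, 8:] = (gait.u_nominal.P, gait.u_nominal.k1,
                              gait.u_nominal.k2)
            valid[i, j] = True
    return GainGrid(sl_axis=grid.sl_axis.copy(),
                    sf_axis=grid.sf_axis.copy(), data=data, valid=valid,
                    meta=dict(grid.meta))


def interpolate_policy(sl_t: float, sf_t: float, grid: GainGrid
                       ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bilinear interpolation of (K_gain, x_nominal, u_nominal) at a target.

    Queries exactly on a grid node return that node's stored values
    bit-identically.  Targets outside the hull, or inside a cell with an
    invalid corner, raise :class:`OutOfHullError`.
    """
    if not grid.contains(sl_t, sf_t):
        raise OutOfHullError(
            f"target ({sl_t}, {sf_t}) outside gain-grid hull {grid.hull}")
    sls, sfs = grid.sl_axis, grid.sf_axis
    i = int(np.clip(np.searchsorted(sls, sl_t) - 1, 0, len(sls) - 2))
    j = int(np.clip(np.searchsorted(sfs, sf_t) - 1, 0, len(sfs) - 2))
    # snap to exact nodes for bit-identical reproduction
    if sl_t == sls[i + 1]:
        i += 1
        wx = 0.0
    else:
        wx = (sl_t - sls[i]) / (sls[i + 1] - sls[i])
    if sf_t == sfs[j + 1]:
        j += 1
        wy = 0.0
    else:
        wy = (sf_t - sfs[j]) / (sfs[j + 1] - sfs[j])
    if wx == 0.0 and wy == 0.0:
        if not grid.valid[i, j]:
            raise OutOfHullError(f"grid node ({sl_t}, {sf_t}) is invalid")
        vals = grid.data[i, j]
    else:
        i1 = i + 1 if wx > 0.0 else i
        j1 = j + 1 if wy > 0.0 else j
        corners = [(i, j), (i1, j), (i, j1), (i1, j1)]
        if not all(grid.valid[ci, cj] for ci, cj in corners):
            raise OutOfHullError(
                f"target ({sl_t}, {sf_t}) touches an unsolved grid cell")
        vals = ((1 - wx) * (1 - wy) * grid.data[i, j]
                + wx * (1 - wy) * grid.data[i1, j]
                + (1 - wx) * wy * grid.data[i, j1]
                + wx * wy * grid.data[i1, j1])
    K = vals[:6].reshape(3, 2)
    return K, vals[6:8].copy(), vals[8:].copy()


def policy_controller(sl_t: float, sf_t: float,
                      grid: GainGrid) -> LocalController:
    """The interpolated policy packaged as a once-per-step controller."""
    K, xn, un = interpolate_policy(sl_t, sf_t, grid)
    return LocalController(K_gain=K, x_nominal=xn,
                           u_nominal=ActuationInput(max(un[0], 0.0),
                                                    un[1], un[2]),
                           gait_key=(sl_t, sf_t))


@dataclass
class TargetPath:
    """Ordered per-step target gaits (SL_t, SF_t), steps s = 1..n."""

    targets: np.ndarray          # (n, 2)
    kind: str = "constant"
    params: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return len(self.targets)

    @classmethod
    def constant(cls, sl: float, sf: float, n_steps: int) -> "TargetPath":
        return cls(np.tile([sl, sf], (n_steps, 1)), "constant",
                   {"SL": sl, "SF": sf})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"step": np.arange(1, self.n_steps + 1),
                             "SL_target": self.targets[:, 0],
                             "SF_target": self.targets[:, 1]})


@dataclass
class TrackingRun:
    """Realized closed-loop walk along a target path."""

    path: TargetPath
    outcome: str                 # completed | fell
    fell_at: Optional[int]
    realized: np.ndarray         # (n_done, 2) per-step (SL, SF)
    states: np.ndarray           # (n_done, 2) step-start states after step
    actuations: np.ndarray       # (n_done, 3)
    start_gait: Tuple[float, float]
    rms_pct: Tuple[float, float] = (np.nan, np.nan)

    @property
    def completed(self) -> bool:
        return self.outcome == "completed"

    def to_dataframe(self) -> pd.DataFrame:
        n = len(self.realized)
        df = self.path.to_dataframe().iloc[:n].reset_index(drop=True)
        df["SL_actual"] = self.realized[:, 0]
        df["SF_actual"] = self.realized[:, 1]
        df["P"] = self.actuations[:, 0]
        df["k1"] = self.actuations[:, 1]
        df["k2"] = self.actuations[:, 2]
        df["fell"] = False
        if self.fell_at is not None and n:
            df.loc[n - 1, "fell"] = True
        return df


def track_path(path: TargetPath, start: LimitCycleGait, grid: GainGrid,
               integration_tol: float = DEFAULT_TOL) -> TrackingRun:
    """Track a target path with the interpolated policy, once per step.

    The walker starts from the limit-cycle state of the initial gait.  For
    each step the policy is interpolated at that step's target gait, the
    feedback law is evaluated at the current state (push-off clamped at
    zero), and one step is simulated.  The run stops at a fall.  RMS
    tracking errors are reported as percentages of the starting gait's SL
    and SF.
    """
    x = start.x_star.copy()
    n = path.n_steps
    realized = np.empty((n, 2))
    states = np.empty((n, 2))
    actus = np.empty((n, 3))
    outcome = "completed"
    fell_at = None
    done = 0
    for s in range(n):
        sl_t, sf_t = path.targets[s]
        ctrl = policy_controller(sl_t, sf_t, grid)
        u = control_step(x, ctrl)
        x2, y, status = step_map(x, u, tol=integration_tol)
        if status != "completed":
            outcome = "fell"
            fell_at = s + 1
            break
        x = x2
        realized[s] = y
        states[s] = x
        actus[s] = (u.P, u.k1, u.k2)
        done = s + 1
    run = TrackingRun(path=path, outcome=outcome, fell_at=fell_at,
                      realized=realized[:done], states=states[:done],
                      actuations=actus[:done],
                      start_gait=(start.SL, start.SF))
    if done:
        err = run.realized - path.targets[:done]
        rms = np.sqrt(np.mean(err ** 2, axis=0))
        run.rms_pct = (float(100.0 * rms[0] / start.SL),
                       float(100.0 * rms[1] / start.SF))
    return run


def exponential_reference(start_value: float, target_value: float,
                          n_steps: int, tau: float) -> np.ndarray:
    """Exponential approach target + (start - target) exp(-s / tau),
    evaluated at s = 0..n_steps (s = 0 is the starting value)."""
    if tau <= 0.0:
        raise ValueError("time constant must be positive")
    if n_steps < 1:
        raise ValueError("need at least one step")
    s = np.arange(n_steps + 1)
    return target_value + (start_value - target_value) * np.exp(-s / tau)


def _reference_path(target: LimitCycleGait, start_value: float, axis: str,
                    n_steps: int, tau: float) -> TargetPath:
    targets = np.tile([target.SL, target.SF], (n_steps, 1))
    col = 0 if axis == "SL" else 1
    ref = exponential_reference(start_value,
                                target.SL if axis == "SL" else target.SF,
                                n_steps, tau)
    targets[:, col] = ref[1:]
    return TargetPath(targets, "exponential-reference",
                      {"axis": axis, "tau": tau, "start": start_value})


@dataclass
class OptimalResponse:
    """Outcome of the response-time optimization at one gait and axis."""

    gait_key: Tuple[float, float]
    axis: str
    tau: float
    response_steps: float        # mean of the +15% and -15% runs
    per_run_steps: Tuple[float, float]
    cost: float
    runs: tuple = ()


def optimize_response_time(target: LimitCycleGait, perturb_axis: str,
                           grid: GainGrid, max_steps: int = 10,
                           perturb_frac: float = 0.15,
                           integration_tol: float = DEFAULT_TOL,
                           count_initial_stride: bool = False,
                           solver_tol: float = 1e-11) -> OptimalResponse:
    """Optimal policy response time to ±15% single-axis perturbations.

    Two exponential reference paths (from the gaits perturbed 15% above and
    below the target along ``perturb_axis``) share one time constant tau
    and serve as the per-step command sequence for the policy.  The shared
    tau is chosen to minimize the summed RMS deviation of the realized
    (SL, SF) path from the final target over both runs, with falls
    penalized: commanding the target too aggressively overshoots or falls,
    commanding it too slowly converges late, so the optimum is interior.
    The response time is the 5%-criterion settling time of the tracked
    quantity on the optimal runs, averaged over the two perturbation signs.
    """
    val = target.SL if perturb_axis == "SL" else target.SF
    starts = []
    for sign in (+1.0, -1.0):
        pv = val * (1.0 + sign * perturb_frac)
        spec = (GaitSpec(pv, target.SF) if perturb_axis == "SL"
                else GaitSpec(target.SL, pv))
        g = solve_limit_cycle(spec, guess=target, tol=solver_tol,
                              integration_tol=integration_tol)
        if not g.converged:
            g = solve_limit_cycle(spec, tol=solver_tol,
                                  integration_tol=integration_tol)
        if not g.converged:
            raise RuntimeError(f"perturbed gait {spec} did not converge")
        starts.append(g)

    goal = np.array([target.SL, target.SF])

    def run_pair(tau):
        runs = []
        cost = 0.0
        for g in starts:
            sv = g.SL if perturb_axis == "SL" else g.SF
            path = _reference_path(target, sv, perturb_axis, max_steps, tau)
            run = track_path(path, g, grid, integration_tol)
            if not run.completed:
                n_done = len(run.realized)
                cost += 1e3 * (1.0 + (max_steps - n_done) / max_steps)
                runs.append(run)
                continue
            err = run.realized - goal[None, :]
            cost += float(np.sum(np.sqrt(np.mean(err ** 2, axis=0))))
            runs.append(run)
        return cost, runs

    # the landscape has fall-penalty plateaus: coarse deterministic scan,
    # then bounded refinement around the best bracket
    taus = np.geomspace(0.12, float(max_steps), 14)
    coarse = [run_pair(t)[0] for t in taus]
    b = int(np.argmin(coarse))
    lo = taus[max(b - 1, 0)]
    hi = taus[min(b + 1, len(taus) - 1)]
    res = minimize_scalar(lambda tau: run_pair(tau)[0], bounds=(lo, hi),
                          method="bounded",
                          options={"xatol": 5e-3, "maxiter": 40})
    tau = float(res.x) if res.fun <= coarse[b] else float(taus[b])
    cost, runs = run_pair(tau)
    times = []
    col = 0 if perturb_axis == "SL" else 1
    for g, run in zip(starts, runs):
        if not run.completed:
            times.append(np.nan)
            continue
        sv = g.SL if perturb_axis == "SL" else g.SF
        errs = run.realized[:, col] - val
        t = settling_time(errs, sv - val)
        if count_initial_stride and np.isfinite(t):
            t += 1.0
        times.append(t)
    return OptimalResponse(gait_key=(target.SL, target.SF),
                           axis=perturb_axis, tau=tau,
                           response_steps=float(np.mean(times)),
                           per_run_steps=(times[0], times[1]),
                           cost=cost, runs=tuple(runs))


def sine_path(start: LimitCycleGait, amplitude: float,
              n_steps: int, grid: Optional[GainGrid] = None) -> TargetPath:
    """Sinusoidal gait-space path centred on the starting gait.

    Step length completes two full cycles while step frequency completes
    one, with equal amplitudes:
    SL(s) = SL0 + a sin(4 pi s / n), SF(s) = SF0 + a sin(2 pi s / n).
    """
    s = np.arange(1, n_steps + 1)
    sl = start.SL + amplitude * np.sin(4.0 * np.pi * s / n_steps)
    sf = start.SF + amplitude * np.sin(2.0 * np.pi * s / n_steps)
    targets = np.column_stack([sl, sf])
    if grid is not None:
        for sl_t, sf_t in targets:
            if not grid.contains(sl_t, sf_t):
                raise OutOfHullError(
                    f"sine path leaves the gain-grid hull at ({sl_t:.4g},"
                    f" {sf_t:.4g})")
    return TargetPath(targets, "sinusoid",
                      {"amplitude": amplitude, "n_steps": n_steps,
                       "SL0": start.SL, "SF0": start.SF})


def min_path_length(start: LimitCycleGait, amplitude: float,
                    grid: GainGrid, cap: int = 400,
                    integration_tol: float = DEFAULT_TOL
                    ) -> Tuple[Optional[int], Optional[TrackingRun]]:
    """Smallest sinusoidal path length the policy completes without a fall.

    Path lengths are doubled from a small start until one completes, then
    bisected between the last failure and the first success.  Returns
    (None, None) when nothing at or below ``cap`` completes.
    """
    if amplitude == 0.0:
        run = track_path(sine_path(start, 0.0, 1, grid), start, grid,
                         integration_tol)
        return (1, run) if run.completed else (None, None)

    def attempt(n):
        run = track_path(sine_path(start, amplitude, n, grid), start, grid,
                         integration_tol)
        return run if run.completed else None

    lo = 1            # known failure (or untested, treated as failure)
    n = 8
    best = None
    while n <= cap:
        run = attempt(n)
        if run is not None:
            best = (n, run)
            break
        lo = n
        n *= 2
    if best is None:
        return None, None
    hi, hi_run = best
    while hi - lo > 1:
        mid = (lo + hi) // 2
        run = attempt(mid)
        if run is not None:
            hi, hi_run = mid, run
        else:
            lo = mid
    return hi, hi_run
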