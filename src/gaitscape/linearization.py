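"""Discrete linearized return maps, stability and controllability analysis.

Around each periodic gait the step-to-step return map is linearized by
finite differences:

    dx_{i+1} = A dx_i + B du_i
    dy_i     = C dx_i + D du_i

with x = (theta, theta_dot) the reduced state at a step start,
u = (P, k) for the single-spring walker or (P, k1, k2) for the
double-spring walker, and y = (SL, SF) the step length and frequency of the
executed step.  A gait is open-loop stable when both eigenvalues of A lie
inside the unit circle, and controllable when the controllability matrix
[B, AB] has full rank.

Matrix indexing convention: state rows/columns are ordered
(theta, theta_dot), input columns (P, k) or (P, k1, k2), output rows
(SL, SF).  B[0, 0], D[0, 0] and D[1, 0] vanish identically: the push-off is
applied at the end of the step, so it can affect neither the next stance
angle nor the executed step's length or timing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .dynamics import ActuationInput, step_map
from .limit_cycle import GaitGrid, LimitCycleGait

__all__ = [
    "LinearizedMaps", "StabilityReport", "ControllabilityReport",
    "finite_difference_A", "finite_difference_BCD", "linearize_gait",
    "classify_stability", "controllability_test", "stability_grid",
    "locate_zero_boundary", "NonEvaluableGaitError", "DEFAULT_FD_STEP",
    "DEFAULT_RANK_TOL",
]

DEFAULT_FD_STEP = 1e-7
DEFAULT_RANK_TOL = 1e-8


class NonEvaluableGaitError(RuntimeError):
    """A finite-difference probe step did not complete."""


@dataclass
class LinearizedMaps:
    """Finite-difference return-map matrices around one gait."""

    A: np.ndarray            # 2 x 2
    B: np.ndarray            # 2 x m
    C: np.ndarray            # 2 x 2
    D: np.ndarray            # 2 x m
    mode: str                # "single" (m = 2) or "double" (m = 3)
    fd_step: float
    gait: Optional[LimitCycleGait] = None

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.A)

    @property
    def max_eig_magnitude(self) -> float:
        return float(np.max(np.abs(self.eigenvalues)))


def _probe(x, u, integration_tol):
    x2, y, status = step_map(x, u, tol=integration_tol)
    if status != "completed":
        raise NonEvaluableGaitError(
            f"finite-difference probe step ended in '{status}'")
    return x2, y


def _base_point(gait: LimitCycleGait, integration_tol):
    x0 = gait.x_star
    u0 = gait.u_nominal
    fx0, y0 = _probe(x0, u0, integration_tol)
    return x0, u0, fx0, y0


def finite_difference_A(gait: LimitCycleGait, delta: float = DEFAULT_FD_STEP,
                        integration_tol: float = 1e-13,
                        central: bool = False) -> np.ndarray:
    """State-transition Jacobian A by one-sided forward differences.

    Column j is [F(x* + delta e_j) - F(x*)] / delta with the nominal
    actuations held fixed.  ``central`` switches to central differences
    (used as an independent cross-check of the one-sided default).
    """
    if not gait.converged:
        raise ValueError("gait must be converged before linearization")
    x0, u0, fx0, _ = _base_point(gait, integration_tol)
    A = np.empty((2, 2))
    for j in range(2):
        e = np.zeros(2)
        e[j] = delta
        fp, _ = _probe(x0 + e, u0, integration_tol)
        if central:
            fm, _ = _probe(x0 - e, u0, integration_tol)
            A[:, j] = (fp - fm) / (2.0 * delta)
        else:
            A[:, j] = (fp - fx0) / delta
    return A


def finite_difference_BCD(gait: LimitCycleGait,
                          delta: float = DEFAULT_FD_STEP,
                          mode: str = "double",
                          integration_tol: float = 1e-13
                          ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Input, output and feedthrough matrices B, C, D by forward differences.

    In single-spring mode the input vector is (P, k) and the stiffness
    column perturbs both springs together; in double-spring mode the inputs
    (P, k1, k2) are perturbed independently.
    """
    if not gait.converged:
        raise ValueError("gait must be converged before linearization")
    x0, u0, fx0, y0 = _base_point(gait, integration_tol)
    m = 2 if mode == "single" else 3
    B = np.empty((2, m))
    D = np.empty((2, m))
    P, k1, k2 = u0.P, u0.k1, u0.k2
    if mode == "single":
        pert_inputs = [ActuationInput(P + delta, k1, k2),
                       ActuationInput(P, k1 + delta, k2 + delta)]
    else:
        pert_inputs = [ActuationInput(P + delta, k1, k2),
                       ActuationInput(P, k1 + delta, k2),
                       ActuationInput(P, k1, k2 + delta)]
    for j, up in enumerate(pert_inputs):
        fp, yp = _probe(x0, up, integration_tol)
        B[:, j] = (fp - fx0) / delta
        D[:, j] = (yp - y0) / delta
    C = np.empty((2, 2))
    for j in range(2):
        e = np.zeros(2)
        e[j] = delta
        _, yp = _probe(x0 + e, u0, integration_tol)
        C[:, j] = (yp - y0) / delta
    return B, C, D


def linearize_gait(gait: LimitCycleGait, delta: float = DEFAULT_FD_STEP,
                   mode: str = "double",
                   integration_tol: float = 1e-13) -> LinearizedMaps:
    """Convenience wrapper building the full (A, B, C, D) set for a gait."""
    A = finite_difference_A(gait, delta, integration_tol)
    B, C, D = finite_difference_BCD(gait, delta, mode, integration_tol)
    return LinearizedMaps(A=A, B=B, C=C, D=D, mode=mode, fd_step=delta,
                          gait=gait)


@dataclass
class StabilityReport:
    """Per-gait eigenvalue magnitudes and stability region labels."""

    sl: np.ndarray
    sf: np.ndarray
    max_eig: np.ndarray
    stable: np.ndarray
    region: np.ndarray        # 'center', 'left', 'right' or ''

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"SL": self.sl, "SF": self.sf,
                             "max_eig": self.max_eig,
                             "stable": self.stable,
                             "region": self.region})

    def region_mean(self, label: str) -> float:
        m = self.region == label
        if not m.any():
            return np.nan
        return float(self.max_eig[m].mean())


def stability_grid(grid: GaitGrid, delta: float = DEFAULT_FD_STEP,
                   integration_tol: float = 1e-13,
                   stride: int = 1) -> pd.DataFrame:
    """max |eigenvalue| of A at every (optionally strided) converged cell."""
    rows = []
    for i in range(0, grid.shape[0], stride):
        for j in range(0, grid.shape[1], stride):
            if not grid.converged[i, j]:
                continue
            g = grid.gait(i, j)
            try:
                A = finite_difference_A(g, delta, integration_tol)
                lam = float(np.max(np.abs(np.linalg.eigvals(A))))
            except NonEvaluableGaitError:
                lam = np.nan
            rows.append({"SL": g.SL, "SF": g.SF, "i": i, "j": j,
                         "max_eig": lam})
    return pd.DataFrame(rows)


def classify_stability(eig_table: pd.DataFrame) -> StabilityReport:
    """Label gaits as center-stable / left-unstable / right-unstable.

    The central region is the largest connected component of stable cells
    (max |eig| < 1).  Unstable cells are labelled 'left' when they sit at a
    lower step frequency than the stable band of their step-length row and
    'right' otherwise; rows with no stable band borrow the nearest row that
    has one.
    """
    sls = np.unique(eig_table["SL"].to_numpy())
    sfs = np.unique(eig_table["SF"].to_numpy())
    shape = (len(sls), len(sfs))
    eig = np.full(shape, np.nan)
    i = np.searchsorted(sls, eig_table["SL"].to_numpy())
    j = np.searchsorted(sfs, eig_table["SF"].to_numpy())
    eig[i, j] = eig_table["max_eig"].to_numpy()
    stable = np.isfinite(eig) & (eig < 1.0)
    labels_arr = np.full(shape, "", dtype=object)
    lab, n = ndimage.label(stable)
    if n > 0:
        sizes = ndimage.sum_labels(np.ones(shape), lab, np.arange(1, n + 1))
        center_lab = 1 + int(np.argmax(sizes))
        center = lab == center_lab
    else:
        center = np.zeros(shape, bool)
    labels_arr[center] = "center"
    # per-row stable band bounds from the central component
    lo = np.full(shape[0], np.nan)
    hi = np.full(shape[0], np.nan)
    for r in range(shape[0]):
        cols = np.where(center[r])[0]
        if cols.size:
            lo[r], hi[r] = cols[0], cols[-1]
    rows_with = np.where(np.isfinite(lo))[0]
    for r in range(shape[0]):
        if rows_with.size == 0:
            break
        rr = rows_with[np.argmin(np.abs(rows_with - r))]
        for c in range(shape[1]):
            if labels_arr[r, c] or not np.isfinite(eig[r, c]):
                continue
            if stable[r, c]:
                continue  # stable but outside the central component
            labels_arr[r, c] = "left" if c < lo[rr] else "right"
    ii, jj = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                         indexing="ij")
    keep = np.isfinite(eig).ravel()
    return StabilityReport(
        sl=sls[ii.ravel()[keep]], sf=sfs[jj.ravel()[keep]],
        max_eig=eig.ravel()[keep],
        stable=stable.ravel()[keep],
        region=np.asarray(labels_arr.ravel()[keep], dtype=object))


@dataclass
class ControllabilityReport:
    """Rank analysis of the controllability matrix [B, AB] for one gait."""

    controllability_matrix: np.ndarray
    singular_values: np.ndarray
    rank: int
    controllable: bool
    mode: str
    zero_boundary_score: float   # max(|A12|,|B12|,|B22|)^-ish proximity probe

    def to_row(self) -> dict:
        return {"rank": self.rank, "controllable": self.controllable,
                "sv_ratio": float(self.singular_values[-1]
                                  / self.singular_values[0]),
                "zero_boundary_score": self.zero_boundary_score}


def locate_zero_boundary(sl: float, sf_bracket: Tuple[float, float],
                         seed_gait: LimitCycleGait,
                         delta: float = DEFAULT_FD_STEP,
                         integration_tol: float = 1e-13,
                         solver_tol: float = 1e-11,
                         max_bisect: int = 40):
    """Locate the single-spring loss-of-control boundary along one row.

    Bisects the sign change of the stiffness-to-next-stance-angle
    sensitivity B[0, 1] in step frequency at fixed step length, re-solving
    the limit cycle at each probe (warm-started from ``seed_gait`` and then
    from the previous probe, staying on one gait family).  Returns the
    refined (gait, LinearizedMaps) pair at the boundary.  On the boundary
    the state coupling A[0, 1] and the stiffness-to-stance-rate sensitivity
    B[1, 1] vanish together with B[0, 1], so the controllability matrix
    loses rank there.
    """
    from .limit_cycle import GaitSpec, solve_limit_cycle

    def probe(sf, guess):
        g = solve_limit_cycle(GaitSpec(sl, sf), guess=guess,
                              tol=solver_tol,
                              integration_tol=integration_tol)
        if not g.converged:
            raise NonEvaluableGaitError(
                f"limit cycle at ({sl}, {sf}) did not converge during "
                "zero-boundary bisection")
        m = linearize_gait(g, delta, "single", integration_tol)
        return g, m

    lo, hi = sf_bracket
    g_lo, m_lo = probe(lo, seed_gait)
    g_hi, m_hi = probe(hi, g_lo)
    f_lo, f_hi = m_lo.B[0, 1], m_hi.B[0, 1]
    if f_lo * f_hi > 0:
        raise ValueError(
            f"B[0, 1] does not change sign on SF bracket {sf_bracket}")
    g_mid, m_mid = g_lo, m_lo
    for _ in range(max_bisect):
        mid = 0.5 * (lo + hi)
        g_mid, m_mid = probe(mid, g_mid)
        f_mid = m_mid.B[0, 1]
        if f_mid == 0.0 or hi - lo < 1e-9:
            break
        if f_lo * f_mid <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    return g_mid, m_mid


def controllability_test(maps: LinearizedMaps,
                         rank_tol: float = DEFAULT_RANK_TOL
                         ) -> ControllabilityReport:
    """Numerical rank of [B, AB] with a singular-value ratio threshold.

    For the single-spring walker a zero-boundary proximity score is also
    reported: the largest magnitude among the entries that vanish together
    where the walker loses control (the stiffness-to-stance-angle
    sensitivity B[0, 1], the state coupling A[0, 1], and the
    stiffness-to-stance-rate sensitivity B[1, 1]); small values of the
    score mean the gait sits near the zero-boundary.
    """
    ctrb = np.hstack([maps.B, maps.A @ maps.B])
    sv = np.linalg.svd(ctrb, compute_uv=False)
    rank = int(np.sum(sv > rank_tol * sv[0])) if sv[0] > 0 else 0
    if maps.mode == "single":
        score = float(max(abs(maps.A[0, 1]), abs(maps.B[0, 1]),
                          abs(maps.B[1, 1])))
    else:
        score = np.nan
    return ControllabilityReport(
        controllability_matrix=ctrb, singular_values=sv, rank=rank,
        controllable=rank == 2, mode=maps.mode, zero_boundary_score=score)
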