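"""Experiment orchestration: configuration, fixtures and table recipes.

This module wires the lower layers into the package's standard
experiments: the five-representative-gait response-time table for the
local deadbeat controllers, the optimal policy response-time table, the
gait-space summary statistics (eigenvalue-region means and MTP means with
and without control), and small solved sub-grid fixtures for tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .limit_cycle import (GAIT_SPACE_BOUNDS, GaitCache, GaitGrid, GaitSpec,
                          LimitCycleGait, continuation_sweep,
                          solve_limit_cycle, solve_limit_cycle_continued)
from .control import (build_controller, mtp_search, mtp_survey,
                      response_time_experiment)
from .policy import build_gain_grid, optimize_response_time

__all__ = [
    "ExperimentConfig", "REPRESENTATIVE_GAITS", "make_fixture_grid",
    "reproduce_table1", "reproduce_table2", "reproduce_summary_stats",
    "representative_gait_controllers",
]

# (SL, SF) pairs sampling the five regions of the gait space
REPRESENTATIVE_GAITS: Tuple[Tuple[float, float], ...] = (
    (0.60, 0.60),   # centre
    (0.85, 0.85),   # top right
    (0.85, 0.35),   # top left
    (0.35, 0.85),   # bottom right
    (0.35, 0.35),   # bottom left
)
REGION_NAMES = ("Centre", "Top right", "Top left", "Bottom right",
                "Bottom left")


@dataclass
class ExperimentConfig:
    """All tunables of the standard experiments in one place."""

    sl_range: Tuple[float, float] = GAIT_SPACE_BOUNDS
    sf_range: Tuple[float, float] = GAIT_SPACE_BOUNDS
    increment: float = 0.01
    integration_tol: float = 1e-13
    solver_tol: float = 1e-11
    fd_step: float = 1e-7
    representative_gaits: Sequence[Tuple[float, float]] = REPRESENTATIVE_GAITS
    mtp_cap_radius: float = 0.15
    mtp_steps: int = 100
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self):
        for name in ("integration_tol", "solver_tol", "fd_step",
                     "increment"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo_sl, hi_sl = self.sl_range
        lo_sf, hi_sf = self.sf_range
        for sl, sf in self.representative_gaits:
            if not (lo_sl <= sl <= hi_sl and lo_sf <= sf <= hi_sf):
                raise ValueError(
                    f"representative gait ({sl}, {sf}) outside grid ranges")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                v = raw[f.name]
                if f.name in ("sl_range", "sf_range"):
                    v = tuple(v)
                elif f.name == "representative_gaits":
                    v = tuple(tuple(p) for p in v)
                kwargs[f.name] = v
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["sl_range"] = list(d["sl_range"])
        d["sf_range"] = list(d["sf_range"])
        d["representative_gaits"] = [list(p)
                                     for p in d["representative_gaits"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def make_fixture_grid(center: Tuple[float, float] = (0.6, 0.6),
                      half_width: float = 0.03, increment: float = 0.01,
                      config: Optional[ExperimentConfig] = None) -> GaitGrid:
    """Small fully solved sub-grid around a center gait (test fixture).

    Deterministic given the configuration; raises if any cell fails to
    converge.
    """
    cfg = config or ExperimentConfig()
    sl0, sf0 = center
    rng = np.random.default_rng(cfg.seed)
    seed_spec = GaitSpec(round(sl0 + half_width, 10),
                         round(sf0 + half_width, 10))
    seed = solve_limit_cycle_continued(seed_spec, tol=cfg.solver_tol,
                                       integration_tol=cfg.integration_tol,
                                       rng=rng)
    grid = continuation_sweep(
        (round(sl0 - half_width, 10), round(sl0 + half_width, 10)),
        (round(sf0 - half_width, 10), round(sf0 + half_width, 10)),
        increment, seed_gait=seed, tol=cfg.solver_tol,
        integration_tol=cfg.integration_tol, rng=rng)
    n_cells = grid.shape[0] * grid.shape[1]
    if grid.n_converged != n_cells:
        raise RuntimeError(
            f"fixture grid incomplete: {grid.n_converged}/{n_cells} cells")
    return grid


def representative_gait_controllers(config: Optional[ExperimentConfig] = None):
    """Solve the five representative gaits and their deadbeat controllers."""
    cfg = config or ExperimentConfig()
    out = []
    rng = np.random.default_rng(cfg.seed)
    for (sl, sf), region in zip(cfg.representative_gaits, REGION_NAMES):
        gait = solve_limit_cycle_continued(
            GaitSpec(sl, sf), tol=cfg.solver_tol,
            integration_tol=cfg.integration_tol, rng=rng)
        if not gait.converged:
            raise RuntimeError(f"representative gait ({sl}, {sf}) "
                               "did not converge")
        ctrl = build_controller(gait, integration_tol=cfg.integration_tol)
        out.append((region, gait, ctrl))
    return out


def reproduce_table1(config: Optional[ExperimentConfig] = None,
                     count_initial_stride: bool = True) -> pd.DataFrame:
    """Local-controller MTP and response times at the representative gaits.

    For each gait: the controlled maximum tolerable perturbation radius,
    then the settling time after perturbing step frequency and step length
    up and down by that radius, running the target gait's deadbeat
    controller from the perturbed gait's limit-cycle state.  Step counts
    follow the convention in which the perturbed starting stride is stride
    one (``count_initial_stride``).
    """
    cfg = config or ExperimentConfig()
    rows = []
    for region, gait, ctrl in representative_gait_controllers(cfg):
        cache = GaitCache(gait, increment=cfg.increment, tol=cfg.solver_tol,
                          integration_tol=cfg.integration_tol)
        res = mtp_search(gait, cache, controlled=True, controller=ctrl,
                         n_steps=cfg.mtp_steps,
                         cap_radius=cfg.mtp_cap_radius,
                         integration_tol=cfg.integration_tol)
        mtp = res.mtp_radius
        row = {"region": region, "SL": gait.SL, "SF": gait.SF,
               "mtp_magnitude": mtp}
        for axis, sign, col in (("SF", +1, "rt_sf_up"),
                                ("SF", -1, "rt_sf_down"),
                                ("SL", +1, "rt_sl_up"),
                                ("SL", -1, "rt_sl_down")):
            sl_p = gait.SL + (sign * mtp if axis == "SL" else 0.0)
            sf_p = gait.SF + (sign * mtp if axis == "SF" else 0.0)
            pert = solve_limit_cycle(GaitSpec(round(sl_p, 10),
                                              round(sf_p, 10)),
                                     guess=gait, tol=cfg.solver_tol,
                                     integration_tol=cfg.integration_tol)
            if not pert.converged:
                row[col] = np.nan
                continue
            r = response_time_experiment(
                gait, ctrl, pert, axis,
                count_initial_stride=count_initial_stride,
                integration_tol=cfg.integration_tol)
            row[col] = r["settling_steps"]
        rows.append(row)
    return pd.DataFrame(rows)


def _policy_patch(gait: LimitCycleGait, cfg: ExperimentConfig,
                  frac: float = 0.18):
    """Gain grid covering the ±15% perturbation experiments at one gait."""
    lo_b, hi_b = GAIT_SPACE_BOUNDS
    inc = cfg.increment

    def clip_range(v):
        lo = max(lo_b, np.floor(v * (1 - frac) / inc) * inc)
        hi = min(hi_b, np.ceil(v * (1 + frac) / inc) * inc)
        return (round(lo, 10), round(hi, 10))

    grid = continuation_sweep(clip_range(gait.SL), clip_range(gait.SF),
                              inc, seed_gait=gait, tol=cfg.solver_tol,
                              integration_tol=cfg.integration_tol)
    return build_gain_grid(grid, cfg.fd_step, cfg.integration_tol)


def reproduce_table2(config: Optional[ExperimentConfig] = None
                     ) -> pd.DataFrame:
    """Optimal policy response times to ±15% SL and SF perturbations.

    Each representative gait gets a local gain-grid patch covering the
    perturbed region; the shared exponential-reference time constant is
    optimized per axis (10-step paths; 30 steps for the top-left gait's
    step-frequency perturbation).
    """
    cfg = config or ExperimentConfig()
    rows = []
    for region, gait, _ in representative_gait_controllers(cfg):
        gg = _policy_patch(gait, cfg)
        row = {"region": region, "SL": gait.SL, "SF": gait.SF}
        for axis, col in (("SF", "rt_sf"), ("SL", "rt_sl")):
            max_steps = 30 if (region == "Top left" and axis == "SF") else 10
            try:
                r = optimize_response_time(
                    gait, axis, gg, max_steps=max_steps,
                    integration_tol=cfg.integration_tol,
                    solver_tol=cfg.solver_tol)
                row[col] = r.response_steps
                row[col + "_tau"] = r.tau
            except Exception as exc:
                if isinstance(exc, KeyboardInterrupt):
                    raise
                row[col] = np.nan
                row[col + "_tau"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def reproduce_summary_stats(config: Optional[ExperimentConfig] = None,
                            table1: Optional[pd.DataFrame] = None,
                            mtp_grid: Optional[GaitGrid] = None,
                            mtp_stride: int = 2,
                            count_initial_stride: bool = True) -> dict:
    """Gait-space summary statistics.

    Response-time means over the five representative gaits (SL and SF
    perturbations pooled separately), and mean +/- SD of the maximum
    tolerable perturbation with and without control over a sub-sampled
    grid (``mtp_grid`` with every ``mtp_stride``-th cell as target).
    """
    cfg = config or ExperimentConfig()
    if table1 is None:
        table1 = reproduce_table1(cfg, count_initial_stride)
    sl_times = table1[["rt_sl_up", "rt_sl_down"]].to_numpy().ravel()
    sf_times = table1[["rt_sf_up", "rt_sf_down"]].to_numpy().ravel()
    out = {
        "response_sl_mean": float(np.nanmean(sl_times)),
        "response_sl_sd": float(np.nanstd(sl_times, ddof=1)),
        "response_sf_mean": float(np.nanmean(sf_times)),
        "response_sf_sd": float(np.nanstd(sf_times, ddof=1)),
        "table1": table1,
    }
    if mtp_grid is not None:
        open_df = mtp_survey(mtp_grid, mtp_stride, controlled=False,
                             increment=cfg.increment,
                             cap_radius=cfg.mtp_cap_radius,
                             integration_tol=cfg.integration_tol,
                             solver_tol=cfg.solver_tol)
        ctrl_df = mtp_survey(mtp_grid, mtp_stride, controlled=True,
                             increment=cfg.increment,
                             cap_radius=cfg.mtp_cap_radius,
                             integration_tol=cfg.integration_tol,
                             solver_tol=cfg.solver_tol)
        out.update({
            "mtp_open_mean": float(np.nanmean(open_df["mtp"])),
            "mtp_open_sd": float(np.nanstd(open_df["mtp"], ddof=1)),
            "mtp_controlled_mean": float(np.nanmean(ctrl_df["mtp"])),
            "mtp_controlled_sd": float(np.nanstd(ctrl_df["mtp"], ddof=1)),
            "mtp_open": open_df,
            "mtp_controlled": ctrl_df,
        })
    return out
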