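"""Intermediate ("ghost") state analysis of the G1-S switch.

Just above the fold the switch lingers in the remnant of the annihilated
fixed points -- a ghost transient produced by critical slowing down.  On
the activity scale a(r) = 1 - tanh(r), G1 progression becomes
multi-phasic: a long, highly variable plateau at intermediate activity,
followed by a rapid, stereotyped final rise into S phase.  This module
decomposes trajectories by first crossings of three activity thresholds
(active, high, S-entry), aligns and bin-averages trajectories by total
G1 length, and runs the inhibitory-perturbation experiment showing that
cells in the intermediate state revert to quiescence unless they have
passed the commitment region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .rb_switch import RbParams, Trajectory, activity_proxy, drift, find_bifurcation

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdSpec",
    "GhostEnsembleParams",
    "PhaseDurations",
    "GhostEnsemble",
    "classify_phases",
    "run_ghost_ensemble",
    "align_and_bin",
    "perturbation_experiment",
]


def _default_s_entry() -> float:
    return float(1.0 - np.tanh(RbParams().r_thresh))


@dataclass(frozen=True)
class ThresholdSpec:
    """Activity thresholds delimiting the ghost region.

    ``active_threshold`` marks entry into the ghost region,
    ``high_threshold`` the exit from it, and ``s_entry_threshold``
    (1 - tanh(r_thresh)) the S-phase entry.
    """

    active_threshold: float = 0.4
    high_threshold: float = 0.7
    s_entry_threshold: float = field(default_factory=_default_s_entry)

    def __post_init__(self) -> None:
        if not self.active_threshold < self.high_threshold < self.s_entry_threshold:
            raise ValueError("thresholds must satisfy active < high < s_entry")


@dataclass(frozen=True)
class GhostEnsembleParams:
    """Ensemble settings for the ghost simulation.

    Per-cell Cyclin D is drawn from Normal(C_crit + 0.008, 0.004^2),
    placing the population barely past the fold where the ghost delay is
    long and steeply level-dependent.
    """

    n_cells: int = 50000
    t_max: float = 100.0
    dt: float = 0.05
    C_offset: float = 0.008
    C_sd: float = 0.004
    seed: int | None = None


@dataclass
class PhaseDurations:
    """First-crossing times (hours) of one cell; NaN marks a censored phase."""

    t_active: float
    t_high: float
    t_s: float

    @property
    def phase1(self) -> float:
        return self.t_high - self.t_active

    @property
    def phase2(self) -> float:
        return self.t_s - self.t_high

    @property
    def total_g1(self) -> float:
        return self.t_s - self.t_active


@dataclass
class GhostEnsemble:
    """Crossing times for an ensemble, plus (optionally) stored paths."""

    t_active: np.ndarray
    t_high: np.ndarray
    t_s: np.ndarray
    C: np.ndarray
    paths: np.ndarray | None = None  # (n_stored, n_times) activity paths
    path_times: np.ndarray | None = None

    @property
    def phase1(self) -> np.ndarray:
        return self.t_high - self.t_active

    @property
    def phase2(self) -> np.ndarray:
        return self.t_s - self.t_high

    @property
    def total_g1(self) -> np.ndarray:
        return self.t_s - self.t_active

    @property
    def censored_fraction(self) -> float:
        return float(np.mean(np.isnan(self.t_s)))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "C": self.C,
                "t_active_h": self.t_active,
                "t_high_h": self.t_high,
                "t_s_h": self.t_s,
                "phase1_h": self.phase1,
                "phase2_h": self.phase2,
                "total_g1_h": self.total_g1,
            }
        )


def classify_phases(trajectory: Trajectory, thresholds: ThresholdSpec = ThresholdSpec()) -> PhaseDurations:
    """First-crossing times of the three activity thresholds for one path.

    Crossings that never occur are NaN (censored).  The trajectory must be
    sampled on a uniform grid (as produced by the simulators here).
    """
    a = trajectory.activity
    t = trajectory.times
    out = []
    for thr in (
        thresholds.active_threshold,
        thresholds.high_threshold,
        thresholds.s_entry_threshold,
    ):
        above = np.flatnonzero(a >= thr)
        out.append(float(t[above[0]]) if above.size else float("nan"))
    return PhaseDurations(*out)


def run_ghost_ensemble(
    rb: RbParams = RbParams(),
    params: GhostEnsembleParams = GhostEnsembleParams(),
    thresholds: ThresholdSpec = ThresholdSpec(),
    store_paths: int = 0,
    C_crit: float | None = None,
) -> GhostEnsemble:
    """Simulate the ghost ensemble and record threshold-crossing times.

    Crossings are detected on the fly, so the full 50k-cell ensemble does
    not require storing trajectories; the first ``store_paths`` cells'
    activity paths are kept for alignment plots.
    """
    rng = np.random.default_rng(params.seed)
    if C_crit is None:
        C_crit = find_bifurcation(rb).C_crit_high
    C = rng.normal(C_crit + params.C_offset, params.C_sd, params.n_cells)
    if np.any(C < 0):
        logger.warning("clipping %d negative Cyclin D draws at 0", int(np.sum(C < 0)))
        C = np.clip(C, 0.0, None)

    n = params.n_cells
    dt, t_max = params.dt, params.t_max
    n_steps = int(round(t_max / dt))
    thr_r = np.array(
        [
            # activity >= thr  <=>  r <= atanh(1 - thr)
            np.arctanh(1.0 - thresholds.active_threshold),
            np.arctanh(1.0 - thresholds.high_threshold),
            np.arctanh(1.0 - thresholds.s_entry_threshold),
        ]
    )
    crossings = np.full((3, n), np.nan)
    r = np.full(n, rb.r0)
    sqrt_dt = math.sqrt(dt)
    n_store = min(store_paths, n)
    paths = np.full((n_store, n_steps + 1), np.nan) if n_store else None
    if paths is not None:
        paths[:, 0] = activity_proxy(r[:n_store])
    for i in range(n_steps):
        z = rng.standard_normal(n)
        r = np.maximum(r + drift(r, C, rb) * dt + rb.sigma * r * sqrt_dt * z, 0.0)
        t_now = (i + 1) * dt
        for j in range(3):
            new = np.isnan(crossings[j]) & (r <= thr_r[j])
            if new.any():
                crossings[j, new] = t_now
        if paths is not None:
            paths[:, i + 1] = activity_proxy(r[:n_store])
    path_times = np.arange(n_steps + 1) * dt if paths is not None else None
    return GhostEnsemble(
        t_active=crossings[0],
        t_high=crossings[1],
        t_s=crossings[2],
        C=C,
        paths=paths,
        path_times=path_times,
    )


@dataclass
class BinnedTrajectories:
    """S-entry-aligned, bin-averaged activity curves."""

    grid: np.ndarray  # common time axis, t=0 at S entry (negative in G1)
    bin_edges: np.ndarray  # on total G1 length
    mean_curves: list  # one mean activity curve per non-empty bin
    sample_curves: list  # one representative path per non-empty bin
    bin_labels: list


def align_and_bin(
    paths: np.ndarray,
    path_times: np.ndarray,
    t_s: np.ndarray,
    total_g1: np.ndarray,
    bin_edges: np.ndarray | None = None,
    grid: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> BinnedTrajectories:
    """Align activity paths to S entry (t=0) and average within G1 bins.

    ``paths`` holds one activity trajectory per row on the common axis
    ``path_times``; censored cells (NaN ``t_s``) are dropped.  Bin edges
    on total G1 length default to the quartiles of the uncensored cells.
    Alignment shifts each path by its own S-entry time and linearly
    interpolates onto ``grid`` (default: from -max(total G1) to 0 at the
    native step); aligning already-aligned paths is a no-op because the
    shift is recomputed from ``t_s``.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    ok = ~np.isnan(t_s)
    if not ok.any():
        raise ValueError("no uncensored trajectory to align")
    paths, t_s, total_g1 = paths[ok], t_s[ok], total_g1[ok]
    if bin_edges is None:
        bin_edges = np.quantile(total_g1, [0.0, 0.25, 0.5, 0.75, 1.0])
    if grid is None:
        dt = path_times[1] - path_times[0]
        grid = np.arange(-float(np.nanmax(total_g1)), dt / 2, dt)

    mean_curves, sample_curves, labels = [], [], []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        inbin = (total_g1 >= lo) & (total_g1 <= hi)
        if not inbin.any():
            logger.warning("empty G1 bin [%.2f, %.2f] h omitted", lo, hi)
            continue
        aligned = np.full((int(inbin.sum()), grid.size), np.nan)
        for row, (p, ts) in enumerate(zip(paths[inbin], t_s[inbin])):
            shifted = path_times - ts
            valid = ~np.isnan(p)
            aligned[row] = np.interp(grid, shifted[valid], p[valid], left=np.nan, right=np.nan)
        import warnings as _warnings

        with _warnings.catch_warnings():
            # grid points before the earliest aligned sample are all-NaN
            _warnings.simplefilter("ignore", RuntimeWarning)
            mean_curves.append(np.nanmean(aligned, axis=0))
        sample_curves.append(aligned[rng.integers(aligned.shape[0])])
        labels.append((float(lo), float(hi)))
    return BinnedTrajectories(
        grid=grid,
        bin_edges=np.asarray(bin_edges),
        mean_curves=mean_curves,
        sample_curves=sample_curves,
        bin_labels=labels,
    )


@dataclass
class PerturbationResult:
    """Outcome of the inhibitory-perturbation experiment."""

    labels: np.ndarray  # 'proceeds' | 'reverts' | 'other' per cell
    counts: dict
    activity_at_perturb: np.ndarray
    paths: np.ndarray
    path_times: np.ndarray

    def to_dict(self) -> dict:
        return dict(self.counts)


def perturbation_experiment(
    rb: RbParams = RbParams(),
    thresholds: ThresholdSpec = ThresholdSpec(),
    n: int = 100,
    t_max: float = 80.0,
    dt: float = 0.05,
    t_perturb: float = 15.0,
    delta_C: float = -0.1,
    C0: float | None = None,
    seed: int | None = None,
    revert_window: float = 5.0,
) -> PerturbationResult:
    """Sudden mitogen drop during the ghost transient.

    All cells hold C = C0 (default: the critical value) until
    ``t_perturb``, when C changes by ``delta_C`` (clipped at 0).  Each
    cell is labelled ``"proceeds"`` if its activity crosses the S-entry
    threshold after the perturbation, ``"reverts"`` if it never enters S,
    was in the active state (> 0.5) just before the drop, and averages
    below 0.4 over the final ``revert_window`` hours, and ``"other"``
    otherwise.
    """
    rng = np.random.default_rng(seed)
    if C0 is None:
        C0 = find_bifurcation(rb).C_crit_high
    C_post = max(C0 + delta_C, 0.0)
    if C0 + delta_C < 0:
        logger.warning("post-perturbation C clipped at 0")
    n_steps = int(round(t_max / dt))
    i_pert = int(round(t_perturb / dt))
    sqrt_dt = math.sqrt(dt)

    r = np.full(n, rb.r0)
    acts = np.empty((n, n_steps + 1))
    acts[:, 0] = activity_proxy(r)
    s_entry_after = np.zeros(n, dtype=bool)
    thr_r_s = np.arctanh(1.0 - thresholds.s_entry_threshold)
    for i in range(n_steps):
        C_now = C0 if i < i_pert else C_post
        z = rng.standard_normal(n)
        r = np.maximum(r + drift(r, C_now, rb) * dt + rb.sigma * r * sqrt_dt * z, 0.0)
        acts[:, i + 1] = activity_proxy(r)
        if i >= i_pert:
            s_entry_after |= r <= thr_r_s

    act_before = acts[:, i_pert]  # last sample before the drop takes effect
    n_tail = max(int(round(revert_window / dt)), 1)
    tail_mean = acts[:, -n_tail:].mean(axis=1)

    labels = np.full(n, "other", dtype=object)
    labels[s_entry_after] = "proceeds"
    reverts = (~s_entry_after) & (act_before > 0.5) & (tail_mean < 0.4)
    labels[reverts] = "reverts"
    counts = {
        "proceeds": int(np.sum(labels == "proceeds")),
        "reverts": int(np.sum(labels == "reverts")),
        "other": int(np.sum(labels == "other")),
    }
    return PerturbationResult(
        labels=labels,
        counts=counts,
        activity_at_perturb=act_before,
        paths=acts,
        path_times=np.arange(n_steps + 1) * dt,
    )
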