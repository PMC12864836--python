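"""Single-cell Rb/E2F G1-S switch.

The concentration of active (unphosphorylated) Rb protein, ``r``, obeys

    dr = (1 - (gamma_D + gamma_P(r, C)) r) dt + sigma r dW,

where production is constant (scaled to 1), ``gamma_D`` is the
degradation/dilution rate and ``gamma_P`` the phosphorylation rate.
Phosphorylation is driven by Cyclin D activity ``C`` (saturating with scale
``k1``) and suppressed cooperatively by ``r`` itself (Hill coefficient 2,
scale ``k2``), a phenomenological stand-in for the E2F/CycE positive
feedback.  The deterministic part undergoes a saddle-node (fold)
bifurcation in ``C``: the high-``r`` G1 state annihilates at an upper fold
``C_crit``, beyond which ``r`` collapses and the cell enters S phase once
``r`` drops below ``r_thresh``.

This module provides the vector field, fixed-point and fold analysis, and
Euler-Maruyama simulation of single trajectories and first-passage
ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "RbParams",
    "FixedPointSet",
    "BifurcationResult",
    "Trajectory",
    "gamma_P",
    "drift",
    "drift_dr",
    "drift_dC",
    "find_fixed_points",
    "find_bifurcation",
    "simulate_rb",
    "first_passage_ensemble",
    "activity_proxy",
]

#: sign tolerance below which a stability eigenvalue is reported as marginal
_MARGINAL_TOL = 1e-10


@dataclass(frozen=True)
class RbParams:
    """Parameters of the stochastic Rb switch (rates in 1/hour).

    Defaults are the reference parameter set: degradation scaled to 1,
    a strong phosphorylation amplitude V=100 and a narrow feedback scale
    k2=0.1, which place the upper fold at C_crit ~ 0.35.
    """

    gamma_D: float = 1.0
    V: float = 100.0
    k1: float = 1.0
    k2: float = 0.1
    sigma: float = 0.3
    r0: float = 4.0
    r_thresh: float = 0.05

    def __post_init__(self) -> None:
        for name in ("gamma_D", "V", "k1", "k2", "r0", "r_thresh"):
            if not getattr(self, name) > 0:
                raise ValueError(f"RbParams.{name} must be strictly positive")
        if self.sigma < 0:
            raise ValueError("RbParams.sigma must be non-negative")
        if not self.r_thresh < self.r0:
            raise ValueError("r_thresh must be below the birth level r0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class FixedPointSet:
    """All non-negative fixed points of the deterministic switch at one C."""

    C: float
    roots: tuple[float, ...]
    stabilities: tuple[str, ...]

    def stable_roots(self) -> tuple[float, ...]:
        return tuple(r for r, s in zip(self.roots, self.stabilities) if s == "stable")


@dataclass(frozen=True)
class BifurcationResult:
    """Fold structure of the switch over a range of C.

    ``bistable`` is False when no fold exists in the searched range (e.g.
    when the phosphorylation amplitude is too weak for bistability); the
    fold fields are then NaN.
    """

    bistable: bool
    C_crit_low: float = float("nan")
    C_crit_high: float = float("nan")
    r_fold_low: float = float("nan")
    r_fold_high: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Trajectory:
    """A single simulated path of the switch on a uniform time grid."""

    times: np.ndarray
    r_values: np.ndarray
    C: float | np.ndarray
    exited: bool
    exit_time: float  # NaN when censored at t_max

    @property
    def activity(self) -> np.ndarray:
        return activity_proxy(self.r_values)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_h": self.times, "r": self.r_values, "activity": self.activity}
        )


def _check_nonneg(name: str, value) -> None:
    if np.any(np.asarray(value) < 0):
        raise ValueError(f"{name} must be non-negative")


def gamma_P(r, C, params: RbParams = RbParams()):
    """Phosphorylation rate V * C/(1+C/k1) * 1/(1+(r/k2)^2) (1/hour)."""
    _check_nonneg("r", r)
    _check_nonneg("C", C)
    r = np.asarray(r, dtype=float)
    C = np.asarray(C, dtype=float)
    out = params.V * (C / (1.0 + C / params.k1)) / (1.0 + (r / params.k2) ** 2)
    return out if out.ndim else float(out)


def drift(r, C, params: RbParams = RbParams()):
    """Deterministic part of dr/dt: 1 - (gamma_D + gamma_P(r, C)) r."""
    out = 1.0 - (params.gamma_D + gamma_P(r, C, params)) * np.asarray(r, dtype=float)
    return out if np.ndim(out) else float(out)


def drift_dr(r, C, params: RbParams = RbParams()):
    """Analytic d(drift)/dr; determines linear stability of fixed points."""
    r = np.asarray(r, dtype=float)
    C = np.asarray(C, dtype=float)
    u = (r / params.k2) ** 2
    W = params.V * C / (1.0 + C / params.k1)
    out = -params.gamma_D - W * (1.0 - u) / (1.0 + u) ** 2
    return out if out.ndim else float(out)


def drift_dC(r, C, params: RbParams = RbParams()):
    """Analytic d(drift)/dC (the control direction of the fold)."""
    r = np.asarray(r, dtype=float)
    C = np.asarray(C, dtype=float)
    dW = params.V / (1.0 + C / params.k1) ** 2
    out = -r * dW / (1.0 + (r / params.k2) ** 2)
    return out if out.ndim else float(out)


def _cubic_coefficients(C: float, params: RbParams) -> np.ndarray:
    # Multiplying drift=0 by (1+(r/k2)^2) gives the cubic
    #   -(gamma_D/k2^2) r^3 + (1/k2^2) r^2 - (gamma_D + W) r + 1 = 0
    # with W = V C / (1 + C/k1).
    W = params.V * C / (1.0 + C / params.k1)
    k2sq = params.k2**2
    return np.array([-params.gamma_D / k2sq, 1.0 / k2sq, -(params.gamma_D + W), 1.0])


def find_fixed_points(C: float, params: RbParams = RbParams()) -> FixedPointSet:
    """All non-negative fixed points of the switch at control value C.

    Roots of the equivalent cubic, sorted ascending, with stability from
    the sign of d(drift)/dr (eigenvalues within 1e-10 of zero reported as
    ``"marginal"``, which occurs only exactly at a fold).
    """
    _check_nonneg("C", C)
    raw = np.roots(_cubic_coefficients(float(C), params))
    real = raw[np.abs(raw.imag) < 1e-9 * np.maximum(1.0, np.abs(raw))].real
    roots = np.sort(real[real >= -1e-12])
    roots = np.clip(roots, 0.0, None)
    stabilities = []
    for r in roots:
        lam = drift_dr(r, C, params)
        if abs(lam) < _MARGINAL_TOL:
            stabilities.append("marginal")
        else:
            stabilities.append("stable" if lam < 0 else "unstable")
    return FixedPointSet(C=float(C), roots=tuple(roots), stabilities=tuple(stabilities))


def _root_count(C: float, params: RbParams) -> int:
    return len(find_fixed_points(C, params).roots)


def _polish_fold(C_guess: float, r_guess: float, params: RbParams) -> tuple[float, float]:
    from scipy.optimize import fsolve

    def equations(v):
        r, C = v
        return [drift(r, max(C, 0.0), params), drift_dr(r, max(C, 0.0), params)]

    (r_f, C_f), _, ier, _ = fsolve(equations, [r_guess, C_guess], full_output=True)
    if ier != 1:
        raise RuntimeError("fold polishing did not converge")
    return float(C_f), float(r_f)


def find_bifurcation(
    params: RbParams = RbParams(),
    C_search_range: tuple[float, float] = (1e-3, 2.0),
    n_scan: int = 400,
    tol_C: float = 1e-6,
) -> BifurcationResult:
    """Locate both folds of the switch by bisection on the root count.

    Scans ``C_search_range`` for changes in the number of fixed points
    (1 <-> 3), bisects each bracketing interval to ``tol_C``, then polishes
    the fold by solving drift = 0 and d(drift)/dr = 0 simultaneously.
    Returns ``BifurcationResult(bistable=False)`` when no fold is found.
    """
    lo, hi = C_search_range
    grid = np.linspace(lo, hi, n_scan)
    counts = np.array([_root_count(C, params) for C in grid])
    change_idx = np.flatnonzero(np.diff(counts) != 0)
    if change_idx.size < 2:
        return BifurcationResult(bistable=False)

    folds: list[tuple[float, float]] = []
    for i in change_idx[:2]:
        a, b = grid[i], grid[i + 1]
        ca = counts[i]
        while b - a > tol_C:
            mid = 0.5 * (a + b)
            if _root_count(mid, params) == ca:
                a = mid
            else:
                b = mid
        C_b = 0.5 * (a + b)
        # at the fold, the merging pair sits at the double root: take the
        # middle root of the 3-root side as the initial guess
        side = b if counts[i] == 3 else a
        fp = find_fixed_points(side, params)
        guess_r = fp.roots[1] if len(fp.roots) == 3 else fp.roots[0]
        folds.append(_polish_fold(C_b, guess_r, params))

    (C1, r1), (C2, r2) = folds
    if C1 > C2:
        (C1, r1), (C2, r2) = (C2, r2), (C1, r1)
    return BifurcationResult(
        bistable=True,
        C_crit_low=C1,
        C_crit_high=C2,
        r_fold_low=r1,
        r_fold_high=r2,
    )


def activity_proxy(r):
    """Rb/E2F switch activity 1 - tanh(r), bounded in [0, 1)."""
    _check_nonneg("r", r)
    out = 1.0 - np.tanh(np.asarray(r, dtype=float))
    return out if out.ndim else float(out)


def simulate_rb(
    params: RbParams,
    C,
    dt: float = 0.05,
    t_max: float = 100.0,
    seed: int | np.random.Generator | None = None,
    record: bool = True,
) -> Trajectory:
    """Euler-Maruyama integration of the switch from r0 (Ito interpretation).

    ``C`` may be a scalar (constant Cyclin D activity during G1) or an
    array with one value per step.  The path is clipped at r=0 after each
    step and stops at the first sample strictly below ``r_thresh`` (the
    G1/S exit) or at ``t_max`` (censored, ``exit_time`` NaN).
    """
    if dt <= 0 or t_max <= 0:
        raise ValueError("dt and t_max must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_steps = int(round(t_max / dt))
    C_arr = np.broadcast_to(np.asarray(C, dtype=float), (n_steps,))
    _check_nonneg("C", C_arr)

    r = params.r0
    sqrt_dt = np.sqrt(dt)
    rs = np.empty(n_steps + 1)
    rs[0] = r
    exited = False
    exit_time = float("nan")
    last = n_steps
    for i in range(n_steps):
        z = rng.standard_normal()
        r = r + drift(r, C_arr[i], params) * dt + params.sigma * r * sqrt_dt * z
        r = max(r, 0.0)
        rs[i + 1] = r
        if r < params.r_thresh:
            exited = True
            exit_time = (i + 1) * dt
            last = i + 1
            break
    times = np.arange(last + 1) * dt
    return Trajectory(
        times=times,
        r_values=rs[: last + 1] if record else rs[last : last + 1],
        C=C if np.ndim(C) == 0 else np.asarray(C),
        exited=exited,
        exit_time=exit_time,
    )


def first_passage_ensemble(
    params: RbParams,
    C,
    dt: float = 0.05,
    t_max: float = 100.0,
    n: int | None = None,
    seed: int | np.random.Generator | None = None,
    sigma: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized G1 first-passage times for many independent cells.

    ``C`` is either a scalar (with ``n`` required) or an array of per-cell
    Cyclin D activities.  Returns ``(exit_times, censored)`` where censored
    cells carry NaN exit times.  Cells that have already exited are dropped
    from the update loop, so the cost scales with the surviving population.
    """
    if dt <= 0 or t_max <= 0:
        raise ValueError("dt and t_max must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    C_arr = np.asarray(C, dtype=float)
    if C_arr.ndim == 0:
        if n is None:
            raise ValueError("n is required when C is a scalar")
        C_arr = np.full(n, float(C_arr))
    _check_nonneg("C", C_arr)
    n_cells = C_arr.size
    sig = params.sigma if sigma is None else sigma

    r = np.full(n_cells, params.r0)
    exit_times = np.full(n_cells, np.nan)
    alive = np.arange(n_cells)
    C_live = C_arr.copy()
    sqrt_dt = np.sqrt(dt)
    n_steps = int(round(t_max / dt))
    for i in range(n_steps):
        z = rng.standard_normal(alive.size)
        r = r + drift(r, C_live, params) * dt + sig * r * sqrt_dt * z
        r = np.maximum(r, 0.0)
        hit = r < params.r_thresh
        if hit.any():
            exit_times[alive[hit]] = (i + 1) * dt
            keep = ~hit
            alive, r, C_live = alive[keep], r[keep], C_live[keep]
            if alive.size == 0:
                break
    censored = np.isnan(exit_times)
    return exit_times, censored
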