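"""Critical dynamics near the fold: the saddle-node normal form.

Near the fold the switch reduces to the one-dimensional noisy process

    dx = (x^2 + mu) dt + xi dW,

where ``x`` is the rescaled coordinate (positive ``x`` is the exit
direction), ``mu`` is the rescaled distance from the bifurcation
(``mu`` proportional to ``C - C_crit``) and ``xi`` the noise amplitude at
the critical point.  The mean transition time admits the exact closed form

    T(mu, xi) = 2^{1/3} pi^2 xi^{-2/3} ( Ai^2[-2^{2/3} xi^{-4/3} mu]
                                       + Bi^2[-2^{2/3} xi^{-4/3} mu] ),

with Airy functions Ai, Bi.  For mu < 0 (sub-critical, noise-driven
escape over a barrier) the Kramers approximation

    T ~ (pi / sqrt|mu|) exp( (8/3) |mu|^{3/2} / xi^2 )

applies, giving the super-exponential scaling log T ~ |mu|^{3/2}.

This module evaluates the exact and approximate mean delays (in log space
where the exact formula overflows), estimates the delay empirically by
simulation, fits the scaling exponent, simulates time-dependent mu(t)
protocols, and computes the local reduction of the full Rb switch onto
the normal form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import special

from .rb_switch import RbParams, drift, drift_dC, find_bifurcation

__all__ = [
    "NormalFormParams",
    "ReductionCoefficients",
    "EmpiricalMFPT",
    "ScalingFit",
    "mfpt_exact",
    "log_mfpt_exact",
    "mfpt_kramers",
    "log_mfpt_kramers",
    "mfpt_empirical",
    "scaling_exponent",
    "simulate_normal_form",
    "reduce_to_normal_form",
    "predict_exit_time",
]

#: Airy argument beyond which Ai^2+Bi^2 is evaluated via exponentially
#: scaled Airy functions to avoid overflow of Bi.  Continuity across the
#: switch-over is covered by tests.
AIRY_SWITCH = 8.0


@dataclass(frozen=True)
class NormalFormParams:
    """Rescaled distance from the fold ``mu`` and critical noise ``xi``."""

    mu: float
    xi: float

    def __post_init__(self) -> None:
        if not self.xi > 0:
            raise ValueError("xi must be strictly positive")


def _airy_argument(mu, xi):
    return -(2.0 ** (2.0 / 3.0)) * np.asarray(xi, dtype=float) ** (-4.0 / 3.0) * np.asarray(
        mu, dtype=float
    )


def log_mfpt_exact(mu, xi):
    """log of the exact mean delay; safe deep in the sub-critical regime.

    For Airy arguments above ``AIRY_SWITCH`` the sum Ai^2+Bi^2 is computed
    from the exponentially scaled functions Ai_e, Bi_e of scipy
    (Bi(z) = Bi_e(z) exp(+(2/3) z^{3/2})), which is exact, not asymptotic.
    """
    mu = np.asarray(mu, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if np.any(xi <= 0):
        raise ValueError("xi must be strictly positive")
    z = _airy_argument(mu, xi)
    z, xi = np.broadcast_arrays(z, xi)
    out = np.empty(z.shape)
    prefac = (1.0 / 3.0) * math.log(2.0) + 2.0 * math.log(math.pi) - (2.0 / 3.0) * np.log(xi)

    small = z <= AIRY_SWITCH
    if small.any():
        ai, _, bi, _ = special.airy(z[small])
        out[small] = np.log(ai**2 + bi**2)
    big = ~small
    if big.any():
        zb = z[big]
        aie, _, bie, _ = special.airye(zb)
        w = (2.0 / 3.0) * zb**1.5
        # Ai^2 + Bi^2 = e^{2w} (Bi_e^2 + Ai_e^2 e^{-4w})
        out[big] = 2.0 * w + np.log(bie**2 + aie**2 * np.exp(-4.0 * w))
    out = out + prefac
    return out if out.ndim else float(out)


def mfpt_exact(mu, xi):
    """Exact mean delay of the normal form (rescaled time units).

    Finite and positive for every ``mu``; strictly decreasing in ``mu``.
    May overflow to inf deep in the sub-critical regime -- use
    :func:`log_mfpt_exact` there.
    """
    out = np.exp(log_mfpt_exact(mu, xi))
    return out if np.ndim(out) else float(out)


def log_mfpt_kramers(mu, xi):
    """log of the Kramers escape-time approximation (mu < 0 only)."""
    mu = np.asarray(mu, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if np.any(mu >= 0):
        raise ValueError("the Kramers approximation requires mu < 0")
    if np.any(xi <= 0):
        raise ValueError("xi must be strictly positive")
    amu = np.abs(mu)
    out = np.log(np.pi) - 0.5 * np.log(amu) + (8.0 / 3.0) * amu**1.5 / xi**2
    return out if out.ndim else float(out)


def mfpt_kramers(mu, xi):
    """Kramers approximation (pi/sqrt|mu|) exp((8/3)|mu|^{3/2}/xi^2).

    Escape over the barrier dU = (4/3)|mu|^{3/2} of the double-well
    potential U(x) = -x^3/3 - mu x; valid for mu < 0 and
    |mu|^{3/2}/xi^2 >> 1.
    """
    out = np.exp(log_mfpt_kramers(mu, xi))
    return out if np.ndim(out) else float(out)


@dataclass(frozen=True)
class EmpiricalMFPT:
    """Monte-Carlo first-passage estimate with its standard error."""

    mean: float
    se: float
    n: int
    n_censored: int
    exit_times: np.ndarray

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "se": self.se,
            "n": self.n,
            "n_censored": self.n_censored,
        }


def _default_boundaries(mu: float) -> tuple[float, float]:
    # wide enough that the potential difference to the fold region exceeds
    # the noise scale for every xi used in practice; truncation error is
    # below Monte-Carlo noise
    b = max(3.0, 3.0 * math.sqrt(abs(mu)))
    return -b, b


def mfpt_empirical(
    mu: float,
    xi: float,
    n: int = 2000,
    seed: int | np.random.Generator | None = None,
    dt: float = 0.01,
    x0: float | None = None,
    x_absorb: float | None = None,
    t_cap: float | None = None,
) -> EmpiricalMFPT:
    """Monte-Carlo mean first-passage time of dx = (x^2+mu) dt + xi dW.

    Paths start at ``x0`` and are absorbed at ``x_absorb`` (defaults
    +-max(3, 3 sqrt|mu|)).  Paths that have not been absorbed by
    ``t_cap`` (default 50x the exact prediction) are reported in
    ``n_censored`` and excluded from the mean, never silently dropped.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    lo, hi = _default_boundaries(mu)
    x0 = lo if x0 is None else x0
    x_absorb = hi if x_absorb is None else x_absorb
    if not x0 < x_absorb:
        raise ValueError("x0 must lie below x_absorb")
    if t_cap is None:
        t_cap = 50.0 * min(mfpt_exact(mu, xi), 1e6)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    x = np.full(n, float(x0))
    exit_times = np.full(n, np.nan)
    alive = np.arange(n)
    sqrt_dt = math.sqrt(dt)
    n_steps = int(math.ceil(t_cap / dt))
    for i in range(n_steps):
        x = x + (x * x + mu) * dt + xi * sqrt_dt * rng.standard_normal(alive.size)
        hit = x >= x_absorb
        if hit.any():
            exit_times[alive[hit]] = (i + 1) * dt
            keep = ~hit
            alive, x = alive[keep], x[keep]
            if alive.size == 0:
                break
    done = exit_times[~np.isnan(exit_times)]
    n_censored = n - done.size
    mean = float(done.mean()) if done.size else float("nan")
    se = float(done.std(ddof=1) / math.sqrt(done.size)) if done.size > 1 else float("nan")
    return EmpiricalMFPT(mean=mean, se=se, n=n, n_censored=n_censored, exit_times=done)


@dataclass(frozen=True)
class ScalingFit:
    """Least-squares fit of log(log T) against log|mu|."""

    exponent: float
    intercept: float
    regime_ok: bool
    min_barrier_ratio: float

    def to_dict(self) -> dict:
        return asdict(self)


def scaling_exponent(xi: float, mu_grid) -> ScalingFit:
    """Fitted exponent of the super-exponential scaling log T ~ |mu|^p.

    Regresses log(log T_exact) on log|mu| over a sub-critical grid; in the
    deep-barrier regime (|mu|^{3/2}/xi^2 >> 1) the slope approaches 3/2.
    A warning is recorded (``regime_ok=False``) when the grid violates
    min |mu|^{3/2}/xi^2 >= 20.
    """
    mu_grid = np.asarray(mu_grid, dtype=float)
    if np.any(mu_grid >= 0):
        raise ValueError("all mu in the grid must be negative")
    ratio = float(np.min(np.abs(mu_grid) ** 1.5 / xi**2))
    regime_ok = ratio >= 20.0
    if not regime_ok:
        warnings.warn(
            "scaling_exponent: barrier ratio |mu|^{3/2}/xi^2 below 20; "
            "the fitted exponent may be biased away from 3/2",
            stacklevel=2,
        )
    y = np.log(log_mfpt_exact(mu_grid, xi))
    X = np.log(np.abs(mu_grid))
    slope, intercept = np.polyfit(X, y, 1)
    return ScalingFit(
        exponent=float(slope),
        intercept=float(intercept),
        regime_ok=regime_ok,
        min_barrier_ratio=ratio,
    )


def simulate_normal_form(
    mu_fn,
    xi: float,
    dt: float = 0.01,
    t_max: float = 200.0,
    n: int = 1000,
    seed: int | np.random.Generator | None = None,
    x0: float = -3.0,
    x_absorb: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-path exit times under a constant or time-dependent mu(t).

    ``mu_fn`` is either a scalar (the critical-lengthening regime, mu held
    fixed) or a callable of time in rescaled units (e.g. a linear ramp,
    the time-dependent regime).  Returns ``(exit_times, censored)``.
    """
    if xi < 0:
        raise ValueError("xi must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mu_of_t = mu_fn if callable(mu_fn) else (lambda t, _m=float(mu_fn): _m)

    x = np.full(n, float(x0))
    exit_times = np.full(n, np.nan)
    alive = np.arange(n)
    sqrt_dt = math.sqrt(dt)
    n_steps = int(round(t_max / dt))
    for i in range(n_steps):
        mu_t = mu_of_t(i * dt)
        noise = xi * sqrt_dt * rng.standard_normal(alive.size) if xi > 0 else 0.0
        x = x + (x * x + mu_t) * dt + noise
        hit = x >= x_absorb
        if np.any(hit):
            exit_times[alive[hit]] = (i + 1) * dt
            keep = ~hit
            alive, x = alive[keep], x[keep]
            if alive.size == 0:
                break
    return exit_times, np.isnan(exit_times)


@dataclass(frozen=True)
class ReductionCoefficients:
    """Local expansion of the Rb switch at its upper fold.

    With drift f(r, C) ~ a (C - C_crit) + b (r - r_fold)^2 (a, b < 0 for
    this fold orientation), the substitution x = b (r - r_fold) maps the
    dynamics onto dx/dt = x^2 + mu with mu = a b (C - C_crit), keeping
    time in hours (time_scale = 1).  The multiplicative noise sigma*r
    enters as xi = |b| sigma r_fold.
    """

    C_crit: float
    r_fold: float
    a: float  # d(drift)/dC at the fold
    b: float  # (1/2) d^2(drift)/dr^2 at the fold
    mu_per_C: float  # a*b: mu = mu_per_C * (C - C_crit)
    x_scale: float  # r - r_fold = x_scale * x  (signed, = 1/b)
    time_scale: float  # hours per rescaled time unit

    def map_params(self, C: float, sigma: float) -> NormalFormParams:
        """Normal-form (mu, xi) for a given Cyclin D activity and noise."""
        return NormalFormParams(
            mu=self.mu_per_C * (C - self.C_crit),
            xi=abs(self.b) * sigma * self.r_fold,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def reduce_to_normal_form(params: RbParams = RbParams()) -> ReductionCoefficients:
    """Taylor-expand the switch drift at the upper fold.

    Raises when no fold exists or the fold is degenerate (quadratic
    coefficient numerically zero).
    """
    bif = find_bifurcation(params)
    if not bif.bistable:
        raise ValueError("no fold: the parameter set is not bistable")
    r_f, C_c = bif.r_fold_high, bif.C_crit_high
    a = drift_dC(r_f, C_c, params)
    h = 1e-5 * max(1.0, abs(r_f))
    b = 0.5 * (drift(r_f + h, C_c, params) - 2.0 * drift(r_f, C_c, params) + drift(r_f - h, C_c, params)) / h**2
    if abs(b) < 1e-8:
        raise ValueError("degenerate fold: quadratic coefficient vanishes")
    return ReductionCoefficients(
        C_crit=C_c,
        r_fold=r_f,
        a=float(a),
        b=float(b),
        mu_per_C=float(a * b),
        x_scale=float(1.0 / b),
        time_scale=1.0,
    )


def predict_exit_time(
    params: RbParams,
    C: float,
    x_window: float = 5.0,
    red: ReductionCoefficients | None = None,
) -> float:
    """Semi-analytic mean G1 length: deterministic approach + fold delay.

    Splits the passage from r0 to r_thresh into a deterministic approach
    from r0 to the fold region (|x| <= x_window in normal-form
    coordinates), the Airy mean delay through the fold, and the
    deterministic tail down to r_thresh.  The Airy formula integrates the
    full line, so the deterministic time already spent outside the window
    (about 2/x_window rescaled units) is subtracted.
    """
    red = reduce_to_normal_form(params) if red is None else red
    width = abs(red.x_scale) * x_window
    r_up = red.r_fold + width
    r_low = max(red.r_fold - width, params.r_thresh)

    nf = red.map_params(C, params.sigma)
    t_fold = mfpt_exact(nf.mu, nf.xi) - 2.0 / x_window

    from scipy.integrate import solve_ivp

    def segment(r_from: float, r_to: float) -> float:
        if r_from <= r_to:
            return 0.0
        event = lambda t, y: y[0] - r_to
        event.terminal = True
        event.direction = -1
        sol = solve_ivp(
            lambda t, y: [drift(y[0], C, params)],
            [0.0, 1e4],
            [r_from],
            events=event,
            rtol=1e-8,
            atol=1e-10,
        )
        if len(sol.t_events[0]) == 0:
            raise RuntimeError("deterministic segment did not reach its target level")
        return float(sol.t_events[0][0])

    return segment(params.r0, r_up) + t_fold + segment(r_low, params.r_thresh)
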