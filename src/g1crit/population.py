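"""Agent-based stem-cell population control coupled to the G1-S switch.

Each cell runs its own copy of the stochastic Rb switch; the Cyclin D
activity it experiences is set by a population feedback C = f(N) (or
C = f(alpha_i N) for mis-sensing mutants, or C = f(D) when feedback is
routed through the differentiated pool).  A cell divides when its Rb
level first drops below r_thresh, plus a slow baseline division at rate
1/T_baseline.  Fate follows a competing-risks rule between the division
clock and a stochastic differentiation commitment timer (mean tau_d):

* RD topology ("Renewal precedes Differentiation"): dividing before the
  commitment timer fires means self-renewal; a cell whose timer fires
  first differentiates.  Paired with feedback where more cells lengthen
  G1 (df/dN < 0), e.g. the hyperbolic C = C_crit N_st / N.
* DR topology ("Differentiation precedes Renewal"): the rule is
  inverted -- dividing young means differentiation, dividing after the
  timer means self-renewal.  Paired with df/dN > 0, e.g. the linear
  C = C_crit N / N_st.

The continuous description dN/dt = N theta(T)/T with the net bias
theta(T) = 2 P_R(T) - 1 places the set point at N_s = f^{-1}(C_crit) and
is stable iff sign(d theta/dT) = sign(df/dN).  Because every extended
steady-state G1 length requires C ~ C_crit, the feedback self-tunes the
population to the vicinity of the fold.

The analytical layer (theta_of_T, growth_rate, stability_check,
predicted_set_point) and the simulation layer (step_population,
run_homeostasis, run_mutation_experiment, run_two_compartment) live side
by side so tests can cross-check one against the other.
"""

from __future__ import annotations

import math
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .rb_switch import RbParams, gamma_P

logger = logging.getLogger(__name__)

__all__ = [
    "CellRecord",
    "FeedbackSpec",
    "TopologySpec",
    "MutationSpec",
    "PopulationParams",
    "PopulationState",
    "PopulationTrace",
    "feedback_C",
    "assign_fate",
    "renewal_probability",
    "theta_of_T",
    "growth_rate",
    "stability_check",
    "predicted_set_point",
    "step_population",
    "run_homeostasis",
    "run_mutation_experiment",
    "run_two_compartment",
]

#: reference critical Cyclin D value (the upper fold of the default switch)
DEFAULT_C_CRIT = 0.35


@dataclass(frozen=True)
class FeedbackSpec:
    """Population feedback C = f(.) and its parameters.

    Variants:

    * ``hyperbolic_RD``: C = C_crit * N_st / N_eff  (df/dN < 0)
    * ``linear_DR``:     C = C_crit * N_eff / N_st  (df/dN > 0)
    * ``ligand_mitogen``: quasi-steady-state secreted mitogen,
      C = mitogen_gain * ligand_production / (k_deg * N_eff); identical in
      shape to ``hyperbolic_RD``
    * ``ligand_inhibitor``: quasi-steady-state secreted inhibitor,
      C = inhibitor_gain * k_deg * N_eff / ligand_production; identical in
      shape to ``linear_DR``
    * ``differentiated_pool``: ligand secreted by the differentiated
      compartment; ``ligand_action="inhibitor"`` (default) gives
      C = C_crit * D_ref / D (pairs stably with RD),
      ``ligand_action="mitogen"`` gives C = C_crit * D / D_ref (the
      pairing selected by the quasi-static sign criterion with DR, but
      Hopf-unstable at criticality once the pool's relaxation is
      resolved -- see the methods note)

    ``N_eff`` is the population size as perceived by the cell,
    ``alpha_i * N``.
    """

    variant: str = "hyperbolic_RD"
    C_crit: float = DEFAULT_C_CRIT
    N_st: float = 100.0
    mitogen_gain: float = 1.0
    inhibitor_gain: float = 1.0
    ligand_production: float = 1.0
    k_deg: float = 1.0
    differentiated_production: float = 1.0
    differentiated_removal: float = 0.05  # gamma, 1/hour
    ligand_action: str = "inhibitor"  # differentiated_pool only
    D_ref: float | None = None

    _VARIANTS = (
        "hyperbolic_RD",
        "linear_DR",
        "ligand_mitogen",
        "ligand_inhibitor",
        "differentiated_pool",
    )

    def __post_init__(self) -> None:
        if self.variant not in self._VARIANTS:
            raise ValueError(f"unknown feedback variant {self.variant!r}")
        if self.ligand_action not in ("inhibitor", "mitogen"):
            raise ValueError("ligand_action must be 'inhibitor' or 'mitogen'")
        for name in (
            "C_crit",
            "N_st",
            "mitogen_gain",
            "inhibitor_gain",
            "ligand_production",
            "k_deg",
            "differentiated_production",
            "differentiated_removal",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"FeedbackSpec.{name} must be strictly positive")

    def default_D_ref(self, tau_d: float = 20.0) -> float:
        """D value at which C = C_crit for the differentiated-pool variant.

        Chosen so the steady-state identity N_s / T_s = gamma * D_s places
        the stem-cell set point at N_st, with T_s = tau_d ln 2 (the zero of
        theta for the exponential timer).
        """
        if self.D_ref is not None:
            return self.D_ref
        T_s = tau_d * math.log(2.0)
        return self.N_st / (self.differentiated_removal * T_s)


@dataclass(frozen=True)
class TopologySpec:
    """Fate topology and commitment-timer law.

    ``fate_timing`` selects when an RD differentiation is executed:
    ``"race"`` (default) removes the cell the moment its commitment clock
    fires if it has not divided by then -- the plain competing-risks
    reading, required for recovery from above the set point; with
    ``"at_division"`` the check happens only when a division fires.  DR
    fate is always decided at division (a fired timer merely marks the
    cell renewal-destined).  The renewal probability P_R(T), and hence
    theta(T), is identical under both timings.
    """

    kind: str = "RD"
    timer_mean: float = 20.0  # tau_d, hours
    timer_distribution: str = "exponential"  # exponential | deterministic | gamma
    timer_shape: float = 2.0  # shape k of the gamma alternative
    fate_timing: str = "race"

    def __post_init__(self) -> None:
        if self.kind not in ("RD", "DR"):
            raise ValueError("topology kind must be 'RD' or 'DR'")
        if self.timer_mean <= 0:
            raise ValueError("timer_mean must be strictly positive")
        if self.timer_distribution not in ("exponential", "deterministic", "gamma"):
            raise ValueError(f"unknown timer distribution {self.timer_distribution!r}")
        if self.fate_timing not in ("race", "at_division"):
            raise ValueError("fate_timing must be 'race' or 'at_division'")

    def draw_timers(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.timer_distribution == "exponential":
            return rng.exponential(self.timer_mean, n)
        if self.timer_distribution == "deterministic":
            return np.full(n, self.timer_mean)
        k = self.timer_shape
        return rng.gamma(k, self.timer_mean / k, n)

    def timer_survival(self, T) -> np.ndarray | float:
        """P(commitment timer > T)."""
        T = np.asarray(T, dtype=float)
        if self.timer_distribution == "exponential":
            out = np.exp(-T / self.timer_mean)
        elif self.timer_distribution == "deterministic":
            out = (T < self.timer_mean).astype(float)
        else:
            from scipy.stats import gamma as gamma_dist

            k = self.timer_shape
            out = gamma_dist.sf(T, k, scale=self.timer_mean / k)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class MutationSpec:
    """Mis-sensing mutation model for the sensitivity alpha_i."""

    enabled: bool = False
    p_m: float = 0.001
    sigma_mut: float = 0.5
    alpha_min: float = 0.03

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_m <= 1.0:
            raise ValueError("p_m must lie in [0, 1]")
        if self.sigma_mut < 0:
            raise ValueError("sigma_mut must be non-negative")
        if not self.alpha_min > 0:
            raise ValueError("alpha_min must be strictly positive")


@dataclass(frozen=True)
class PopulationParams:
    """Full configuration of one homeostasis run."""

    rb: RbParams = field(default_factory=RbParams)
    feedback: FeedbackSpec = field(default_factory=FeedbackSpec)
    topology: TopologySpec = field(default_factory=TopologySpec)
    mutation: MutationSpec = field(default_factory=MutationSpec)
    dt: float = 0.1
    T_baseline: float = 720.0
    t_max: float = 5000.0
    capacity: int | None = None  # default 10 * N_st, grown on demand
    on_overflow: str = "grow"  # grow | error
    N0: int = 100
    seed: int | None = None
    record_every: int = 1  # steps between trace records

    def __post_init__(self) -> None:
        if self.N0 < 1:
            raise ValueError("N0 must be at least 1")
        if self.capacity is not None and self.capacity < self.N0:
            raise ValueError("capacity must be at least N0")
        if self.on_overflow not in ("grow", "error"):
            raise ValueError("on_overflow must be 'grow' or 'error'")


@dataclass
class CellRecord:
    """One agent, as a plain record (the simulator stores arrays)."""

    active: bool
    age: float
    r: float
    commitment_time: float
    alpha: float = 1.0
    clone_id: int = 0


class PopulationState:
    """Structure-of-arrays storage for the agent population.

    Fixed-capacity arrays with free-slot reuse; capacity grows (or the run
    fails loudly) when exhausted, never silently truncates.
    """

    def __init__(self, params: PopulationParams, rng: np.random.Generator):
        cap = params.capacity or max(10 * int(params.feedback.N_st), params.N0 + 32)
        self.active = np.zeros(cap, dtype=bool)
        self.age = np.zeros(cap)
        self.r = np.full(cap, params.rb.r0)
        self.commitment = params.topology.draw_timers(cap, rng)
        self.alpha = np.ones(cap)
        self.clone_id = np.zeros(cap, dtype=np.int64)
        self.active[: params.N0] = True
        # differentiated pool (two-compartment runs): start at the pool size
        # consistent with N0 via the steady-state identity N/T_s = gamma*D
        if params.feedback.variant == "differentiated_pool":
            T_s = params.topology.timer_mean * math.log(2.0)
            self.D = params.N0 / (params.feedback.differentiated_removal * T_s)
        else:
            self.D = 0.0
        self.t = 0.0
        self.next_clone = 1
        # per-step event counters, reset by the caller
        self.renewals = 0
        self.differentiations = 0
        # completed-cycle bookkeeping (age at renewal/differentiation)
        self.cycle_age_sum = 0.0
        self.cycle_count = 0

    @property
    def N(self) -> int:
        return int(self.active.sum())

    def _grow(self, extra: int, on_overflow: str) -> None:
        if on_overflow == "error":
            raise RuntimeError("population capacity exhausted")
        old = self.active.size
        new = old + max(extra, old)
        for name in ("age", "r", "alpha"):
            arr = getattr(self, name)
            grown = np.zeros(new, dtype=arr.dtype)
            grown[:old] = arr
            setattr(self, name, grown)
        grown = np.zeros(new, dtype=bool)
        grown[:old] = self.active
        self.active = grown
        grown = np.zeros(new, dtype=np.int64)
        grown[:old] = self.clone_id
        self.clone_id = grown
        grown = np.zeros(new)
        grown[:old] = self.commitment
        self.commitment = grown
        logger.info("population capacity grown to %d", new)


@dataclass
class PopulationTrace:
    """Recorded time series of one run."""

    times: np.ndarray
    N: np.ndarray
    mean_alpha: np.ndarray
    division_events: np.ndarray
    differentiation_events: np.ndarray
    mean_C: np.ndarray
    D: np.ndarray
    cycle_age_sum: np.ndarray | None = None
    cycle_count: np.ndarray | None = None
    extinct: bool = False
    extinction_time: float = float("nan")

    def mean_cycle_length(self) -> float:
        """Mean completed-cycle duration over the second half of the run.

        Each completed cycle (renewal or differentiation) contributes its
        cell's age at the event.
        """
        if self.cycle_age_sum is None or self.cycle_count is None:
            return float("nan")
        half = len(self.cycle_count) // 2
        total = self.cycle_count[half:].sum()
        return float(self.cycle_age_sum[half:].sum() / total) if total else float("nan")

    def long_run_mean_N(self) -> float:
        """Mean live-cell count over the second half of the run."""
        half = len(self.N) // 2
        return float(np.mean(self.N[half:]))

    def long_run_mean_C(self) -> float:
        half = len(self.mean_C) // 2
        vals = self.mean_C[half:]
        return float(np.nanmean(vals)) if np.any(~np.isnan(vals)) else float("nan")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_h": self.times,
                "N": self.N,
                "mean_alpha": self.mean_alpha,
                "divisions": self.division_events,
                "differentiations": self.differentiation_events,
                "mean_C": self.mean_C,
                "D": self.D,
            }
        )


# ---------------------------------------------------------------------------
# analytical layer


def feedback_C(N: float, spec: FeedbackSpec, alpha=1.0, D: float | None = None, tau_d: float = 20.0):
    """Control parameter perceived by a cell of sensitivity ``alpha``.

    Vectorized over ``alpha``.  ``N = 0`` falls back to the value for
    ``N = 1`` (extinction is handled by the simulation loop).
    """
    if N < 0:
        raise ValueError("N must be non-negative")
    if N == 0:
        logger.warning("feedback_C called with N=0; falling back to N=1")
        N = 1
    alpha = np.asarray(alpha, dtype=float)
    if spec.variant == "differentiated_pool":
        if D is None:
            raise ValueError("differentiated_pool feedback requires D")
        eff = np.maximum(alpha * D, 1e-9)
        D_ref = spec.default_D_ref(tau_d)
        if spec.ligand_action == "mitogen":
            out = spec.C_crit * eff / D_ref
        else:
            out = spec.C_crit * D_ref / eff
    else:
        eff = np.maximum(alpha * N, 1e-12)
        if spec.variant in ("hyperbolic_RD",):
            out = spec.C_crit * spec.N_st / eff
        elif spec.variant in ("linear_DR",):
            out = spec.C_crit * eff / spec.N_st
        elif spec.variant == "ligand_mitogen":
            out = spec.mitogen_gain * spec.ligand_production / (spec.k_deg * eff)
        else:  # ligand_inhibitor
            out = spec.inhibitor_gain * spec.k_deg * eff / spec.ligand_production
    out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def assign_fate(topology: TopologySpec, age_at_division: float, commitment_time: float) -> str:
    """Fate of a division event under the competing-risks rule.

    RD renews iff the cell divides strictly before its commitment time;
    DR is exactly inverted.  The tie ``age == commitment`` follows the
    ``age >= commitment`` branch.
    """
    if age_at_division < 0 or commitment_time < 0:
        raise ValueError("ages and commitment times must be non-negative")
    young = age_at_division < commitment_time
    renew = young if topology.kind == "RD" else not young
    return "renew" if renew else "differentiate"


def renewal_probability(topology: TopologySpec, T) -> np.ndarray | float:
    """P_R(T): probability a division at cycle length T self-renews."""
    surv = topology.timer_survival(T)
    return surv if topology.kind == "RD" else 1.0 - np.asarray(surv) if np.ndim(surv) else 1.0 - surv


def theta_of_T(topology: TopologySpec, T) -> np.ndarray | float:
    """Net self-renewal bias theta(T) = 2 P_R(T) - 1 in [-1, 1].

    For the RD topology with exponential timer, theta(T) =
    2 exp(-T/tau_d) - 1, crossing zero at T = tau_d ln 2.
    """
    if np.any(np.asarray(T) < 0):
        raise ValueError("T must be non-negative")
    p_r = topology.timer_survival(T)
    p_r = np.asarray(p_r, dtype=float)
    if topology.kind == "DR":
        p_r = 1.0 - p_r
    out = 2.0 * p_r - 1.0
    return out if out.ndim else float(out)


def growth_rate(T: float, theta: float) -> tuple[float, float]:
    """(exact, linearized) per-hour net growth of the population.

    Exact form (1/T) ln(1+theta) follows the discrete generation map
    N -> (1+theta) N; the linearized theta/T is the form used in the
    stability analysis.  Both vanish at theta = 0.
    """
    if T <= 0:
        raise ValueError("T must be strictly positive")
    if theta <= -1.0:
        raise ValueError("theta must exceed -1")
    return math.log1p(theta) / T, theta / T


def stability_check(dtheta_dT: float, df_dN: float) -> str:
    """Set-point stability from the signs of d(theta)/dT and df/dN.

    The feedback chain delta_theta = (d theta/dT)(d Phi/dC)(df/dN) delta_N
    with d Phi/dC < 0 (more mitogen shortens G1) is stabilizing iff the
    two remaining slopes share a sign.  Zero slopes are marginal.
    """
    if not (np.isfinite(dtheta_dT) and np.isfinite(df_dN)):
        raise ValueError("slopes must be finite")
    if dtheta_dT == 0.0 or df_dN == 0.0:
        return "marginal"
    return "stable" if (dtheta_dT > 0) == (df_dN > 0) else "unstable"


def predicted_set_point(spec: FeedbackSpec, C_crit: float | None = None) -> float:
    """Analytical set point N_s = f^{-1}(C_crit)."""
    C_crit = spec.C_crit if C_crit is None else C_crit
    if spec.variant == "hyperbolic_RD":
        return spec.N_st * spec.C_crit / C_crit
    if spec.variant == "linear_DR":
        return spec.N_st * C_crit / spec.C_crit
    if spec.variant == "ligand_mitogen":
        return spec.mitogen_gain * spec.ligand_production / (spec.k_deg * C_crit)
    if spec.variant == "ligand_inhibitor":
        return C_crit * spec.ligand_production / (spec.inhibitor_gain * spec.k_deg)
    raise ValueError(
        "differentiated_pool feedback has its set point on D, not N; "
        "use default_D_ref and the steady-state identity N_s/T_s = gamma D_s"
    )


# ---------------------------------------------------------------------------
# simulation layer


def step_population(state: PopulationState, params: PopulationParams, rng: np.random.Generator) -> PopulationState:
    """Advance the population by one time step dt (in place).

    Update order: feedback -> Rb Euler-Maruyama -> age -> (RD race:
    commitment exits) -> division check (threshold crossing or baseline)
    -> fate -> divisions executed (parent reset + daughter copy, daughter
    alpha possibly mutated).  Event counters accumulate on the state.
    """
    fb, topo, mut, rb = params.feedback, params.topology, params.mutation, params.rb
    dt = params.dt
    idx = np.flatnonzero(state.active)
    N = idx.size
    if N == 0:
        state.t += dt
        return state

    # 1. feedback: each cell perceives alpha_i * N (or the D pool)
    C = feedback_C(N, fb, alpha=state.alpha[idx], D=state.D, tau_d=topo.timer_mean)
    C = np.atleast_1d(np.asarray(C, dtype=float))

    # 2. Rb dynamics (Euler-Maruyama, Ito, clip at 0)
    r = state.r[idx]
    r = r + (1.0 - (rb.gamma_D + gamma_P(r, C, rb)) * r) * dt
    r = r + rb.sigma * state.r[idx] * math.sqrt(dt) * rng.standard_normal(N)
    r = np.maximum(r, 0.0)
    state.r[idx] = r

    # 3. ageing
    state.age[idx] += dt

    # 4a. RD race: a cell whose commitment clock has fired differentiates now
    if topo.kind == "RD" and topo.fate_timing == "race":
        lapsed = state.age[idx] >= state.commitment[idx]
        if lapsed.any():
            gone = idx[lapsed]
            state.active[gone] = False
            state.differentiations += gone.size
            state.D += 2.0 * gone.size
            state.cycle_age_sum += float(state.age[gone].sum())
            state.cycle_count += gone.size
            keep = ~lapsed
            idx, r, C = idx[keep], r[keep], C[keep]
            N = idx.size
            if N == 0:
                state.t += dt
                return state

    # 4b. division check: threshold crossing or slow baseline divisions
    marked = (r < rb.r_thresh) | (rng.random(N) < dt / params.T_baseline)
    div_idx = idx[marked]
    if div_idx.size:
        state.cycle_age_sum += float(state.age[div_idx].sum())
        state.cycle_count += div_idx.size
        young = state.age[div_idx] < state.commitment[div_idx]
        renew = young if topo.kind == "RD" else ~young

        # differentiating divisions: cell removed, two differentiated daughters
        diff_cells = div_idx[~renew]
        state.active[diff_cells] = False
        state.differentiations += diff_cells.size
        state.D += 2.0 * diff_cells.size

        # renewing divisions: reset parent, create daughter copy
        parents = div_idx[renew]
        n_new = parents.size
        if n_new:
            state.r[parents] = rb.r0
            state.age[parents] = 0.0
            state.commitment[parents] = topo.draw_timers(n_new, rng)
            free = np.flatnonzero(~state.active)
            if free.size < n_new:
                state._grow(n_new - free.size, params.on_overflow)
                free = np.flatnonzero(~state.active)
            slots = free[:n_new]
            state.active[slots] = True
            state.r[slots] = rb.r0
            state.age[slots] = 0.0
            state.commitment[slots] = topo.draw_timers(n_new, rng)
            alpha_d = state.alpha[parents].copy()
            clone_d = state.clone_id[parents].copy()
            if mut.enabled and mut.p_m > 0:
                hit = rng.random(n_new) < mut.p_m
                n_hit = int(hit.sum())
                if n_hit:
                    factor = rng.lognormal(0.0, mut.sigma_mut, n_hit)
                    alpha_d[hit] = np.maximum(alpha_d[hit] * factor, mut.alpha_min)
                    clone_d[hit] = state.next_clone + np.arange(n_hit)
                    state.next_clone += n_hit
            state.alpha[slots] = alpha_d
            state.clone_id[slots] = clone_d
            state.renewals += n_new

    # differentiated pool decay (no-op unless a two-compartment run feeds it)
    state.D += -fb.differentiated_removal * state.D * dt
    state.t += dt
    state._last_mean_C = float(np.mean(C)) if N else float("nan")
    return state


def _run(params: PopulationParams) -> tuple[PopulationTrace, PopulationState]:
    rng = np.random.default_rng(params.seed)
    state = PopulationState(params, rng)
    n_steps = int(round(params.t_max / params.dt))
    every = max(params.record_every, 1)
    n_rec = n_steps // every
    times = np.empty(n_rec)
    Ns = np.empty(n_rec, dtype=np.int64)
    mean_alpha = np.empty(n_rec)
    renew_ev = np.zeros(n_rec, dtype=np.int64)
    diff_ev = np.zeros(n_rec, dtype=np.int64)
    mean_C = np.full(n_rec, np.nan)
    D_rec = np.zeros(n_rec)
    cyc_sum = np.zeros(n_rec)
    cyc_cnt = np.zeros(n_rec, dtype=np.int64)

    extinct = False
    extinction_time = float("nan")
    k = 0
    for i in range(n_steps):
        step_population(state, params, rng)
        if (i + 1) % every == 0:
            idx = np.flatnonzero(state.active)
            times[k] = state.t
            Ns[k] = idx.size
            mean_alpha[k] = float(state.alpha[idx].mean()) if idx.size else float("nan")
            renew_ev[k] = state.renewals
            diff_ev[k] = state.differentiations
            state.renewals = 0
            state.differentiations = 0
            cyc_sum[k] = state.cycle_age_sum
            cyc_cnt[k] = state.cycle_count
            state.cycle_age_sum = 0.0
            state.cycle_count = 0
            mean_C[k] = getattr(state, "_last_mean_C", float("nan"))
            D_rec[k] = state.D
            k += 1
        if state.N == 0 and not extinct:
            extinct = True
            extinction_time = state.t
            # record the tail as zeros and stop integrating
            while k < n_rec:
                times[k] = times[k - 1] + every * params.dt if k else state.t
                Ns[k] = 0
                mean_alpha[k] = float("nan")
                mean_C[k] = float("nan")
                D_rec[k] = state.D
                k += 1
            break
    trace = PopulationTrace(
        times=times,
        N=Ns,
        mean_alpha=mean_alpha,
        division_events=renew_ev + diff_ev,
        differentiation_events=diff_ev,
        mean_C=mean_C,
        D=D_rec,
        cycle_age_sum=cyc_sum,
        cycle_count=cyc_cnt,
        extinct=extinct,
        extinction_time=extinction_time,
    )
    return trace, state


def run_homeostasis(params: PopulationParams) -> PopulationTrace:
    """Full homeostasis run; the long-run mean N is read off the trace.

    Extinction does not raise: the trace is returned with
    ``extinct=True`` and the extinction time flagged.
    """
    trace, _ = _run(params)
    return trace


@dataclass
class CloneSummary:
    """End-state summary of a mutation run."""

    final_N: int
    final_mean_alpha: float
    clone_sizes: dict
    clone_alphas: dict


def run_mutation_experiment(params: PopulationParams) -> tuple[PopulationTrace, CloneSummary]:
    """Mutation-invasion run: track N(t), mean alpha(t), clone structure.

    Requires ``params.mutation.enabled`` with p_m > 0.  Under both
    topologies the population drifts towards under-sensing mutants
    (alpha < 1) whose private set point is higher; the DR topology resists
    longer because its invaders carry long cycle times.
    """
    if not (params.mutation.enabled and params.mutation.p_m > 0):
        raise ValueError("mutation experiment requires mutation.enabled and p_m > 0")
    trace, state = _run(params)
    idx = np.flatnonzero(state.active)
    clones, counts = np.unique(state.clone_id[idx], return_counts=True)
    clone_alphas = {int(c): float(state.alpha[idx][state.clone_id[idx] == c].mean()) for c in clones}
    summary = CloneSummary(
        final_N=idx.size,
        final_mean_alpha=float(state.alpha[idx].mean()) if idx.size else float("nan"),
        clone_sizes={int(c): int(n) for c, n in zip(clones, counts)},
        clone_alphas=clone_alphas,
    )
    return trace, summary


def run_two_compartment(params: PopulationParams) -> PopulationTrace:
    """Two-compartment run: feedback read from the differentiated pool D.

    Every division adds its differentiated output to D (two cells for a
    differentiating division, none for a renewal) and D decays at rate
    gamma; at steady state N_s / T_s = gamma * D_s.  The mitogen-from-D
    feedback has df/dN > 0 along the chain and therefore requires the DR
    fate rule for stability.
    """
    if params.feedback.variant != "differentiated_pool":
        raise ValueError("run_two_compartment requires the differentiated_pool feedback")
    if params.feedback.differentiated_removal <= 0:
        raise ValueError("differentiated_removal (gamma) must be strictly positive")
    trace, _ = _run(params)
    return trace
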