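# Methods

## The single-cell switch

Active (unphosphorylated) Rb, `r`, is produced at a constant rate
(scaled to 1) and removed by degradation (rate `gamma_D`) and
phosphorylation:

    dr = (1 - (gamma_D + gamma_P(r, C)) r) dt + sigma r dW,
    gamma_P(r, C) = V * C/(1 + C/k1) * 1/(1 + (r/k2)^2).

Cyclin D activity `C` drives phosphorylation with saturation scale
`k1`; the Hill-2 suppression in `r` is a minimal phenomenological stand-in
for the cooperative E2F/CycE positive feedback, and any bistable model
with a fold would serve. The noise is multiplicative Ito noise of
amplitude `sigma*r`; its precise form is immaterial near the fold, where
only the local noise amplitude enters.

Reference parameters (used everywhere unless a test says otherwise):
`gamma_D = 1 /h`, `V = 100 /h`, `k1 = 1`, `k2 = 0.1`, `sigma = 0.3
/sqrt(h)`, birth level `r0 = 4`, G1/S exit threshold `r_thresh = 0.05`.
With these the deterministic part is bistable for `C` in (0.218, 0.352):
the G1 state (high `r`) annihilates at the upper fold `C_crit = 0.352`
(printed as 0.35 at two decimals). G1 length is the first-passage time
from `r0` to below `r_thresh`.

Numerical choices:

* Fixed points come from the expanded cubic (a companion-matrix root
  solve), stability from the analytic `d(drift)/dr`; eigenvalues within
  1e-10 of zero are reported as marginal.
* Folds are bracketed by bisection on the root count (tolerance 1e-6 in
  `C`) and polished by solving `drift = 0`, `d(drift)/dr = 0`
  simultaneously.
* SDE paths use Euler-Maruyama with post-step clipping `r <- max(r, 0)`
  (the exact dynamics keep `r > 0`, but a discrete step can undershoot);
  exit is the first sample strictly below `r_thresh`, with no sub-step
  interpolation. The O(dt) bias this leaves is covered by a
  dt-halving convergence test. Default steps: 0.05 h for single-cell
  ensembles and ghost runs, 0.1 h for population runs.

## Normal form and first-passage theory

Near the fold the dynamics reduce to `dx = (x^2 + mu) dt + xi dW`. The
local expansion at `(r_fold, C_crit)` gives `drift ~ a (C - C_crit) +
b (r - r_fold)^2` with both coefficients negative for this fold
orientation; the substitution `x = b (r - r_fold)` (time kept in hours)
yields `mu = a*b*(C - C_crit)` and `xi = |b| sigma r_fold`. At the
reference parameters `a = -1.096`, `b = -1.821`, so `mu = 1.995 (C -
C_crit)` and `xi = 0.261` at `sigma = 0.3`. These proportionality
constants are not universal; they are recomputed from the expansion and
reported with results.

The mean transition time has the exact closed form

    T(mu, xi) = 2^{1/3} pi^2 xi^{-2/3} (Ai^2[z] + Bi^2[z]),
    z = -2^{2/3} xi^{-4/3} mu,

evaluated directly for `z <= 8` and via scipy's exponentially scaled
Airy functions beyond (this is exact, not asymptotic; a continuity test
covers the switch-over). For `mu < 0` the Kramers escape form
`(pi/sqrt|mu|) exp((8/3)|mu|^{3/2}/xi^2)` follows from the double-well
potential `U(x) = -x^3/3 - mu x` with barrier `(4/3)|mu|^{3/2}`; the
prefactor is the standard double-well one. Regressing `log log T`
against `log|mu|` in the deep-barrier regime returns the super-exponential
scaling exponent 3/2.

Monte-Carlo first-passage runs start at `x0 = -max(3, 3 sqrt|mu|)` and
absorb at the mirror point; comparisons against the exact formula in
tests widen the boundaries to +-12 so that the truncated deterministic
tail time (about 2/|boundary|) is far below the Monte-Carlo error. Paths
exceeding 50x the predicted mean are reported as censored, never
dropped. The semi-analytic predictor for the full switch (deterministic
approach from `r0` to the fold region, plus the Airy delay, plus the
deterministic tail to `r_thresh`, minus the double-counted window edges)
is an asymptotic weak-noise statement: it matches simulated ensembles
within Monte-Carlo error at `sigma <= 0.05` but over-predicts by ~5-20%
at the reference `sigma = 0.3`, where fluctuations explore the region
in which the quadratic expansion has already degraded.

## Ghost-state analysis

Just past the fold (per-cell `C ~ Normal(C_crit + 0.008, 0.004^2)`,
50,000 cells, 100 h horizon, dt = 0.05 h) trajectories linger in the
remnant of the annihilated fixed points. On the activity scale
`a = 1 - tanh(r)` we record first crossings of three thresholds: active
(0.4), high (0.7) and S entry (`1 - tanh(r_thresh)`). The entry phase
(active to high) is long, variable and heavy-tailed; the final rise
(high to S) is fast and stereotyped. Trajectory averages are computed
after aligning each path to its S-entry time and binning by total G1
length (default bins: quartiles, since no canonical edges exist);
interpolation is linear on the activity scale. The inhibitory
perturbation (C dropped by 0.1 at 15 h from `C = C_crit`, 100 cells,
80 h) labels cells "proceeds" (S entry after the drop) or "reverts" (no
S entry, activity > 0.5 just before the drop, mean activity < 0.4 over
the final 5 h — the averaging window is our choice; the classification
rule does not fix it).

## Population control

Each agent carries age, its own `r`, a commitment timer drawn at birth
(exponential, mean `tau_d = 20 h` — the minimal memoryless choice;
deterministic and gamma timers are selectable) and a sensing factor
`alpha` (1 unless mutated). Per step (dt = 0.1 h): count `N`; each cell
perceives `C = f(alpha_i N)`; Euler-Maruyama update of `r`; ageing;
division when `r < r_thresh`, plus a baseline division with probability
`dt/T_baseline` (`T_baseline = 720 h`); fate by competing risks;
renewal resets the parent (age 0, `r = r0`, fresh timer) and copies a
daughter into a free slot (capacity defaults to 10 N_st and either
grows or fails loudly); differentiation removes the cell. Extinction
ends the run flagged, with no respawn.

Fate timing. The competing-risks rule races the division clock against
the commitment timer. In the RD topology the default semantics remove a
cell the moment its commitment clock fires if it has not divided by
then; a variant that defers the check to the next division
(`fate_timing="at_division"`) is provided, and the renewal probability
`P_R(T) = exp(-T/tau_d)` — hence `theta(T) = 2 P_R(T) - 1` and the set
point — is identical under both. The timings differ dynamically: under
the deferred check, an RD population started well above its set point
ages past every commitment timer while feedback holds `C` sub-critical,
so once `C` recrosses the fold every division differentiates and the
population deterministically extinguishes. The race semantics recover
from above robustly, which is the behaviour the framework requires of
the RD loop; the deferred variant is kept because its collapse is
itself informative (and tested). DR fate is always decided at division:
a fired timer merely marks the cell renewal-destined.

Feedback variants: hyperbolic `C = C_crit N_st/N` (df/dN < 0, pairs
with RD), linear `C = C_crit N/N_st` (df/dN > 0, pairs with DR), and
their mechanistic ligand equivalents at quasi-steady state (secreted
mitogen consumed per-capita; secreted inhibitor). Ligand dynamics are
not integrated explicitly: the timescale separation that justifies the
quasi-steady state is assumed, as a slow ligand would add exactly the
kind of loop delay analysed next. Stability of a set point requires
`sign(d theta/dT) = sign(df/dN)`; both default pairings satisfy it, and
the population self-tunes so that the time-averaged `C` sits within
about 0.02 of the fold — homeostasis at criticality.

Mutations: at each renewal the daughter's `alpha` is, with probability
`p_m = 0.001`, multiplied by a log-normal draw (median 1, log-sd
`sigma_mut = 0.5`) and clipped below at `alpha_min = 0.03`; the parent
keeps its value. A mutant uses its own `alpha` against the global `N`
(it mis-senses; it does not distort others' signal). Under-sensing
mutants (`alpha < 1`) have a higher private set point and invade in
both topologies; in RD their shortened G1 makes the sweep fast, in DR
their lengthened G1 slows it by orders of magnitude. Mutation-run
horizons are not externally fixed; 7000 h was chosen by convergence
diagnostics (RD sweeps complete well before it, DR sweeps are partial,
preserving the contrast).

## Two-compartment feedback

With the differentiated pool `D` fed by each differentiating division
(two cells) and cleared at rate `gamma` (default 0.05 /h; `D` then
relaxes over ~20 h), steady state implies `N_s/T_s = gamma D_s`. The
pool-mediated feedback deserves care that the quasi-static sign rule
does not provide. Writing `s = Phi'(C) f'(D)` for the loop slope,
linearization of `(N, D)` about the steady state gives determinant
`-(N_s/T_s^2) theta'(T_s) s` and trace `-(N_s/T_s)(theta'(T_s) +
1/T_s) s - gamma`. A mitogen pool (`f' > 0`, `s < 0`) with DR
(`theta' > 0`) has positive determinant but trace proportional to
`-Phi'(C_s) C_crit (theta' + 1/T_s) - 1` (gamma cancels from the sign):
at criticality `|Phi'|` is enormous, the trace is positive, and the
pairing is Hopf-unstable for every `gamma` — the agent model shows the
corresponding relaxation oscillations. An inhibitor pool (`f' < 0`,
`s > 0`) with RD is stable unconditionally, because the differentiation
influx `(1 - theta)N/T` responds to `C` with the opposite sign to
`theta`. The package therefore defaults `ligand_action="inhibitor"`
with RD for quantitative two-compartment runs (the steady-state
identity holds to within a few percent, with `T_s` measured as the mean
age at cycle completion), and exposes the mitogen pairing, whose
instability is itself under test. For the same reason the large-gamma
limit does not reduce to direct-N feedback: the pool tracks the
differentiation flux `(1-theta)N/T`, not `N`, and the difference is
exactly the destabilizing term. `D_ref` (the pool size at which the
feedback returns `C_crit`) is calibrated from `N_st` via the identity
with the nominal `T_s = tau_d ln 2`; because the realized mean cycle
length under the race semantics is shorter, the run settles somewhat
below the nominal `N_st`, which the tests account for by checking the
identity rather than the nominal target.

## Condition-level analysis and synthetic data

Culture conditions map to mean Cyclin D activities; per-cell variation
enters as `C ~ Normal(C_m, 0.05^2)` clipped at 0 and held constant
through G1. The four reference conditions are mTeSR1 (`C_m = 0.5`,
n = 114), E8+IWP2 (0.6, 105), E8 (0.7, 112) and mTeSR1+Wnt (1.5, 104).
When only relative Wnt activities are available, the linear calibration
places the fold at 3/4 of the minimal observed activity; the explicit
per-condition values above override that mapping. Cells not exiting by
100 h are censored: excluded from moments, counted in the summary (how
non-exiting cells entered the original box plots is not recorded, so
exclusion-with-count is our documented convention). Quartiles use
linear interpolation between order statistics; whiskers extend to the
farthest point within 1.5 IQR — whisker placement depends on the
quantile convention, hence it is fixed here.

Model-vs-baseline scoring: `R^2 = 1 - SS_res/SS_tot` across conditions,
unweighted, separately for means and variances; the baseline is an OLS
regression of the observed statistic on Wnt activity. With only four
conditions, R^2 on variances is dominated by the sampling noise of the
variance of ~110 heavy-tailed values, and the two-parameter baseline
partially absorbs that noise; the model-beats-baseline comparison is
therefore sharp for means and noisy for variances (about an 80% win
probability per replicate at these sample sizes).

The synthetic generator reuses the exact forward model (no shortcut
sampler), so parameter recovery is a pure inverse problem. Recovery
matches observed (mean, log-variance) pairs against a simulated
reference grid in `C_m` (step 0.01, `C_s` assumed known at 0.05);
identifiability is sharp near the fold, where the summaries move
steeply, and degrades far above it, where flat objective profiles are
flagged rather than hidden. Optional Gaussian measurement noise
(default 0, matching the modelled experiment) exists for robustness
studies. What passing recovery shows is internal consistency of the
inference under the model's own assumptions — constant per-cell `C`,
normal condition spread, no measurement error — not that real imaging
data would be as well behaved.

## Reproducibility

Every stochastic routine takes a seed or numpy Generator; experiment
helpers derive sub-seeds with `SeedSequence.spawn`. The simulators are
vectorized over cells/paths with a single generator per run, so results
do not depend on any per-cell iteration order. Every CLI/config run
writes a manifest (resolved parameters, seed, versions, output
checksums) from which it can be reproduced bit-identically. Hours are
the universal time unit; output columns carry unit suffixes.

## Known limitations

* No spatial structure, no asymmetric divisions, no explicit ligand
  ODEs, no mechanistic multi-variable CycE/E2F model, and no
  parameter inference for the switch itself.
* The normal-form mapping is quantitative only for weak noise; at the
  reference noise it is a ~10% semi-analytic guide.
* The two-compartment mitogen/DR pairing is unstable at criticality
  (see above); only the inhibitor/RD pairing is quantitatively
  homeostatic here.
* Sample-variance-based R^2 comparisons at n ~ 100 per condition are
  intrinsically noisy; means are the reliable axis.
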