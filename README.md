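# g1crit

Cell-cycle criticality at the G1-S transition: a stochastic Rb/E2F
switch driven through a saddle-node bifurcation, the fold's
first-passage theory, and an agent-based stem-cell population simulator
in which competition feedback self-tunes the tissue to the critical
point.

## Who this is for

Systems biologists and modellers studying how G1 length is set and used:
why G1 duration diverges (and becomes wildly variable) near a mitogen
threshold, how a "ghost" intermediate Rb/E2F state arises from critical
slowing down, and how coupling cell-cycle length to fate choice gives a
self-organized homeostatic set point for stem-cell pools — with opposite
design trade-offs for the two possible feedback topologies.

## The model

Active Rb `r` follows the Ito SDE

    dr = (1 − (γ_D + γ_P(r, C)) r) dt + σ r dW,
    γ_P(r, C) = V · C/(1 + C/k₁) · 1/(1 + (r/k₂)²),

where `C` is Cyclin D activity. At the reference parameters
(γ_D = 1/h, V = 100/h, k₁ = 1, k₂ = 0.1, σ = 0.3) the G1 state
annihilates at the fold `C_crit ≈ 0.35`; G1 length is the first passage
from `r₀ = 4` to `r < 0.05`. Near the fold the dynamics reduce to the
normal form `dx = (x² + μ)dt + ξ dW` with `μ ∝ C − C_crit`, whose mean
delay is exactly

    T(μ, ξ) = 2^{1/3} π² ξ^{−2/3} (Ai²[−2^{2/3} ξ^{−4/3} μ] + Bi²[·]),

giving the super-exponential sensitivity `log T ~ |μ|^{3/2}` for μ < 0
(Kramers regime). The population layer couples division (first passage)
to fate via competing risks against a commitment timer
(θ(T) = 2e^{−T/τ_d} − 1 for the RD topology) and a feedback `C = f(N)`;
the set point `N_s = f⁻¹(C_crit)` is stable iff
sign(∂θ/∂T) = sign(∂f/∂N). See `docs/methods.md` for the full account.

## Worked example

```python
from g1crit import (RbParams, find_bifurcation, reduce_to_normal_form,
                    mfpt_exact, run_homeostasis)
from g1crit.population import PopulationParams, FeedbackSpec, TopologySpec

rb = RbParams()
bif = find_bifurcation(rb)
print(f"folds: C_low={bif.C_crit_low:.4f} C_high={bif.C_crit_high:.4f} "
      f"r_fold={bif.r_fold_high:.4f}")

red = reduce_to_normal_form(rb)
nf = red.map_params(bif.C_crit_high + 0.005, rb.sigma)
print(f"mapped (mu, xi) = ({nf.mu:.4f}, {nf.xi:.3f}); "
      f"mean fold delay = {mfpt_exact(nf.mu, nf.xi):.1f} h")

trace = run_homeostasis(PopulationParams(
    feedback=FeedbackSpec(variant="hyperbolic_RD", N_st=100),
    topology=TopologySpec(kind="RD"),
    N0=10, t_max=5000.0, seed=42, record_every=10))
print(f"long-run N = {trace.long_run_mean_N():.1f}, "
      f"mean C = {trace.long_run_mean_C():.3f}")
```

prints

```
folds: C_low=0.2176 C_high=0.3521 r_fold=0.4781
mapped (mu, xi) = (0.0100, 0.261); mean fold delay = 14.4 h
long-run N = 105.1, mean C = 0.334
```

The fold sits at `C ≈ 0.35`; a cell held 0.005 above it waits ~14 h in
the ghost region before committing; and a ten-cell seed population grows
to and holds the 100-cell set point, with the time-averaged Cyclin D
signal parked just below the critical value — the population has tuned
itself to the bifurcation.

A CLI mirrors the library (`g1crit bifurcation`, `mfpt`, `scaling`,
`homeostasis`, `mutation`, `two-compartment`, `ghost`, `wntfit`,
`synth`, or `g1crit run config.yaml`); every run writes its outputs plus
a manifest with the resolved parameters, seed and checksums.

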