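"""Configuration, stage dispatch, seeding and run manifests.

Every figure-level experiment is a small YAML (or JSON) config naming a
stage and its parameter block.  ``run_stage`` validates the config,
executes the stage with the global seed, writes tabular outputs, and
drops a ``manifest.json`` recording the fully resolved configuration,
seed, package versions and SHA-256 checksums of every output -- so a run
can be reproduced bit-identically from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .rb_switch import RbParams, find_bifurcation
from .normal_form import mfpt_exact, mfpt_kramers, mfpt_empirical, scaling_exponent, log_mfpt_exact, log_mfpt_kramers
from .population import (
    FeedbackSpec,
    MutationSpec,
    PopulationParams,
    TopologySpec,
    run_homeostasis,
    run_mutation_experiment,
    run_two_compartment,
)
from .ghost import GhostEnsembleParams, ThresholdSpec, perturbation_experiment, run_ghost_ensemble
from .synthetic_data import GeneratorConfig, generate_dataset
from .wnt_fit import DEFAULT_CONDITIONS, ConditionSpec, fit_r2, simulate_condition, summarize_condition

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "load_config", "run_stage", "STAGES"]


class ConfigError(ValueError):
    """A config that fails schema validation, raised before any computation."""


@dataclass(frozen=True)
class RunConfig:
    """One runnable experiment: a stage, its parameters, a seed, an outdir."""

    stage: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "results"
    log_level: str = "INFO"


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML/JSON config file into a RunConfig."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "stage" not in raw:
        raise ConfigError("config must be a mapping with a 'stage' key")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _build(cls, block: dict | None, **overrides):
    block = dict(block or {})
    block.update(overrides)
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {cls.__name__}: {exc}") from exc


def _population_params(p: dict, seed: int) -> PopulationParams:
    return _build(
        PopulationParams,
        {k: v for k, v in p.items() if k not in ("rb", "feedback", "topology", "mutation")},
        rb=_build(RbParams, p.get("rb")),
        feedback=_build(FeedbackSpec, p.get("feedback")),
        topology=_build(TopologySpec, p.get("topology")),
        mutation=_build(MutationSpec, p.get("mutation")),
        seed=seed,
    )


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=float) + "\n")


# --------------------------------------------------------------------------
# stage implementations: each takes (params-dict, seed, outdir) and returns
# a list of output paths


def _stage_bifurcation(p: dict, seed: int, outdir: Path) -> list[Path]:
    rb = _build(RbParams, p.get("rb"))
    result = find_bifurcation(rb, tuple(p.get("C_search_range", (1e-3, 2.0))))
    out = outdir / "bifurcation.json"
    _write_json(out, result.to_dict())
    return [out]


def _stage_mfpt(p: dict, seed: int, outdir: Path) -> list[Path]:
    mu, xi = float(p["mu"]), float(p["xi"])
    payload = {
        "mu": mu,
        "xi": xi,
        "exact": mfpt_exact(mu, xi),
        "kramers": mfpt_kramers(mu, xi) if mu < 0 else None,
    }
    n_emp = int(p.get("empirical", 0))
    if n_emp:
        emp = mfpt_empirical(mu, xi, n=n_emp, seed=seed, dt=float(p.get("dt", 0.01)))
        payload.update(
            empirical_mean=emp.mean, empirical_se=emp.se, empirical_censored=emp.n_censored
        )
    out = outdir / "mfpt.json"
    _write_json(out, payload)
    return [out]


def _stage_scaling(p: dict, seed: int, outdir: Path) -> list[Path]:
    import pandas as pd

    xi = float(p.get("xi", 0.05))
    mu_grid = np.asarray(p.get("mu_grid", np.linspace(-0.6, -0.2, 20)), dtype=float)
    fit = scaling_exponent(xi, mu_grid)
    table = pd.DataFrame(
        {
            "mu": mu_grid,
            "xi": xi,
            "log_T_exact": log_mfpt_exact(mu_grid, xi),
            "log_T_kramers": log_mfpt_kramers(mu_grid, xi),
        }
    )
    csv = outdir / "scaling.csv"
    table.to_csv(csv, index=False)
    out = outdir / "scaling.json"
    _write_json(out, fit.to_dict())
    return [csv, out]


def _trace_outputs(trace, outdir: Path, extra: dict | None = None) -> list[Path]:
    csv = outdir / "trace.csv"
    trace.to_dataframe().to_csv(csv, index=False)
    summary = {
        "long_run_mean_N": trace.long_run_mean_N(),
        "long_run_mean_C": trace.long_run_mean_C(),
        "extinct": trace.extinct,
        "extinction_time_h": trace.extinction_time,
    }
    summary.update(extra or {})
    out = outdir / "summary.json"
    _write_json(out, summary)
    return [csv, out]


def _stage_homeostasis(p: dict, seed: int, outdir: Path) -> list[Path]:
    return _trace_outputs(run_homeostasis(_population_params(p, seed)), outdir)


def _stage_mutation(p: dict, seed: int, outdir: Path) -> list[Path]:
    p = dict(p)
    mut = dict(p.get("mutation") or {})
    mut.setdefault("enabled", True)
    p["mutation"] = mut
    trace, clones = run_mutation_experiment(_population_params(p, seed))
    extra = {
        "final_N": clones.final_N,
        "final_mean_alpha": clones.final_mean_alpha,
        "n_clones": len(clones.clone_sizes),
    }
    paths = _trace_outputs(trace, outdir, extra)
    clone_path = outdir / "clones.json"
    _write_json(clone_path, {"sizes": clones.clone_sizes, "alphas": clones.clone_alphas})
    return paths + [clone_path]


def _stage_two_compartment(p: dict, seed: int, outdir: Path) -> list[Path]:
    p = dict(p)
    fb = dict(p.get("feedback") or {})
    fb.setdefault("variant", "differentiated_pool")
    p["feedback"] = fb
    p.setdefault("topology", {"kind": "DR"})
    return _trace_outputs(run_two_compartment(_population_params(p, seed)), outdir)


def _stage_ghost(p: dict, seed: int, outdir: Path) -> list[Path]:
    rb = _build(RbParams, p.get("rb"))
    thresholds = _build(ThresholdSpec, p.get("thresholds"))
    outputs: list[Path] = []
    if p.get("perturb", False):
        res = perturbation_experiment(
            rb,
            thresholds,
            n=int(p.get("n_cells", 100)),
            t_max=float(p.get("t_max", 80.0)),
            dt=float(p.get("dt", 0.05)),
            t_perturb=float(p.get("t_perturb", 15.0)),
            delta_C=float(p.get("delta_C", -0.1)),
            seed=seed,
        )
        out = outdir / "perturbation.json"
        _write_json(out, res.counts)
        outputs.append(out)
    else:
        ens_block = {
            k: p[k] for k in ("n_cells", "t_max", "dt", "C_offset", "C_sd") if k in p
        }
        ens = _build(GhostEnsembleParams, ens_block, seed=seed)
        result = run_ghost_ensemble(rb, ens, thresholds)
        csv = outdir / "phases.csv"
        result.to_dataframe().to_csv(csv, index=False)
        out = outdir / "ghost_summary.json"
        _write_json(
            out,
            {
                "censored_fraction": result.censored_fraction,
                "phase1_median_h": float(np.nanmedian(result.phase1)),
                "phase2_median_h": float(np.nanmedian(result.phase2)),
            },
        )
        outputs += [csv, out]
    return outputs


def _conditions_from(p: dict) -> tuple[ConditionSpec, ...]:
    if "conditions" in p:
        return tuple(_build(ConditionSpec, c) for c in p["conditions"])
    return DEFAULT_CONDITIONS


def _stage_synth(p: dict, seed: int, outdir: Path) -> list[Path]:
    cfg = _build(
        GeneratorConfig,
        {k: p[k] for k in ("measurement_noise_sd", "dt", "t_max") if k in p},
        conditions=_conditions_from(p),
        rb=_build(RbParams, p.get("rb")),
        seed=seed,
    )
    df = generate_dataset(cfg)
    out = outdir / "synthetic_g1.csv"
    df.to_csv(out, index=False)
    return [out]


def _stage_wntfit(p: dict, seed: int, outdir: Path) -> list[Path]:
    import pandas as pd

    rb = _build(RbParams, p.get("rb"))
    conditions = _conditions_from(p)
    rng = np.random.default_rng(seed)

    if "observed_csv" in p:
        obs_df = pd.read_csv(p["observed_csv"])
    else:  # self-consistency mode: observed data from the forward model
        obs_df = generate_dataset(
            GeneratorConfig(conditions=conditions, rb=rb, seed=int(rng.integers(2**31)))
        )
    observed, activities = [], []
    for spec in conditions:
        grp = obs_df[obs_df["condition"] == spec.label]
        observed.append(
            summarize_condition(
                grp["g1_hours"].to_numpy(dtype=float),
                grp["censored"].to_numpy(dtype=bool) if "censored" in grp else None,
            )
        )
        activities.append(spec.wnt_activity)

    n_model = int(p.get("n_model_cells", 4000))
    model = []
    rows = []
    for spec in conditions:
        big = ConditionSpec(spec.label, spec.wnt_activity, spec.C_mean, spec.C_sd, n_model)
        summ = summarize_condition(simulate_condition(big, rb, seed=rng))
        model.append(summ)
        rows.append({"condition": spec.label, "wnt_activity": spec.wnt_activity, **summ.to_dict()})
    fit = fit_r2(model, observed, activities)
    csv = outdir / "condition_summaries.csv"
    pd.DataFrame(rows).to_csv(csv, index=False)
    out = outdir / "fit.json"
    _write_json(out, fit.to_dict())
    return [csv, out]


STAGES = {
    "bifurcation": _stage_bifurcation,
    "mfpt": _stage_mfpt,
    "scaling": _stage_scaling,
    "homeostasis": _stage_homeostasis,
    "mutation": _stage_mutation,
    "two_compartment": _stage_two_compartment,
    "ghost": _stage_ghost,
    "wntfit": _stage_wntfit,
    "synth": _stage_synth,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_stage(config: RunConfig) -> dict:
    """Execute one configured stage and write its outputs plus a manifest.

    Returns the manifest dict.  Unknown stages or malformed parameter
    blocks raise :class:`ConfigError` before any computation starts.
    """
    if config.stage not in STAGES:
        raise ConfigError(
            f"unknown stage {config.stage!r}; expected one of {sorted(STAGES)}"
        )
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = STAGES[config.stage](dict(config.params), int(config.seed), outdir)
    import scipy

    manifest = {
        "stage": config.stage,
        "seed": int(config.seed),
        "params": config.params,
        "versions": {
            "g1crit": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
        },
        "outputs": {str(path.name): _sha256(path) for path in outputs},
    }
    _write_json(outdir / "manifest.json", manifest)
    return manifest
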