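"""Experiment orchestration: validation, execution, reproducible output.

An :class:`ExperimentPlan` bundles a :class:`~modfluct.dynamics.SimulationConfig`
with diagnostic exponents and an experiment name.  ``validate_config`` checks
every parameter window up front and reports all violations at once;
``run_experiment`` executes the corresponding module pipeline and, when an
output directory is given, writes tidy CSV tables plus a JSON summary carrying
the full configuration echo and seed.  Re-running the same plan reproduces
every statistic bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .dynamics import SimulationConfig, sample_initial, simulate_interacting
from .fluctstats import (
    DiagnosticConfig,
    clt_test,
    coupling_probability,
    estimate_rate,
    FluctuationSamples,
    iid_identity_value,
    lln_probability,
    pair_fluctuation,
    predicted_variance,
    smoothed_error,
    solve_intermediate_pde,
)
from .grid import TorusGrid, wrapped_gaussian
from .kernels import (
    MollifierSpec,
    RieszSpec,
    build_kernel_tables,
    kernel_scaling_report,
)
from .pde import TestFunction, solve_dual_backward, solve_forward

__all__ = [
    "ExperimentPlan",
    "ConfigError",
    "validate_config",
    "run_experiment",
    "plan_from_json",
]

EXPERIMENTS = ("kernels_verify", "rate", "clt", "lln", "couple", "pde_only")


class ConfigError(ValueError):
    """Aggregated, human-readable configuration violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid experiment plan:\n  - " + "\n  - ".join(violations))


@dataclass
class ExperimentPlan:
    experiment: str
    config: SimulationConfig
    diagnostics: DiagnosticConfig = field(default_factory=DiagnosticConfig)
    N_list: tuple[int, ...] = (64, 128, 256, 512)
    replicas: int = 8
    phi: TestFunction = field(default_factory=lambda: TestFunction(center=(1.0, 0.0, 0.0), width=1.0))
    output_dir: str | None = None


def validate_config(plan: ExperimentPlan) -> ExperimentPlan:
    """Check all parameter windows; raise ConfigError listing every violation."""
    v: list[str] = []
    c = plan.config
    if plan.experiment not in EXPERIMENTS:
        v.append(f"unknown experiment {plan.experiment!r}; choose from {EXPERIMENTS}")
    if c.d < 3:
        v.append(f"dimension d={c.d} must be >= 3")
    elif not (0.0 < c.lam < c.d - 2):
        v.append(f"Riesz exponent lambda={c.lam} must lie in (0, d-2) = (0, {c.d - 2})")
    if c.kappa not in (-1, 0, 1):
        v.append(f"interaction sign kappa={c.kappa} must be -1, 0, or +1 (0 is test mode)")
    if c.kappa == 0 and not c.test_mode:
        v.append("kappa=0 requires test_mode")
    if c.sigma <= 0 and not c.test_mode:
        v.append(f"diffusion sigma={c.sigma} must be positive outside test mode")
    if c.dt <= 0 or c.T <= 0:
        v.append("dt and T must be positive")
    if plan.experiment == "rate":
        bound = 1.0 / (8 * c.lam + 12)
        if not (0.0 < c.beta < bound):
            v.append(
                f"rate runs require 0 < beta < 1/(8*lambda+12) = {bound:.6g}, got beta={c.beta}"
            )
        if len(plan.N_list) < 3:
            v.append(f"rate runs require >= 3 particle counts, got {len(plan.N_list)}")
    if plan.experiment == "couple":
        lo = c.beta * (c.lam + 3)
        hi = 0.5 - c.beta * (c.lam + 1)
        if not (lo < plan.diagnostics.alpha < hi):
            v.append(
                f"coupling exponent alpha={plan.diagnostics.alpha} must lie in "
                f"(beta*(lambda+3), 1/2 - beta*(lambda+1)) = ({lo:.4g}, {hi:.4g})"
            )
    if plan.experiment == "lln":
        hi = 0.5 - c.beta * (c.lam + 1)
        if not (0.0 <= plan.diagnostics.theta < hi):
            v.append(
                f"LLN exponent theta={plan.diagnostics.theta} must lie in [0, "
                f"1/2 - beta*(lambda+1)) = [0, {hi:.4g})"
            )
    # mollifier resolution: support diameter 2*eta must span >= 4 cells
    try:
        grid = c.make_grid()
        # the largest N yields the smallest eta and is the binding case
        N_probe = max(plan.N_list) if plan.experiment in ("rate", "lln", "couple") else c.N
        eta = float(N_probe) ** (-c.beta) if c.eta is None else c.eta
        if 2 * eta < 4 * grid.h:
            v.append(
                f"mollification radius eta={eta:.4g} unresolved: support diameter "
                f"2*eta must span >= 4 cells of h={grid.h:.4g}"
            )
    except ValueError as exc:
        v.append(str(exc))
    if v:
        raise ConfigError(v)
    return plan


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _echo(plan: ExperimentPlan) -> dict:
    return {
        "experiment": plan.experiment,
        "config": dataclasses.asdict(plan.config),
        "diagnostics": dataclasses.asdict(plan.diagnostics),
        "N_list": list(plan.N_list),
        "replicas": plan.replicas,
        "phi": dataclasses.asdict(plan.phi),
    }


def _log(run_id: str, module: str, msg: str) -> None:
    print(f"[{run_id}] {module}: {msg}", flush=True)


def run_experiment(plan: ExperimentPlan) -> dict:
    """Execute a validated plan; returns the summary dict (and writes files)."""
    plan = validate_config(plan)
    c = plan.config
    run_id = f"{plan.experiment}-seed{c.seed}"
    t_start = time.time()
    spec = RieszSpec(c.d, c.lam) if 0 < c.lam < c.d - 2 else None
    grid = c.make_grid()
    summary: dict = {"run_id": run_id, "plan": _echo(plan)}

    if plan.experiment == "kernels_verify":
        moll = MollifierSpec(eta=c.eta_value, beta=c.beta, d=c.d)
        tables = build_kernel_tables(spec, moll, grid)
        nz = grid.k_norm > 0
        fact = float(
            np.abs(tables.V_eta_symbol - tables.Z_eta_symbol**2)[nz].max()
            / np.abs(tables.V_eta_symbol).max()
        )
        report = kernel_scaling_report(spec, c.beta if c.beta > 0 else 0.05,
                                       [1000, 10000, 100000])
        summary["symbol_factorization_rel_error"] = fact
        summary["scaling_report"] = report
        _log(run_id, "kernels", f"factorization rel error {fact:.3g}")

    elif plan.experiment == "rate":
        fit = estimate_rate(c, plan.N_list, plan.replicas, seed=c.seed)
        summary["rate_fit"] = {
            "N": fit.N_list,
            "estimates": fit.estimates,
            "standard_errors": fit.standard_errors,
            "slope": fit.slope,
            "slope_se": fit.slope_se,
        }
        _log(run_id, "fluctstats", f"decay exponent r = {fit.slope:.3f} +/- {fit.slope_se:.3f}")

    elif plan.experiment == "clt":
        moll = MollifierSpec(eta=c.eta_value, beta=c.beta, d=c.d)
        tables = build_kernel_tables(spec, moll, grid)
        u0 = wrapped_gaussian(grid, c.center_value, c.s0)
        ubar = solve_intermediate_pde(c, tables, u0)
        u_limit = solve_forward(u0, tables.Phi_symbol, c.sigma, c.kappa, c.dt, c.T,
                                snapshot_stride=c.snapshot_stride, tag="limit")
        dual = solve_dual_backward(u_limit, plan.phi, c.T, tables.Phi_symbol,
                                   c.sigma, c.kappa, c.dt,
                                   snapshot_stride=c.snapshot_stride)
        pred, pred0, pred_dyn = predicted_variance(u_limit, dual, u0, plan.phi,
                                                   c.sigma, c.T)
        values = []
        ubar_T = ubar.field_at(c.T)
        for rep in range(plan.replicas):
            rng = np.random.default_rng(np.random.SeedSequence((c.seed, 5, rep)))
            times, snaps = simulate_interacting(c, tables, rng)
            values.append(pair_fluctuation(snaps[-1], ubar_T, plan.phi))
        samples = FluctuationSamples(
            t=c.T, phi=plan.phi, values=np.asarray(values),
            predicted_variance=pred, predicted_initial_part=pred0,
            predicted_dynamic_part=pred_dyn,
        )
        summary["clt"] = {"predicted_variance": pred,
                          "initial_part": pred0, "dynamic_part": pred_dyn,
                          **clt_test(samples)}
        summary["clt"]["values"] = samples.values
        _log(run_id, "fluctstats",
             f"variance ratio {summary['clt']['variance_ratio']:.3f}, "
             f"KS p = {summary['clt']['ks_pvalue']:.3f}")

    elif plan.experiment in ("lln", "couple"):
        results = []
        for N in plan.N_list:
            cN = replace(c, N=N, eta=None)
            moll = MollifierSpec.from_particle_count(N, c.beta, d=c.d)
            tables = build_kernel_tables(spec, moll, grid)
            ubar = solve_intermediate_pde(cN, tables)
            if plan.experiment == "lln":
                res = lln_probability(cN, tables, ubar, plan.diagnostics.theta,
                                      plan.diagnostics.replicas, seed=c.seed)
            else:
                res = coupling_probability(cN, tables, ubar, plan.diagnostics.alpha,
                                           plan.diagnostics.replicas, seed=c.seed)
            res = {k: v for k, v in res.items()}
            results.append(res)
            _log(run_id, "fluctstats",
                 f"N={N}: exceedance probability {res['probability']:.3f} "
                 f"(threshold {res['threshold']:.3g})")
        summary["probabilities"] = results

    elif plan.experiment == "pde_only":
        moll = MollifierSpec(eta=c.eta_value, beta=c.beta, d=c.d)
        tables = build_kernel_tables(spec, moll, grid)
        u0 = wrapped_gaussian(grid, c.center_value, c.s0)
        sol = solve_intermediate_pde(c, tables, u0)
        summary["pde"] = {
            "times": sol.times,
            "mass_series": sol.mass_series,
            "min_series": sol.min_series,
            "blew_up": sol.blew_up,
            "sup_norms": [float(np.abs(s.values).max()) for s in sol.snapshots],
        }
        _log(run_id, "pde", f"mass drift {np.abs(sol.mass_series - 1).max():.3g}")

    summary["elapsed_seconds"] = time.time() - t_start
    if plan.output_dir is not None:
        _write_outputs(plan, summary)
    return summary


def _write_outputs(plan: ExperimentPlan, summary: dict) -> None:
    import pandas as pd

    out = Path(plan.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = summary["run_id"]
    with open(out / f"{stem}.json", "w") as f:
        json.dump(summary, f, indent=2, default=_json_default, sort_keys=True)
    if "rate_fit" in summary:
        fit = summary["rate_fit"]
        pd.DataFrame({
            "N": fit["N"],
            "mean_sup_l2_sq": np.asarray(fit["estimates"]),
            "standard_error": np.asarray(fit["standard_errors"]),
        }).to_csv(out / f"{stem}.csv", index=False)
    if "clt" in summary:
        pd.DataFrame({"replicate": np.arange(len(summary["clt"]["values"])),
                      "pairing": np.asarray(summary["clt"]["values"])}).to_csv(
            out / f"{stem}.csv", index=False)
    if "probabilities" in summary:
        rows = [{"N": r["N"], "threshold": r["threshold"],
                 "probability": r["probability"]} for r in summary["probabilities"]]
        pd.DataFrame(rows).to_csv(out / f"{stem}.csv", index=False)


def plan_from_json(path) -> ExperimentPlan:
    """Build an ExperimentPlan from a JSON config file (seeds are mandatory)."""
    with open(path) as f:
        raw = json.load(f)
    cfg_raw = dict(raw.get("config", {}))
    if "seed" not in cfg_raw:
        raise ConfigError(["config.seed is mandatory (no wall-clock defaults)"])
    if "center" in cfg_raw and cfg_raw["center"] is not None:
        cfg_raw["center"] = tuple(cfg_raw["center"])
    config = SimulationConfig(**cfg_raw)
    diag = DiagnosticConfig(**raw.get("diagnostics", {}))
    phi_raw = raw.get("phi")
    phi = TestFunction(**{**phi_raw, "center": tuple(np.atleast_1d(phi_raw["center"]))}) \
        if phi_raw else TestFunction(center=(1.0, 0.0, 0.0), width=1.0)
    return ExperimentPlan(
        experiment=raw["experiment"],
        config=config,
        diagnostics=diag,
        N_list=tuple(raw.get("N_list", (64, 128, 256, 512))),
        replicas=int(raw.get("replicas", 8)),
        phi=phi,
        output_dir=raw.get("output_dir"),
    )
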