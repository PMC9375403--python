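"""Orchestration of the calibration-vs-non-calibration simulation study.

Each replication of a scenario simulates

1. a calibration sample (latent mean 0) and a two-arm trial sample from the
   same archetype item bank;
2. the *calibrated* analysis: item thresholds estimated on the calibration
   sample (latent mean fixed at 0), then held fixed (anchored) in the trial
   fits;
3. the *non-calibrated* analysis: thresholds re-estimated freely on the
   trial sample itself;
4. for each analysis, both comparison methods: the Wald test on the group
   coefficient, and the t-test on pooled-prior EAP trait estimates.

Operating characteristics over replications -- rejection rate (type-I error
when gamma = 0, power otherwise), position bias of the effect estimate, and
its SD -- are aggregated per (approach x method) cell.

Reproducibility: replication ``r`` of a scenario uses
``SeedSequence([scenario.seed, r])`` split into independent calibration and
trial streams, so results do not depend on execution order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .comparison import ComparisonResult, ttest_eap, wald_group_test
from .data_sim import PopulationSpec, TrialSpec, draw_latent, simulate_responses, simulate_trial
from .estimation import FitOptions, eap_latent, fit_random_pcm
from .item_model import ItemBank, make_archetype_bank

__all__ = [
    "ScenarioSpec",
    "CellResult",
    "ReplicationRecord",
    "CriteriaResult",
    "run_replication",
    "run_scenario",
    "compute_criteria",
    "criteria_frame",
    "run_grid",
    "default_grid",
    "load_config",
]

logger = logging.getLogger(__name__)

APPROACHES = ("non_calibrated", "calibrated")
METHODS = ("wald_gamma", "ttest_eap")


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation design grid."""

    J: int = 4
    M: int = 3
    archetype: int = 2
    n_calibration: int = 250
    calibration_variance: float = 1.0
    n_trial: int = 200  # per arm
    mu: float = 0.0  # placebo latent mean (mistargeting)
    gamma: float = 0.2
    n_replications: int = 500
    seed: int = 0
    alpha: float = 0.05
    n_nodes: int = 21

    def __post_init__(self) -> None:
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")

    def label(self) -> str:
        return (
            f"J{self.J}_M{self.M}_a{self.archetype}_Ncal{self.n_calibration}"
            f"_v{self.calibration_variance:g}_Nt{self.n_trial}"
            f"_mu{self.mu:g}_g{self.gamma:g}"
        )


@dataclass(frozen=True)
class CellResult:
    effect: float
    p_value: float
    converged: bool
    flagged: bool


@dataclass
class ReplicationRecord:
    """The four (approach x method) analysis cells of one replication."""

    cells: dict[tuple[str, str], CellResult]
    calibration_converged: bool


@dataclass(frozen=True)
class CriteriaResult:
    """Operating characteristics of one analysis cell over replications."""

    approach: str
    method: str
    criterion: str  # "type_i_error" | "power"
    rejection_rate: float  # percent
    position_bias: float  # mean(effect - gamma_true), signed
    abs_position_bias: float
    sd_estimates: float
    n_used: int
    n_flagged: int


def _cell(result: ComparisonResult | None, converged: bool, flagged: bool) -> CellResult:
    if result is None:
        return CellResult(np.nan, np.nan, False, flagged)
    return CellResult(result.effect, result.p_value, converged, flagged)


def run_replication(scenario: ScenarioSpec, rep_index: int) -> ReplicationRecord:
    """Simulate and analyse one replication of a scenario."""
    ss = np.random.SeedSequence([scenario.seed, rep_index])
    cal_ss, trial_ss = ss.spawn(2)
    rng_cal = np.random.default_rng(cal_ss)
    rng_trial = np.random.default_rng(trial_ss)

    bank = make_archetype_bank(scenario.J, scenario.M, scenario.archetype)
    cal_theta = draw_latent(
        PopulationSpec(0.0, scenario.calibration_variance, scenario.n_calibration),
        rng_cal,
    )
    cal_data = simulate_responses(bank, cal_theta, rng_cal)
    trial = simulate_trial(
        bank, TrialSpec(scenario.n_trial, scenario.mu, scenario.gamma), rng_trial
    )

    opts = FitOptions(n_quadrature_nodes=scenario.n_nodes)
    cal_fit = fit_random_pcm(cal_data, fix_latent_mean=True, options=opts)
    anchor = cal_fit.bank

    cells: dict[tuple[str, str], CellResult] = {}
    for approach in APPROACHES:
        anchored = approach == "calibrated"
        fixed = anchor if anchored else None
        ok_upstream = cal_fit.converged if anchored else True

        gfit = fit_random_pcm(trial, include_group=True, fixed_items=fixed, options=opts)
        try:
            wald = wald_group_test(gfit)
        except ValueError:
            wald = None
        cells[(approach, "wald_gamma")] = _cell(
            wald, gfit.converged and ok_upstream and wald is not None, gfit.flagged
        )

        pooled = fit_random_pcm(trial, include_group=False, fixed_items=fixed, options=opts)
        if pooled.converged:
            eap = eap_latent(trial, pooled)
            tt = ttest_eap(eap, trial.group)
        else:
            tt = None
        cells[(approach, "ttest_eap")] = _cell(
            tt, pooled.converged and ok_upstream and tt is not None, pooled.flagged
        )
    return ReplicationRecord(cells=cells, calibration_converged=cal_fit.converged)


def run_scenario(
    scenario: ScenarioSpec, progress_every: int | None = None
) -> list[ReplicationRecord]:
    """All replications of one scenario (sequential; order-independent seeding)."""
    records = []
    for r in range(scenario.n_replications):
        records.append(run_replication(scenario, r))
        if progress_every and (r + 1) % progress_every == 0:
            logger.info("%s: %d/%d replications", scenario.label(), r + 1, scenario.n_replications)
    return records


def compute_criteria(
    records: list[ReplicationRecord], gamma_true: float, alpha: float = 0.05
) -> list[CriteriaResult]:
    """Aggregate replication records into the four operating-characteristic rows."""
    if len(records) < 2:
        raise ValueError("need at least 2 replication records")
    criterion = "type_i_error" if gamma_true == 0 else "power"
    out = []
    for approach, method in itertools.product(APPROACHES, METHODS):
        cells = [rec.cells[(approach, method)] for rec in records]
        used = [c for c in cells if c.converged]
        if not used:
            raise ValueError(f"all replications failed for {(approach, method)}")
        effects = np.array([c.effect for c in used])
        pvals = np.array([c.p_value for c in used])
        out.append(
            CriteriaResult(
                approach=approach,
                method=method,
                criterion=criterion,
                rejection_rate=100.0 * float(np.mean(pvals < alpha)),
                position_bias=float(np.mean(effects - gamma_true)),
                abs_position_bias=float(abs(np.mean(effects - gamma_true))),
                sd_estimates=float(np.std(effects, ddof=1)),
                n_used=len(used),
                n_flagged=int(sum(c.flagged for c in cells)),
            )
        )
    return out


def criteria_frame(results: list[CriteriaResult], scenario: ScenarioSpec | None = None) -> pd.DataFrame:
    frame = pd.DataFrame([vars(r) for r in results])
    if scenario is not None:
        for key in reversed(("J", "M", "archetype", "n_calibration", "calibration_variance",
                             "n_trial", "mu", "gamma", "n_replications", "seed")):
            frame.insert(0, key, getattr(scenario, key))
    return frame


def default_grid(n_replications: int = 500, seed: int = 20220812) -> list[ScenarioSpec]:
    """The reported scenario grid: archetype 2, N_cal = 250, variance 1,
    (J, M) in {4,7,10} x {3,5}, N_trial in {200, 500} per arm,
    mu in {0, 0.5, 2}, gamma in {0, 0.2}."""
    grid = []
    combos = itertools.product((4, 7, 10), (3, 5), (200, 500), (0.0, 0.5, 2.0), (0.0, 0.2))
    for i, (J, M, n_trial, mu, gamma) in enumerate(combos):
        grid.append(
            ScenarioSpec(
                J=J, M=M, archetype=2, n_calibration=250, calibration_variance=1.0,
                n_trial=n_trial, mu=mu, gamma=gamma,
                n_replications=n_replications, seed=seed + i,
            )
        )
    return grid


def run_grid(
    scenarios: list[ScenarioSpec],
    out_dir: str | Path | None = None,
    keep_replications: bool = False,
) -> pd.DataFrame:
    """Run a list of scenarios and return (and optionally write) the criteria table."""
    frames = []
    long_rows = []
    for scenario in scenarios:
        logger.info("running scenario %s (%d replications)", scenario.label(), scenario.n_replications)
        records = run_scenario(scenario, progress_every=100)
        frames.append(criteria_frame(compute_criteria(records, scenario.gamma, scenario.alpha), scenario))
        if keep_replications:
            for r, rec in enumerate(records):
                for (approach, method), cell in rec.cells.items():
                    long_rows.append(
                        {"scenario": scenario.label(), "replication": r,
                         "approach": approach, "method": method,
                         "effect": cell.effect, "p_value": cell.p_value,
                         "converged": cell.converged}
                    )
    columns = ["J", "M", "archetype", "n_calibration", "calibration_variance",
               "n_trial", "mu", "gamma", "n_replications", "seed",
               "approach", "method", "criterion", "rejection_rate",
               "position_bias", "abs_position_bias", "sd_estimates",
               "n_used", "n_flagged"]
    table = (
        pd.concat(frames, ignore_index=True)[columns]
        if frames
        else pd.DataFrame(columns=columns)
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "criteria.csv", index=False)
        if keep_replications:
            pd.DataFrame(long_rows).to_csv(out_dir / "replications.csv", index=False)
    return table


def load_config(path: str | Path) -> list[ScenarioSpec]:
    """Parse a YAML scenario-grid config into ScenarioSpecs.

    Layout::

        run: {reps: 500, seed: 1, alpha: 0.05, nodes: 21}
        scenarios:
          - instrument: {J: 4, M: 3, archetype: 2}
            calibration: {N: 250, variance: 1}
            trial: {N: 200, mu: 0, gamma: [0, 0.2]}

    Scalar values may be lists; each scenario block expands to the cartesian
    product of its list-valued keys.  An omitted ``scenarios`` key yields the
    default grid.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    run = cfg.get("run", {})
    reps = run.get("reps", 500)
    seed = run.get("seed", 0)
    alpha = run.get("alpha", 0.05)
    nodes = run.get("nodes", 21)

    if "scenarios" not in cfg:
        return [replace(s, alpha=alpha, n_nodes=nodes)
                for s in default_grid(n_replications=reps, seed=seed)]

    key_map = {
        ("instrument", "J"): "J", ("instrument", "M"): "M",
        ("instrument", "archetype"): "archetype",
        ("calibration", "N"): "n_calibration",
        ("calibration", "variance"): "calibration_variance",
        ("trial", "N"): "n_trial", ("trial", "mu"): "mu", ("trial", "gamma"): "gamma",
    }
    scenarios: list[ScenarioSpec] = []
    counter = 0
    for i, block in enumerate(cfg["scenarios"]):
        flat: dict[str, list] = {}
        for (section, key), name in key_map.items():
            sec = block.get(section, {})
            if not isinstance(sec, dict):
                raise ValueError(f"scenario {i}: section '{section}' must be a mapping")
            unknown = set(sec) - {k for (s, k) in key_map if s == section}
            if unknown:
                raise ValueError(f"scenario {i}: unknown key '{sorted(unknown)[0]}' in '{section}'")
            if key in sec:
                val = sec[key]
                flat[name] = list(val) if isinstance(val, (list, tuple)) else [val]
        names = list(flat)
        for combo in itertools.product(*(flat[n] for n in names)):
            kwargs = dict(zip(names, combo))
            scenarios.append(
                ScenarioSpec(
                    n_replications=reps, seed=seed + counter, alpha=alpha,
                    n_nodes=nodes, **kwargs,
                )
            )
            counter += 1
    return scenarios
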