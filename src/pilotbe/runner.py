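"""Orchestration of the full simulation experiment.

The experiment grid crosses variability scenarios (baseline plus five
IIV/IOV levels applied separately to ka, V and ke), two truth groups
(test ka multiplier 1.0 = truly bioequivalent, 0.3 = truly
bioinequivalent), a range of even sample sizes, and replicate trials.
Every decision method analyses the same simulated trials within a cell.
Bioequivalence is evaluated on Cmax only.

Per-trial seeds are derived from the master seed with
``SeedSequence(master, spawn_key=(scenario, truth, n, rep))`` so any
subset of cells reproduces bit-identically in any execution order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import abe, bootstrapbe, f2sim, perf
from .nca import nca_table
from .popsim import TRULY_BE, PopulationModel, TrialDesign, simulate_trial

__all__ = [
    "Scenario",
    "ExperimentPlan",
    "DEFAULT_SCENARIOS",
    "METHODS",
    "trial_seed",
    "run_cell",
    "run_experiment",
    "summarize",
    "summarize_range",
    "empirical_sample_size",
    "load_plan",
]

VARIABILITY_LEVELS = ((30, 0), (30, 10), (30, 20), (30, 30), (0, 45))


@dataclass(frozen=True)
class Scenario:
    varying_parameter: str  # 'ka' | 'V' | 'ke' | 'none'
    iiv_cv: float
    iov_cv: float

    @property
    def label(self) -> str:
        if self.varying_parameter == "none":
            return "baseline"
        return f"{self.varying_parameter} {self.iiv_cv:g}% IIV & {self.iov_cv:g}% IOV"


DEFAULT_SCENARIOS: tuple[Scenario, ...] = (Scenario("none", 0, 0),) + tuple(
    Scenario(p, iiv, iov)
    for p in ("ka", "V", "ke")
    for iiv, iov in VARIABILITY_LEVELS
)

#: Decision methods: name -> callable(trial, rng) -> bool verdict.
METHODS = {
    "abe": lambda trial, rng: abe.analyze_abe(trial).decision_abe,
    "centrality": lambda trial, rng: abe.analyze_abe(trial).decision_centrality,
    "bootstrap": lambda trial, rng: bootstrapbe.bootstrap_be(trial, rng=rng).decision,
    "f2_amean_35": lambda trial, rng: f2sim.analyze_f2(trial, "arithmetic", 35).decision,
    "f2_amean_41": lambda trial, rng: f2sim.analyze_f2(trial, "arithmetic", 41).decision,
    "f2_amean_50": lambda trial, rng: f2sim.analyze_f2(trial, "arithmetic", 50).decision,
    "f2_gmean_35": lambda trial, rng: f2sim.analyze_f2(trial, "geometric", 35).decision,
    "f2_gmean_41": lambda trial, rng: f2sim.analyze_f2(trial, "geometric", 41).decision,
    "f2_gmean_50": lambda trial, rng: f2sim.analyze_f2(trial, "geometric", 50).decision,
}

DEFAULT_METHODS = ("abe", "centrality", "bootstrap", "f2_amean_35", "f2_gmean_35")


@dataclass(frozen=True)
class ExperimentPlan:
    scenarios: tuple[Scenario, ...] = DEFAULT_SCENARIOS
    truth_multipliers: tuple[float, ...] = (1.0, 0.3)
    n_grid: tuple[int, ...] = tuple(range(12, 31, 2))
    reps: int = 100
    methods: tuple[str, ...] = DEFAULT_METHODS
    master_seed: int = 0
    base_model: PopulationModel = field(default_factory=PopulationModel)

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not self.scenarios:
            raise ValueError("scenario list must be non-empty")
        if any(n % 2 for n in self.n_grid):
            raise ValueError("n_grid must contain even values only")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @property
    def n_trials(self) -> int:
        return (
            len(self.scenarios) * len(self.truth_multipliers)
            * len(self.n_grid) * self.reps
        )


def trial_seed(
    master_seed: int, scenario_idx: int, truth_idx: int, n: int, rep: int
) -> np.random.SeedSequence:
    """Deterministic, order-independent per-trial seed stream."""
    return np.random.SeedSequence(master_seed, spawn_key=(scenario_idx, truth_idx, n, rep))


def _cell_model(base: PopulationModel, scenario: Scenario, multiplier: float) -> PopulationModel:
    return replace(
        base,
        varying_parameter=scenario.varying_parameter,
        iiv_cv=scenario.iiv_cv,
        iov_cv=scenario.iov_cv,
        test_ka_multiplier=multiplier,
    )


def run_cell(
    plan: ExperimentPlan,
    scenario_idx: int,
    truth_idx: int,
    n: int,
) -> pd.DataFrame:
    """Simulate the cell's replicate trials and apply every method.

    Returns one row per (rep, method) with the boolean verdict; all
    methods see the same simulated trial within a rep.
    """
    scenario = plan.scenarios[scenario_idx]
    multiplier = plan.truth_multipliers[truth_idx]
    model = _cell_model(plan.base_model, scenario, multiplier)
    design = TrialDesign(n_subjects=n)
    rows = []
    for rep in range(plan.reps):
        ss = trial_seed(plan.master_seed, scenario_idx, truth_idx, n, rep)
        sim_seed, analysis_seed = ss.spawn(2)
        trial = simulate_trial(model, design, sim_seed)
        tab = nca_table(trial)
        rng = np.random.Generator(np.random.PCG64(analysis_seed))
        for method in plan.methods:
            decision = _apply_method(method, trial, tab, rng)
            rows.append(
                {
                    "scenario": scenario.label,
                    "parameter": scenario.varying_parameter,
                    "iiv": scenario.iiv_cv,
                    "iov": scenario.iov_cv,
                    "truth": model.truth_label,
                    "truly_be": multiplier == 1.0,
                    "n": n,
                    "rep": rep,
                    "method": method,
                    "decision": bool(decision),
                }
            )
    return pd.DataFrame(rows)


def _apply_method(method: str, trial, tab: pd.DataFrame, rng) -> bool:
    # reuse the precomputed NCA table for the ANOVA-based methods
    if method == "abe":
        return abe.analyze_abe(tab).decision_abe
    if method == "centrality":
        return abe.analyze_abe(tab).decision_centrality
    return METHODS[method](trial, rng)


def run_experiment(plan: ExperimentPlan, progress: bool = False) -> pd.DataFrame:
    """Run every cell of the plan; long-format per-trial decisions."""
    frames = []
    cells = list(
        itertools.product(
            range(len(plan.scenarios)), range(len(plan.truth_multipliers)), plan.n_grid
        )
    )
    for k, (si, ti, n) in enumerate(cells):
        frames.append(run_cell(plan, si, ti, n))
        if progress:
            print(f"cell {k + 1}/{len(cells)} done", flush=True)
    return pd.concat(frames, ignore_index=True)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Confusion statistics per (scenario, n, method), in percent.

    Cells missing one truth group are skipped.  Statistic columns follow
    the confusion-matrix module; counts are included.
    """
    rows = []
    for (scenario, n, method), grp in results.groupby(["scenario", "n", "method"]):
        if grp["truly_be"].nunique() < 2:
            continue
        tp, fn, fp, tn = perf.accumulate(grp["truly_be"], grp["decision"])
        summ = perf.statistics(tp, fn, fp, tn)
        row = {"scenario": scenario, "n": n, "method": method,
               "tp": tp, "fn": fn, "fp": fp, "tn": tn}
        row.update(summ.as_percent())
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_range(summary: pd.DataFrame, n_low: int = 12, n_high: int = 30) -> pd.DataFrame:
    """Format each statistic as a 'low-high' range over two sample sizes."""
    stats_cols = ["sensitivity", "specificity", "precision", "npv",
                  "accuracy", "f1", "mcc", "kappa"]
    rows = []
    for (scenario, method), grp in summary.groupby(["scenario", "method"]):
        lo = grp[grp["n"] == n_low]
        hi = grp[grp["n"] == n_high]
        if lo.empty or hi.empty:
            continue
        row = {"scenario": scenario, "method": method}
        for col in stats_cols:
            a, b = lo[col].iloc[0], hi[col].iloc[0]
            row[col] = f"{a:.1f}" if a == b else f"{a:.1f}–{b:.1f}"
        rows.append(row)
    return pd.DataFrame(rows)


def empirical_sample_size(
    sensitivities: pd.Series | dict[int, float], target: float = 0.80
) -> int | str:
    """Smallest grid n with empirical sensitivity >= target.

    ``sensitivities`` maps n -> sensitivity fraction (or %, detected by
    values > 1).  Returns the '>max' sentinel string when the target is
    never reached on the grid.
    """
    s = pd.Series(sensitivities).sort_index()
    if s.empty:
        raise ValueError("empty sensitivity grid")
    vals = s / 100.0 if (s > 1.0).any() else s
    hit = vals[vals >= target]
    if hit.empty:
        return f">{int(s.index.max())}"
    return int(hit.index[0])


def load_plan(path) -> ExperimentPlan:
    """Build an ExperimentPlan from a YAML plan file.

    Recognized keys: master_seed (required), reps, n_grid, methods,
    truth_multipliers, scenarios (list of {parameter, iiv, iov}), and
    model (PopulationModel field overrides).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "master_seed" not in cfg:
        raise ValueError("plan file must set master_seed")
    kwargs: dict = {"master_seed": int(cfg["master_seed"])}
    if "reps" in cfg:
        kwargs["reps"] = int(cfg["reps"])
    if "n_grid" in cfg:
        kwargs["n_grid"] = tuple(int(n) for n in cfg["n_grid"])
    if "methods" in cfg:
        kwargs["methods"] = tuple(cfg["methods"])
    if "truth_multipliers" in cfg:
        kwargs["truth_multipliers"] = tuple(float(m) for m in cfg["truth_multipliers"])
    if "scenarios" in cfg:
        kwargs["scenarios"] = tuple(
            Scenario(s["parameter"], float(s.get("iiv", 0)), float(s.get("iov", 0)))
            for s in cfg["scenarios"]
        )
    if "model" in cfg:
        kwargs["base_model"] = PopulationModel(**cfg["model"])
    return ExperimentPlan(**kwargs)
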