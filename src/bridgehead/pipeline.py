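"""Orchestration of the step-by-step invasion-history analysis.

``run_step`` pools the observed genotypes for one ladder step, computes
the observed summary vector, builds (or reuses) the step's reference
table and runs random-forest scenario choice.  ``run_ladder`` executes
the steps in order and finishes with parameter estimation under the
winning final-step scenario.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .abcrf import (
    ModelChoiceResult,
    ParamEstimate,
    choose_model,
    estimate_parameter,
)
from .genotypes import GenotypeMatrix
from .ladder import StepDefinition, study_ladder
from .scenarios import DEFAULT_GENERATION_TIME
from .simulate import ReferenceTable, generate_reference_table
from .sumstats import SummaryVector, summary_vector

__all__ = ["PROFILES", "StepRecord", "LadderReport", "run_step", "run_ladder"]

PROFILES = {
    # n_sims_per_scenario, n_loci
    "desk": (2_000, 500),
    "full": (10_000, 2_000),
    "smoke": (150, 100),
}


def _param_units(name: str) -> str:
    if name.startswith(("t_", "d_")):
        return "years"
    if name.startswith(("N_", "Nb_")):
        return "diploids"
    return ""


@dataclass
class StepRecord:
    """Everything one executed ladder step produced."""

    step_id: str
    pooling: dict[str, str]
    roster: list[str]
    sample_sizes: dict[str, int]
    n_loci: int
    observed: SummaryVector
    table: ReferenceTable
    choice: ModelChoiceResult
    skipped: bool = False
    skip_reason: str = ""

    def summary(self) -> str:
        if self.skipped:
            return f"step {self.step_id}: skipped ({self.skip_reason})"
        head = f"step {self.step_id}: selected {self.choice.selected}"
        votes = ", ".join(f"{k}={v}" for k, v in sorted(self.choice.votes.items()))
        return (f"{head}  [{votes}]  "
                f"P={self.choice.posterior_probability:.3f}")


@dataclass
class LadderReport:
    """Per-step choices plus final parameter estimates."""

    steps: list[StepRecord] = field(default_factory=list)
    final_scenario: str | None = None
    estimates: list[ParamEstimate] = field(default_factory=list)

    def summary(self) -> str:
        lines = ["invasion-history ladder", "=" * 40]
        lines += [s.summary() for s in self.steps]
        if self.final_scenario is not None:
            lines.append(f"final topology: {self.final_scenario}")
            lines += ["  " + e.summary() for e in self.estimates]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "steps": [
                {
                    "step_id": s.step_id,
                    "skipped": s.skipped,
                    "skip_reason": s.skip_reason,
                    "votes": None if s.skipped else s.choice.votes,
                    "selected": None if s.skipped else s.choice.selected,
                    "posterior_probability": (
                        None if s.skipped else s.choice.posterior_probability
                    ),
                    "prior_error_rate": (
                        None if s.skipped else s.choice.prior_error_rate
                    ),
                }
                for s in self.steps
            ],
            "final_scenario": self.final_scenario,
            "estimates": [
                {"name": e.name, "median": e.median, "q025": e.q025,
                 "q975": e.q975, "units": e.units}
                for e in self.estimates
            ],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text


def _derive_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1)) + 1


def pool_for_step(step: StepDefinition, g: GenotypeMatrix) -> GenotypeMatrix:
    """Apply the step's locality pooling; unmapped localities are dropped."""
    pooled = g.rename_populations(step.pooling, drop_unmapped=True)
    present = set(pooled.populations)
    missing = [p for p in step.required if p not in present]
    if missing:
        raise ValueError(
            f"step {step.step_id}: no individuals for population(s) "
            f"{', '.join(missing)} after pooling"
        )
    return pooled


def run_step(
    step: StepDefinition,
    g: GenotypeMatrix,
    n_sims_per_scenario: int = 2_000,
    n_loci: int = 500,
    seed: int = 0,
    sample_sizes: dict[str, int] | None = None,
    generation_time: float = DEFAULT_GENERATION_TIME,
    engine: str = "msprime",
    n_trees: int = 500,
    table: ReferenceTable | None = None,
) -> StepRecord:
    """Run one ladder step on observed (or synthetic) genotypes.

    ``table`` may supply a cached reference table; it must carry exactly
    the step's candidate labels.  The observed dataset is thinned at
    random (seeded) to ``n_loci`` SNPs when it has more, and the
    simulated datasets match the observed per-population sample sizes
    unless ``sample_sizes`` overrides them.
    """
    rng = np.random.default_rng(seed)
    pooled = pool_for_step(step, g)
    roster = list(step.candidates[0].sampled)

    eff_loci = min(n_loci, pooled.n_loci)
    if pooled.n_loci > eff_loci:
        keep = np.sort(rng.choice(pooled.n_loci, size=eff_loci, replace=False))
        pooled = pooled.subset(loci=keep)

    if sample_sizes is None:
        counts = pooled.sample_sizes()
        sample_sizes = {p: counts[p] for p in roster}

    observed = summary_vector(pooled, roster)

    # seeds drawn unconditionally so a cached table reproduces the record
    table_seed = int(rng.integers(1, 2**31))
    forest_seed = int(rng.integers(1, 2**31))
    if table is not None:
        if sorted(table.labels) != sorted(step.labels()):
            raise ValueError(
                f"cached table labels {table.labels} do not match step "
                f"{step.step_id} candidates {step.labels()}"
            )
    else:
        table = generate_reference_table(
            step,
            n_sims_per_scenario=n_sims_per_scenario,
            n_loci=eff_loci,
            sample_sizes=sample_sizes,
            seed=table_seed,
            generation_time=generation_time,
            engine=engine,
        )

    choice = choose_model(table, observed, n_trees=n_trees, seed=forest_seed)
    return StepRecord(
        step_id=step.step_id,
        pooling=dict(step.pooling),
        roster=roster,
        sample_sizes=dict(sample_sizes),
        n_loci=eff_loci,
        observed=observed,
        table=table,
        choice=choice,
    )


def run_ladder(
    g: GenotypeMatrix,
    steps: list[StepDefinition] | None = None,
    profile: str = "desk",
    n_sims_per_scenario: int | None = None,
    n_loci: int | None = None,
    seed: int = 0,
    generation_time: float = DEFAULT_GENERATION_TIME,
    engine: str = "msprime",
    n_trees: int = 500,
    estimate_final: bool = True,
    skip_unsatisfiable: bool = True,
) -> LadderReport:
    """Execute the step ladder end to end.

    Steps whose pooling cannot be satisfied by the data (e.g. the
    Japanese sub-steps when localities were already pooled regionally)
    are recorded as skipped when ``skip_unsatisfiable`` is set, otherwise
    they abort the run; any other step failure aborts with the partial
    report preserved in the raised error's ``report`` attribute.

    After the last step, every time, admixture, bottleneck and duration
    parameter of the winning scenario is estimated from that scenario's
    rows of the final reference table.
    """
    steps = study_ladder() if steps is None else steps
    if n_sims_per_scenario is None or n_loci is None:
        prof = PROFILES[profile]
        n_sims_per_scenario = n_sims_per_scenario or prof[0]
        n_loci = n_loci or prof[1]

    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(steps) + 1)
    report = LadderReport()
    last_record: StepRecord | None = None

    for i, step in enumerate(steps):
        try:
            pool_for_step(step, g)
        except ValueError as exc:
            if skip_unsatisfiable:
                report.steps.append(
                    StepRecord(step.step_id, dict(step.pooling), [], {}, 0,
                               None, None, None, skipped=True,
                               skip_reason=str(exc))
                )
                continue
            raise
        try:
            record = run_step(
                step, g,
                n_sims_per_scenario=n_sims_per_scenario,
                n_loci=n_loci,
                seed=_derive_seed(child[i]),
                generation_time=generation_time,
                engine=engine,
                n_trees=n_trees,
            )
        except Exception as exc:
            exc.report = report  # partial report preserved
            raise
        report.steps.append(record)
        last_record = record

    if estimate_final and last_record is not None:
        winner = last_record.choice.selected
        report.final_scenario = winner
        scenario = next(c for c in steps[-1].candidates if c.label == winner)
        restricted = last_record.table.restrict(winner)
        est_seed = _derive_seed(child[-1])
        for k, name in enumerate(sorted(scenario.priors.names())):
            if not name.startswith(("t_", "r_", "Nb_", "d_")):
                continue
            report.estimates.append(
                estimate_parameter(
                    restricted, last_record.observed, name,
                    n_trees=n_trees, seed=est_seed + k,
                    units=_param_units(name),
                )
            )
    return report
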