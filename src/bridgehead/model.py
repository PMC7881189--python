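"""Model/Results front-end for the invasion-history analysis.

:class:`ScenarioChoiceModel` fits one ladder step (scenario choice) and
:class:`InvasionHistoryModel` fits the whole step ladder; both follow the
familiar build-then-``fit()`` pattern, with Results objects carrying the
vote counts, posterior probabilities, parameter estimates and a
``summary()`` table, plus a simple vote plot.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genotypes import GenotypeMatrix
from .ladder import StepDefinition, study_ladder
from .pipeline import PROFILES, LadderReport, StepRecord, run_ladder, run_step
from .scenarios import DEFAULT_GENERATION_TIME
from .variant_io import read_vcf

__all__ = [
    "ScenarioChoiceModel",
    "ScenarioChoiceResults",
    "InvasionHistoryModel",
    "InvasionHistoryResults",
]


@dataclass
class ScenarioChoiceResults:
    """Results of one ladder step."""

    record: StepRecord

    @property
    def votes(self) -> dict[str, int]:
        return self.record.choice.votes

    @property
    def selected(self) -> str:
        return self.record.choice.selected

    @property
    def posterior_probability(self) -> float:
        return self.record.choice.posterior_probability

    def summary(self) -> str:
        lines = [f"ladder step {self.record.step_id}",
                 f"populations: {', '.join(self.record.roster)}",
                 f"loci used: {self.record.n_loci}",
                 self.record.choice.summary()]
        return "\n".join(lines)

    def plot_votes(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        labels = sorted(self.votes)
        ax.bar(labels, [self.votes[k] for k in labels])
        ax.set_ylabel("RF votes")
        ax.set_title(f"step {self.record.step_id}: selected {self.selected}")
        return ax


class ScenarioChoiceModel:
    """Scenario choice for a single ladder step on genotype data."""

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        step: StepDefinition,
        n_sims_per_scenario: int = 2_000,
        n_loci: int = 500,
        generation_time: float = DEFAULT_GENERATION_TIME,
        engine: str = "msprime",
    ):
        self.genotypes = genotypes
        self.step = step
        self.n_sims_per_scenario = n_sims_per_scenario
        self.n_loci = n_loci
        self.generation_time = generation_time
        self.engine = engine

    @classmethod
    def from_vcf(cls, vcf_path, popmap, step: StepDefinition, **kwargs):
        return cls(read_vcf(vcf_path, popmap), step, **kwargs)

    def fit(self, seed: int = 0) -> ScenarioChoiceResults:
        record = run_step(
            self.step,
            self.genotypes,
            n_sims_per_scenario=self.n_sims_per_scenario,
            n_loci=self.n_loci,
            seed=seed,
            generation_time=self.generation_time,
            engine=self.engine,
        )
        return ScenarioChoiceResults(record)


@dataclass
class InvasionHistoryResults:
    """Full-ladder results: per-step votes plus final parameter estimates."""

    report: LadderReport

    @property
    def final_scenario(self) -> str | None:
        return self.report.final_scenario

    @property
    def estimates(self):
        return self.report.estimates

    def estimate(self, name: str):
        for e in self.report.estimates:
            if e.name == name:
                return e
        raise KeyError(f"no estimate for parameter {name!r}")

    def summary(self) -> str:
        return self.report.summary()

    def to_json(self, path=None) -> str:
        return self.report.to_json(path)

    def plot_votes(self, ax=None):
        """Stacked per-step vote fractions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        executed = [s for s in self.report.steps if not s.skipped]
        for i, s in enumerate(executed):
            bottom = 0.0
            for label in sorted(s.choice.votes):
                frac = s.choice.votes[label] / s.choice.n_trees
                ax.bar(i, frac, bottom=bottom,
                       color="C0" if label == s.choice.selected else "C7",
                       edgecolor="white")
                bottom += frac
        ax.set_xticks(range(len(executed)))
        ax.set_xticklabels([s.step_id for s in executed])
        ax.set_xlabel("ladder step")
        ax.set_ylabel("vote fraction (selected in blue)")
        return ax


class InvasionHistoryModel:
    """The whole step ladder as one fitted model.

    ``profile`` selects the simulation effort per step: ``"desk"``
    (2,000 simulations per scenario on 500 SNPs), ``"full"`` (10,000 on
    2,000) or ``"smoke"``; explicit ``n_sims_per_scenario`` / ``n_loci``
    override it.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        steps: list[StepDefinition] | None = None,
        profile: str = "desk",
        n_sims_per_scenario: int | None = None,
        n_loci: int | None = None,
        generation_time: float = DEFAULT_GENERATION_TIME,
        engine: str = "msprime",
    ):
        if profile not in PROFILES:
            raise ValueError(f"unknown profile {profile!r}; available: {list(PROFILES)}")
        self.genotypes = genotypes
        self.steps = steps if steps is not None else study_ladder()
        self.profile = profile
        self.n_sims_per_scenario = n_sims_per_scenario
        self.n_loci = n_loci
        self.generation_time = generation_time
        self.engine = engine

    @classmethod
    def from_vcf(cls, vcf_path, popmap, **kwargs):
        return cls(read_vcf(vcf_path, popmap), **kwargs)

    def fit(self, seed: int = 0) -> InvasionHistoryResults:
        report = run_ladder(
            self.genotypes,
            steps=self.steps,
            profile=self.profile,
            n_sims_per_scenario=self.n_sims_per_scenario,
            n_loci=self.n_loci,
            seed=seed,
            generation_time=self.generation_time,
            engine=self.engine,
        )
        return InvasionHistoryResults(report)
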