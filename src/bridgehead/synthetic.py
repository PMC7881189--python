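"""Synthetic study-scale fixtures with known generative truth.

The default preset simulates under the winning final-step invasion
topology (admixed Hawaiian bridgehead, Louisiana/Texas founded from
Hawaii, Florida founded by admixture of Louisiana/Texas and southcentral
China) with its reported point values — introduction times 138, 98 and
87 years before sampling and admixture fractions 0.48 (Hong Kong region
into Hawaii) and 0.49 (Louisiana/Texas into Florida).  Founding
bottlenecks are drawn from the scenario's priors under the fixture seed;
stable sizes and native split times take fixed study-like values
(:data:`STUDY_NUISANCE`) so the simulated native range carries the strong
regional structure of the real data — without it the admixture sources
would be nearly interchangeable.

Missing genotypes are injected completely at random and per-locus mean
depths are synthesized log-normally, so the full SNP/individual filter
chain can be exercised on the fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .genotypes import MISSING, GenotypeMatrix
from .ladder import final_scenario
from .scenarios import DEFAULT_GENERATION_TIME
from .simulate import SimulationRequest, simulate_dataset
from .variant_io import write_popmap, write_vcf

__all__ = ["StudyEmulationConfig", "POINT_VALUES", "make_study_fixture", "write_fixture"]

POINT_VALUES = {
    "t_hawaii": 138.0,
    "t_latx": 98.0,
    "t_florida": 87.0,
    "r_hawaii": 0.48,   # Hong Kong region share of the Hawaii founding
    "r_florida": 0.49,  # Louisiana/Texas share of the Florida founding
}

STUDY_NUISANCE = {
    # Stable sizes at colony-scale effective numbers typical of eusocial
    # insects, and native splits deep enough that the simulated native
    # range shows the strong regional structure the real data exhibit
    # (regional F_ST ~ 0.1 between the eastern Asian sub-regions, ~ 0.2
    # against southcentral China).  All values lie inside the scenario
    # priors.  Founding bottlenecks stay prior-drawn.
    "N_southcentral": 3_000.0,
    "N_hongkong_region": 3_000.0,
    "N_sub_eastern_asia": 3_000.0,
    "N_eastern_asia_anc": 3_000.0,
    "N_root": 3_000.0,
    "N_hawaii": 3_000.0,
    "N_latx": 3_000.0,
    "N_florida": 3_000.0,
    "t_eastern_asia_anc": 3_000.0,
    "t_root": 8_000.0,
}

PRESETS = ("study-s6c",)


@dataclass
class StudyEmulationConfig:
    """Knobs of the study-scale fixture generator."""

    preset: str = "study-s6c"
    sample_sizes: dict[str, int] | None = None  # diploids per population (default 10)
    n_loci: int = 2_000
    missingness: float = 0.068
    individual_missingness: dict[str, float] = field(default_factory=dict)
    population_missingness: dict[str, float] = field(default_factory=dict)
    depth_mean: float = 44.0
    depth_sigma: float = 0.4
    seed: int = 0
    generation_time: float = DEFAULT_GENERATION_TIME
    engine: str = "msprime"

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; available: {PRESETS}")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0, 1)")


def make_study_fixture(
    cfg: StudyEmulationConfig | None = None,
) -> tuple[GenotypeMatrix, dict]:
    """Simulate a study-structure dataset and return it with its truth record.

    The truth record contains the full generative parameter vector, the
    scenario label and every configuration field, and suffices to
    re-create the fixture bit-identically.
    """
    cfg = cfg or StudyEmulationConfig()
    scenario = final_scenario()
    rng = np.random.default_rng(cfg.seed)

    params = scenario.priors.sample(rng)  # founding bottlenecks et al.
    params.update(STUDY_NUISANCE)
    params.update(POINT_VALUES)
    sample_sizes = cfg.sample_sizes or {p: 10 for p in scenario.sampled}

    g = simulate_dataset(
        SimulationRequest(
            scenario=scenario,
            params=params,
            sample_sizes=sample_sizes,
            n_loci=cfg.n_loci,
            seed=int(rng.integers(1, 2**31)),
            generation_time=cfg.generation_time,
            engine=cfg.engine,
        )
    )

    # per-locus mean depths (log-normal around the study-scale coverage)
    g.loci["mean_depth"] = rng.lognormal(
        mean=np.log(cfg.depth_mean), sigma=cfg.depth_sigma, size=cfg.n_loci
    )

    # missing genotypes, completely at random, with per-population and
    # per-individual overrides (used to plant filterable defects)
    rate = np.full(g.n_individuals, cfg.missingness)
    for pop, r in cfg.population_missingness.items():
        rate[np.asarray(g.populations, dtype=object) == pop] = r
    for ind, r in cfg.individual_missingness.items():
        rate[g.individuals.index(ind)] = r
    if (rate > 0).any():
        mask = rng.random(g.codes.shape) < rate[:, None]
        g.codes[mask] = MISSING

    truth = {
        "scenario": scenario.label,
        "params": {k: float(v) for k, v in params.items()},
        "point_values": dict(POINT_VALUES),
        "config": {
            "preset": cfg.preset,
            "sample_sizes": dict(sample_sizes),
            "n_loci": cfg.n_loci,
            "missingness": cfg.missingness,
            "individual_missingness": dict(cfg.individual_missingness),
            "population_missingness": dict(cfg.population_missingness),
            "depth_mean": cfg.depth_mean,
            "depth_sigma": cfg.depth_sigma,
            "seed": cfg.seed,
            "generation_time": cfg.generation_time,
            "engine": cfg.engine,
        },
    }
    return g, truth


def write_fixture(g: GenotypeMatrix, truth: dict, directory) -> dict[str, Path]:
    """Emit VCF + popmap + truth file for CLI consumption."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": directory / "fixture.vcf",
        "popmap": directory / "fixture.popmap",
        "truth": directory / "fixture.truth.yaml",
    }
    write_vcf(g, paths["vcf"])
    write_popmap(g, paths["popmap"])
    paths["truth"].write_text(yaml.safe_dump(truth, sort_keys=False))
    return paths
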