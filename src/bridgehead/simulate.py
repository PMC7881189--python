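"""Simulation of unlinked biallelic SNPs under a demographic scenario.

Each locus carries a coalescent genealogy of all sampled lineages with
exactly one mutation placed uniformly at random on its branches, so every
locus is polymorphic in the pooled sample.  Because a SNP is a site
*discovered through* its mutation, the genealogy of an ascertained SNP is
not a plain draw from the coalescent: under Poisson mutation at rate
``mu -> 0`` conditioned on polymorphism, trees are sampled with
probability proportional to their total branch length.  The engines
realise this length-biased distribution exactly with an independence
Metropolis sampler over the stream of simulated genealogies (acceptance
``L'/L``), which reproduces the neutral site-frequency-spectrum and
differentiation expectations of the infinitesimal-mutation model.  There
is no mutation-rate parameter and per-SNP statistics live on the
ascertained scale.  Diploid genotypes pair lineages within individuals.

Two engines share this contract: the production engine built on msprime,
and a small pure-Python discrete-lineage simulator used as an independent
distributional oracle in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, default_locus_frame
from .scenarios import (
    DEFAULT_GENERATION_TIME,
    Admixture,
    Bottleneck,
    DemographicScenario,
    PriorSpec,
    Split,
    _resolve,
)

__all__ = [
    "SimulationRequest",
    "simulate_dataset",
    "ReferenceTable",
    "generate_reference_table",
]


@dataclass
class SimulationRequest:
    """Everything needed to simulate one SNP dataset."""

    scenario: DemographicScenario
    params: dict[str, float]
    sample_sizes: dict[str, int]  # diploids per sampled population
    n_loci: int
    seed: int
    generation_time: float = DEFAULT_GENERATION_TIME
    engine: str = "msprime"

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if any(n < 1 for n in self.sample_sizes.values()):
            raise ValueError("sample sizes must be >= 1")

    def run(self) -> GenotypeMatrix:
        return simulate_dataset(self)


def simulate_dataset(req: SimulationRequest) -> GenotypeMatrix:
    """Simulate a :class:`GenotypeMatrix` under the request's scenario.

    Deterministic per seed.  Raises if the scenario is structurally
    invalid (e.g. lineages cannot reach a common root).
    """
    violations = req.scenario.validate(req.params)
    if violations:
        raise ValueError(
            f"scenario {req.scenario.label!r}: " + "; ".join(violations)
        )
    if req.engine == "msprime":
        codes = _simulate_msprime(req)
    elif req.engine == "naive":
        codes = _simulate_naive(req)
    else:
        raise ValueError(f"unknown engine {req.engine!r}")

    individuals: list[str] = []
    populations: list[str] = []
    for pop, n in req.sample_sizes.items():
        individuals.extend(f"{pop}_{k}" for k in range(n))
        populations.extend([pop] * n)
    return GenotypeMatrix(
        codes=codes,
        individuals=individuals,
        populations=populations,
        loci=default_locus_frame(req.n_loci),
    )


# ---------------------------------------------------------------------------
# length-biased genealogy sampling (SNP ascertainment)
# ---------------------------------------------------------------------------

ASCERTAINMENT_THIN = 2
"""Metropolis steps consumed per emitted locus."""

ASCERTAINMENT_BURN = 16
"""Warm-up Metropolis steps before the first locus is emitted."""


def ascertainment_steps(n_loci: int) -> int:
    """Number of raw genealogies consumed to emit ``n_loci`` SNP loci."""
    return ASCERTAINMENT_BURN + ASCERTAINMENT_THIN * n_loci


def _metropolis_loci(tree_stream, n_loci: int, rng: np.random.Generator):
    """Yield ``n_loci`` length-biased (state, cum_lengths) tree states.

    ``tree_stream`` yields (state, cum_lengths) pairs where
    ``cum_lengths`` is the cumulative branch-length array over nodes.
    Independence Metropolis with acceptance ``min(1, L'/L)`` has the
    length-biased distribution as its exact stationary law; thinning
    keeps residual dependence between consecutive loci negligible while
    the marginal distribution of every emitted tree is exact.
    """
    current = None
    current_total = -1.0
    emitted = 0
    for step, (state, cum) in enumerate(tree_stream):
        total = cum[-1]
        if current is None or rng.random() < total / current_total:
            current = (state, cum)
            current_total = total
        if step >= ASCERTAINMENT_BURN and \
                (step - ASCERTAINMENT_BURN) % ASCERTAINMENT_THIN == ASCERTAINMENT_THIN - 1:
            yield current
            emitted += 1
            if emitted == n_loci:
                return


# ---------------------------------------------------------------------------
# msprime engine
# ---------------------------------------------------------------------------

def _simulate_msprime(req: SimulationRequest) -> np.ndarray:
    import msprime

    dem = req.scenario.to_demography(req.params, req.generation_time)
    rng = np.random.default_rng(req.seed)
    ms_seed = int(rng.integers(1, 2**31))
    n_ind = sum(req.sample_sizes.values())
    codes = np.empty((n_ind, req.n_loci), dtype=np.int8)

    replicates = msprime.sim_ancestry(
        samples=req.sample_sizes,
        demography=dem,
        ploidy=2,
        num_replicates=ascertainment_steps(req.n_loci),
        random_seed=ms_seed,
    )
    ind_of_node: np.ndarray | None = None

    def stream():
        nonlocal ind_of_node
        for ts in replicates:
            if ind_of_node is None:
                ind_of_node = np.asarray(ts.tables.nodes.individual)
            tree = ts.first()
            parent = tree.parent_array[: ts.num_nodes]
            times = ts.nodes_time
            lengths = np.where(parent != -1, times[parent] - times, 0.0)
            yield tree, np.cumsum(lengths)

    for j, (tree, cum) in enumerate(_metropolis_loci(stream(), req.n_loci, rng)):
        node = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        derived = np.fromiter(tree.samples(node), dtype=np.int64)
        # sample-node -> individual layout is identical across replicates
        codes[:, j] = np.bincount(ind_of_node[derived], minlength=n_ind)
    return codes


# ---------------------------------------------------------------------------
# naive discrete-lineage engine (oracle)
# ---------------------------------------------------------------------------

def _concrete_events(req: SimulationRequest):
    """Flatten the scenario into (time_in_generations, spec) tuples."""
    G = req.generation_time
    p = req.params
    out = []
    for ev in req.scenario.events:
        t = _resolve(ev.time, p) / G
        if isinstance(ev, Split):
            out.append((t, ("split", ev.derived, ev.ancestral)))
        elif isinstance(ev, Admixture):
            out.append((t, ("admix", ev.target, ev.source_a, ev.source_b,
                            _resolve(ev.proportion, p))))
        elif isinstance(ev, Bottleneck):
            d = _resolve(ev.duration, p) / G
            out.append((max(t - d, 0.0), ("size", ev.pop, _resolve(ev.size, p))))
    out.sort(key=lambda x: x[0])
    return out


def _naive_tree(req: SimulationRequest, base_sizes, events, rng):
    """One genealogy as a list of (leaf-set, birth, death) branch segments.

    Continuous-time coalescent written directly from the model:
    exponential pairwise-coalescence waiting times within each population
    (rate k(k-1)/2 per 2N generations) and event handling at epoch
    boundaries.
    """
    lineages: dict[str, list[tuple[tuple[int, ...], float]]] = {
        pop: [] for pop in base_sizes
    }
    leaf = 0
    for pop, n in req.sample_sizes.items():
        for _ in range(2 * n):
            lineages[pop].append(((leaf,), 0.0))
            leaf += 1
    sizes = dict(base_sizes)
    segments: list[tuple[tuple[int, ...], float, float]] = []
    t = 0.0
    queue = list(events)

    while sum(len(v) for v in lineages.values()) > 1:
        rates = {
            pop: len(v) * (len(v) - 1) / 2 / (2 * sizes[pop])
            for pop, v in lineages.items()
            if len(v) > 1
        }
        total_rate = sum(rates.values())
        wait = rng.exponential(1 / total_rate) if total_rate > 0 else np.inf
        next_ev = queue[0][0] if queue else np.inf
        if t + wait < next_ev:
            t += wait
            pops = list(rates)
            probs = np.array([rates[q] for q in pops]) / total_rate
            pop = pops[rng.choice(len(pops), p=probs)]
            i, k = rng.choice(len(lineages[pop]), size=2, replace=False)
            i, k = sorted((int(i), int(k)))
            (la, ba) = lineages[pop][i]
            (lb, bb) = lineages[pop][k]
            del lineages[pop][k], lineages[pop][i]
            segments.append((la, ba, t))
            segments.append((lb, bb, t))
            lineages[pop].append((la + lb, t))
        else:
            if not queue:
                raise RuntimeError(
                    f"scenario {req.scenario.label!r}: remaining lineages "
                    "cannot coalesce (disconnected root)"
                )
            t, spec = queue.pop(0)
            if spec[0] == "split":
                _, derived, ancestral = spec
                lineages[ancestral].extend(lineages[derived])
                lineages[derived] = []
            elif spec[0] == "admix":
                _, target, a, b, r = spec
                for lin in lineages[target]:
                    lineages[a if rng.random() < r else b].append(lin)
                lineages[target] = []
            else:
                _, pop, size = spec
                sizes[pop] = size
    return segments


def _simulate_naive(req: SimulationRequest) -> np.ndarray:
    rng = np.random.default_rng(req.seed)
    p = req.params
    n_ind = sum(req.sample_sizes.values())
    base_sizes = {
        pop: _resolve(size, p) for pop, size in req.scenario.populations.items()
    }
    events = _concrete_events(req)
    codes = np.empty((n_ind, req.n_loci), dtype=np.int8)

    def stream():
        while True:
            segments = _naive_tree(req, base_sizes, events, rng)
            cum = np.cumsum([d - b for _, b, d in segments])
            yield segments, cum

    for j, (segments, cum) in enumerate(
        _metropolis_loci(stream(), req.n_loci, rng)
    ):
        k = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        derived = segments[k][0]
        dosage = np.zeros(n_ind, dtype=np.int8)
        for lf in derived:
            dosage[lf // 2] += 1
        codes[:, j] = dosage
    return codes


# ---------------------------------------------------------------------------
# reference table
# ---------------------------------------------------------------------------

_PAR = "par:"
_STAT = "stat:"


@dataclass
class ReferenceTable:
    """Rows of (scenario label, parameter vector, summary statistics).

    The training data for random-forest ABC.  Parameter columns are
    prefixed ``par:`` and statistic columns ``stat:`` in the underlying
    frame so the partition survives a CSV round-trip.
    """

    data: pd.DataFrame

    @property
    def param_names(self) -> list[str]:
        return [c[len(_PAR):] for c in self.data.columns if c.startswith(_PAR)]

    @property
    def stat_names(self) -> list[str]:
        return [c[len(_STAT):] for c in self.data.columns if c.startswith(_STAT)]

    @property
    def labels(self) -> list[str]:
        return sorted(self.data["scenario"].unique())

    def __len__(self) -> int:
        return len(self.data)

    def stats_matrix(self) -> np.ndarray:
        return self.data[[_STAT + s for s in self.stat_names]].to_numpy(dtype=float)

    def scenario_column(self) -> np.ndarray:
        return self.data["scenario"].to_numpy()

    def parameter(self, name: str) -> np.ndarray:
        return self.data[_PAR + name].to_numpy(dtype=float)

    def restrict(self, label: str) -> "ReferenceTable":
        sub = self.data[self.data["scenario"] == label].reset_index(drop=True)
        if sub.empty:
            raise KeyError(f"no rows for scenario {label!r}")
        return ReferenceTable(sub.dropna(axis=1, how="all"))

    def concat(self, other: "ReferenceTable") -> "ReferenceTable":
        return ReferenceTable(
            pd.concat([self.data, other.data], ignore_index=True)
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReferenceTable":
        return cls(pd.read_csv(path))


def generate_reference_table(
    step,
    priors: PriorSpec | None = None,
    n_sims_per_scenario: int = 10_000,
    n_loci: int = 2_000,
    sample_sizes: dict[str, int] | None = None,
    seed: int = 0,
    generation_time: float = DEFAULT_GENERATION_TIME,
    engine: str = "msprime",
) -> ReferenceTable:
    """Simulate the ABC-RF training table for a ladder step.

    For every candidate scenario and every replicate: draw a parameter
    vector from that candidate's priors (or ``priors`` if given), simulate
    ``n_loci`` SNPs, and compute the summary-statistic vector.  Rows are
    reproducible per seed and generated from per-row seed streams, so the
    table can be rebuilt in chunks without changing values.
    """
    from .sumstats import stat_names as stat_name_list
    from .sumstats import summary_vector

    # a StepDefinition (>= 2 candidates, model choice) or a bare list of
    # scenarios (>= 1, e.g. a single-scenario table for parameter estimation)
    candidates = step.candidates if hasattr(step, "candidates") else list(step)
    if not candidates:
        raise ValueError("need at least one candidate scenario")
    roster = list(candidates[0].sampled)
    for c in candidates:
        if sorted(c.sampled) != sorted(roster):
            raise ValueError(
                f"candidate {c.label!r} samples {c.sampled}, expected {roster}"
            )
    if sample_sizes is None:
        sample_sizes = {p: 10 for p in roster}

    names = stat_name_list(roster)
    all_params = sorted({n for c in candidates for n in c.priors.names()})
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(candidates) * n_sims_per_scenario)

    records: list[dict] = []
    k = 0
    for cand in candidates:
        cand_priors = priors if priors is not None else cand.priors
        for rep in range(n_sims_per_scenario):
            rng = np.random.default_rng(children[k])
            k += 1
            try:
                params = cand_priors.sample(rng)
                g = simulate_dataset(
                    SimulationRequest(
                        scenario=cand,
                        params=params,
                        sample_sizes={p: sample_sizes[p] for p in roster},
                        n_loci=n_loci,
                        seed=int(rng.integers(1, 2**31)),
                        generation_time=generation_time,
                        engine=engine,
                    )
                )
                vec = summary_vector(g, roster)
            except Exception as exc:
                raise RuntimeError(
                    f"simulation failed for scenario {cand.label!r}, "
                    f"replicate {rep}: {exc}"
                ) from exc
            rec = {"scenario": cand.label}
            rec.update({_PAR + n: params.get(n, np.nan) for n in all_params})
            rec.update({_STAT + n: v for n, v in zip(names, vec.values)})
            records.append(rec)
    return ReferenceTable(pd.DataFrame.from_records(records))
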