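"""Invasion scenarios: named populations, event schedules and priors.

A :class:`DemographicScenario` is a backward-in-time event schedule over
named populations: population splits, two-source admixture foundings, and
founding bottlenecks (a transient reduction of effective size immediately
after an introduction).  Event times, sizes and admixture proportions can
be numeric literals or *parameter names* resolved against a sampled
parameter vector; :class:`PriorSpec` holds the uniform priors and strict
inequality constraints used to draw those vectors.

Times are expressed in years before sampling and converted to coalescent
generations with a configurable generation time only when a scenario is
handed to a simulation engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import yaml

Value = Union[str, float, int]

SCHEMA_VERSION = 1

DEFAULT_GENERATION_TIME = 5.0
"""Default generation time in years (colony-level generation of a
subterranean termite: several years from foundation to mature alate
production)."""


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Split:
    """Backward in time at ``time``, lineages of ``derived`` join ``ancestral``."""

    time: Value
    derived: str
    ancestral: str


@dataclass(frozen=True)
class Admixture:
    """``target`` founded at ``time`` from ``source_a`` (fraction
    ``proportion``) and ``source_b`` (the rest)."""

    time: Value
    target: str
    source_a: str
    source_b: str
    proportion: Value


@dataclass(frozen=True)
class Bottleneck:
    """``pop`` had effective size ``size`` during the ``duration`` years
    immediately after its founding at ``time`` (same time value as the
    founding event)."""

    time: Value
    pop: str
    size: Value
    duration: Value


Event = Union[Split, Admixture, Bottleneck]


def _resolve(v: Value, params: dict[str, float]) -> float:
    if isinstance(v, str):
        try:
            return float(params[v])
        except KeyError:
            raise KeyError(f"parameter {v!r} missing from parameter vector") from None
    return float(v)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Named independent Uniform(lo, hi) priors plus strict inequalities.

    ``constraints`` is a list of ``(greater, lesser)`` parameter-name
    pairs, each read as ``greater > lesser``.  Sampling is by rejection.
    """

    uniforms: dict[str, tuple[float, float]] = field(default_factory=dict)
    constraints: list[tuple[str, str]] = field(default_factory=list)

    def add(self, name: str, lo: float, hi: float) -> None:
        if not lo < hi:
            raise ValueError(f"prior {name!r}: need lo < hi, got ({lo}, {hi})")
        self.uniforms[name] = (float(lo), float(hi))

    def constrain(self, greater: str, lesser: str) -> None:
        self.constraints.append((greater, lesser))

    def validate(self) -> None:
        for name, (lo, hi) in self.uniforms.items():
            if not lo < hi:
                raise ValueError(f"prior {name!r}: lo >= hi")
        for a, b in self.constraints:
            for n in (a, b):
                if n not in self.uniforms:
                    raise ValueError(f"constraint references unknown parameter {n!r}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        adj: dict[str, list[str]] = {}
        for a, b in self.constraints:
            adj.setdefault(a, []).append(b)
        state: dict[str, int] = {}

        def visit(u: str) -> None:
            state[u] = 1
            for v in adj.get(u, []):
                if state.get(v) == 1:
                    raise ValueError("constraint graph is cyclic")
                if state.get(v) is None:
                    visit(v)
            state[u] = 2

        for u in list(adj):
            if state.get(u) is None:
                visit(u)

    def names(self) -> list[str]:
        return list(self.uniforms)

    def sample(self, rng: np.random.Generator, max_attempts: int = 1_000_000) -> dict[str, float]:
        """One parameter vector satisfying every constraint (rejection)."""
        names = self.names()
        lo = np.array([self.uniforms[n][0] for n in names])
        hi = np.array([self.uniforms[n][1] for n in names])
        pos = {n: i for i, n in enumerate(names)}
        cons = [(pos[a], pos[b]) for a, b in self.constraints]
        attempts = 0
        batch = 256
        while attempts < max_attempts:
            draws = rng.uniform(lo, hi, size=(batch, len(names)))
            ok = np.ones(batch, dtype=bool)
            for ia, ib in cons:
                ok &= draws[:, ia] > draws[:, ib]
            hits = np.flatnonzero(ok)
            if hits.size:
                return dict(zip(names, draws[hits[0]]))
            attempts += batch
        raise RuntimeError(
            f"prior constraints unsatisfied after {max_attempts} rejection attempts"
        )

    def merged_with(self, other: "PriorSpec") -> "PriorSpec":
        merged = PriorSpec(dict(self.uniforms), list(self.constraints))
        merged.uniforms.update(other.uniforms)
        merged.constraints.extend(other.constraints)
        return merged


# ---------------------------------------------------------------------------
# scenario
# ---------------------------------------------------------------------------

@dataclass
class DemographicScenario:
    """A rooted event schedule over named populations.

    ``populations`` maps population name -> stable diploid effective size
    (a numeric literal or parameter name).  ``sampled`` flags which
    populations carry present-day samples.  ``priors`` travels with the
    scenario so reference-table generation can draw its parameters.
    """

    label: str
    populations: dict[str, Value]
    events: list[Event]
    sampled: list[str] = field(default_factory=list)
    priors: PriorSpec = field(default_factory=PriorSpec)

    # -- validation ---------------------------------------------------
    def founding_events(self) -> dict[str, Event]:
        out: dict[str, Event] = {}
        for ev in self.events:
            if isinstance(ev, Split):
                out[ev.derived] = ev
            elif isinstance(ev, Admixture):
                out[ev.target] = ev
        return out

    def validate(self, params: dict[str, float] | None = None) -> list[str]:
        """Return a list of invariant violations (empty list = valid)."""
        v: list[str] = []
        founders = self.founding_events()

        for ev in self.events:
            names = [ev.time]
            if isinstance(ev, Admixture):
                names += [ev.proportion]
            if isinstance(ev, Bottleneck):
                names += [ev.size, ev.duration]
            for name in names:
                if isinstance(name, str) and params is None and name not in self.priors.uniforms:
                    v.append(f"{type(ev).__name__}: parameter {name!r} has no prior")

        # referenced populations exist
        for ev in self.events:
            refs = (
                [ev.derived, ev.ancestral] if isinstance(ev, Split)
                else [ev.target, ev.source_a, ev.source_b] if isinstance(ev, Admixture)
                else [ev.pop]
            )
            for p in refs:
                if p not in self.populations:
                    v.append(f"{type(ev).__name__}: unknown population {p!r}")

        # every population except a single root is founded exactly once
        founded = {p: 0 for p in self.populations}
        for p in founders:
            if p in founded:
                founded[p] += 1
        for ev in self.events:
            if isinstance(ev, (Split, Admixture)):
                tgt = ev.derived if isinstance(ev, Split) else ev.target
                if sum(1 for e in self.events
                       if isinstance(e, (Split, Admixture))
                       and (e.derived if isinstance(e, Split) else e.target) == tgt) > 1:
                    v.append(f"population {tgt!r} founded more than once")
                    break
        roots = [p for p, k in founded.items() if k == 0]
        if len(roots) != 1:
            v.append(
                f"scenario must have exactly one root population, found {roots!r} "
                "(disconnected or over-connected lineage graph)"
            )

        # bottlenecks attach to the founding event of the same population
        for ev in self.events:
            if isinstance(ev, Bottleneck):
                f = founders.get(ev.pop)
                if f is None:
                    v.append(f"Bottleneck on {ev.pop!r}: population has no founding event")
                elif f.time != ev.time:
                    v.append(
                        f"Bottleneck on {ev.pop!r}: time does not match its founding event"
                    )

        if params is not None:
            for ev in self.events:
                t = _resolve(ev.time, params)
                if t <= 0:
                    v.append(f"{type(ev).__name__} at non-positive time {t}")
                if isinstance(ev, Admixture):
                    r = _resolve(ev.proportion, params)
                    if not (0 < r < 1):
                        v.append(
                            f"Admixture into {ev.target!r}: proportion {r} out of range (0, 1)"
                        )
                if isinstance(ev, Bottleneck):
                    nb = _resolve(ev.size, params)
                    d = _resolve(ev.duration, params)
                    if nb < 1:
                        v.append(f"Bottleneck on {ev.pop!r}: size {nb} < 1")
                    if d < 0:
                        v.append(f"Bottleneck on {ev.pop!r}: negative duration {d}")
                    if d > t:
                        v.append(
                            f"Bottleneck on {ev.pop!r}: duration {d} extends past sampling"
                        )
            # a founded population must merge into sources that still exist
            for ev in self.events:
                if isinstance(ev, (Split, Admixture)):
                    tgt = ev.derived if isinstance(ev, Split) else ev.target
                    t = _resolve(ev.time, params)
                    srcs = (
                        [ev.ancestral] if isinstance(ev, Split)
                        else [ev.source_a, ev.source_b]
                    )
                    for s in srcs:
                        f = founders.get(s)
                        if f is not None and _resolve(f.time, params) <= t:
                            v.append(
                                f"{tgt!r} founded at {t} from {s!r}, which does not "
                                f"exist yet (founded at {_resolve(f.time, params)})"
                            )
        return v

    # -- engine-facing ------------------------------------------------
    def to_demography(
        self,
        params: dict[str, float],
        generation_time: float = DEFAULT_GENERATION_TIME,
    ):
        """Concrete :class:`msprime.Demography` with times in generations."""
        import msprime

        violations = self.validate(params)
        if violations:
            raise ValueError("invalid scenario: " + "; ".join(violations))

        dem = msprime.Demography()
        for name, size in self.populations.items():
            dem.add_population(name=name, initial_size=_resolve(size, params))

        # Foundings are encoded as lineage movements (mass migrations), not
        # msprime population splits: a source population here persists to
        # the present (it may carry samples and seed further foundings),
        # whereas msprime's split machinery would only activate it at the
        # event time and silently shift its sampling time into the past.
        events: list[tuple[float, int, dict]] = []  # (time_gen, order, spec)
        for order, ev in enumerate(self.events):
            t = _resolve(ev.time, params) / generation_time
            if isinstance(ev, Split):
                events.append((t, order, {"kind": "split", "derived": ev.derived,
                                          "ancestral": ev.ancestral}))
            elif isinstance(ev, Admixture):
                r = _resolve(ev.proportion, params)
                events.append((t, order, {"kind": "admix", "target": ev.target,
                                          "a": ev.source_a, "b": ev.source_b, "r": r}))
            else:
                d = _resolve(ev.duration, params) / generation_time
                nb = _resolve(ev.size, params)
                start = max(t - d, 0.0)
                events.append((start, order, {"kind": "size", "pop": ev.pop, "size": nb}))

        for t, _, spec in sorted(events, key=lambda x: (x[0], x[1])):
            if spec["kind"] == "split":
                dem.add_mass_migration(time=t, source=spec["derived"],
                                       dest=spec["ancestral"], proportion=1.0)
            elif spec["kind"] == "admix":
                # backward in time: each target lineage goes to source a
                # with probability r, the remainder to source b
                dem.add_mass_migration(time=t, source=spec["target"],
                                       dest=spec["a"], proportion=spec["r"])
                dem.add_mass_migration(time=t, source=spec["target"],
                                       dest=spec["b"], proportion=1.0)
            else:
                dem.add_population_parameters_change(
                    time=t, population=spec["pop"], initial_size=spec["size"]
                )
        dem.sort_events()
        return dem

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        def val(v: Value):
            return v if isinstance(v, str) else float(v)

        evs = []
        for ev in self.events:
            if isinstance(ev, Split):
                evs.append({"split": {"time": val(ev.time), "derived": ev.derived,
                                      "ancestral": ev.ancestral}})
            elif isinstance(ev, Admixture):
                evs.append({"admixture": {"time": val(ev.time), "target": ev.target,
                                          "source_a": ev.source_a, "source_b": ev.source_b,
                                          "proportion": val(ev.proportion)}})
            else:
                evs.append({"bottleneck": {"time": val(ev.time), "pop": ev.pop,
                                           "size": val(ev.size), "duration": val(ev.duration)}})
        return {
            "schema": SCHEMA_VERSION,
            "label": self.label,
            "populations": {k: val(v) for k, v in self.populations.items()},
            "sampled": list(self.sampled),
            "events": evs,
            "priors": {
                "uniforms": {k: list(v) for k, v in self.priors.uniforms.items()},
                "constraints": [list(c) for c in self.priors.constraints],
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DemographicScenario":
        if d.get("schema") != SCHEMA_VERSION:
            raise ValueError(f"unsupported scenario schema {d.get('schema')!r}")
        events: list[Event] = []
        for ev in d["events"]:
            (kind, spec), = ev.items()
            if kind == "split":
                events.append(Split(spec["time"], spec["derived"], spec["ancestral"]))
            elif kind == "admixture":
                events.append(Admixture(spec["time"], spec["target"], spec["source_a"],
                                        spec["source_b"], spec["proportion"]))
            elif kind == "bottleneck":
                events.append(Bottleneck(spec["time"], spec["pop"], spec["size"],
                                         spec["duration"]))
            else:
                raise ValueError(f"unknown event kind {kind!r}")
        priors = PriorSpec(
            {k: tuple(v) for k, v in d["priors"]["uniforms"].items()},
            [tuple(c) for c in d["priors"]["constraints"]],
        )
        return cls(label=d["label"], populations=dict(d["populations"]),
                   events=events, sampled=list(d["sampled"]), priors=priors)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "DemographicScenario":
        return cls.from_dict(yaml.safe_load(text))


def validate_scenario(
    s: DemographicScenario, params: dict[str, float] | None = None
) -> list[str]:
    """Functional alias for :meth:`DemographicScenario.validate`."""
    return s.validate(params)


def sample_parameters(
    priors: PriorSpec, seed: int | np.random.Generator, max_attempts: int = 1_000_000
) -> dict[str, float]:
    """Draw one constrained parameter vector, deterministic per seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    priors._check_acyclic()
    return priors.sample(rng, max_attempts=max_attempts)


# ---------------------------------------------------------------------------
# builder
# ---------------------------------------------------------------------------

# default prior windows (years / diploids), overridable per call
NATIVE_SIZE_PRIOR = (100.0, 100_000.0)
INTRODUCED_SIZE_PRIOR = (100.0, 50_000.0)
INTRO_TIME_PRIOR = (50.0, 300.0)
BOTTLENECK_SIZE_PRIOR = (1.0, 100.0)
BOTTLENECK_DURATION_PRIOR = (0.0, 50.0)
ADMIXTURE_PRIOR = (0.01, 0.99)


class ScenarioBuilder:
    """Compose invasion scenarios with automatically named parameters.

    Parameter naming: ``N_<pop>`` stable sizes, ``t_<pop>`` founding
    times, ``r_<pop>`` admixture proportion from the first source,
    ``Nb_<pop>`` / ``d_<pop>`` founding-bottleneck size and duration.
    """

    def __init__(self, label: str):
        self.scenario = DemographicScenario(label, {}, [], [], PriorSpec())

    def _size_param(self, pop: str, prior: tuple[float, float]) -> str:
        name = f"N_{pop}"
        self.scenario.priors.add(name, *prior)
        return name

    def native(self, pop: str, size_prior: tuple[float, float] = NATIVE_SIZE_PRIOR,
               sampled: bool = True) -> "ScenarioBuilder":
        self.scenario.populations[pop] = self._size_param(pop, size_prior)
        if sampled:
            self.scenario.sampled.append(pop)
        return self

    def ancestor(self, pop: str, derived: list[str], time_prior: tuple[float, float],
                 size_prior: tuple[float, float] = NATIVE_SIZE_PRIOR) -> "ScenarioBuilder":
        """Unsampled ancestral population into which ``derived`` merge."""
        self.scenario.populations[pop] = self._size_param(pop, size_prior)
        tname = f"t_{pop}"
        self.scenario.priors.add(tname, *time_prior)
        for d in derived:
            self.scenario.events.append(Split(tname, d, pop))
        return self

    def introduced(
        self,
        pop: str,
        sources: tuple[str, ...],
        time_prior: tuple[float, float] = INTRO_TIME_PRIOR,
        size_prior: tuple[float, float] = INTRODUCED_SIZE_PRIOR,
        admixture_prior: tuple[float, float] = ADMIXTURE_PRIOR,
        bottleneck: bool = True,
        sampled: bool = True,
    ) -> "ScenarioBuilder":
        """Sampled (or staging) population founded from one or two sources."""
        self.scenario.populations[pop] = self._size_param(pop, size_prior)
        if sampled:
            self.scenario.sampled.append(pop)
        tname = f"t_{pop}"
        self.scenario.priors.add(tname, *time_prior)
        if len(sources) == 1:
            self.scenario.events.append(Split(tname, pop, sources[0]))
        elif len(sources) == 2:
            rname = f"r_{pop}"
            self.scenario.priors.add(rname, *admixture_prior)
            self.scenario.events.append(
                Admixture(tname, pop, sources[0], sources[1], rname)
            )
        else:
            raise ValueError("introduced population needs one or two sources")
        if bottleneck:
            nb, d = f"Nb_{pop}", f"d_{pop}"
            self.scenario.priors.add(nb, *BOTTLENECK_SIZE_PRIOR)
            self.scenario.priors.add(d, *BOTTLENECK_DURATION_PRIOR)
            self.scenario.events.append(Bottleneck(tname, pop, nb, d))
        return self

    def before(self, earlier_pop_or_param: str, later_pop_or_param: str) -> "ScenarioBuilder":
        """Require the first founding to predate the second (backward time:
        ``t_first > t_second``)."""
        def t(x: str) -> str:
            return x if x.startswith("t_") else f"t_{x}"
        self.scenario.priors.constrain(t(earlier_pop_or_param), t(later_pop_or_param))
        return self

    def build(self) -> DemographicScenario:
        s = self.scenario
        violations = s.validate()
        if violations:
            raise ValueError(f"scenario {s.label!r} invalid: " + "; ".join(violations))
        s.priors._check_acyclic()
        return s
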