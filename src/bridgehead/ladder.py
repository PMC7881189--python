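"""The six-step invasion-history scenario ladder.

Each step pools sampling localities into scenario populations and pits a
small roster of candidate invasion scenarios against each other.  Steps 1
through 3 ask which native region(s) seeded the introduced US range; steps
4 and 5 separate Hawaii from the mainland and test for a Hawaiian
bridgehead; step 6 tests a distinct introduction into Florida.  Sub-steps
2A/2B probe the regional assignment of the two Japanese populations and
sub-step 4 splits the mainland into Florida versus Louisiana/Texas.

Candidate sets are the natural enumeration (each introduced population
from each single source or each pairwise admixture, with or without a
bridgehead); users can supply their own rosters as scenario files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .scenarios import DemographicScenario, ScenarioBuilder

__all__ = [
    "StepDefinition",
    "study_ladder",
    "EXCLUDED_LOCALITIES",
    "SOUTHCENTRAL_LOCALITIES",
    "HONGKONG_REGION_LOCALITIES",
    "SUB_EASTERN_LOCALITIES",
    "US_LOCALITIES",
]

# sampling localities ------------------------------------------------------

SOUTHCENTRAL_LOCALITIES = ["Beihai", "Changsha", "Guilin", "Hainan", "Hengyang", "Nanning"]
HONGKONG_REGION_LOCALITIES = ["HongKong", "Jieyang", "Lufeng", "Okinawa", "Taiwan", "Xiamen"]
SUB_EASTERN_LOCALITIES = ["Fuzhou", "Hangzhou", "MainlandJapan", "Wenzhou"]
US_LOCALITIES = ["Hawaii", "Texas", "Louisiana", "Florida"]

EXCLUDED_LOCALITIES = ["Xinyu", "Mississippi"]
"""Single-sample localities left out of every ladder step."""

# prior windows specific to the ladder (years)
NATIVE_SUBSPLIT_TIME = (350.0, 10_000.0)   # Hong Kong region vs sub-eastern Asia
NATIVE_ROOT_TIME = (500.0, 20_000.0)       # eastern Asia vs southcentral China
JAPAN_INTRO_TIME = (50.0, 2_000.0)         # Japanese populations (pre-modern trade)


@dataclass
class StepDefinition:
    """One ladder step: a locality pooling and >= 2 candidate scenarios."""

    step_id: str
    pooling: dict[str, str]
    candidates: list[DemographicScenario]
    description: str = ""
    required: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.candidates) < 2:
            raise ValueError(f"step {self.step_id}: need >= 2 candidate scenarios")
        if not self.required:
            self.required = sorted({p for c in self.candidates for p in c.sampled})
        missing = [p for p in self.required if p not in self.pooling.values()]
        if missing:
            raise ValueError(
                f"step {self.step_id}: pooling does not cover population(s) {missing}"
            )

    def labels(self) -> list[str]:
        return [c.label for c in self.candidates]

    # -- serialization (same schema-tagged format as scenarios) --------
    def to_dict(self) -> dict:
        from .scenarios import SCHEMA_VERSION

        return {
            "schema": SCHEMA_VERSION,
            "step_id": self.step_id,
            "description": self.description,
            "pooling": dict(self.pooling),
            "required": list(self.required),
            "candidates": [c.to_dict() for c in self.candidates],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StepDefinition":
        from .scenarios import SCHEMA_VERSION

        if d.get("schema") != SCHEMA_VERSION:
            raise ValueError(f"unsupported step schema {d.get('schema')!r}")
        return cls(
            step_id=d["step_id"],
            pooling=dict(d["pooling"]),
            candidates=[DemographicScenario.from_dict(c) for c in d["candidates"]],
            description=d.get("description", ""),
            required=list(d.get("required", [])),
        )

    def to_yaml(self) -> str:
        import yaml

        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "StepDefinition":
        import yaml

        return cls.from_dict(yaml.safe_load(text))


def _pooling(groups: dict[str, list[str]]) -> dict[str, str]:
    """Locality -> scenario-population map, with identity aliases so data
    already carrying pooled labels pass through."""
    out: dict[str, str] = {}
    for pooled, localities in groups.items():
        for loc in localities:
            out[loc] = pooled
        out.setdefault(pooled, pooled)
    return out


# scenario-population shorthand
SC = "southcentral"
EA = "eastern_asia"
HKR = "hongkong_region"
SEA = "sub_eastern_asia"
US = "us"
HI = "hawaii"
ML = "mainland_us"
LATX = "latx"
FL = "florida"


def _two_region_natives(b: ScenarioBuilder) -> ScenarioBuilder:
    b.native(SC).native(EA)
    b.ancestor("root", [EA, SC], NATIVE_ROOT_TIME)
    return b


def _three_region_natives(b: ScenarioBuilder, hk: str = HKR, sea: str = SEA) -> ScenarioBuilder:
    b.native(SC).native(hk).native(sea)
    b.ancestor("eastern_asia_anc", [hk, sea], NATIVE_SUBSPLIT_TIME)
    b.ancestor("root", ["eastern_asia_anc", SC], NATIVE_ROOT_TIME)
    b.scenario.priors.constrain("t_root", "t_eastern_asia_anc")
    return b


# ---------------------------------------------------------------------------
# step builders
# ---------------------------------------------------------------------------

def _step1() -> StepDefinition:
    def cand(label: str, sources: tuple[str, ...]) -> DemographicScenario:
        b = ScenarioBuilder(label)
        _two_region_natives(b)
        b.introduced(US, sources)
        return b.build()

    return StepDefinition(
        step_id="1",
        pooling=_pooling({
            SC: SOUTHCENTRAL_LOCALITIES,
            EA: HONGKONG_REGION_LOCALITIES + SUB_EASTERN_LOCALITIES + [HKR, SEA],
            US: US_LOCALITIES + [HI, LATX, FL, ML],
        }),
        candidates=[
            cand("S1a", (SC,)),
            cand("S1b", (EA,)),
            cand("S1c", (EA, SC)),
        ],
        description="Source of the pooled US introduction: southcentral China, "
                    "eastern Asia, or admixture of both.",
    )


def _step2() -> StepDefinition:
    def cand(label: str, sources: tuple[str, ...]) -> DemographicScenario:
        b = ScenarioBuilder(label)
        _three_region_natives(b)
        b.introduced(US, sources)
        return b.build()

    return StepDefinition(
        step_id="2",
        pooling=_pooling({
            SC: SOUTHCENTRAL_LOCALITIES,
            HKR: HONGKONG_REGION_LOCALITIES,
            SEA: SUB_EASTERN_LOCALITIES,
            US: US_LOCALITIES + [HI, LATX, FL, ML],
        }),
        candidates=[
            cand("S2a", (HKR,)),
            cand("S2b", (SEA,)),
            cand("S2c", (HKR, SEA)),
        ],
        description="Which eastern Asian sub-region seeded the US: the Hong Kong "
                    "region, sub-eastern Asia, or admixture of both.",
    )


def _step2a() -> StepDefinition:
    hk_core = "hongkong_core"

    def cand(label: str, source: str) -> DemographicScenario:
        b = ScenarioBuilder(label)
        _three_region_natives(b, hk=hk_core)
        b.introduced("okinawa", (source,), time_prior=JAPAN_INTRO_TIME)
        return b.build()

    return StepDefinition(
        step_id="2A",
        pooling=_pooling({
            SC: SOUTHCENTRAL_LOCALITIES,
            hk_core: [l for l in HONGKONG_REGION_LOCALITIES if l != "Okinawa"] + [HKR],
            SEA: SUB_EASTERN_LOCALITIES,
            "okinawa": ["Okinawa"],
        }),
        candidates=[cand("S2Aa", hk_core), cand("S2Ab", SEA)],
        description="Regional assignment of Okinawa: founded out of the Hong Kong "
                    "region core or out of sub-eastern Asia.",
    )


def _step2b() -> StepDefinition:
    sea_core = "sub_eastern_core"

    def cand(label: str, source: str) -> DemographicScenario:
        b = ScenarioBuilder(label)
        _three_region_natives(b, sea=sea_core)
        b.introduced("mainland_japan", (source,), time_prior=JAPAN_INTRO_TIME)
        return b.build()

    return StepDefinition(
        step_id="2B",
        pooling=_pooling({
            SC: SOUTHCENTRAL_LOCALITIES,
            HKR: HONGKONG_REGION_LOCALITIES,
            sea_core: [l for l in SUB_EASTERN_LOCALITIES if l != "MainlandJapan"] + [SEA],
            "mainland_japan": ["MainlandJapan"],
        }),
        candidates=[cand("S2Ba", sea_core), cand("S2Bb", HKR)],
        description="Regional assignment of mainland Japan: founded out of "
                    "sub-eastern Asia core or out of the Hong Kong region.",
    )


def _step3() -> StepDefinition:
    def two_way(label: str) -> DemographicScenario:
        b = ScenarioBuilder(label)
        _three_region_natives(b)
        b.introduced(US, (HKR, SEA))
        return b.build()

    def three_way(label: str, first: tuple[str, str], second: str) -> DemographicScenario:
        b = ScenarioBuilder(label)
        _three_region_natives(b)
        b.introduced("stage", first, sampled=False, bottleneck=False)
        b.introduced(US, ("stage", second))
        b.before("stage", US)
        return b.build()

    return StepDefinition(
        step_id="3",
        pooling=_pooling({
            SC: SOUTHCENTRAL_LOCALITIES,
            HKR: HONGKONG_REGION_LOCALITIES,
            SEA: SUB_EASTERN_LOCALITIES,
            US: US_LOCALITIES + [HI, LATX, FL, ML],
        }),
        candidates=[
            two_way("S3a"),
            three_way("S3b", (HKR, SEA), SC),
            three_way("S3c", (HKR, SC), SEA),
            three_way("S3d", (SEA, SC), HKR),
        ],
        description="Two-source versus three-source admixture into the pooled US, "
                    "for every ordering of the first admixture event.",
    )


def _step4() -> StepDefinition:
    def cand(label: str, hi_src: tuple[str, ...], ml_src: tuple[str, ...]) -> DemographicScenario:
        b = ScenarioBuilder(label)
        _two_region_natives(b)
        b.introduced(HI, hi_src)
        b.introduced(ML, ml_src)
        b.before(HI, ML)
        return b.build()

    return StepDefinition(
        step_id="4",
        pooling=_pooling({
            SC: SOUTHCENTRAL_LOCALITIES,
            EA: HONGKONG_REGION_LOCALITIES + SUB_EASTERN_LOCALITIES + [HKR, SEA],
            HI: ["Hawaii"],
            ML: ["Texas", "Louisiana", "Florida", LATX, FL],
        }),
        candidates=[
            cand("S4a", (EA,), (EA,)),
            cand("S4b", (SC,), (SC,)),
            cand("S4c", (EA,), (SC,)),
            cand("S4d", (SC,), (EA,)),
            cand("S4e", (EA, SC), (EA, SC)),
            cand("S4f", (EA,), (HI,)),
            cand("S4g", (EA, SC), (HI,)),
        ],
        description="Origin of Hawaii versus the pooled mainland, including "
                    "Hawaiian-bridgehead scenarios; Hawaii constrained to "
                    "predate the mainland introduction.",
    )


def _sub_step4() -> StepDefinition:
    def cand(label: str, latx_src: str) -> DemographicScenario:
        b = ScenarioBuilder(label)
        _two_region_natives(b)
        b.introduced(HI, (EA, SC))
        b.introduced(LATX, (latx_src,))
        b.introduced(FL, (LATX,))
        b.before(HI, LATX)
        b.before(LATX, FL)
        return b.build()

    return StepDefinition(
        step_id="sub4",
        pooling=_pooling({
            SC: SOUTHCENTRAL_LOCALITIES,
            EA: HONGKONG_REGION_LOCALITIES + SUB_EASTERN_LOCALITIES + [HKR, SEA],
            HI: ["Hawaii"],
            LATX: ["Texas", "Louisiana"],
            FL: ["Florida"],
        }),
        candidates=[cand("Sub4a", EA), cand("Sub4b", SC), cand("Sub4c", HI)],
        description="With the mainland split into Florida and Louisiana/Texas: "
                    "source of Louisiana/Texas (native regions or Hawaiian "
                    "bridgehead).",
    )


def _step5() -> StepDefinition:
    def cand(label: str, hi_src: tuple[str, ...]) -> DemographicScenario:
        b = ScenarioBuilder(label)
        _three_region_natives(b)
        b.introduced(HI, hi_src)
        b.introduced(ML, (HI,))
        b.before(HI, ML)
        return b.build()

    return StepDefinition(
        step_id="5",
        pooling=_pooling({
            SC: SOUTHCENTRAL_LOCALITIES,
            HKR: HONGKONG_REGION_LOCALITIES,
            SEA: SUB_EASTERN_LOCALITIES,
            HI: ["Hawaii"],
            ML: ["Texas", "Louisiana", "Florida", LATX, FL],
        }),
        candidates=[
            cand("S5a", (HKR,)),
            cand("S5b", (SEA,)),
            cand("S5c", (HKR, SEA)),
        ],
        description="With the Hong Kong region separated again: which eastern "
                    "Asian sub-region(s) seeded the Hawaiian bridgehead.",
    )


def _step6() -> StepDefinition:
    def cand(label: str, fl_src: tuple[str, ...]) -> DemographicScenario:
        b = ScenarioBuilder(label)
        _three_region_natives(b)
        b.introduced(HI, (HKR, SEA))
        b.introduced(LATX, (HI,))
        b.introduced(FL, fl_src)
        b.before(HI, LATX)
        b.before(LATX, FL)
        return b.build()

    return StepDefinition(
        step_id="6",
        pooling=_pooling({
            SC: SOUTHCENTRAL_LOCALITIES,
            HKR: HONGKONG_REGION_LOCALITIES,
            SEA: SUB_EASTERN_LOCALITIES,
            HI: ["Hawaii"],
            LATX: ["Texas", "Louisiana"],
            FL: ["Florida"],
        }),
        candidates=[
            cand("S6a", (LATX,)),
            cand("S6b", (SC,)),
            cand("S6c", (LATX, SC)),
        ],
        description="Distinct introduction into Florida: from Louisiana/Texas "
                    "alone, from southcentral China alone, or admixture of both, "
                    "on top of the admixed Hawaiian bridgehead.",
    )


def study_ladder() -> list[StepDefinition]:
    """The full step ladder in execution order (1, 2, 2A, 2B, 3, 4, sub4, 5, 6)."""
    return [
        _step1(), _step2(), _step2a(), _step2b(), _step3(),
        _step4(), _sub_step4(), _step5(), _step6(),
    ]


def final_scenario() -> DemographicScenario:
    """The winning step-6 topology (admixed Hawaiian bridgehead plus a
    separate southcentral-China contribution to Florida)."""
    return _step6().candidates[2]
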