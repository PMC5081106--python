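"""Domain types shared by the simulation, harmonisation and modelling stages."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

SEXES = ("female", "male")

#: Diabetes definitions a survey stratum can report. PRIMARY_FPG7 is the
#: harmonisation target: fasting plasma glucose >= 7.0 mmol/L, or a history of
#: diagnosed diabetes, or use of insulin / oral hypoglycaemic drugs.
PRIMARY_FPG7 = "PRIMARY_FPG7"
OGTT_11_1 = "OGTT_11_1"
HBA1C_6_5 = "HBA1C_6_5"
MEAN_FPG = "MEAN_FPG"


def fpg_cutoff(threshold_mmol_l: float) -> str:
    """Definition tag for an FPG-based cutoff other than 7.0 mmol/L."""
    return f"FPG_CUTOFF_{threshold_mmol_l:g}"


SCOPES = ("national", "subnational", "community")
URBANICITIES = ("mixed", "urban_only", "rural_only")

#: Adult age groups used for populations, truth surfaces and standardisation:
#: 18-19, then five-year bands 20-24 ... 75-79, and 80+. Half-open [lo, hi).
AGE_GROUPS: tuple[tuple[int, int], ...] = ((18, 20),) + tuple(
    (lo, lo + 5) for lo in range(20, 80, 5)
) + ((80, 200),)


def age_group_midpoint(lo: int, hi: int) -> float:
    """Representative age of a group; the open-ended 80+ group uses 82.5."""
    if hi > 100:
        return 82.5
    return 0.5 * (lo + hi)


AGE_MIDPOINTS = np.array([age_group_midpoint(lo, hi) for lo, hi in AGE_GROUPS])


def age_groups_in_range(age_lo: int, age_hi: int) -> list[int]:
    """Indices of the canonical age groups fully contained in [age_lo, age_hi)."""
    out = []
    for i, (lo, hi) in enumerate(AGE_GROUPS):
        if lo >= age_lo and (hi <= age_hi or (hi > 100 and age_hi > 100)):
            out.append(i)
    return out


@dataclass(frozen=True)
class HierarchySpec:
    """Country -> region -> super-region nesting with an implied world root."""

    countries: tuple[tuple[str, str, str], ...]  # (country, region, super_region)

    def __post_init__(self):
        ids = [c for c, _, _ in self.countries]
        if len(ids) != len(set(ids)):
            raise ValueError("country ids must be unique")
        region_to_super: dict[str, str] = {}
        for _, r, s in self.countries:
            if region_to_super.setdefault(r, s) != s:
                raise ValueError(f"region {r!r} mapped to multiple super-regions")

    @property
    def country_ids(self) -> list[str]:
        return [c for c, _, _ in self.countries]

    @property
    def region_of(self) -> dict[str, str]:
        return {c: r for c, r, _ in self.countries}

    @property
    def super_region_of_region(self) -> dict[str, str]:
        return {r: s for _, r, s in self.countries}

    @property
    def region_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, r, _ in self.countries:
            seen.setdefault(r)
        return list(seen)

    @property
    def super_region_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, _, s in self.countries:
            seen.setdefault(s)
        return list(seen)

    def countries_in_region(self, region: str) -> list[str]:
        return [c for c, r, _ in self.countries if r == region]


@dataclass
class SurveyDatapoint:
    """One sex/age-stratum prevalence observation with its metadata.

    ``se`` is the standard error of ``prevalence`` on the proportion scale;
    when omitted it is derived from binomial counts at read time.
    """

    study_id: str
    country_id: str
    mid_year: int
    sex: str
    age_lo: int
    age_hi: int
    n_examined: int
    prevalence: float
    se: float
    definition: str = PRIMARY_FPG7
    scope: str = "national"
    urbanicity: str = "mixed"
    study_urban_fraction: float = float("nan")

    def __post_init__(self):
        if self.age_lo < 18:
            raise ValueError("age_lo must be >= 18")
        # MEAN_FPG datapoints carry a mean concentration in mmol/L in the
        # value field; all other definitions carry a proportion.
        if self.definition != MEAN_FPG and not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.n_examined < 1:
            raise ValueError("n_examined must be >= 1")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if self.scope not in SCOPES:
            raise ValueError(f"scope must be one of {SCOPES}")
        if self.urbanicity not in URBANICITIES:
            raise ValueError(f"urbanicity must be one of {URBANICITIES}")

    def copy(self, **changes) -> "SurveyDatapoint":
        return replace(self, **changes)


@dataclass
class PairedObservation(SurveyDatapoint):
    """A stratum with prevalence under both the primary and one alternative
    definition, computed from the same examined individuals.

    ``prevalence``/``definition`` describe the alternative (source) measure;
    for MEAN_FPG sources ``prevalence`` holds the mean FPG in mmol/L instead
    of a proportion. ``primary_prevalence`` is the same stratum under the
    primary outcome.
    """

    primary_prevalence: float = float("nan")

    def __post_init__(self):
        super().__post_init__()
        if not 0.0 <= self.primary_prevalence <= 1.0:
            raise ValueError("primary_prevalence must lie in [0, 1]")


@dataclass
class StandardPopulation:
    """Age-group weights used for direct age standardisation."""

    weights: dict[tuple[int, int], float]
    provenance: str = ""

    def __post_init__(self):
        total = float(sum(self.weights.values()))
        if total <= 0:
            raise ValueError("standard population weights must sum to > 0")
        self.weights = {k: v / total for k, v in self.weights.items()}

    def vector(self, age_groups=None) -> np.ndarray:
        if age_groups is None:
            age_groups = list(self.weights)
        try:
            w = np.array([self.weights[g] for g in age_groups], dtype=float)
        except KeyError as e:  # pragma: no cover - message only
            raise KeyError(f"standard population missing age group {e}") from e
        return w / w.sum()


@dataclass
class DecompositionResult:
    """Change in case counts split into growth/ageing, prevalence and
    interaction components (all in persons)."""

    total_change: float
    component_growth_ageing: float
    component_prevalence: float
    component_interaction: float

    @property
    def shares(self) -> dict[str, float]:
        """Each component over the component sum, in percent."""
        s = (
            self.component_growth_ageing
            + self.component_prevalence
            + self.component_interaction
        )
        return {
            "growth_ageing": 100.0 * self.component_growth_ageing / s,
            "prevalence": 100.0 * self.component_prevalence / s,
            "interaction": 100.0 * self.component_interaction / s,
        }


@dataclass
class TargetAssessment:
    """Posterior assessment of the 2025 global diabetes target for one unit."""

    unit: str
    sex: str
    probability_met: float
    projected_2025: np.ndarray
    baseline_2010: np.ndarray

    def __post_init__(self):
        if not 0.0 <= self.probability_met <= 1.0:
            raise ValueError("probability_met must lie in [0, 1]")


@dataclass
class ValidationReport:
    """Hold-out validation summary: residuals are posterior-mean estimate
    minus withheld observation, in percentage points."""

    median_error: float
    median_absolute_error: float
    coverage_95: float
    residuals: "object"  # pandas.DataFrame, one row per withheld stratum
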