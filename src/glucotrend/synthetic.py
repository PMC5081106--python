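"""Synthetic world and survey generator.

Builds a ground-truth world — a country/region/super-region hierarchy with
known probit-scale prevalence surfaces, country covariates and populations —
and simulates population-based health-examination surveys from it: national,
subnational and community studies, rural/urban selectivity, several
biomarker-based diabetes definitions, binomial sampling error, and
scope-dependent non-sampling error. The generating parameters are retained on
the returned object so parameter-recovery tests know the answers.

The truth surface is drawn from the same structural family the trend model
assumes: a global level and linear trend, nested hierarchical deviations in
level and slope, smooth non-linear year components (reduced-rank second-order
random-walk smooths), an increasing age profile whose steepness grows with
the country-year level, and linear effects of country covariates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .transforms import binomial_se, inv_probit, probit
from .types import (
    AGE_GROUPS,
    AGE_MIDPOINTS,
    HBA1C_6_5,
    MEAN_FPG,
    OGTT_11_1,
    PRIMARY_FPG7,
    SEXES,
    HierarchySpec,
    PairedObservation,
    StandardPopulation,
    SurveyDatapoint,
    age_groups_in_range,
    fpg_cutoff,
)

COVARIATE_COLUMNS = (
    "education_years",
    "urbanisation",
    "food_score",
    "mean_bmi",
    "log_income",
)

#: Covariates that enter the truth surface (log_income is emitted for the
#: cross-walk regressions but does not drive true prevalence).
TRUTH_COVARIATES = ("education_years", "urbanisation", "food_score", "mean_bmi")


@dataclass
class DefinitionMap:
    """Probit-scale link between an alternative definition and the primary
    outcome: probit(primary) = intercept + slope * source_scale + covariate
    terms + interactions + Normal(0, noise_sd).

    For MEAN_FPG sources ``source_scale`` is mean FPG in mmol/L centred at
    ``mean_center``; for all others it is probit(source prevalence).
    """

    intercept: float
    slope: float
    age_coef: float = 0.0  # per decade of (age - 50)
    sex_coef: float = 0.0  # male minus female
    year_coef: float = 0.0  # per decade of centred year
    income_coef: float = 0.0  # per unit log income (centred)
    interactions: dict = field(default_factory=dict)  # e.g. {"source:age": 0.3}
    noise_sd: float = 0.08
    mean_center: float = 5.6  # mmol/L, MEAN_FPG only


def default_definition_maps() -> dict[str, DefinitionMap]:
    """Plausible biomarker relationships (prevalence based on 2hOGTT runs
    higher than FPG-based prevalence; a 7.8 mmol/L FPG cutoff runs lower)."""
    return {
        OGTT_11_1: DefinitionMap(intercept=-0.18, slope=0.95),
        HBA1C_6_5: DefinitionMap(intercept=0.05, slope=0.95),
        fpg_cutoff(7.8): DefinitionMap(intercept=0.22, slope=1.0),
        MEAN_FPG: DefinitionMap(intercept=-1.5, slope=1.1, noise_sd=0.12),
    }


@dataclass
class WorldConfig:
    """Configuration of the synthetic world's generative process.

    Hierarchy sizes are free; the probit-scale defaults produce adult
    prevalences rising from roughly 4-5% to 8-10% over 1980-2014, in line
    with population-based global estimates for this period.
    """

    n_super_regions: int = 2
    n_regions_per_super: int = 2
    n_countries_per_region: int = 3
    year_start: int = 1980
    year_end: int = 2014
    sexes: tuple[str, ...] = SEXES

    # global level and trend on the probit scale (age-standardised)
    base_level: float = -1.55
    trend_per_decade: float = 0.12
    sex_level_offset: float = 0.04  # male minus female at mid-year
    sex_trend_offset: float = 0.02  # per decade

    # hierarchical deviation SDs (probit scale; slopes per decade)
    sd_super_intercept: float = 0.15
    sd_region_intercept: float = 0.10
    sd_country_intercept: float = 0.10
    sd_super_slope: float = 0.05
    sd_region_slope: float = 0.04
    sd_country_slope: float = 0.04

    # smooth non-linear year components (reduced-rank RW2 wiggle)
    sd_nonlinear: dict = field(
        default_factory=lambda: {
            "world": 0.04,
            "super_region": 0.03,
            "region": 0.03,
            "country": 0.03,
        }
    )
    nonlinear_rank: int = 4

    # age profile: logistic rise with age, steeper where level is higher
    age_amplitude: float = 0.85
    age_steepness: float = 0.25  # multiplier slope per probit unit of level

    # covariate effects per SD of the z-scored covariate
    beta_education: float = -0.02
    beta_urbanisation: float = 0.04
    beta_food: float = 0.03
    beta_bmi: float = 0.08

    # probit-scale urban minus rural gap, constant over age
    rural_urban_gap: float = 0.25

    definition_maps: dict = field(default_factory=default_definition_maps)

    def validate(self):
        if self.n_super_regions < 1 or self.n_regions_per_super < 1 or (
            self.n_countries_per_region < 1
        ):
            raise ValueError("hierarchy must have >= 1 unit at every level")
        if self.year_end - self.year_start < 1:
            raise ValueError("year span must cover at least 2 years")


def _age_profile(amplitude: float) -> np.ndarray:
    """Centred increasing age profile over the canonical age groups."""
    g = 1.0 / (1.0 + np.exp(-(AGE_MIDPOINTS - 50.0) / 12.0))
    w = who_standard_population().vector()
    return amplitude * (g - float(w @ g))


def rw2_basis(n_years: int, rank: int) -> np.ndarray:
    """Reduced-rank spectral basis of a second-order random walk.

    Eigenvectors of the RW2 structure matrix with positive eigenvalues,
    scaled by 1/sqrt(eigenvalue) so iid coefficients give an RW2 smooth; the
    constant and linear null space is excluded (those directions are carried
    by explicit intercept and slope terms). The basis is rescaled to unit
    average marginal variance across years, so a coefficient SD parameter is
    the typical size of the smooth itself rather than of its innovations.
    """
    D = np.zeros((n_years - 2, n_years))
    for i in range(n_years - 2):
        D[i, i : i + 3] = (1.0, -2.0, 1.0)
    K = D.T @ D
    vals, vecs = np.linalg.eigh(K)
    pos = vals > 1e-8
    vals, vecs = vals[pos], vecs[:, pos]
    order = np.argsort(vals)  # smoothest first
    vals, vecs = vals[order], vecs[:, order]
    rank = min(rank, len(vals))
    B = vecs[:, :rank] / np.sqrt(vals[:rank])
    return B / np.sqrt((B**2).sum(axis=1).mean())


@dataclass
class WorldTruth:
    """Synthetic ground truth: hierarchy, true probit prevalence surfaces,
    covariates, populations, and the parameters that generated them."""

    hierarchy: HierarchySpec
    years: np.ndarray  # calendar years
    sexes: tuple[str, ...]
    true_probit: np.ndarray  # (country, year, sex, age) mixed-population scale
    covariates: "object"  # DataFrame with country_id, year, covariate columns
    population: np.ndarray  # (country, year, sex, age) persons
    urbanisation: np.ndarray  # (country, year) fraction urban
    params: dict
    config: WorldConfig
    seed: int

    def _cidx(self, country_id: str) -> int:
        try:
            return self.hierarchy.country_ids.index(country_id)
        except ValueError:
            raise KeyError(f"unknown country {country_id!r}") from None

    def _yidx(self, year: int) -> int:
        if not self.years[0] <= year <= self.years[-1]:
            raise KeyError(f"year {year} outside world range")
        return int(year - self.years[0])

    def _sidx(self, sex: str) -> int:
        try:
            return self.sexes.index(sex)
        except ValueError:
            raise KeyError(f"unknown sex {sex!r}") from None

    def true_prevalence(self, country_id, year, sex) -> np.ndarray:
        """True mixed-population prevalence by canonical age group."""
        z = self.true_probit[self._cidx(country_id), self._yidx(year), self._sidx(sex)]
        return inv_probit(z)

    def stratum_probit(
        self, country_id, year, sex, age_lo, age_hi, urban_fraction=None
    ) -> float:
        """Population-weighted probit-scale prevalence of an age stratum.

        ``urban_fraction`` shifts the surface by the world's rural-urban gap
        times (study urban fraction - country urbanisation); None means a
        representatively mixed sample.
        """
        groups = age_groups_in_range(age_lo, age_hi)
        if not groups:
            raise ValueError(
                f"stratum [{age_lo}, {age_hi}) covers no canonical age group"
            )
        ci, yi, si = self._cidx(country_id), self._yidx(year), self._sidx(sex)
        z = self.true_probit[ci, yi, si, groups]
        pop = self.population[ci, yi, si, groups]
        w = pop / pop.sum()
        val = float(w @ z)
        if urban_fraction is not None:
            val += self.config.rural_urban_gap * (
                urban_fraction - self.urbanisation[ci, yi]
            )
        return val

    def true_summary(self, country_id, year, sex, weights: StandardPopulation) -> float:
        """Age-standardised true prevalence: exact weighted sum over groups."""
        prev = self.true_prevalence(country_id, year, sex)
        return float(weights.vector() @ prev)


def who_standard_population() -> StandardPopulation:
    """WHO world standard population restricted to adults (packaged fixture).

    The fixture splits the 15-19 weight proportionally to single years of
    age for the 18-19 group, merges 80-84 and 85+ into 80+, and the loader
    renormalises over ages >= 18.
    """
    from .io import load_standard_population

    return load_standard_population()


def build_world(config: WorldConfig | None = None, seed: int = 0) -> WorldTruth:
    """Draw a ground-truth world from the configured generative process."""
    import pandas as pd

    config = config or WorldConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))

    countries = []
    for s in range(config.n_super_regions):
        for r in range(config.n_regions_per_super):
            for c in range(config.n_countries_per_region):
                countries.append(
                    (f"C{s}{r}{c}", f"R{s}{r}", f"S{s}")
                )
    hierarchy = HierarchySpec(tuple(countries))
    C = len(countries)
    years = np.arange(config.year_start, config.year_end + 1)
    T = len(years)
    nsex, nage = len(config.sexes), len(AGE_GROUPS)
    t_dec = (years - years.mean()) / 10.0

    sr_ids = hierarchy.super_region_ids
    r_ids = hierarchy.region_ids
    # hierarchical level and slope deviations
    a_s = rng.normal(0, config.sd_super_intercept, len(sr_ids))
    b_s = rng.normal(0, config.sd_super_slope, len(sr_ids))
    a_r = rng.normal(0, config.sd_region_intercept, len(r_ids))
    b_r = rng.normal(0, config.sd_region_slope, len(r_ids))
    a_c = rng.normal(0, config.sd_country_intercept, C)
    b_c = rng.normal(0, config.sd_country_slope, C)

    basis = rw2_basis(T, config.nonlinear_rank)
    rank = basis.shape[1]
    sdn = config.sd_nonlinear
    w_world = basis @ rng.normal(0, sdn.get("world", 0.0), rank)
    w_s = basis @ rng.normal(0, sdn.get("super_region", 0.0), (rank, len(sr_ids)))
    w_r = basis @ rng.normal(0, sdn.get("region", 0.0), (rank, len(r_ids)))
    w_c = basis @ rng.normal(0, sdn.get("country", 0.0), (rank, C))

    # covariates: smooth country trajectories
    rows = []
    urb = np.zeros((C, T))
    for ci, (cid, _, _) in enumerate(countries):
        edu0 = rng.uniform(3.0, 8.0)
        edu1 = edu0 + rng.uniform(1.5, 5.0)
        u0 = rng.uniform(0.2, 0.5)
        u1 = min(0.95, u0 + rng.uniform(0.1, 0.4))
        bmi0 = rng.uniform(23.0, 25.5)
        bmi1 = bmi0 + rng.uniform(0.8, 3.0)
        inc0 = rng.uniform(7.5, 10.0)
        inc1 = inc0 + rng.uniform(0.2, 1.2)
        phase = rng.uniform(0, 2 * np.pi)
        frac = (years - years[0]) / (years[-1] - years[0])
        logistic = 1.0 / (1.0 + np.exp(-6.0 * (frac - 0.5)))
        urb[ci] = u0 + (u1 - u0) * logistic
        food = 0.6 * np.sin(2 * np.pi * frac + phase) + rng.normal(0, 0.3) + frac
        for ti, yr in enumerate(years):
            rows.append(
                {
                    "country_id": cid,
                    "year": int(yr),
                    "education_years": edu0 + (edu1 - edu0) * frac[ti],
                    "urbanisation": urb[ci, ti],
                    "food_score": food[ti],
                    "mean_bmi": bmi0 + (bmi1 - bmi0) * frac[ti],
                    "log_income": inc0 + (inc1 - inc0) * frac[ti],
                }
            )
    covariates = pd.DataFrame(rows)

    betas = {
        "education_years": config.beta_education,
        "urbanisation": config.beta_urbanisation,
        "food_score": config.beta_food,
        "mean_bmi": config.beta_bmi,
    }
    zcov = np.zeros((C, T))
    for col, beta in betas.items():
        v = covariates[col].to_numpy()
        z = (v - v.mean()) / (v.std() if v.std() > 0 else 1.0)
        zcov += beta * z.reshape(C, T)

    age_prof = _age_profile(config.age_amplitude)

    true_probit = np.zeros((C, T, nsex, nage))
    region_index = {r: i for i, r in enumerate(r_ids)}
    super_index = {s: i for i, s in enumerate(sr_ids)}
    for ci, (cid, rid, sid) in enumerate(countries):
        ri, si = region_index[rid], super_index[sid]
        for sxi, sex in enumerate(config.sexes):
            sex_sign = 1.0 if sex == "male" else -1.0
            level = (
                config.base_level
                + sex_sign * config.sex_level_offset
                + (config.trend_per_decade + sex_sign * config.sex_trend_offset)
                * t_dec
                + a_s[si] + b_s[si] * t_dec
                + a_r[ri] + b_r[ri] * t_dec
                + a_c[ci] + b_c[ci] * t_dec
                + w_world + w_s[:, si] + w_r[:, ri] + w_c[:, ci]
                + zcov[ci]
            )
            steep = 1.0 + config.age_steepness * (level - config.base_level)
            true_probit[ci, :, sxi, :] = (
                level[:, None] + steep[:, None] * age_prof[None, :]
            )

    # populations: growing totals, ageing pyramid
    population = np.zeros((C, T, nsex, nage))
    widths = np.array([min(hi, 90) - lo for lo, hi in AGE_GROUPS], dtype=float)
    for ci in range(C):
        base = float(np.exp(rng.normal(15.3, 0.8)))  # adult population size
        growth = rng.uniform(0.005, 0.025)
        rho0, rho1 = rng.uniform(0.040, 0.050), rng.uniform(0.022, 0.032)
        for ti in range(T):
            rho = rho0 + (rho1 - rho0) * ti / max(T - 1, 1)
            share = widths * np.exp(-rho * (AGE_MIDPOINTS - 18.0))
            share /= share.sum()
            total = base * np.exp(growth * ti)
            for sxi in range(nsex):
                population[ci, ti, sxi] = total * share / nsex

    params = {
        "a_super": a_s, "b_super": b_s, "a_region": a_r, "b_region": b_r,
        "a_country": a_c, "b_country": b_c,
        "w_world": w_world, "w_super": w_s, "w_region": w_r, "w_country": w_c,
        "covariate_betas": betas, "age_profile": age_prof,
        "age_steepness": config.age_steepness,
        "rural_urban_gap": config.rural_urban_gap,
    }
    return WorldTruth(
        hierarchy=hierarchy,
        years=years,
        sexes=tuple(config.sexes),
        true_probit=true_probit,
        covariates=covariates,
        population=population,
        urbanisation=urb,
        params=params,
        config=config,
        seed=int(seed),
    )


@dataclass
class StudySpec:
    """One simulated study: where/when it sampled, its scope and selectivity,
    which definition it measured, and its sex-age strata with sample sizes."""

    study_id: str
    country_id: str
    mid_year: int
    scope: str = "national"
    urbanicity: str = "mixed"
    study_urban_fraction: float = float("nan")
    definition: str = PRIMARY_FPG7
    strata: tuple = ()  # (sex, age_lo, age_hi, n_examined)


@dataclass
class SurveyPlan:
    """A set of studies plus the global bias parameters of the simulation:
    probit-scale offsets for non-national scopes and rural/urban selectivity
    beyond the world's own gap, and non-sampling noise SDs by scope."""

    studies: tuple
    offset_subnational: float = 0.1
    offset_community: float = 0.2
    offset_urban_extra: float = 0.0
    offset_rural_extra: float = 0.0
    noise_sd: dict = field(
        default_factory=lambda: {
            "national": 0.0,
            "subnational": 0.07,
            "community": 0.12,
        }
    )

    def __post_init__(self):
        for spec in self.studies:
            for _, _, _, n in spec.strata:
                if n < 1:
                    raise ValueError("stratum sample sizes must be positive")
        for v in self.noise_sd.values():
            if v < 0:
                raise ValueError("noise SDs must be non-negative")

    @property
    def scope_offsets(self) -> dict[str, float]:
        return {
            "national": 0.0,
            "subnational": self.offset_subnational,
            "community": self.offset_community,
        }


DEFAULT_AGE_STRATA = ((18, 30), (30, 40), (40, 50), (50, 60), (60, 70), (70, 200))


def make_survey_plan(
    world: WorldTruth,
    studies_per_country: int = 8,
    seed: int = 0,
    scope_probs=(0.5, 0.3, 0.2),
    urbanicity_probs=(0.82, 0.10, 0.08),
    definition_probs=None,
    n_range=(400, 2500),
    sexes=None,
    age_strata=DEFAULT_AGE_STRATA,
    **plan_kwargs,
) -> SurveyPlan:
    """Draw a realistic survey plan: study years spread over the period,
    mostly national mixed samples under the primary definition, with the
    configured shares of subnational/community scope, rural/urban-only
    selectivity, and alternative biomarker definitions."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    sexes = tuple(sexes) if sexes is not None else world.sexes
    if definition_probs is None:
        definition_probs = {PRIMARY_FPG7: 1.0}
    defs = list(definition_probs)
    def_p = np.array([definition_probs[d] for d in defs], dtype=float)
    def_p /= def_p.sum()

    studies = []
    k = 0
    for cid in world.hierarchy.country_ids:
        ci = world._cidx(cid)
        for _ in range(studies_per_country):
            year = int(rng.integers(world.years[0], world.years[-1] + 1))
            scope = SCOPE_CHOICES[rng.choice(3, p=np.asarray(scope_probs))]
            urbanicity = URB_CHOICES[rng.choice(3, p=np.asarray(urbanicity_probs))]
            u_country = world.urbanisation[ci, world._yidx(year)]
            if urbanicity == "urban_only":
                ufrac = float(np.clip(rng.uniform(0.85, 1.0), 0, 1))
            elif urbanicity == "rural_only":
                ufrac = float(np.clip(rng.uniform(0.0, 0.15), 0, 1))
            else:
                ufrac = float(u_country)
            definition = defs[rng.choice(len(defs), p=def_p)]
            strata = tuple(
                (sex, lo, hi, int(rng.integers(n_range[0], n_range[1] + 1)))
                for sex in sexes
                for lo, hi in age_strata
            )
            studies.append(
                StudySpec(
                    study_id=f"{cid}_study{k:04d}",
                    country_id=cid,
                    mid_year=year,
                    scope=scope,
                    urbanicity=urbanicity,
                    study_urban_fraction=ufrac,
                    definition=definition,
                    strata=strata,
                )
            )
            k += 1
    return SurveyPlan(studies=tuple(studies), **plan_kwargs)


SCOPE_CHOICES = ("national", "subnational", "community")
URB_CHOICES = ("mixed", "urban_only", "rural_only")


def _study_rng(seed: int, study_id: str) -> np.random.Generator:
    """One stream per study, derived from (seed, study_id) so the output does
    not depend on iteration order."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(study_id.encode())])
    )


def simulate_surveys(
    world: WorldTruth, plan: SurveyPlan, seed: int = 0
) -> list[SurveyDatapoint]:
    """Simulate survey datapoints from the world under the plan.

    Each stratum's true probit-scale prevalence (population-weighted over the
    canonical age groups it covers, shifted by rural/urban selectivity) is
    offset by the scope bias, a study-level non-sampling error draw, and the
    extra rural/urban offsets; the observed count is Binomial(n, Phi(.)).
    Alternative-definition studies report the definition-mapped quantity.
    """
    out: list[SurveyDatapoint] = []
    offsets = plan.scope_offsets
    for spec in plan.studies:
        rng = _study_rng(seed, spec.study_id)
        noise_sd = plan.noise_sd.get(spec.scope, 0.0)
        study_err = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        shift = offsets[spec.scope] + study_err
        if spec.urbanicity == "urban_only":
            shift += plan.offset_urban_extra
        elif spec.urbanicity == "rural_only":
            shift += plan.offset_rural_extra
        ufrac = None if spec.urbanicity == "mixed" else spec.study_urban_fraction
        for sex, age_lo, age_hi, n in spec.strata:
            z = world.stratum_probit(
                spec.country_id, spec.mid_year, sex, age_lo, age_hi,
                urban_fraction=ufrac,
            ) + shift
            dmap = None
            if spec.definition != PRIMARY_FPG7:
                dmap = world.config.definition_maps[spec.definition]
            if dmap is not None and spec.definition == MEAN_FPG:
                # report mean FPG in mmol/L instead of a prevalence
                mean_fpg = dmap.mean_center + (z - dmap.intercept) / dmap.slope
                obs = float(mean_fpg + rng.normal(0, 0.05))
                se = 0.04 / np.sqrt(n / 500.0)
                out.append(
                    SurveyDatapoint(
                        study_id=spec.study_id, country_id=spec.country_id,
                        mid_year=spec.mid_year, sex=sex,
                        age_lo=age_lo, age_hi=age_hi, n_examined=n,
                        prevalence=obs, se=float(se),
                        definition=spec.definition, scope=spec.scope,
                        urbanicity=spec.urbanicity,
                        study_urban_fraction=spec.study_urban_fraction,
                    )
                )
                continue
            if dmap is not None:
                # invert the map: the study measured the source definition
                z = (z - dmap.intercept) / dmap.slope
            p = float(inv_probit(z))
            x = int(rng.binomial(n, p))
            prev = x / n
            out.append(
                SurveyDatapoint(
                    study_id=spec.study_id, country_id=spec.country_id,
                    mid_year=spec.mid_year, sex=sex,
                    age_lo=age_lo, age_hi=age_hi, n_examined=n,
                    prevalence=prev, se=float(binomial_se((x + 0.5) / (n + 1), n)),
                    definition=spec.definition, scope=spec.scope,
                    urbanicity=spec.urbanicity,
                    study_urban_fraction=spec.study_urban_fraction,
                )
            )
    return out


def synthetic_income(country_id: str) -> float:
    """Deterministic log per-capita income for a synthetic country id,
    usable as the income lookup when fitting cross-walks on paired data
    from :func:`simulate_paired_observations`."""
    rng = np.random.default_rng(zlib.crc32(country_id.encode()))
    return float(9.0 + 0.8 * rng.standard_normal())


def simulate_paired_observations(
    n: int,
    source_definition: str,
    dmap: DefinitionMap | None = None,
    seed: int = 0,
    n_regions: int = 6,
    region_sd: float = 0.06,
    n_examined_range=(50, 2000),
    year_range=(1980, 2014),
) -> list[PairedObservation]:
    """Simulate strata measured under both the primary outcome and one
    alternative definition, for fitting cross-walk regressions.

    The primary probit prevalence follows the definition map applied to the
    source measurement plus covariate terms, interactions and Gaussian noise
    — the generative process the cross-walk regression assumes, with known
    coefficients.
    """
    dmap = dmap or default_definition_maps()[source_definition]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 303]))
    region_effects = rng.normal(0.0, region_sd, n_regions)
    out = []
    for i in range(n):
        region_idx = int(rng.integers(n_regions))
        region = f"R{region_idx}"
        country = f"{region}_C{int(rng.integers(4))}"
        sex = "male" if rng.random() < 0.5 else "female"
        sex_num = 1.0 if sex == "male" else 0.0
        age_lo = int(rng.choice([18, 25, 35, 45, 55, 65, 75]))
        age_hi = age_lo + 10 if age_lo < 75 else 200
        age_mid = age_lo + 5 if age_lo < 75 else 82.5
        year = int(rng.integers(year_range[0], year_range[1] + 1))
        income = synthetic_income(country)
        nex = int(rng.integers(n_examined_range[0], n_examined_range[1] + 1))

        if source_definition == MEAN_FPG:
            src_value = float(rng.normal(5.6, 0.5))
            src_scale = src_value - dmap.mean_center
        else:
            src_value = float(inv_probit(rng.normal(-1.4, 0.5)))
            src_scale = float(probit(src_value))

        age_c = (age_mid - 50.0) / 10.0
        year_c = (year - np.mean(year_range)) / 10.0
        income_c = income - 9.0
        z = (
            dmap.intercept
            + dmap.slope * src_scale
            + dmap.age_coef * age_c
            + dmap.sex_coef * sex_num
            + dmap.year_coef * year_c
            + dmap.income_coef * income_c
            + dmap.interactions.get("source:age", 0.0) * src_scale * age_c
            + dmap.interactions.get("source:sex", 0.0) * src_scale * sex_num
            + dmap.interactions.get("source:year", 0.0) * src_scale * year_c
            + region_effects[region_idx]
            + rng.normal(0.0, dmap.noise_sd)
        )
        primary = float(inv_probit(z))
        if source_definition == MEAN_FPG:
            se = 0.04 / np.sqrt(nex / 500.0)
        else:
            se = float(binomial_se(max(src_value, 1e-4), nex))
        out.append(
            PairedObservation(
                study_id=f"paired_{source_definition}_{i:05d}",
                country_id=country,
                mid_year=year,
                sex=sex,
                age_lo=age_lo,
                age_hi=age_hi,
                n_examined=nex,
                prevalence=src_value,
                se=se,
                definition=source_definition,
                scope="national",
                urbanicity="mixed",
                study_urban_fraction=float("nan"),
                primary_prevalence=primary,
            )
        )
    return out
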