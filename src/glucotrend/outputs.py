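"""Derived quantities: age-standardised and crude prevalence, case counts,
the decomposition of count changes into population growth/ageing, prevalence
change and their interaction, and the probability of meeting the 2025 global
diabetes target under continuation of post-2000 trends.
"""

from __future__ import annotations

import numpy as np

from .transforms import inv_probit, probit
from .types import DecompositionResult, StandardPopulation, TargetAssessment


def age_standardise(age_specific, weights: StandardPopulation | np.ndarray):
    """Directly age-standardised prevalence: sum of weight_a * prevalence_a.

    ``age_specific`` may be a vector over age groups or an array whose last
    axis is the age group (e.g. per posterior draw). Weights are renormalised
    to sum to 1.
    """
    w = weights.vector() if isinstance(weights, StandardPopulation) else (
        np.asarray(weights, dtype=float)
    )
    w = w / w.sum()
    age_specific = np.asarray(age_specific, dtype=float)
    if age_specific.shape[-1] != len(w):
        raise ValueError(
            f"age axis length {age_specific.shape[-1]} does not match "
            f"{len(w)} weights"
        )
    return age_specific @ w


def crude_and_counts(age_specific, population):
    """Crude prevalence and case counts from age-specific prevalence and the
    actual population age structure.

    crude = sum_a pop_a * prev_a / sum_a pop_a; count = sum_a pop_a * prev_a.
    Applied along the last axis, per draw.
    """
    pop = np.asarray(population, dtype=float)
    total = pop.sum()
    if total <= 0:
        raise ValueError("total population must be positive")
    prev = np.asarray(age_specific, dtype=float)
    counts = prev @ pop
    return counts / total, counts


def decompose_change(prev_t0, prev_t1, pop_t0, pop_t1) -> DecompositionResult:
    """Decompose the change in case counts between two time points into
    population growth/ageing (G), change in age-specific prevalence (P) and
    their interaction (I); G + P + I equals the total count change exactly.

    G = sum_a (pop_t1 - pop_t0) * prev_t0
    P = sum_a pop_t0 * (prev_t1 - prev_t0)
    I = sum_a (pop_t1 - pop_t0) * (prev_t1 - prev_t0)
    """
    p0, p1 = np.asarray(prev_t0, float), np.asarray(prev_t1, float)
    n0, n1 = np.asarray(pop_t0, float), np.asarray(pop_t1, float)
    if not (p0.shape == p1.shape == n0.shape == n1.shape):
        raise ValueError("prevalence and population age groups must match")
    G = float((n1 - n0) @ p0)
    P = float(n0 @ (p1 - p0))
    I = float((n1 - n0) @ (p1 - p0))
    return DecompositionResult(
        total_change=G + P + I,
        component_growth_ageing=G,
        component_prevalence=P,
        component_interaction=I,
    )


def component_shares(components) -> np.ndarray:
    """Shares of components in percent: each over the component sum."""
    c = np.asarray(components, dtype=float)
    return 100.0 * c / c.sum()


def project_post2000(
    draws, unit, sex, weights: StandardPopulation,
    target_year: int = 2025, window_start: int = 2000, population=None,
) -> np.ndarray:
    """Project each draw's age-standardised trajectory to ``target_year``.

    Per draw, an ordinary least-squares line is fitted on the probit scale to
    the trajectory over ``window_start``..end-of-support and extrapolated;
    the projection is mapped back to a proportion.
    """
    years = draws.years
    if window_start < years[0]:
        raise ValueError("projection window starts before fitted support")
    if target_year <= years[-1]:
        raise ValueError("target year must lie beyond the fitted support")
    sel = years >= window_start
    if sel.sum() < 3:
        raise ValueError("projection window must cover at least 3 years")
    traj = draws.age_standardised(unit, sex, weights, population)  # (draw, year)
    z = probit(traj[:, sel])
    t = years[sel].astype(float)
    tbar = t.mean()
    denom = float(((t - tbar) ** 2).sum())
    slope = (z * (t - tbar)).sum(axis=1) / denom
    intercept = z.mean(axis=1)
    z_target = intercept + slope * (target_year - tbar)
    return inv_probit(z_target)


def target_probability(
    projected_2025: np.ndarray, baseline_2010: np.ndarray,
    unit: str = "world", sex: str = "both",
) -> TargetAssessment:
    """Posterior probability of meeting the global diabetes target: the
    fraction of paired draws in which projected 2025 age-standardised
    prevalence does not exceed the 2010 level (ties count as met)."""
    proj = np.asarray(projected_2025, dtype=float)
    base = np.asarray(baseline_2010, dtype=float)
    if proj.shape != base.shape:
        raise ValueError("projected and baseline draws must be paired")
    return TargetAssessment(
        unit=unit,
        sex=sex,
        probability_met=float(np.mean(proj <= base)),
        projected_2025=proj,
        baseline_2010=base,
    )


def assess_target(
    draws, unit, sex, weights: StandardPopulation,
    baseline_year: int = 2010, target_year: int = 2025,
    window_start: int = 2000, population=None,
) -> TargetAssessment:
    """Convenience wrapper: project post-2000 trends and compare with the
    baseline year, draw by draw."""
    proj = project_post2000(
        draws, unit, sex, weights, target_year=target_year,
        window_start=window_start, population=population,
    )
    base = draws.age_standardised(unit, sex, weights, population)[
        :, draws._yidx(baseline_year)
    ]
    return target_probability(proj, base, unit=unit, sex=sex)


def summary_table(draws, weights: StandardPopulation, population=None):
    """Tidy per-(country, year, sex) posterior summaries: mean and 2.5/97.5
    percentiles of age-standardised prevalence, crude prevalence and counts."""
    import pandas as pd

    pop = population if population is not None else draws.population
    rows = []
    w = weights.vector()
    for ci, country in enumerate(draws.countries):
        for si, sex in enumerate(draws.sexes):
            block = draws.prevalence[:, ci, :, si, :].astype(float)
            std = block @ w  # (draw, year)
            for ti, year in enumerate(draws.years):
                rec = {"country_id": country, "sex": sex, "year": int(year)}
                q = np.percentile(std[:, ti], [2.5, 97.5])
                rec.update(
                    std_mean=float(std[:, ti].mean()),
                    std_lo=float(q[0]), std_hi=float(q[1]),
                )
                if pop is not None:
                    page = pop[ci, ti, si, :]
                    crude, counts = crude_and_counts(block[:, ti, :], page)
                    qc = np.percentile(crude, [2.5, 97.5])
                    qn = np.percentile(counts, [2.5, 97.5])
                    rec.update(
                        crude_mean=float(crude.mean()),
                        crude_lo=float(qc[0]), crude_hi=float(qc[1]),
                        count_mean=float(counts.mean()),
                        count_lo=float(qn[0]), count_hi=float(qn[1]),
                    )
                rows.append(rec)
    return pd.DataFrame(rows)
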