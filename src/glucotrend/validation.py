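"""Hold-out validation: withhold datapoints, re-fit, and score the model's
estimates against the withheld observations.

Residuals are posterior-mean estimated prevalence minus observed stratum
prevalence, in percentage points; coverage uses the 2.5-97.5 posterior
percentiles of the estimate at the withheld stratum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import ValidationReport, age_groups_in_range

SCHEMES = ("random_fraction", "whole_country", "whole_study")


def make_holdout_split(datapoints, scheme: str, fraction: float, seed: int = 0):
    """Partition datapoints into (train, test), disjoint and exhaustive.

    ``random_fraction`` withholds individual datapoints; ``whole_study``
    withholds every stratum of sampled studies; ``whole_country`` withholds
    every datapoint of sampled countries.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 404]))
    n = len(datapoints)
    if scheme == "random_fraction":
        k = int(round(fraction * n))
        held = set(rng.choice(n, size=k, replace=False).tolist())
        test = [dp for i, dp in enumerate(datapoints) if i in held]
        train = [dp for i, dp in enumerate(datapoints) if i not in held]
    else:
        key = "country_id" if scheme == "whole_country" else "study_id"
        units = sorted({getattr(dp, key) for dp in datapoints})
        k = min(max(1, int(round(fraction * len(units)))), len(units) - 1)
        if k < 1:
            raise ValueError("hold-out fraction leaves an empty training set")
        held_units = set(
            rng.choice(len(units), size=k, replace=False).tolist()
        )
        held_names = {u for i, u in enumerate(units) if i in held_units}
        test = [dp for dp in datapoints if getattr(dp, key) in held_names]
        train = [dp for dp in datapoints if getattr(dp, key) not in held_names]
    if not train:
        raise ValueError("hold-out fraction leaves an empty training set")
    return train, test


def _estimate_stratum(draws, dp, population=None):
    """Posterior draws of the model's estimate at a withheld stratum:
    population-weighted mean prevalence over the age groups it covers."""
    groups = age_groups_in_range(dp.age_lo, dp.age_hi)
    if not groups:
        raise KeyError(
            f"stratum [{dp.age_lo}, {dp.age_hi}) maps to no estimated age group"
        )
    cell = draws.predict_prevalence(dp.country_id, dp.mid_year, dp.sex)
    pop = population if population is not None else draws.population
    if pop is not None:
        ci = draws._cidx(dp.country_id)
        ti = draws._yidx(dp.mid_year)
        si = draws._sidx(dp.sex)
        w = pop[ci, ti, si, groups]
        w = w / w.sum()
    else:
        w = np.full(len(groups), 1.0 / len(groups))
    return cell[:, groups] @ w


def evaluate_holdout(draws, test, population=None) -> ValidationReport:
    """Score posterior estimates against withheld datapoints."""
    rows = []
    for dp in test:
        est = _estimate_stratum(draws, dp, population)
        lo, hi = np.percentile(est, [2.5, 97.5])
        rows.append(
            {
                "study_id": dp.study_id,
                "country_id": dp.country_id,
                "mid_year": dp.mid_year,
                "sex": dp.sex,
                "age_lo": dp.age_lo,
                "age_hi": dp.age_hi,
                "observed": dp.prevalence,
                "estimated": float(est.mean()),
                "residual_pp": 100.0 * (float(est.mean()) - dp.prevalence),
                "cri_lo": float(lo),
                "cri_hi": float(hi),
                "covered": bool(lo <= dp.prevalence <= hi),
            }
        )
    residuals = pd.DataFrame(rows)
    if residuals.empty:
        raise ValueError("no withheld datapoints to evaluate")
    return ValidationReport(
        median_error=float(residuals["residual_pp"].median()),
        median_absolute_error=float(residuals["residual_pp"].abs().median()),
        coverage_95=float(100.0 * residuals["covered"].mean()),
        residuals=residuals,
    )
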