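"""Cross-walk regressions: convert prevalence measured under a non-primary
diabetes definition (2hOGTT-, HbA1c-, alternative-FPG-cutoff- or
mean-FPG-based) into the primary outcome, propagating conversion uncertainty.

The regressions are fit on the probit scale of both prevalences and include
terms for age, sex, study year and an income covariate. Candidate interaction
subsets are scored by BIC and the best-fitting subset retained; regional
random intercepts are included only when the training set exceeds 400
datapoints, below which a regional effect is not reliably identifiable.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .transforms import inv_probit, probit, probit_se
from .types import MEAN_FPG, PRIMARY_FPG7, SurveyDatapoint

logger = logging.getLogger(__name__)

MIN_SAMPLE = 25  # strata examined in fewer people than this are excluded
RANDOM_EFFECT_THRESHOLD = 400  # regional random intercepts above this n
MIN_TRAIN = 50

CANDIDATE_INTERACTIONS = ("source:age", "source:sex", "source:year")

YEAR_CENTER = 1997.0
AGE_CENTER = 50.0
INCOME_CENTER = 9.0


def filter_min_sample(datapoints):
    """Drop datapoints examined in fewer than ``MIN_SAMPLE`` people.

    Order is preserved; the number removed is logged.
    """
    kept = [d for d in datapoints if d.n_examined >= MIN_SAMPLE]
    removed = len(datapoints) - len(kept)
    if removed:
        logger.info(
            "excluded %d of %d datapoints with n < %d",
            removed, len(datapoints), MIN_SAMPLE,
        )
    return kept


def _age_mid(dp) -> float:
    return 0.5 * (dp.age_lo + min(dp.age_hi, 90))


def default_region_of(country_id: str) -> str:
    """Region label for the random-intercept grouping; country ids of the
    form ``<region>_<suffix>`` group by their region prefix, anything else
    forms its own group."""
    return country_id.split("_")[0]


def _income_value(dp, income) -> float:
    if income is None:
        return INCOME_CENTER
    if callable(income):
        return float(income(dp))
    return float(income[(dp.country_id, dp.mid_year)])


def _source_scale(dp, source_definition: str, mean_center: float) -> float:
    if source_definition == MEAN_FPG:
        return float(dp.prevalence) - mean_center
    return float(probit(dp.prevalence))


def _feature_row(dp, source_definition, mean_center, income, interactions):
    src = _source_scale(dp, source_definition, mean_center)
    age_c = (_age_mid(dp) - AGE_CENTER) / 10.0
    sex = 1.0 if dp.sex == "male" else 0.0
    year_c = (dp.mid_year - YEAR_CENTER) / 10.0
    base = {
        "const": 1.0, "source": src, "age": age_c, "sex": sex,
        "year": year_c,
    }
    if income is not None:
        # income term only when an income lookup is available; a constant
        # placeholder column would be collinear with the intercept
        base["income"] = _income_value(dp, income) - INCOME_CENTER
    for term in interactions:
        _, other = term.split(":")
        base[term] = src * base[other]
    return base


@dataclass
class CrosswalkModel:
    """A fitted conversion regression for one non-primary definition."""

    source_definition: str
    coef_names: list[str]
    coefficients: np.ndarray
    cov_params: np.ndarray
    residual_variance: float
    random_effect_variance: float | None
    interactions: tuple[str, ...]
    n_train: int
    bic: float
    bic_no_interaction: float
    mean_center: float = 5.6
    converged: bool = True

    def __post_init__(self):
        if self.residual_variance < 0:
            raise ValueError("residual variance must be >= 0")
        has_re = self.random_effect_variance is not None
        if has_re != (self.n_train > RANDOM_EFFECT_THRESHOLD):
            raise ValueError(
                "regional random effects present iff n_train > "
                f"{RANDOM_EFFECT_THRESHOLD}"
            )

    @property
    def coef(self) -> dict[str, float]:
        return dict(zip(self.coef_names, self.coefficients))

    def to_json(self) -> str:
        return json.dumps(
            {
                "source_definition": self.source_definition,
                "coef_names": list(self.coef_names),
                "coefficients": list(map(float, self.coefficients)),
                "cov_params": np.asarray(self.cov_params).tolist(),
                "residual_variance": self.residual_variance,
                "random_effect_variance": self.random_effect_variance,
                "interactions": list(self.interactions),
                "n_train": self.n_train,
                "bic": self.bic,
                "bic_no_interaction": self.bic_no_interaction,
                "mean_center": self.mean_center,
                "converged": self.converged,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CrosswalkModel":
        doc = json.loads(text)
        doc["coefficients"] = np.asarray(doc["coefficients"], dtype=float)
        doc["cov_params"] = np.asarray(doc["cov_params"], dtype=float)
        doc["interactions"] = tuple(doc["interactions"])
        return cls(**doc)


def _fit_one(y, X: pd.DataFrame, groups, use_re: bool):
    """Fit one candidate regression; returns (params, cov, resid_var,
    re_var, bic, converged)."""
    n, k = X.shape
    if np.linalg.matrix_rank(X.to_numpy()) < k:
        raise ValueError("degenerate design matrix: collinear covariates")
    if not use_re:
        res = sm.OLS(y, X).fit()
        return (
            res.params.to_numpy(), res.cov_params().to_numpy(),
            float(res.scale), None, float(res.bic), True,
        )
    model = sm.MixedLM(y, X, groups=groups)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False, method="lbfgs", maxiter=400)
        converged = bool(getattr(res, "converged", True))
        if not converged or not np.isfinite(res.llf):
            res2 = model.fit(reml=False, method="powell", maxiter=800)
            if np.isfinite(res2.llf) and (
                not np.isfinite(res.llf) or res2.llf > res.llf
            ):
                res = res2
                converged = bool(getattr(res2, "converged", True))
    # ML-based BIC: fixed effects + random-intercept variance + residual
    n_params = k + 2
    bic = -2.0 * float(res.llf) + n_params * np.log(n)
    cov_re = np.asarray(res.cov_re)
    re_var = float(cov_re.ravel()[0]) if cov_re.size else 0.0
    fe = res.params.to_numpy()[:k]
    cov = np.asarray(res.cov_params())[:k, :k]
    return fe, cov, float(res.scale), re_var, bic, converged


def fit_crosswalk(
    paired,
    source_definition: str,
    income=None,
    candidate_interactions=CANDIDATE_INTERACTIONS,
    region_of=default_region_of,
    mean_center: float = 5.6,
) -> CrosswalkModel:
    """Fit the conversion regression for one source definition.

    probit(primary prevalence) is regressed on the source measurement scale
    (probit of source prevalence, or centred mean FPG in mmol/L), age, sex,
    study year and income. Every subset of ``candidate_interactions`` is
    fitted and the BIC-minimising subset retained.
    """
    data = [d for d in filter_min_sample(paired) if d.definition == source_definition]
    if len(data) < MIN_TRAIN:
        raise ValueError(
            f"need >= {MIN_TRAIN} paired observations after the n >= "
            f"{MIN_SAMPLE} filter; got {len(data)}"
        )
    n = len(data)
    use_re = n > RANDOM_EFFECT_THRESHOLD
    y = probit([d.primary_prevalence for d in data])
    groups = pd.Series([region_of(d.country_id) for d in data])

    best = None
    bic_no_interaction = None
    for r in range(len(candidate_interactions) + 1):
        for combo in itertools.combinations(candidate_interactions, r):
            X = pd.DataFrame(
                [
                    _feature_row(d, source_definition, mean_center, income, combo)
                    for d in data
                ]
            )
            params, cov, resid_var, re_var, bic, converged = _fit_one(
                y, X, groups, use_re
            )
            if combo == ():
                bic_no_interaction = bic
            if best is None or bic < best["bic"]:
                best = dict(
                    combo=combo, names=list(X.columns), params=params, cov=cov,
                    resid_var=resid_var, re_var=re_var, bic=bic,
                    converged=converged,
                )
    return CrosswalkModel(
        source_definition=source_definition,
        coef_names=best["names"],
        coefficients=best["params"],
        cov_params=best["cov"],
        residual_variance=best["resid_var"],
        random_effect_variance=best["re_var"] if use_re else None,
        interactions=best["combo"],
        n_train=n,
        bic=best["bic"],
        bic_no_interaction=bic_no_interaction,
        mean_center=mean_center,
        converged=best["converged"],
    )


def predict_probit(model: CrosswalkModel, dp, income=None) -> tuple[float, float]:
    """Point prediction of probit(primary prevalence) and its variance.

    The variance combines coefficient uncertainty (delta method on the
    linear predictor), the regression's residual variance, the regional
    random-intercept variance for an unseen region, and the datapoint's own
    sampling error propagated through the source term.
    """
    row = _feature_row(
        dp, model.source_definition, model.mean_center, income, model.interactions
    )
    x = np.array([row[name] for name in model.coef_names])
    yhat = float(x @ model.coefficients)
    quad = float(x @ model.cov_params @ x)
    if not np.isfinite(quad) or quad < 0.0:
        # coefficient covariance can be unusable when the mixed-model
        # Hessian is singular at a variance boundary; drop that term rather
        # than emit a non-finite SE
        quad = 0.0
    var = quad + model.residual_variance
    if model.random_effect_variance is not None:
        var += model.random_effect_variance
    # sampling error of the source measurement, on the source scale
    if model.source_definition == MEAN_FPG:
        se_src = float(dp.se)
    else:
        se_src = float(probit_se(dp.prevalence, dp.se))
    slope = model.coef.get("source", 0.0)
    for term in model.interactions:
        _, other = term.split(":")
        slope += model.coef[term] * row[other]
    var += slope**2 * se_src**2
    return yhat, var


def apply_crosswalk(
    model: CrosswalkModel, dp: SurveyDatapoint, income=None
) -> SurveyDatapoint:
    """Convert one datapoint to the primary definition.

    Returns a copy with ``definition = PRIMARY_FPG7``, the model's point
    prediction mapped back to a proportion, and a standard error that
    includes conversion uncertainty. The output SE is floored at the input
    sampling SE: conversion never makes a datapoint more informative.
    """
    if dp.definition != model.source_definition:
        raise ValueError(
            f"datapoint definition {dp.definition!r} does not match model "
            f"source {model.source_definition!r}"
        )
    yhat, var = predict_probit(model, dp, income=income)
    p_new = float(inv_probit(yhat))
    dens = float(np.exp(-0.5 * yhat**2) / np.sqrt(2 * np.pi))
    se_new = dens * float(np.sqrt(var))
    if model.source_definition != MEAN_FPG:
        se_new = max(se_new, float(dp.se))
    return dp.copy(definition=PRIMARY_FPG7, prevalence=p_new, se=se_new)


def harmonise(datapoints, models: dict[str, CrosswalkModel], income=None):
    """Convert every non-primary datapoint using the fitted model for its
    definition; primary datapoints pass through untouched."""
    out = []
    for dp in datapoints:
        if dp.definition == PRIMARY_FPG7:
            out.append(dp)
        else:
            try:
                model = models[dp.definition]
            except KeyError:
                raise KeyError(
                    f"no cross-walk model for definition {dp.definition!r}"
                ) from None
            out.append(apply_crosswalk(model, dp, income=income))
    return out
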