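"""Bayesian hierarchical probit model of prevalence by country, year, age
and sex.

The linear predictor on the probit scale combines a global intercept and
linear year trend; nested random intercepts and slopes for super-regions,
regions and countries; smooth non-linear year components (second-order
random-walk smooths in a reduced-rank spectral basis) at each hierarchy
level; an age spline whose steepness increases with the country-year level;
fixed effects of country covariates; fixed offsets for subnational and
community scope; per-study random effects with scope-specific variances; and
a rural/urban effect weighted by the difference between study-level and
country-level urbanisation.

The likelihood is Normal on probit-transformed stratum prevalences, with
variance equal to the delta-method sampling variance plus a scope-specific
non-sampling variance. Because every coefficient block then has a Gaussian
full conditional (the age-steepness interaction is bilinear, so each factor
is conditionally linear), the model is fitted by blocked Gibbs sampling;
standard-deviation parameters carry half-normal priors and are updated by
scalar slice sampling. Sexes are fitted separately.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.special import ndtr, ndtri

from .synthetic import rw2_basis, who_standard_population
from .transforms import probit, probit_se
from .types import (
    AGE_GROUPS,
    AGE_MIDPOINTS,
    PRIMARY_FPG7,
    HierarchySpec,
    StandardPopulation,
)

HIER_LEVELS = ("world", "super_region", "region", "country")


@dataclass
class ModelConfig:
    """Model and MCMC settings.

    ``draws`` is the total number of retained post-burn-in samples across
    chains. Prior scales are on the probit scale; trend slopes are per
    decade of centred year.
    """

    hierarchy: HierarchySpec = None
    year_start: int = 1980
    year_end: int = 2014
    covariates: tuple[str, ...] = (
        "education_years", "urbanisation", "food_score", "mean_bmi",
    )
    chains: int = 2
    burnin: int = 500
    draws: int = 5000
    thin: int = 1
    seed: int = 0

    rw2_levels: tuple[str, ...] = HIER_LEVELS
    rw2_rank: int = 5
    age_knots: tuple[float, ...] = (35.0, 50.0, 65.0)
    steepness_ref: float = -1.5  # probit level at which the age multiplier is 1

    prior_sd_fixed: float = 10.0
    prior_sd_age: float = 2.0
    halfnormal_scale: dict = field(
        default_factory=lambda: {
            "super_intercept": 0.5, "super_slope": 0.2,
            "region_intercept": 0.3, "region_slope": 0.15,
            "country_intercept": 0.3, "country_slope": 0.15,
            "rw2_world": 0.15, "rw2_super_region": 0.1,
            "rw2_region": 0.1, "rw2_country": 0.1,
            "study_subnational": 0.3, "study_community": 0.3,
            "tau_subnational": 0.25, "tau_community": 0.25,
        }
    )

    rhat_threshold: float = 1.1
    ess_floor: float = 100.0

    def validate(self):
        if self.hierarchy is None:
            raise ValueError("config.hierarchy is required")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required")
        if self.year_end - self.year_start < 1:
            raise ValueError("year range must cover at least 2 years")
        if self.draws < 1 or self.burnin < 0 or self.thin < 1:
            raise ValueError("invalid MCMC settings")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)


def _age_basis(ages, knots) -> np.ndarray:
    """Cubic B-spline basis over age, clamped at 18 and 85, columns centred
    with the adult standard-population weights so the basis carries no
    overall level (the intercept does)."""
    kv = np.r_[[18.0] * 4, list(knots), [85.0] * 4]
    ages = np.clip(np.asarray(ages, dtype=float), 18.0, 85.0 - 1e-9)
    B = BSpline.design_matrix(ages, kv, 3).toarray()
    Bmid = BSpline.design_matrix(
        np.clip(AGE_MIDPOINTS, 18.0, 85.0 - 1e-9), kv, 3
    ).toarray()
    w = who_standard_population().vector()
    return B - (w @ Bmid)[None, :]


def _slice_sample(x0, logpdf, w, rng, lower=1e-8, max_steps=50):
    """Univariate slice sampler (stepping out + shrinkage) on (lower, inf)."""
    logy = logpdf(x0) + np.log(rng.uniform())
    left = x0 - w * rng.uniform()
    right = left + w
    steps = max_steps
    while left > lower and steps > 0 and logpdf(left) > logy:
        left -= w
        steps -= 1
    left = max(left, lower)
    steps = max_steps
    while steps > 0 and logpdf(right) > logy:
        right += w
        steps -= 1
    for _ in range(100):
        x1 = rng.uniform(left, right)
        if logpdf(x1) > logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


def _sd_logpdf_gaussian(values, scale):
    """log p(sigma | values) for iid N(0, sigma^2) values, half-N(scale) prior."""
    m = len(values)
    ss = float(np.dot(values, values))

    def logpdf(s):
        return -m * np.log(s) - ss / (2 * s * s) - s * s / (2 * scale * scale)

    return logpdf


def _tau_logpdf(resid, s2, scale):
    """log p(tau | residuals) where resid_i ~ N(0, s2_i + tau^2)."""
    def logpdf(t):
        v = s2 + t * t
        return float(-0.5 * np.sum(np.log(v) + resid * resid / v)) - (
            t * t / (2 * scale * scale)
        )

    return logpdf


class _Design:
    """Design matrices and index bookkeeping for one sex's datapoints.

    A survey stratum spanning several canonical age groups is represented by
    the population-weighted average of the age-basis rows at those groups'
    midpoints, matching how an observed stratum mixes its member ages.
    """

    def __init__(
        self, datapoints, covariates: pd.DataFrame, config: ModelConfig,
        population=None, sex_index: int = 0,
    ):
        hier = config.hierarchy
        years = config.years
        self.config = config
        self.countries = hier.country_ids
        self.regions = hier.region_ids
        self.supers = hier.super_region_ids
        cidx = {c: i for i, c in enumerate(self.countries)}
        ridx = {r: i for i, r in enumerate(self.regions)}
        sidx = {s: i for i, s in enumerate(self.supers)}
        region_of = hier.region_of
        super_of = hier.super_region_of_region
        self.t_dec = (years - years.mean()) / 10.0

        cov = covariates.set_index(["country_id", "year"])
        self.cov_mean = {k: float(covariates[k].mean()) for k in config.covariates}
        self.cov_sd = {
            k: float(covariates[k].std()) or 1.0 for k in config.covariates
        }
        urb_col = "urbanisation" if "urbanisation" in covariates.columns else None

        from .types import age_groups_in_range

        rows, ys, s2, scopes, study_keys, age_weights = [], [], [], [], [], []
        for dp in datapoints:
            if dp.definition != PRIMARY_FPG7:
                raise ValueError(
                    f"datapoint {dp.study_id} has non-harmonised definition "
                    f"{dp.definition!r}; run the cross-walk first"
                )
            if dp.country_id not in cidx:
                raise KeyError(f"country {dp.country_id!r} not in hierarchy")
            if not years[0] <= dp.mid_year <= years[-1]:
                raise KeyError(f"study year {dp.mid_year} outside model range")
            n1 = dp.n_examined + 1.0
            p = float(np.clip(dp.prevalence, 0.5 / n1, 1.0 - 0.5 / n1))
            z = float(probit(p))
            se_z = float(probit_se(p, max(dp.se, 1e-6)))
            ys.append(z)
            s2.append(se_z**2)
            scopes.append(dp.scope)
            study_keys.append(dp.study_id if dp.scope != "national" else None)
            try:
                crow = cov.loc[(dp.country_id, dp.mid_year)]
            except KeyError:
                raise KeyError(
                    f"no covariates for ({dp.country_id}, {dp.mid_year})"
                ) from None
            covs = [
                (float(crow[k]) - self.cov_mean[k]) / self.cov_sd[k]
                for k in config.covariates
            ]
            if dp.urbanicity != "mixed" and urb_col and not np.isnan(
                dp.study_urban_fraction
            ):
                urbdiff = float(dp.study_urban_fraction) - float(crow[urb_col])
            else:
                urbdiff = 0.0
            groups = age_groups_in_range(dp.age_lo, dp.age_hi)
            if not groups:
                raise ValueError(
                    f"stratum [{dp.age_lo}, {dp.age_hi}) covers no canonical "
                    "age group"
                )
            ci = cidx[dp.country_id]
            ti = int(dp.mid_year - years[0])
            if population is not None:
                w = population[ci, ti, sex_index, groups].astype(float)
                w = w / w.sum()
            else:
                w = np.full(len(groups), 1.0 / len(groups))
            age_weights.append((groups, w))
            rows.append(
                (
                    ci,
                    ridx[region_of[dp.country_id]],
                    sidx[super_of[region_of[dp.country_id]]],
                    ti,
                    covs,
                    1.0 if dp.scope == "subnational" else 0.0,
                    1.0 if dp.scope == "community" else 0.0,
                    urbdiff,
                )
            )

        self.y = np.array(ys)
        self.s2 = np.array(s2)
        self.scope = np.array(scopes)
        n = len(self.y)

        # per-study random-effect index for non-national studies
        studies = sorted({k for k in study_keys if k is not None})
        self.study_index = {k: i for i, k in enumerate(studies)}
        self.obs_study = np.array(
            [self.study_index[k] if k is not None else -1 for k in study_keys]
        )
        self.study_scope = np.array(
            [
                next(
                    self.scope[i]
                    for i in range(n)
                    if study_keys[i] == k
                )
                for k in studies
            ]
        ) if studies else np.array([], dtype=object)

        # nesting structure for the location-sweep Gibbs moves
        self.members_of_super = [
            [ridx[r] for r in self.regions if super_of[r] == s]
            for s in self.supers
        ]
        self.members_of_region = [
            [cidx[c] for c in self.countries if region_of[c] == r]
            for r in self.regions
        ]

        self.X, self.blocks = self._build_X(rows, grid=False)
        self.Bg = _age_basis(AGE_MIDPOINTS, config.age_knots)
        self.B = np.zeros((n, self.Bg.shape[1]))
        for i, (groups, w) in enumerate(age_weights):
            self.B[i] = w @ self.Bg[groups]

        # prediction grid: every (country, year), national mixed population
        grid_rows = []
        for c in self.countries:
            ci = cidx[c]
            ri = ridx[region_of[c]]
            si = sidx[super_of[region_of[c]]]
            for ti, yr in enumerate(years):
                try:
                    crow = cov.loc[(c, int(yr))]
                    covs = [
                        (float(crow[k]) - self.cov_mean[k]) / self.cov_sd[k]
                        for k in config.covariates
                    ]
                except KeyError:
                    covs = [0.0] * len(config.covariates)
                grid_rows.append((ci, ri, si, ti, covs, 0.0, 0.0, 0.0))
        self.Xg, _ = self._build_X(grid_rows, grid=True)

    def _build_X(self, rows, grid: bool):
        config = self.config
        nS, nR, nC = len(self.supers), len(self.regions), len(self.countries)
        T = len(self.t_dec)
        basis = rw2_basis(T, config.rw2_rank)
        rank = basis.shape[1]
        ncov = len(config.covariates)

        names = ["const", "trend"]
        names += [f"cov_{k}" for k in config.covariates]
        names += ["scope_subnational", "scope_community", "urban_gap"]
        blocks: dict[str, list[int]] = {}

        def add_block(label, count):
            start = len(names)
            names.extend([f"{label}_{j}" for j in range(count)])
            blocks[label] = list(range(start, start + count))

        add_block("super_intercept", nS)
        add_block("super_slope", nS)
        add_block("region_intercept", nR)
        add_block("region_slope", nR)
        add_block("country_intercept", nC)
        add_block("country_slope", nC)
        level_units = {
            "world": 1, "super_region": nS, "region": nR, "country": nC,
        }
        for level in config.rw2_levels:
            add_block(f"rw2_{level}", level_units[level] * rank)

        p = len(names)
        X = np.zeros((len(rows), p))
        for i, (ci, ri, si, ti, covs, sub, com, urbdiff) in enumerate(rows):
            td = self.t_dec[ti]
            X[i, 0] = 1.0
            X[i, 1] = td
            X[i, 2 : 2 + ncov] = covs
            X[i, 2 + ncov] = sub
            X[i, 3 + ncov] = com
            X[i, 4 + ncov] = urbdiff
            X[i, blocks["super_intercept"][si]] = 1.0
            X[i, blocks["super_slope"][si]] = td
            X[i, blocks["region_intercept"][ri]] = 1.0
            X[i, blocks["region_slope"][ri]] = td
            X[i, blocks["country_intercept"][ci]] = 1.0
            X[i, blocks["country_slope"][ci]] = td
            for level in config.rw2_levels:
                unit = {"world": 0, "super_region": si, "region": ri,
                        "country": ci}[level]
                cols = blocks[f"rw2_{level}"]
                X[i, cols[unit * rank] : cols[unit * rank] + rank] = basis[ti]
        if not grid:
            self.names = names
            self.n_fixed = 5 + ncov
        return X, blocks


def _sweep_pair(theta, rng, parent_idx, parent_prec, child_idx, child_prec):
    """Resample the non-identified location shift between a parent
    coefficient and the child coefficients nested under it.

    Adding delta to the parent and subtracting it from every child leaves
    the likelihood unchanged; its conditional under the Gaussian priors is
    Gaussian. Sampling it decorrelates nested levels and repairs the slow
    mixing the redundant parametrisation would otherwise cause.
    """
    children = theta[child_idx]
    prec = parent_prec + len(child_idx) * child_prec
    mean = (-theta[parent_idx] * parent_prec + children.sum() * child_prec) / prec
    delta = rng.normal(mean, 1.0 / np.sqrt(prec))
    theta[parent_idx] += delta
    theta[child_idx] -= delta


def _sweep_all(theta, rng, des, sds, config):
    """Location sweeps through the whole nesting: global <-> super-regions,
    super-region <-> its regions, region <-> its countries, for intercepts,
    slopes, and each smooth-basis coefficient where both levels are present."""
    b = des.blocks
    prec = {k: 1.0 / v**2 for k, v in sds.items()}
    prec_fixed = 1.0 / config.prior_sd_fixed**2
    for kind, global_col in (("intercept", 0), ("slope", 1)):
        _sweep_pair(theta, rng, global_col, prec_fixed,
                    b[f"super_{kind}"], prec[f"super_{kind}"])
        for si, regions in enumerate(des.members_of_super):
            _sweep_pair(theta, rng, b[f"super_{kind}"][si],
                        prec[f"super_{kind}"],
                        [b[f"region_{kind}"][r] for r in regions],
                        prec[f"region_{kind}"])
        for ri, countries in enumerate(des.members_of_region):
            _sweep_pair(theta, rng, b[f"region_{kind}"][ri],
                        prec[f"region_{kind}"],
                        [b[f"country_{kind}"][c] for c in countries],
                        prec[f"country_{kind}"])
    rank = config.rw2_rank
    levels = config.rw2_levels
    for k in range(rank):
        if "world" in levels and "super_region" in levels:
            _sweep_pair(theta, rng, b["rw2_world"][k], prec["rw2_world"],
                        [b["rw2_super_region"][u * rank + k]
                         for u in range(len(des.supers))],
                        prec["rw2_super_region"])
        if "super_region" in levels and "region" in levels:
            for si, regions in enumerate(des.members_of_super):
                _sweep_pair(theta, rng, b["rw2_super_region"][si * rank + k],
                            prec["rw2_super_region"],
                            [b["rw2_region"][r * rank + k] for r in regions],
                            prec["rw2_region"])
        if "region" in levels and "country" in levels:
            for ri, countries in enumerate(des.members_of_region):
                _sweep_pair(theta, rng, b["rw2_region"][ri * rank + k],
                            prec["rw2_region"],
                            [b["rw2_country"][c * rank + k] for c in countries],
                            prec["rw2_country"])


def _fit_one_sex(
    datapoints, covariates, config: ModelConfig, sex: str, seed: int,
    population=None, sex_index: int = 0,
):
    des = _Design(
        datapoints, covariates, config, population=population,
        sex_index=sex_index,
    )
    n = len(des.y)
    if n == 0:
        raise ValueError(f"no datapoints for sex {sex!r}")
    p = des.X.shape[1]
    q = des.B.shape[1]
    c0 = config.steepness_ref
    hs = config.halfnormal_scale

    sd_blocks = {  # variance parameter -> coefficient block label(s)
        "super_intercept": ["super_intercept"],
        "super_slope": ["super_slope"],
        "region_intercept": ["region_intercept"],
        "region_slope": ["region_slope"],
        "country_intercept": ["country_intercept"],
        "country_slope": ["country_slope"],
    }
    for level in config.rw2_levels:
        sd_blocks[f"rw2_{level}"] = [f"rw2_{level}"]

    n_study = len(des.study_index)
    per_chain = int(np.ceil(config.draws / config.chains))
    keep_every = config.thin
    n_iter = config.burnin + per_chain * keep_every

    chain_theta, chain_alpha, chain_kappa = [], [], []
    chain_scalars = []  # per-chain dict of trace arrays

    fixed_names = des.names[: des.n_fixed]
    for chain in range(config.chains):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), 7000 + chain])
        )
        theta = np.zeros(p)
        theta[0] = float(np.median(des.y))
        alpha = np.zeros(q)
        kappa = 0.1 + 0.05 * chain
        e_study = np.zeros(n_study)
        sds = {k: hs[k] * 0.5 for k in sd_blocks}
        taus = {"subnational": 0.05, "community": 0.05}

        prior_prec = np.full(p, 1.0 / config.prior_sd_fixed**2)

        t_theta = np.empty((per_chain, p))
        t_alpha = np.empty((per_chain, q))
        t_kappa = np.empty(per_chain)
        scal = {k: np.empty(per_chain) for k in
                list(sd_blocks) + ["tau_subnational", "tau_community"]}

        e_obs = np.zeros(n)
        kept = 0
        for it in range(n_iter):
            tau_obs = np.zeros(n)
            for scope_name, t in taus.items():
                tau_obs[des.scope == scope_name] = t
            v = des.s2 + tau_obs**2
            inv_sqrt_v = 1.0 / np.sqrt(v)

            if n_study:
                e_obs = np.where(des.obs_study >= 0, e_study[np.maximum(des.obs_study, 0)], 0.0)

            # --- theta block (all linear coefficients jointly) ---
            A = des.B @ alpha
            c = 1.0 + kappa * A
            z = des.y - e_obs - A * (1.0 - kappa * c0)
            for label, cols in des.blocks.items():
                key = label if label in sds else None
                if key:
                    prior_prec[cols] = 1.0 / sds[key] ** 2
            u = c * inv_sqrt_v
            Xs = des.X * u[:, None]
            Q = Xs.T @ Xs
            Q[np.diag_indices_from(Q)] += prior_prec
            rhs = Xs.T @ (z * inv_sqrt_v)
            L = np.linalg.cholesky(Q)
            mu = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
            theta = mu + np.linalg.solve(L.T, rng.standard_normal(p))
            _sweep_all(theta, rng, des, sds, config)

            F = des.X @ theta

            # --- age-spline block ---
            d = (1.0 + kappa * (F - c0)) * inv_sqrt_v
            Bs = des.B * d[:, None]
            Qa = Bs.T @ Bs
            Qa[np.diag_indices_from(Qa)] += 1.0 / config.prior_sd_age**2
            rhs_a = Bs.T @ ((des.y - e_obs - F) * inv_sqrt_v)
            La = np.linalg.cholesky(Qa)
            mu_a = np.linalg.solve(La.T, np.linalg.solve(La, rhs_a))
            alpha = mu_a + np.linalg.solve(La.T, rng.standard_normal(q))
            A = des.B @ alpha

            # --- steepness coefficient (conditionally Gaussian) ---
            qvec = (F - c0) * A
            r = des.y - e_obs - F - A
            prec_k = float(np.sum(qvec * qvec / v)) + 1.0  # N(0,1) prior
            mean_k = float(np.sum(qvec * r / v)) / prec_k
            kappa = rng.normal(mean_k, 1.0 / np.sqrt(prec_k))

            eta = F + (1.0 + kappa * (F - c0)) * A

            # --- per-study random effects ---
            if n_study:
                resid = des.y - eta
                num = np.zeros(n_study)
                den = np.zeros(n_study)
                mask = des.obs_study >= 0
                np.add.at(num, des.obs_study[mask], (resid / v)[mask])
                np.add.at(den, des.obs_study[mask], (1.0 / v)[mask])
                for j in range(n_study):
                    sd_j = sds_study_lookup(sds, hs, des.study_scope[j])
                    prec = den[j] + 1.0 / sd_j**2
                    e_study[j] = rng.normal(num[j] / prec, 1.0 / np.sqrt(prec))
                # sweep the redundant shift between each scope's fixed offset
                # and its studies' random effects
                ncov = len(config.covariates)
                for scope_name, col in (
                    ("subnational", 2 + ncov), ("community", 3 + ncov),
                ):
                    jj = np.where(des.study_scope == scope_name)[0]
                    if len(jj):
                        sd_j = sds_study_lookup(sds, hs, scope_name)
                        prec_d = 1.0 / config.prior_sd_fixed**2 + len(jj) / sd_j**2
                        mean_d = (
                            -theta[col] / config.prior_sd_fixed**2
                            + e_study[jj].sum() / sd_j**2
                        ) / prec_d
                        delta = rng.normal(mean_d, 1.0 / np.sqrt(prec_d))
                        theta[col] += delta
                        e_study[jj] -= delta
                F = des.X @ theta
                eta = F + (1.0 + kappa * (F - c0)) * A
                e_obs = np.where(mask, e_study[np.maximum(des.obs_study, 0)], 0.0)

            # --- hierarchy / smooth SDs (slice sampling, half-normal priors) ---
            for key, labels in sd_blocks.items():
                vals = np.concatenate([theta[des.blocks[lab]] for lab in labels])
                sds[key] = _slice_sample(
                    sds[key], _sd_logpdf_gaussian(vals, hs[key]),
                    w=0.5 * hs[key], rng=rng,
                )
            if n_study:
                for scope_name in ("subnational", "community"):
                    vals = e_study[des.study_scope == scope_name]
                    if len(vals):
                        hs_key = f"study_{scope_name}"
                        sds[hs_key] = _slice_sample(
                            sds.get(hs_key, hs[hs_key] * 0.5),
                            _sd_logpdf_gaussian(vals, hs[hs_key]),
                            w=0.5 * hs[hs_key], rng=rng,
                        )

            # --- interweaved (non-centred) SD redraw: with the unit-scale
            # coefficients held fixed, each SD has a conjugate Gaussian
            # conditional truncated to (0, inf); this removes the funnel
            # coupling between an SD and its coefficient block ---
            c = 1.0 + kappa * A
            rbase = des.y - e_obs - A * (1.0 - kappa * c0) - c * F
            for key, labels in sd_blocks.items():
                cols = np.concatenate(
                    [des.blocks[lab] for lab in labels]
                ).astype(int)
                u_blk = theta[cols]
                s_old = sds[key]
                g = des.X[:, cols] @ u_blk
                contrib = c * g
                b = contrib / s_old
                r_plus = rbase + contrib
                prec_s = float(np.sum(b * b / v)) + 1.0 / hs[key] ** 2
                mean_s = float(np.sum(b * r_plus / v)) / prec_s
                sd_s = 1.0 / np.sqrt(prec_s)
                # inverse-CDF draw from the truncated-to-positive Gaussian
                lo_cdf = ndtr(-mean_s / sd_s)
                uu = rng.uniform(lo_cdf, 1.0)
                s_new = float(mean_s + sd_s * ndtri(np.clip(uu, 1e-12, 1 - 1e-16)))
                s_new = max(s_new, 1e-8)
                ratio = s_new / s_old
                theta[cols] = u_blk * ratio
                F = F + g * (ratio - 1.0)
                rbase = r_plus - contrib * ratio
                sds[key] = s_new
            eta = F + (1.0 + kappa * (F - c0)) * A

            # --- scope non-sampling SDs ---
            resid = des.y - eta - e_obs
            for scope_name in ("subnational", "community"):
                m = des.scope == scope_name
                if m.any():
                    taus[scope_name] = _slice_sample(
                        taus[scope_name],
                        _tau_logpdf(resid[m], des.s2[m], hs[f"tau_{scope_name}"]),
                        w=0.1, rng=rng,
                    )

            if it >= config.burnin and (it - config.burnin) % keep_every == 0:
                if kept < per_chain:
                    t_theta[kept] = theta
                    t_alpha[kept] = alpha
                    t_kappa[kept] = kappa
                    for k in sd_blocks:
                        scal[k][kept] = sds[k]
                    scal["tau_subnational"][kept] = taus["subnational"]
                    scal["tau_community"][kept] = taus["community"]
                    kept += 1
        chain_theta.append(t_theta)
        chain_alpha.append(t_alpha)
        chain_kappa.append(t_kappa)
        chain_scalars.append(scal)

    # --- diagnostics on scalar parameters across chains ---
    import arviz as az

    diag_vars = {}
    for j, name in enumerate(fixed_names):
        diag_vars[name] = np.stack([t[:, j] for t in chain_theta])
    diag_vars["age_steepness"] = np.stack(chain_kappa)
    for k in chain_scalars[0]:
        diag_vars[f"sd_{k}"] = np.stack([s[k] for s in chain_scalars])
    idata = az.from_dict(posterior={k: v for k, v in diag_vars.items()})
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rhat_max = float(
        max(float(rhat[k].max()) for k in diag_vars)
    )
    ess_min = float(min(float(ess[k].min()) for k in diag_vars))
    converged = rhat_max < config.rhat_threshold and ess_min >= config.ess_floor
    if not converged:
        warnings.warn(
            f"MCMC convergence diagnostics failed for sex={sex}: "
            f"max R-hat {rhat_max:.3f}, min ESS {ess_min:.0f}",
            RuntimeWarning,
        )
    diagnostics = {
        "rhat_max": rhat_max,
        "ess_min": ess_min,
        "converged": bool(converged),
        "rhat": {k: float(rhat[k].max()) for k in diag_vars},
    }

    theta_all = np.concatenate(chain_theta)[: config.draws]
    alpha_all = np.concatenate(chain_alpha)[: config.draws]
    kappa_all = np.concatenate(chain_kappa)[: config.draws]

    # transform retained draws to the prevalence grid
    C, T = len(des.countries), len(config.years)
    nage = len(AGE_GROUPS)
    prev = np.empty((len(theta_all), C, T, nage), dtype=np.float32)
    Ag_base = des.Bg  # (nage, q)
    for idraw in range(len(theta_all)):
        Fg = des.Xg @ theta_all[idraw]  # (C*T,)
        Ag = Ag_base @ alpha_all[idraw]  # (nage,)
        k = kappa_all[idraw]
        eta = Fg[:, None] + (1.0 + k * (Fg[:, None] - c0)) * Ag[None, :]
        prev[idraw] = ndtr(eta).reshape(C, T, nage).astype(np.float32)

    coefficients = {
        name: np.concatenate(chain_theta)[: config.draws, j]
        for j, name in enumerate(fixed_names)
    }
    coefficients["age_steepness"] = kappa_all
    for k in chain_scalars[0]:
        coefficients[f"sd_{k}"] = np.concatenate(
            [s[k] for s in chain_scalars]
        )[: config.draws]

    return prev, coefficients, diagnostics


def sds_study_lookup(sds, hs, scope_name):
    key = f"study_{scope_name}"
    return sds.get(key, hs[key] * 0.5)


@dataclass
class PosteriorDraws:
    """Retained post-burn-in draws of age-specific prevalence indexed
    (draw, country, year, sex, age group), with convergence diagnostics and
    the fitted study-effect and covariate coefficient draws per sex."""

    prevalence: np.ndarray
    countries: list[str]
    years: np.ndarray
    sexes: tuple[str, ...]
    hierarchy: HierarchySpec
    diagnostics: dict
    coefficients: dict  # sex -> {name: (draw,) array}
    population: np.ndarray | None = None  # (country, year, sex, age)

    def __post_init__(self):
        if np.any(self.prevalence < 0) or np.any(self.prevalence > 1):
            raise ValueError("draws contain prevalences outside [0, 1]")

    @property
    def n_draws(self) -> int:
        return self.prevalence.shape[0]

    def _cidx(self, country: str) -> int:
        try:
            return self.countries.index(country)
        except ValueError:
            raise KeyError(f"country {country!r} not in fitted support") from None

    def _yidx(self, year: int) -> int:
        if not self.years[0] <= year <= self.years[-1]:
            raise KeyError(f"year {year} outside fitted support")
        return int(year - self.years[0])

    def _sidx(self, sex: str) -> int:
        try:
            return self.sexes.index(sex)
        except ValueError:
            raise KeyError(f"sex {sex!r} not in fitted support") from None

    def predict_prevalence(self, country, year, sex) -> np.ndarray:
        """Stored draws of age-specific prevalence, shape (draw, age group).

        Queries outside the fitted support raise; projection beyond the
        fitted years lives in the derived-outputs stage.
        """
        return np.array(
            self.prevalence[:, self._cidx(country), self._yidx(year),
                            self._sidx(sex), :],
            dtype=float,
        )

    def _unit_countries(self, unit: str) -> list[str]:
        if unit == "world":
            return list(self.countries)
        if unit in self.hierarchy.region_ids:
            return self.hierarchy.countries_in_region(unit)
        if unit in self.hierarchy.super_region_ids:
            return [
                c for c, r, s in self.hierarchy.countries if s == unit
            ]
        if unit in self.countries:
            return [unit]
        raise KeyError(f"unknown unit {unit!r}")

    def age_standardised(
        self, unit, sex, weights: StandardPopulation, population=None
    ) -> np.ndarray:
        """Age-standardised prevalence trajectory draws, shape (draw, year).

        For aggregate units each member country is age-standardised and then
        averaged with weights proportional to its adult population.
        """
        w = weights.vector()
        si = self._sidx(sex)
        members = self._unit_countries(unit)
        idx = [self._cidx(c) for c in members]
        block = self.prevalence[:, idx][:, :, :, si, :].astype(float)
        std = block @ w  # (draw, member, year)
        if len(members) == 1:
            return std[:, 0, :]
        pop = population if population is not None else self.population
        if pop is None:
            raise ValueError("aggregating over countries requires populations")
        adult = pop[idx, :, si, :].sum(axis=-1)  # (m, year)
        share = adult / adult.sum(axis=0, keepdims=True)
        return np.einsum("dmy,my->dy", std, share)

    def posterior_prob_increase(
        self, unit, sex, year0: int, year1: int,
        weights: StandardPopulation, population=None,
    ) -> float:
        """Fraction of draws in which age-standardised prevalence is strictly
        higher in year1 than in year0 (0.5 means an increase and a decrease
        are indistinguishable)."""
        y0, y1 = self._yidx(year0), self._yidx(year1)
        if year0 > year1:
            raise ValueError("year0 must not exceed year1")
        traj = self.age_standardised(unit, sex, weights, population)
        return float(np.mean(traj[:, y1] > traj[:, y0]))

    def save(self, path) -> None:
        """Write draws to a chunked zarr container with an index manifest."""
        import zarr

        g = zarr.open_group(str(path), mode="w")
        arr = g.create_array(
            "prevalence", shape=self.prevalence.shape, dtype="f4",
            chunks=(min(self.n_draws, 500),) + self.prevalence.shape[1:],
        )
        arr[:] = self.prevalence
        if self.population is not None:
            ap = g.create_array(
                "population", shape=self.population.shape, dtype="f8"
            )
            ap[:] = self.population
        cg = g.create_group("coefficients")
        for sex, coefs in self.coefficients.items():
            sg = cg.create_group(sex)
            for name, v in coefs.items():
                a = sg.create_array(name, shape=v.shape, dtype="f8")
                a[:] = v
        g.attrs["manifest"] = {
            "countries": list(self.countries),
            "years": [int(y) for y in self.years],
            "sexes": list(self.sexes),
            "age_groups": [list(gp) for gp in AGE_GROUPS],
            "hierarchy": [list(t) for t in self.hierarchy.countries],
            "diagnostics": json.loads(json.dumps(self.diagnostics)),
            "n_draws": int(self.n_draws),
        }

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        import zarr

        g = zarr.open_group(str(path), mode="r")
        man = g.attrs["manifest"]
        coefficients = {}
        if "coefficients" in g:
            for sex in g["coefficients"]:
                coefficients[sex] = {
                    name: np.asarray(g["coefficients"][sex][name])
                    for name in g["coefficients"][sex].array_keys()
                }
        return cls(
            prevalence=np.asarray(g["prevalence"]),
            countries=list(man["countries"]),
            years=np.asarray(man["years"]),
            sexes=tuple(man["sexes"]),
            hierarchy=HierarchySpec(
                tuple(tuple(t) for t in man["hierarchy"])
            ),
            diagnostics=dict(man["diagnostics"]),
            coefficients=coefficients,
            population=(
                np.asarray(g["population"]) if "population" in g else None
            ),
        )


def fit_model(
    datapoints, covariates, populations, config: ModelConfig
) -> PosteriorDraws:
    """Fit the hierarchical probit model, separately by sex, and return the
    posterior draws of age-specific prevalence for every country-year-sex.

    ``populations`` may be a (country, year, sex, age) array aligned with
    the config's hierarchy/years, a long DataFrame with columns country_id,
    year, sex, age_lo, age_hi, population, or None (aggregation over
    countries then requires populations at call time).
    """
    config.validate()
    # canonical order: the fit is invariant to the order datapoints arrive in
    datapoints = sorted(
        datapoints,
        key=lambda d: (d.study_id, d.sex, d.age_lo, d.age_hi, d.mid_year,
                       d.n_examined, d.prevalence),
    )
    sexes = tuple(sorted({dp.sex for dp in datapoints}, reverse=True))
    if not sexes:
        raise ValueError("no datapoints supplied")

    pop_arr = None
    if populations is not None:
        if isinstance(populations, np.ndarray):
            pop_arr = populations
        else:
            from .io import population_array

            pop_arr = population_array(
                populations, config.hierarchy.country_ids, config.years,
                sexes, AGE_GROUPS,
            )

    per_sex_prev, coefficients, diagnostics = [], {}, {}
    for k, sex in enumerate(sexes):
        pts = [dp for dp in datapoints if dp.sex == sex]
        prev, coefs, diag = _fit_one_sex(
            pts, covariates, config, sex, seed=config.seed + 17 * k,
            population=pop_arr, sex_index=k,
        )
        per_sex_prev.append(prev)
        coefficients[sex] = coefs
        diagnostics[sex] = diag

    prevalence = np.stack(per_sex_prev, axis=3)  # (draw, country, year, sex, age)
    return PosteriorDraws(
        prevalence=prevalence,
        countries=list(config.hierarchy.country_ids),
        years=config.years,
        sexes=sexes,
        hierarchy=config.hierarchy,
        diagnostics=diagnostics,
        coefficients=coefficients,
        population=pop_arr,
    )


def hierarchical_component_trajectory(
    draws: PosteriorDraws, unit, sex, weights: StandardPopulation,
    covariates, covariate_names=None, population=None,
) -> np.ndarray:
    """Age-standardised trajectory draws with every member country's own
    covariate fixed-effect contribution removed on the probit scale.

    Isolates the hierarchical part of an estimate (levels, trends, smooth
    components) from what the country's covariates predict — useful for
    examining how strongly a data-poor country is shrunk toward its region
    and the global trajectory.
    """
    import pandas as pd

    if covariate_names is None:
        covariate_names = [
            n[4:] for n in draws.coefficients[sex] if n.startswith("cov_")
        ]
    cov = covariates.set_index(["country_id", "year"])
    zcols = {}
    for k in covariate_names:
        v = covariates[k].to_numpy()
        zcols[k] = (cov[k] - v.mean()) / (v.std() or 1.0)
    coefs = draws.coefficients[sex]
    w = weights.vector()
    si = draws._sidx(sex)
    members = draws._unit_countries(unit)
    pop = population if population is not None else draws.population
    if pop is None and len(members) > 1:
        raise ValueError("aggregating over countries requires populations")

    num = None
    den = None
    for c in members:
        ci = draws._cidx(c)
        block = np.clip(
            draws.prevalence[:, ci, :, si, :].astype(float), 1e-9, 1 - 1e-9
        )
        zadj = np.zeros((draws.n_draws, len(draws.years)))
        for k in covariate_names:
            zs = np.array([zcols[k][(c, int(y))] for y in draws.years])
            zadj += np.outer(coefs[f"cov_{k}"], zs)
        adj = ndtr(ndtri(block) - zadj[:, :, None])
        std = adj @ w  # (draw, year)
        if len(members) == 1:
            return std
        share = pop[ci, :, si, :].sum(axis=-1)
        num = std * share if num is None else num + std * share
        den = share if den is None else den + share
    return num / den


def predict_prevalence(draws: PosteriorDraws, country, year, sex) -> np.ndarray:
    """Module-level convenience wrapper around PosteriorDraws.predict_prevalence."""
    return draws.predict_prevalence(country, year, sex)


def posterior_prob_increase(
    draws: PosteriorDraws, unit, sex, year0, year1,
    weights: StandardPopulation, population=None,
) -> float:
    """Posterior probability that age-standardised prevalence increased
    between year0 and year1 (strict inequality; equal years give 0.0)."""
    return draws.posterior_prob_increase(
        unit, sex, year0, year1, weights, population
    )
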