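"""Probit-scale transforms shared across the package.

All modelling happens on the probit scale: a proportion p in (0, 1) maps to
``Phi^-1(p)`` where Phi is the standard normal CDF. Observed survey
proportions of exactly 0 or 1 are continuity-corrected before the transform
so that the probit likelihood stays finite.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

# Proportions are clamped to this open interval before any probit transform
# of a quantity that did not come with raw counts.
PROB_FLOOR = 1e-6


def probit(p):
    """Map proportions to the probit (inverse standard-normal CDF) scale."""
    p = np.clip(np.asarray(p, dtype=float), PROB_FLOOR, 1.0 - PROB_FLOOR)
    return stats.norm.ppf(p)


def inv_probit(z):
    """Map probit-scale values back to proportions."""
    return stats.norm.cdf(z)


def continuity_correct(successes, n):
    """Anscombe-style correction ``(x + 0.5) / (n + 1)``.

    Keeps proportions strictly inside (0, 1) when a stratum observed zero
    or ``n`` positives, so the probit transform is finite.
    """
    successes = np.asarray(successes, dtype=float)
    n = np.asarray(n, dtype=float)
    return (successes + 0.5) / (n + 1.0)


def corrected_proportion(prevalence, n):
    """Continuity-corrected proportion from a reported prevalence and size.

    The implied positive count is rounded to the nearest integer before the
    correction, matching how a prevalence extracted from a report would have
    been computed from counts.
    """
    prevalence = np.asarray(prevalence, dtype=float)
    n = np.asarray(n, dtype=float)
    x = np.rint(prevalence * n)
    return continuity_correct(x, n)


def probit_se(p, se_p):
    """Delta-method standard error of probit(p) given the SE of p."""
    p = np.clip(np.asarray(p, dtype=float), PROB_FLOOR, 1.0 - PROB_FLOOR)
    dens = stats.norm.pdf(stats.norm.ppf(p))
    return np.asarray(se_p, dtype=float) / dens


def binomial_se(p, n):
    """Binomial sampling standard error of a proportion."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    return np.sqrt(np.clip(p * (1.0 - p), 0.0, None) / n)
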