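"""Performance metrics for polygenic scores.

Continuous traits: squared correlation between the score and the
covariate-residualized phenotype. Binary traits: Mann-Whitney AUC, with
an optional conversion to the logit-scale variance for comparing
methods across traits.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats


def residualized_r2(phenotype, covariates, score) -> float:
    """R^2 of a score against the covariate-residualized phenotype.

    The phenotype is regressed on the covariates (with intercept) and
    the squared Pearson correlation between the residuals and the score
    is returned. With no covariates this is the plain squared
    correlation. A zero-variance score gives 0 with a warning.
    """
    y = np.asarray(phenotype, dtype=float)
    s = np.asarray(score, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 samples")
    if covariates is not None and np.size(covariates):
        C = np.column_stack([np.ones(len(y)), np.asarray(covariates, dtype=float)])
        coef, *_ = np.linalg.lstsq(C, y, rcond=None)
        resid = y - C @ coef
    else:
        resid = y - y.mean()
    if s.std() < 1e-300 or resid.std() < 1e-300:
        warnings.warn("zero-variance score or residual; R^2 defined as 0")
        return 0.0
    r = np.corrcoef(resid, s)[0, 1]
    return float(r * r)


def empirical_auc(binary_phenotype, score) -> float:
    """Mann-Whitney AUC with ties counted 1/2."""
    y = np.asarray(binary_phenotype, dtype=float)
    s = np.asarray(score, dtype=float)
    n_case = int((y == 1).sum())
    n_ctrl = int((y == 0).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)  # midranks handle ties
    u = ranks[y == 1].sum() - n_case * (n_case + 1) / 2.0
    return float(u / (n_case * n_ctrl))


def logit_variance_from_auc(auc: float, squared: bool = False) -> float:
    """Logit-scale variance implied by an AUC.

    Default implements sigma^2 = 2 * Phi^{-1}(AUC) with Phi the standard
    normal CDF; ``squared=True`` selects the liability-scale relation
    sigma^2 = 2 * (Phi^{-1}(AUC))^2 instead.
    """
    if not 0.5 <= auc < 1:
        raise ValueError("AUC must be in [0.5, 1)")
    q = stats.norm.ppf(auc)
    return float(2 * q * q) if squared else float(2 * q)


def relative_improvement(value_a: float, value_b: float) -> float:
    """(a - b) / b: fractional gain of a over baseline b."""
    if value_b <= 0:
        raise ValueError("baseline value must be positive")
    return (value_a - value_b) / value_b
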