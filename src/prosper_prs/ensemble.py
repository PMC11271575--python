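"""Ensemble of candidate PRSs via super learning (stacking).

Every (lambda, c, population) solution of the joint model yields a
candidate PRS on the tuning samples. Linear base learners (lasso path,
ridge path, ordinary least squares for continuous traits; lasso and
plain logistic regression for binary traits) are combined with
cross-validated meta-weights -- non-negative least squares on
out-of-fold predictions for continuous traits, AUC maximization over
the simplex for binary traits. Because every base learner is linear in
the candidates, the stack collapses to a single per-SNP weight vector.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.linear_model import (LassoCV, LinearRegression, LogisticRegression,
                                  LogisticRegressionCV, RidgeCV)
from sklearn.model_selection import KFold, StratifiedKFold

from .data_io import GenotypePanel
from .prosper_core import JointSolution

logger = logging.getLogger(__name__)

RIDGE_ALPHAS = np.arange(1.0, 20.0 + 1e-9, 0.1)
LASSO_N_ALPHAS = 100


@dataclass
class CandidatePRSMatrix:
    """Candidate PRS columns on the tuning samples, keyed (li, ci, pop)."""

    sample_ids: np.ndarray
    keys: list  # of (lambda index, c index, population)
    scores: np.ndarray  # samples x candidates

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.sample_ids), len(self.keys)):
            raise ValueError("score matrix shape mismatch")
        if not np.isfinite(self.scores).all():
            raise ValueError("candidate PRS matrix contains non-finite scores")

    @property
    def n_candidates(self) -> int:
        return len(self.keys)


def candidate_prs_matrix(solution: JointSolution,
                         tuning: GenotypePanel) -> CandidatePRSMatrix:
    """Score every unflagged (lambda, c, population) solution on the
    tuning panel (standardized dosages, matching the fitting scale)."""
    panel = tuning.standardize()
    panel_ids = pd.Index(panel.snp_ids)
    cols, keys = [], []
    for li, ci, pop in solution.candidate_keys():
        beta = solution.beta_series(li, ci, pop)
        usable = beta.index.intersection(panel_ids)
        if len(usable) == 0:
            logger.warning("candidate (%d,%d,%s): no usable SNPs, omitted", li, ci, pop)
            continue
        cols.append(panel.score(beta))
        keys.append((li, ci, pop))
    if not cols:
        raise ValueError("no scorable candidates")
    return CandidatePRSMatrix(panel.sample_ids, keys,
                              np.column_stack(cols))


@dataclass
class EnsembleModel:
    """Fitted super learner, collapsed to per-candidate linear weights."""

    keys: list
    trait_type: str
    meta_weights: dict            # base-learner name -> weight
    candidate_weights: pd.Series  # per candidate key, raw-score scale
    intercept: float
    oof_predictions: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    fold_seed: int = 0

    def predict(self, candidates: CandidatePRSMatrix) -> np.ndarray:
        idx = pd.Index(candidates.keys, tupleize_cols=False)
        w = self.candidate_weights.reindex(idx).fillna(0.0).to_numpy()
        return candidates.scores @ w + self.intercept


def _continuous_learners():
    return {
        "lasso": lambda: LassoCV(alphas=LASSO_N_ALPHAS, cv=5, max_iter=5000),
        "ridge": lambda: RidgeCV(alphas=RIDGE_ALPHAS),
        "ols": lambda: LinearRegression(),
    }


def _binary_learners():
    return {
        "lasso": lambda: LogisticRegressionCV(Cs=10, l1_ratios=[1.0],
                                              solver="liblinear", cv=5,
                                              scoring="neg_log_loss",
                                              use_legacy_attributes=False,
                                              max_iter=2000),
        "linear": lambda: LogisticRegression(C=np.inf, max_iter=2000),
    }


def _fit_linear_coefs(model, Xs, y, binary):
    model.fit(Xs, y)
    if binary:
        return model.coef_.ravel().copy(), float(model.intercept_.ravel()[0])
    return model.coef_.ravel().copy(), float(model.intercept_)


def superlearn_combine(candidates: CandidatePRSMatrix, phenotype,
                       trait_type: str = "continuous", folds: int = 10,
                       seed: int = 0) -> EnsembleModel:
    """Fit the super learner on tuning samples.

    Candidate columns are standardized (exact back-transformation
    recorded) and exact duplicates deduplicated before the penalized
    base learners see them. Meta-weights are constrained to the simplex.
    """
    y = np.asarray(phenotype, dtype=float)
    X = candidates.scores
    n, K = X.shape
    if K > n:
        warnings.warn(
            f"{K} candidate PRSs but only {n} tuning samples; penalized base "
            "learners will handle this, but a tuning sample of 1000-3000 or "
            "more is advisable to avoid overfitting the ensemble")
    binary = trait_type == "binary"
    if binary and set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("binary trait must be coded 0/1")

    # deduplicate identical columns; drop constant columns
    _, rep_idx, inverse = np.unique(X, axis=1, return_index=True, return_inverse=True)
    rep_idx = np.sort(rep_idx)
    uniq = X[:, rep_idx]
    mean, sd = uniq.mean(axis=0), uniq.std(axis=0)
    active = sd > 1e-12
    zero_weights = pd.Series(0.0, index=pd.Index(candidates.keys, tupleize_cols=False))
    if not active.any():
        logger.warning("all candidate columns constant; intercept-only ensemble")
        return EnsembleModel(candidates.keys, trait_type, {},
                             zero_weights, float(y.mean()), fold_seed=seed)
    cols = rep_idx[active]
    Xs = (X[:, cols] - mean[active]) / sd[active]

    learners = _binary_learners() if binary else _continuous_learners()
    names = list(learners)
    if binary:
        splitter = StratifiedKFold(folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(Xs, y)
    else:
        splitter = KFold(folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(Xs)
    Z = np.zeros((n, len(names)))
    for train, test in split_iter:
        for j, name in enumerate(names):
            model = learners[name]()
            model.fit(Xs[train], y[train])
            if binary:
                Z[test, j] = model.decision_function(Xs[test])
            else:
                Z[test, j] = model.predict(Xs[test])

    if binary:
        meta = _maximize_auc_on_simplex(Z, y)
    else:
        w, _ = nnls(Z, y)
        meta = w / w.sum() if w.sum() > 0 else np.zeros_like(w)
    meta_weights = dict(zip(names, meta))

    # refit on the full tuning set and collapse to candidate weights
    coef_std = np.zeros(active.sum())
    intercept = 0.0
    for j, name in enumerate(names):
        if meta[j] == 0:
            continue
        c, b = _fit_linear_coefs(learners[name](), Xs, y, binary)
        coef_std += meta[j] * c
        intercept += meta[j] * b
    if not np.any(meta):
        intercept = float(y.mean())
    w_raw = coef_std / sd[active]
    intercept -= float(w_raw @ mean[active])

    weights = zero_weights.copy()
    for pos, col in enumerate(cols):
        # the representative column carries the weight of its duplicate group
        weights.iloc[col] = w_raw[pos]
    return EnsembleModel(candidates.keys, trait_type, meta_weights, weights,
                         float(intercept), _oof_frame(Z, names), seed)


def _oof_frame(Z, names) -> pd.DataFrame:
    return pd.DataFrame(Z, columns=names)


def _maximize_auc_on_simplex(Z, y, step: float = 0.02) -> np.ndarray:
    """Grid search over simplex weights maximizing the Mann-Whitney AUC
    of the combined out-of-fold prediction."""
    from .evaluate import empirical_auc
    L = Z.shape[1]
    grid = np.arange(0.0, 1.0 + 1e-9, step)
    best, best_w = -np.inf, np.zeros(L)
    if L == 1:
        return np.ones(1)
    if L != 2:
        # coarse Dirichlet-style grid for more than two learners
        rng = np.random.default_rng(0)
        cands = rng.dirichlet(np.ones(L), size=500)
        cands = np.vstack([cands, np.eye(L)])
        for w in cands:
            auc = empirical_auc(y, Z @ w)
            if auc > best:
                best, best_w = auc, w
        return best_w
    for a in grid:
        w = np.array([a, 1.0 - a])
        auc = empirical_auc(y, Z @ w)
        if auc > best:
            best, best_w = auc, w
    return best_w


def collapse_weights(model: EnsembleModel, solution: JointSolution,
                     snp_meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Collapse the stack to final per-SNP weights.

    weight_k = sum over (lambda, c, population) of w_{lambda,c,i} *
    beta_{lambda,c,i,k}, over the union of all populations' SNP sets.
    Scoring genotypes with the collapsed weights reproduces the stacked
    prediction minus its intercept.
    """
    total: dict = {}
    for key, w in model.candidate_weights.items():
        if w == 0.0:
            continue
        li, ci, pop = key
        beta = solution.beta_series(li, ci, pop)
        for snp, b in beta.items():
            if b != 0.0:
                total[snp] = total.get(snp, 0.0) + w * b
    all_ids = pd.Index(np.unique(np.concatenate(
        [solution.snp_ids[p] for p in solution.populations])))
    weights = pd.Series(total, dtype=float).reindex(all_ids).fillna(0.0)
    out = pd.DataFrame({"snp_id": weights.index, "weight": weights.to_numpy()})
    if snp_meta is not None:
        out = out.merge(snp_meta[["snp_id", "chrom", "pos", "a1", "a2"]],
                        on="snp_id", how="left")
        out = out[["snp_id", "chrom", "pos", "a1", "a2", "weight"]]
    return out


def weighted_prs_baseline(prs_by_pop: pd.DataFrame, phenotype):
    """Classical weighted PRS: OLS of the phenotype on one optimal
    single-ancestry PRS per population (with intercept).

    Returns (weights including 'intercept', combined score).
    """
    y = np.asarray(phenotype, dtype=float)
    X = prs_by_pop.to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(y)), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("collinear PRS columns; returning least-norm solution")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    weights = pd.Series(coef, index=["intercept"] + list(prs_by_pop.columns))
    return weights, design @ coef
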