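"""Summary-statistic lasso for a single population.

Minimizes, per LD block,

    beta' (R + delta I) beta - 2 beta' r + 2 lambda |beta|_1

over a (delta, lambda) grid by coordinate descent, and selects the
optimal pair on tuning data. The selected pair supplies the reference
tuning parameters (delta0, lambda0) that the joint multi-population
model consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _solver
from .data_io import GenotypePanel, SumStats
from .ld_reference import LDBlockSet

logger = logging.getLogger(__name__)

DEFAULT_DELTA_GRID = (0.001, 0.01, 0.1, 1.0)
LAMBDA_PATH_LENGTH = 30
LAMBDA_MIN_RATIO = 0.01


def zscore_to_r(z, n, method: str = "sqrt_n"):
    """Convert association z-scores to standardized marginal effects.

    ``sqrt_n``: r = z / sqrt(n), clipped to [-0.999, 0.999].
    ``adjusted``: r = z / sqrt(n - 1 + z^2) (bounded by construction).
    """
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 1):
        raise ValueError("sample size must exceed 1")
    if method == "sqrt_n":
        r = z / np.sqrt(n)
    elif method == "adjusted":
        r = z / np.sqrt(n - 1 + z ** 2)
    else:
        raise ValueError(f"unknown conversion method: {method}")
    return np.clip(r, -0.999, 0.999)


def default_lambda_grid(r: np.ndarray, length: int = LAMBDA_PATH_LENGTH) -> np.ndarray:
    """30 values evenly log-spaced from max|r| down to 0.01 max|r|."""
    rmax = np.abs(r).max()
    if rmax == 0:
        raise ValueError("all summary statistics are zero; no lambda path")
    return np.geomspace(rmax, LAMBDA_MIN_RATIO * rmax, length)


@dataclass
class LassosumPath:
    """Coefficient vectors over a (delta, lambda) grid for one population."""

    population: str
    snp_ids: np.ndarray
    deltas: np.ndarray
    lambdas: np.ndarray  # descending
    betas: dict = field(default_factory=dict)      # (di, li) -> coef vector
    diverged: dict = field(default_factory=dict)   # (di, li) -> bool
    objectives: dict = field(default_factory=dict)
    selected: tuple | None = None  # (delta0, lambda0)

    def beta_series(self, di: int, li: int) -> pd.Series:
        return pd.Series(self.betas[(di, li)], index=self.snp_ids)


def _align_blocks(sumstats: SumStats, ld: LDBlockSet):
    """Per-block (snp_ids, r, R) restricted to SNPs present in both."""
    ss = sumstats.df.set_index("snp_id")["r"]
    out = []
    for block in ld.blocks:
        mask = np.isin(block.snp_ids, ss.index.to_numpy())
        ids = block.snp_ids[mask]
        if len(ids) == 0:
            continue
        r = ss.loc[ids].to_numpy(dtype=float)
        R = block.R[np.ix_(mask, mask)].copy()
        np.fill_diagonal(R, 1.0)  # standardized scale convention
        out.append((block.block_id, ids, r, R))
    if not out:
        raise ValueError(f"{sumstats.population}: no SNPs shared between "
                         "summary statistics and LD reference")
    return out


def solve_lassosum_path(sumstats: SumStats, ld: LDBlockSet,
                        delta_grid=None, lambda_grid=None,
                        tol: float = _solver.TOL,
                        max_sweeps: int = _solver.MAX_SWEEPS) -> LassosumPath:
    """Fit the full (delta, lambda) grid by per-block coordinate descent.

    Within each delta, lambdas are visited in decreasing order with warm
    starts (cold start beta=0 at lambda_max). Divergent fits (L1 norm
    beyond 10x the theoretical bound sum|r|/lambda, or an objective that
    rises on 3 consecutive sweeps) are flagged.
    """
    deltas = np.asarray(DEFAULT_DELTA_GRID if delta_grid is None else delta_grid,
                        dtype=float)
    aligned = _align_blocks(sumstats, ld)
    all_r = np.concatenate([r for _, _, r, _ in aligned])
    lambdas = (default_lambda_grid(all_r) if lambda_grid is None
               else np.sort(np.asarray(lambda_grid, dtype=float))[::-1])
    if np.any(lambdas <= 0):
        raise ValueError("lambda values must be strictly positive")
    snp_ids = np.concatenate([ids for _, ids, _, _ in aligned])
    path = LassosumPath(sumstats.population, snp_ids, deltas, lambdas)

    n_total = len(snp_ids)
    for di, delta in enumerate(deltas):
        for li in range(len(lambdas)):
            path.betas[(di, li)] = np.zeros(n_total)
            path.diverged[(di, li)] = False
            path.objectives[(di, li)] = 0.0
    share = np.zeros((1, 1, 1), dtype=np.bool_)
    C = np.zeros((1, 1))
    for _, ids, r, R in aligned:
        p = len(ids)
        pos = pd.Index(snp_ids).get_indexer(ids)
        present = np.ones((1, p), dtype=np.bool_)
        share_b = np.zeros((1, 1, p), dtype=np.bool_)
        r2d = r[None, :]
        R3d = R[None, :, :]
        sum_abs_r = np.abs(r).sum()
        for di, delta in enumerate(deltas):
            warm = np.zeros((1, p))
            for li, lam in enumerate(lambdas):
                bound = 10.0 * max(sum_abs_r, 1e-12) / lam
                beta, trace, _, diverged = _solver.solve_block(
                    r2d, R3d, present, share_b, C, np.array([lam]),
                    np.array([delta]), beta0=warm, tol=tol,
                    max_sweeps=max_sweeps, divergence_bound=bound)
                if np.abs(beta).sum() > bound:
                    diverged = True
                warm = beta
                path.betas[(di, li)][pos] = beta[0]
                path.diverged[(di, li)] |= bool(diverged)
                path.objectives[(di, li)] += float(trace[-1])
    return path


def _metric_value(score: np.ndarray, phenotype: np.ndarray, metric: str) -> float:
    from .evaluate import empirical_auc, residualized_r2
    if metric == "r2":
        return residualized_r2(phenotype, None, score)
    if metric == "auc":
        return empirical_auc(phenotype, score)
    raise ValueError(f"unknown metric: {metric}")


def select_reference_params(path: LassosumPath, tuning: GenotypePanel,
                            phenotype, metric: str = "r2") -> tuple[float, float]:
    """Pick (delta0, lambda0) maximizing the tuning metric.

    Ties are broken toward the larger lambda (sparser model). The tuning
    panel is standardized to match the scale the coefficients were fit on.
    """
    phenotype = np.asarray(phenotype, dtype=float)
    panel = tuning.standardize()
    best = None  # (metric, lambda, delta, key)
    for (di, li), beta in path.betas.items():
        if path.diverged[(di, li)]:
            continue
        score = panel.score(pd.Series(beta, index=path.snp_ids))
        if np.ptp(score) == 0.0:  # fully shrunk model: no discrimination
            val = 0.0 if metric == "r2" else 0.5
        else:
            val = _metric_value(score, phenotype, metric)
        lam = path.lambdas[li]
        key = (val, lam)
        if best is None or key > best[0]:
            best = (key, path.deltas[di], lam)
    if best is None:
        raise RuntimeError(f"{path.population}: every (delta, lambda) fit diverged")
    path.selected = (float(best[1]), float(best[2]))
    return path.selected
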