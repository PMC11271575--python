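"""Joint multi-population penalized regression on GWAS summary statistics.

M populations are fit simultaneously: each gets its own lasso penalty
lambda_i = lambda * lambda_i0 (lambda_i0 from the single-ancestry fit),
its own fixed LD regularizer delta_i0, and every pair of populations is
tied by a ridge penalty c on the differences of effect sizes at shared
SNPs. Only two tuning parameters remain -- the lasso scale factor
lambda and the similarity penalty c -- searched over a small grid, and
every (lambda, c, population) solution becomes a candidate PRS for the
downstream ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _solver
from .data_io import SumStats
from .ld_reference import LDBlockSet, SharedSnpIndex, build_shared_index

logger = logging.getLogger(__name__)

LAMBDA_PATH_LENGTH = 10
LAMBDA_MIN_RATIO = 0.001
C_MIN, C_MAX, C_PATH_LENGTH = 2.0, 100.0, 10


def build_lambda_path(sumstats_by_pop: list[SumStats], lambda0_by_pop,
                      length: int = LAMBDA_PATH_LENGTH) -> np.ndarray:
    """Scale-factor path for the lasso penalties.

    lambda_max = min over populations of max_k |r_ik| / lambda_i0 (the
    largest factor at which every population still admits a non-zero
    solution); lambda_min = 0.001 lambda_max; values evenly log-spaced,
    decreasing.
    """
    lambda0 = np.asarray(lambda0_by_pop, dtype=float)
    if np.any(lambda0 <= 0):
        raise ValueError("reference lambda0 values must be positive")
    rmax = np.array([np.abs(ss.r).max() for ss in sumstats_by_pop])
    if np.any(rmax == 0):
        raise ValueError("a population has all-zero summary statistics")
    lam_max = float(np.min(rmax / lambda0))
    return np.geomspace(lam_max, LAMBDA_MIN_RATIO * lam_max, length)


def build_c_path(c_min: float = C_MIN, c_max: float = C_MAX,
                 length: int = C_PATH_LENGTH) -> np.ndarray:
    """Similarity-penalty path, evenly spaced on a quad-root scale."""
    if c_min <= 0 or c_min >= c_max:
        raise ValueError("require 0 < c_min < c_max")
    return np.linspace(c_min ** 0.25, c_max ** 0.25, length) ** 4


def prosper_update(u: float, lam: float, delta: float, c_sum: float) -> float:
    """Exact coordinate update: scaled soft-threshold of the partial
    residual u, with denominator 1 + delta + sum of applicable c."""
    shrunk = max(0.0, abs(u) - lam)
    return float(np.sign(u) * shrunk / (1.0 + delta + c_sum))


def distance_scaled_c(c: float, r_scale: float, flagged_pop: str,
                      pair: tuple[str, str]) -> float:
    """Pair penalty with an extra scale for a genetically distant
    population: r_scale * c when the flagged population is in the pair."""
    return r_scale * c if flagged_pop in pair else c


@dataclass
class PenaltyGrid:
    """All penalty settings for one joint fit."""

    populations: list[str]
    delta0: dict  # population -> fixed LD regularizer
    lambda0: dict  # population -> reference lasso penalty
    lambda_path: np.ndarray  # decreasing scale factors
    c_path: np.ndarray  # increasing similarity penalties
    r_scale: float | None = None  # optional distance scaling factor
    flagged_pop: str | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lambda_path) >= 0) or np.any(self.lambda_path <= 0):
            raise ValueError("lambda path must be strictly decreasing and positive")
        if np.any(np.diff(self.c_path) <= 0):
            raise ValueError("c path must be strictly increasing")

    @classmethod
    def from_reference(cls, sumstats_by_pop: list[SumStats], reference_params: dict,
                       lambda_length: int = LAMBDA_PATH_LENGTH,
                       c_length: int = C_PATH_LENGTH,
                       c_min: float = C_MIN, c_max: float = C_MAX,
                       r_scale: float | None = None,
                       flagged_pop: str | None = None) -> "PenaltyGrid":
        """Build the grid from single-ancestry (delta0, lambda0) per population."""
        pops = [ss.population for ss in sumstats_by_pop]
        delta0 = {p: float(reference_params[p][0]) for p in pops}
        lambda0 = {p: float(reference_params[p][1]) for p in pops}
        lam_path = build_lambda_path(sumstats_by_pop, [lambda0[p] for p in pops],
                                     lambda_length)
        return cls(pops, delta0, lambda0, lam_path,
                   build_c_path(c_min, c_max, c_length), r_scale, flagged_pop)

    def pair_c(self, c: float, pop_a: str, pop_b: str) -> float:
        if self.r_scale is None or self.flagged_pop is None:
            return c
        return distance_scaled_c(c, self.r_scale, self.flagged_pop, (pop_a, pop_b))


@dataclass
class JointSolution:
    """Sparse coefficient vectors for every (lambda, c, population)."""

    populations: list[str]
    snp_ids: dict  # population -> modeled SNP order
    lambda_path: np.ndarray
    c_path: np.ndarray
    betas: dict = field(default_factory=dict)      # (li, ci) -> {pop: coefs}
    diverged: dict = field(default_factory=dict)   # (li, ci) -> bool
    objectives: dict = field(default_factory=dict)
    traces: dict = field(default_factory=dict)     # (li, ci) -> list of per-block traces

    @property
    def settings(self) -> list[tuple[int, int]]:
        return sorted(self.betas.keys())

    def candidate_keys(self) -> list[tuple[int, int, str]]:
        """Unflagged (lambda index, c index, population) triples."""
        return [(li, ci, pop) for (li, ci) in self.settings
                if not self.diverged[(li, ci)] for pop in self.populations]

    def beta_series(self, li: int, ci: int, pop: str) -> pd.Series:
        return pd.Series(self.betas[(li, ci)][pop], index=self.snp_ids[pop])


def _assemble_blocks(sumstats_by_pop, ld_by_pop, shared: SharedSnpIndex):
    """Dense per-block arrays over the union of SNPs across populations."""
    pops = [ss.population for ss in sumstats_by_pop]
    M = len(pops)
    r_maps = {ss.population: ss.df.set_index("snp_id")["r"] for ss in sumstats_by_pop}
    # block order: union of block ids in first-seen order
    block_ids: list[str] = []
    for pop in pops:
        for b in ld_by_pop[pop].blocks:
            if b.block_id not in block_ids:
                block_ids.append(b.block_id)
    blocks = []
    for bid in block_ids:
        per_pop = {}
        union: list = []
        seen = set()
        for pop in pops:
            blk = next((b for b in ld_by_pop[pop].blocks if b.block_id == bid), None)
            if blk is None:
                continue
            mask = np.isin(blk.snp_ids, r_maps[pop].index.to_numpy())
            ids = blk.snp_ids[mask]
            per_pop[pop] = (ids, blk.R[np.ix_(mask, mask)])
            for s in ids:
                if s not in seen:
                    seen.add(s)
                    union.append(s)
        if not union:
            continue
        p = len(union)
        index = {s: j for j, s in enumerate(union)}
        present = np.zeros((M, p), dtype=np.bool_)
        r = np.zeros((M, p))
        R = np.zeros((M, p, p))
        for i in range(M):
            R[i][np.diag_indices(p)] = 1.0
        for i, pop in enumerate(pops):
            if pop not in per_pop:
                continue
            ids, Rblk = per_pop[pop]
            pos = np.array([index[s] for s in ids])
            present[i, pos] = True
            r[i, pos] = r_maps[pop].loc[ids].to_numpy(dtype=float)
            R[i][np.ix_(pos, pos)] = Rblk
            R[i][np.diag_indices(p)] = 1.0
        share = np.zeros((M, M, p), dtype=np.bool_)
        for i1 in range(M):
            for i2 in range(M):
                if i1 == i2:
                    continue
                pair_set = shared.shared(pops[i1], pops[i2])
                in_pair = np.array([s in pair_set for s in union], dtype=bool)
                share[i1, i2] = present[i1] & present[i2] & in_pair
        blocks.append({"block_id": bid, "union": np.array(union, dtype=object),
                       "present": present, "r": r, "R": R, "share": share})
    if not blocks:
        raise ValueError("no SNPs shared between summary statistics and LD reference")
    return pops, blocks


def solve_joint_block(r, R, present, share, C, lam, delta, beta0=None,
                      tol: float = _solver.TOL,
                      max_sweeps: int = _solver.MAX_SWEEPS,
                      divergence_bound: float = np.inf,
                      track_objective: bool = True):
    """Coordinate descent for one LD block across all populations.

    Thin wrapper over the compiled kernel; see the module docstring for
    the objective. Returns (beta (M,p), objective trace, converged,
    diverged)."""
    return _solver.solve_block(r, R, present, share, C, lam, delta,
                               beta0=beta0, tol=tol, max_sweeps=max_sweeps,
                               divergence_bound=divergence_bound,
                               track_objective=track_objective)


def solve_prosper_grid(sumstats_by_pop: list[SumStats], ld_by_pop: dict,
                       grid: PenaltyGrid, shared: SharedSnpIndex | None = None,
                       tol: float = _solver.TOL,
                       max_sweeps: int = _solver.MAX_SWEEPS,
                       keep_traces: bool = False) -> JointSolution:
    """Solve every (lambda, c) cell of the penalty grid over all blocks.

    Blocks are independent (block-diagonal LD); within a fixed c the
    lambda path is warm-started from the next-larger lambda. Divergent
    cells are flagged but their partial results retained.
    """
    if shared is None:
        shared = build_shared_index(sumstats_by_pop)
    pops, blocks = _assemble_blocks(sumstats_by_pop, ld_by_pop, shared)
    M = len(pops)
    snp_ids = {}
    for i, pop in enumerate(pops):
        snp_ids[pop] = np.concatenate([b["union"][b["present"][i]] for b in blocks])
    sol = JointSolution(pops, snp_ids, grid.lambda_path, grid.c_path)
    lam0 = np.array([grid.lambda0[p] for p in pops])
    delta = np.array([grid.delta0[p] for p in pops])
    max_abs_r = max(float(np.abs(ss.r).max()) for ss in sumstats_by_pop)
    min_lambda_eff = grid.lambda_path[-1] * lam0.min()
    bound = 10.0 * max_abs_r / min_lambda_eff

    n_cells = len(grid.lambda_path) * len(grid.c_path)
    for li in range(len(grid.lambda_path)):
        for ci in range(len(grid.c_path)):
            sol.betas[(li, ci)] = {pop: np.zeros(len(snp_ids[pop])) for pop in pops}
            sol.diverged[(li, ci)] = False
            sol.objectives[(li, ci)] = 0.0
            if keep_traces:
                sol.traces[(li, ci)] = []

    offsets = {pop: 0 for pop in pops}
    for b in blocks:
        p = len(b["union"])
        pos_in_pop = {pop: slice(offsets[pop], offsets[pop] + int(b["present"][i].sum()))
                      for i, pop in enumerate(pops)}
        for ci, c in enumerate(grid.c_path):
            C = np.zeros((M, M))
            for i1 in range(M):
                for i2 in range(M):
                    if i1 != i2:
                        C[i1, i2] = grid.pair_c(c, pops[i1], pops[i2])
            warm = np.zeros((M, p))
            for li, lam_factor in enumerate(grid.lambda_path):
                lam = lam_factor * lam0
                beta, trace, _, diverged = solve_joint_block(
                    b["r"], b["R"], b["present"], b["share"], C, lam, delta,
                    beta0=warm, tol=tol, max_sweeps=max_sweeps,
                    divergence_bound=bound, track_objective=True)
                warm = beta
                cell = sol.betas[(li, ci)]
                for i, pop in enumerate(pops):
                    cell[pop][pos_in_pop[pop]] = beta[i][b["present"][i]]
                sol.diverged[(li, ci)] |= bool(diverged)
                sol.objectives[(li, ci)] += float(trace[-1])
                if keep_traces:
                    sol.traces[(li, ci)].append(trace)
        for i, pop in enumerate(pops):
            offsets[pop] += int(b["present"][i].sum())
    n_flagged = sum(sol.diverged.values())
    if n_flagged:
        logger.warning("%d of %d grid cells flagged divergent", n_flagged, n_cells)
    return sol


def kkt_max_violation(beta, r, R, present, share, C, lam, delta) -> float:
    """Largest relative KKT violation over all coordinates of one block.

    At a minimizer, for beta_ik != 0 the gradient of the smooth part
    equals -lam_i sign(beta_ik); for beta_ik = 0 its magnitude is at
    most lam_i. Returns max over coordinates of the scaled excess."""
    M, p = beta.shape
    worst = 0.0
    csum = (C[:, :, None] * share).sum(axis=1)
    for i in range(M):
        for k in range(p):
            if not present[i, k]:
                continue
            g = (R[i, k] @ beta[i]) + delta[i] * beta[i, k] - r[i, k]
            for i2 in range(M):
                if i2 != i and share[i, i2, k]:
                    g += C[i, i2] * (beta[i, k] - beta[i2, k])
            if beta[i, k] != 0.0:
                viol = abs(g + lam[i] * np.sign(beta[i, k])) / max(lam[i], 1e-300)
            else:
                viol = max(0.0, abs(g) - lam[i]) / max(lam[i], 1e-300)
            worst = max(worst, viol)
    return worst
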