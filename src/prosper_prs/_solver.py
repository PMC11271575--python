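"""Blockwise coordinate-descent kernels for the joint penalized objective.

One LD block at a time, all M populations jointly. Coefficients live on
the standardized genotype scale; within a block each population i sees

    beta_i' (R_i + delta_i I) beta_i - 2 beta_i' r_i + 2 lambda_i |beta_i|_1

plus, for each population pair sharing a SNP, a ridge penalty
c_{i1,i2} * (beta_{i1,k} - beta_{i2,k})^2 pulling shared effects together.
The exact coordinate update is a scaled soft-threshold:

    beta_ik <- S(u_ik, lambda_i) / (1 + delta_i + sum of applicable c)

with u_ik the partial residual plus the cross-population pull. The
kernels operate on dense per-block arrays indexed over the union of the
block's SNPs across populations; ``present`` masks population membership.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MAX_SWEEPS = 1000
TOL = 1e-7


@njit(cache=True)
def sweep(beta, r, R, present, share, C, lam, delta, csum):
    """One full cyclic sweep (population-major, then SNP order).

    beta (M,p) is updated in place; returns the max absolute coefficient
    change. R is (M,p,p) with unit diagonal on present SNPs; share is
    (M,M,p) membership of SNP k in the pair's shared set; csum[i,k] is
    the precomputed sum of c over partners of population i at SNP k.
    """
    M, p = beta.shape
    max_change = 0.0
    for i in range(M):
        for k in range(p):
            if not present[i, k]:
                continue
            acc = 0.0
            for k2 in range(p):
                acc += R[i, k, k2] * beta[i, k2]
            acc -= beta[i, k]  # remove the diagonal term (R_kk = 1)
            cross = 0.0
            for i2 in range(M):
                if i2 != i and share[i, i2, k]:
                    cross += C[i, i2] * beta[i2, k]
            u = r[i, k] - acc + cross
            denom = 1.0 + delta[i] + csum[i, k]
            if u > lam[i]:
                new = (u - lam[i]) / denom
            elif u < -lam[i]:
                new = (u + lam[i]) / denom
            else:
                new = 0.0
            change = abs(new - beta[i, k])
            if change > max_change:
                max_change = change
            beta[i, k] = new
    return max_change


@njit(cache=True)
def objective(beta, r, R, present, share, C, lam, delta):
    """Value of the joint penalized objective on one block."""
    M, p = beta.shape
    obj = 0.0
    for i in range(M):
        for k in range(p):
            if not present[i, k]:
                continue
            b = beta[i, k]
            if b == 0.0:
                continue
            row = 0.0
            for k2 in range(p):
                row += R[i, k, k2] * beta[i, k2]
            obj += b * (row + delta[i] * b) - 2.0 * b * r[i, k] + 2.0 * lam[i] * abs(b)
    for i1 in range(M):
        for i2 in range(i1 + 1, M):
            for k in range(p):
                if share[i1, i2, k]:
                    d = beta[i1, k] - beta[i2, k]
                    obj += C[i1, i2] * d * d
    return obj


def solve_block(r, R, present, share, C, lam, delta, beta0=None,
                tol: float = TOL, max_sweeps: int = MAX_SWEEPS,
                divergence_bound: float = np.inf,
                track_objective: bool = True):
    """Run coordinate descent on one block until convergence.

    Returns (beta, objective_trace, converged, diverged). Divergence is
    declared when any |beta| exceeds ``divergence_bound`` or the
    objective increases on 3 consecutive sweeps; the partial result is
    retained.
    """
    M, p = r.shape
    beta = np.zeros((M, p)) if beta0 is None else beta0.astype(float).copy()
    csum = (C[:, :, None] * share).sum(axis=1)
    trace = []
    if track_objective:
        trace.append(objective(beta, r, R, present, share, C, lam, delta))
    rises = 0
    converged = False
    diverged = False
    for _ in range(max_sweeps):
        change = sweep(beta, r, R, present, share, C, lam, delta, csum)
        if track_objective:
            obj = objective(beta, r, R, present, share, C, lam, delta)
            if obj > trace[-1] * (1 + 1e-12) + 1e-12:
                rises += 1
            else:
                rises = 0
            trace.append(obj)
            if rises >= 3:
                diverged = True
                break
        if np.abs(beta).max() > divergence_bound:
            diverged = True
            break
        if change < tol:
            converged = True
            break
    return beta, np.array(trace), converged, diverged
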