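"""Independent brute-force oracles for the penalized objectives.

These deliberately avoid coordinate descent: the nonsmooth L1 term is
removed by splitting each coefficient into positive and negative parts,
leaving a smooth box-constrained problem solved with L-BFGS-B.
"""

import numpy as np
from scipy.optimize import minimize


def joint_objective(beta, r, R, present, share, C, lam, delta):
    M, p = beta.shape
    obj = 0.0
    for i in range(M):
        b = np.where(present[i], beta[i], 0.0)
        A = R[i] + delta[i] * np.eye(p)
        obj += b @ A @ b - 2 * b @ r[i] + 2 * lam[i] * np.abs(b).sum()
    for i1 in range(M):
        for i2 in range(i1 + 1, M):
            d = np.where(share[i1, i2], beta[i1] - beta[i2], 0.0)
            obj += C[i1, i2] * (d @ d)
    return float(obj)


def joint_oracle(r, R, present, share, C, lam, delta):
    """Minimize the joint objective with a generic convex solver."""
    M, p = r.shape
    idx = [(i, k) for i in range(M) for k in range(p) if present[i, k]]
    nv = len(idx)

    def unpack(x):
        beta = np.zeros((M, p))
        for j, (i, k) in enumerate(idx):
            beta[i, k] = x[j] - x[nv + j]
        return beta

    def f(x):
        return joint_objective(unpack(x), r, R, present, share, C, lam, delta)

    def grad(x):
        beta = unpack(x)
        g = np.zeros(nv)
        for j, (i, k) in enumerate(idx):
            gi = 2 * (R[i][k] @ beta[i] + delta[i] * beta[i, k] - r[i, k])
            for i2 in range(M):
                if i2 != i and share[i, i2, k]:
                    gi += 2 * C[i, i2] * (beta[i, k] - beta[i2, k])
            g[j] = gi
        return np.concatenate([g + 2 * lam_of(idx, lam),
                               -g + 2 * lam_of(idx, lam)])

    def lam_of(index, lam_vec):
        return np.array([lam_vec[i] for i, _ in index])

    res = minimize(f, np.zeros(2 * nv), jac=grad, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * nv),
                   options={"ftol": 1e-18, "gtol": 1e-12, "maxiter": 50_000})
    beta = _fista_polish(unpack(res.x), r, R, present, share, C, lam, delta)
    return beta, joint_objective(beta, r, R, present, share, C, lam, delta)


def _fista_polish(beta0, r, R, present, share, C, lam, delta, iters=20_000):
    """Accelerated proximal-gradient refinement (independent of any
    coordinate-wise scheme): gradient step on the smooth quadratic part,
    then the L1 proximal map, with Nesterov momentum."""
    M, p = r.shape
    L = 2 * max(np.linalg.eigvalsh(R[i]).max() + delta[i] for i in range(M))
    L += 4 * C.max(initial=0.0) * (M - 1)
    step = 1.0 / L
    beta = beta0 * present
    z = beta.copy()
    t = 1.0
    for _ in range(iters):
        g = np.zeros_like(z)
        for i in range(M):
            g[i] = 2 * (R[i] @ z[i] + delta[i] * z[i] - r[i])
            for i2 in range(M):
                if i2 != i:
                    g[i] += 2 * C[i, i2] * share[i, i2] * (z[i] - z[i2])
        y = z - step * g
        thr = 2 * step * lam[:, None]  # nonsmooth part is 2*lam*|beta|
        new = np.sign(y) * np.maximum(0.0, np.abs(y) - thr) * present
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        z = new + ((t - 1) / t_new) * (new - beta)
        beta, t = new, t_new
    return beta
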