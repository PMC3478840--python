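"""Independent reference implementations used to cross-check the package.

These deliberately use different code paths (naive loops, a generic
convex solver) from the implementations they verify.
"""

import numpy as np
from scipy.optimize import minimize


def brute_cv_fast(trace, window_s=0.1):
    """O(n*w) reference: per-axis max-min over the causal window."""
    w = int(np.ceil(window_s * trace.fs))
    out = np.zeros(len(trace))
    axes = trace.xyz
    for i in range(len(trace)):
        lo = max(0, i - w + 1)
        win = axes[lo : i + 1]
        out[i] = np.sqrt(np.sum((win.max(axis=0) - win.min(axis=0)) ** 2))
    return out


def rbf_matrix(A, B, gamma):
    d2 = (
        np.sum(A**2, axis=1)[:, None]
        - 2.0 * A @ B.T
        + np.sum(B**2, axis=1)[None, :]
    )
    return np.exp(-gamma * np.maximum(d2, 0.0))


def qp_oracle(X, D, gamma, C):
    """L1 soft-margin dual via SLSQP: maximize sum(a) - a^T Q a / 2
    subject to 0 <= a <= C and a . D = 0; bias from the free vectors."""
    m = len(D)
    Q = np.outer(D, D) * rbf_matrix(X, X, gamma)

    def negdual(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - np.ones(m)

    best = None
    for x0 in (np.zeros(m), np.full(m, min(C / 2, 0.5)), np.full(m, 0.1)):
        res = minimize(
            negdual,
            x0,
            jac=grad,
            bounds=[(0.0, C)] * m,
            constraints=[
                {"type": "eq", "fun": lambda a: a @ D, "jac": lambda a: D.astype(float)}
            ],
            method="SLSQP",
            options={"maxiter": 2000, "ftol": 1e-14},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        if res.success:
            break
    a = np.clip(best.x, 0.0, C)
    free = (a > 1e-6) & (a < C - 1e-6)
    K = rbf_matrix(X, X, gamma)
    if free.any():
        b = np.mean(D[free] - (a * D) @ K[:, free])
    else:
        act = a > 1e-8
        b = np.mean(D[act] - (a * D) @ K[:, act])
    return a, float(b)


def qp_scores(X, D, a, b, gamma, probes):
    return rbf_matrix(probes, X, gamma) @ (a * D) + b
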