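"""Independent reference SEM fitter for cross-checking the package engine.

Deliberately different route from ecoimmune.sem everywhere it matters:
the implied covariance is built by accumulating matrix powers of the
coefficient matrix (total-effects series of the acyclic graph) rather than a
matrix inverse; the objective is the raw multivariate-normal negative
log-likelihood rather than the F_ML discrepancy; optimization is Nelder-Mead
followed by numeric-gradient BFGS rather than analytic-gradient L-BFGS-B
with Newton polish. Only the model description is shared.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def _layout(spec):
    """Free-parameter layout mirrored from the model description itself."""
    variables = spec.observed + list(spec.latents)
    idx = {v: k for k, v in enumerate(variables)}
    entries = []  # (name, kind, i, j)
    for latent, inds in spec.latents.items():
        for ind in inds[1:]:
            entries.append((f"{latent}=~{ind}", "loading", idx[ind], idx[latent]))
    for src, dst in spec.paths:
        entries.append((f"{dst}~{src}", "path", idx[dst], idx[src]))
    for v in variables:
        entries.append((f"{v}~~{v}", "variance", idx[v], idx[v]))
    for a, b in spec.covariances:
        entries.append((f"{a}~~{b}", "covariance", idx[a], idx[b]))
    return variables, idx, entries


def implied_cov_path_tracing(spec, theta):
    """Sigma over observed vars via the total-effect series sum_k A^k."""
    variables, idx, entries = _layout(spec)
    m = len(variables)
    A = np.zeros((m, m))
    S0 = np.zeros((m, m))
    for latent, inds in spec.latents.items():
        A[idx[inds[0]], idx[latent]] = 1.0
    for (name, kind, i, j), v in zip(entries, theta):
        if kind in ("loading", "path"):
            A[i, j] = v
        elif kind == "variance":
            S0[i, i] = v
        else:
            S0[i, j] = S0[j, i] = v
    total = np.eye(m)
    power = np.eye(m)
    for _ in range(m):          # A is nilpotent for an acyclic graph
        power = power @ A
        if not power.any():
            break
        total = total + power
    sigma_all = total @ S0 @ total.T
    p = len(spec.observed)
    return sigma_all[:p, :p]


def neg_loglik(spec, theta, S, n):
    """-2/(n-1) * profile Gaussian log-likelihood, up to constants in S."""
    sigma = implied_cov_path_tracing(spec, theta)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    return logdet + float(np.trace(np.linalg.solve(sigma, S)))


def reference_fit(spec, data, seed=0, n_starts=4):
    """Fit by Nelder-Mead + numeric-gradient BFGS. Returns dict of results."""
    X = data[spec.observed].astype(float).dropna().to_numpy()
    n = X.shape[0]
    p = X.shape[1]
    S = np.cov(X, rowvar=False, ddof=1)
    variables, idx, entries = _layout(spec)
    x0 = []
    for name, kind, i, j in entries:
        if kind == "variance":
            x0.append(S[i, i] / 2.0 if i < p else 1.0)
        elif kind == "loading":
            x0.append(1.0)
        else:
            x0.append(0.0)
    x0 = np.array(x0)
    rng = np.random.default_rng(seed)

    def fun(theta):
        return neg_loglik(spec, theta, S, n)

    best = None
    for trial in range(n_starts):
        start = x0 if trial == 0 else x0 + rng.normal(0, 0.2, size=x0.size)
        nm = optimize.minimize(fun, start, method="Nelder-Mead",
                               options={"maxiter": 20000, "fatol": 1e-12,
                                        "xatol": 1e-10})
        bf = optimize.minimize(fun, nm.x, method="BFGS",
                               options={"maxiter": 2000, "gtol": 1e-10})
        cand = bf if bf.fun <= nm.fun else nm
        if best is None or cand.fun < best.fun:
            best = cand
    theta = best.x
    sigma = implied_cov_path_tracing(spec, theta)
    sign, logdet_S = np.linalg.slogdet(S)
    fml = best.fun - logdet_S - p
    chi2 = max((n - 1) * fml, 0.0)
    df = p * (p + 1) // 2 - len(entries)
    # independence baseline
    base_fml = float(np.sum(np.log(np.diag(S)))) - logdet_S
    baseline_chi2 = (n - 1) * base_fml
    baseline_df = p * (p - 1) // 2
    d = np.sqrt(np.diag(S))
    resid = (S - sigma) / np.outer(d, d)
    iu = np.triu_indices(p)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    num = max(chi2 - df, 0.0)
    den = max(baseline_chi2 - baseline_df, num)
    cfi = 1.0 - num / den if den > 0 else 1.0
    rmsea = np.sqrt(num / (df * (n - 1))) if df > 0 else 0.0
    return {
        "names": [e[0] for e in entries],
        "theta": theta,
        "fml": fml,
        "chi2": chi2,
        "df": df,
        "cfi": cfi,
        "srmr": srmr,
        "rmsea": float(rmsea),
        "n": n,
    }
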