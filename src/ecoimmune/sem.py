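"""Covariance-based maximum-likelihood structural equation modelling.

A model has observed variables, optionally latent variables measured by
indicator lists (first loading fixed to 1 for identification), and directed
paths among variables. The implied covariance uses the RAM parameterization

    Sigma(theta) = F (I - A)^-1 S0 (I - A)^-T F^T

with A holding directed coefficients (paths and loadings), S0 the symmetric
matrix of exogenous variances/covariances and residual variances, and F the
selection matrix onto the observed rows. Fitting minimizes the ML
discrepancy

    F_ML(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

with an analytic gradient and seeded multi-start quasi-Newton optimization;
chi2 = (n - 1) F_ML, standard errors come from the numeric Hessian of F_ML
via Cov(theta) = (2 / (n - 1)) H^-1, and RMSEA (with noncentral-chi2 90% CI),
CFI against the independence baseline, and SRMR are reported alongside the
raw and standardized solutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .condition import pow10_rescale
from .records import ANTIBODIES


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass
class SemModelSpec:
    """A latent-path model.

    ``latents`` maps each latent name to its ordered indicator list (the
    first indicator's loading is fixed to 1). ``paths`` are directed (src,
    dst) edges among structural variables. ``covariances`` are free
    covariances among exogenous variables.
    """

    name: str
    observed: list[str]
    latents: dict[str, list[str]] = field(default_factory=dict)
    paths: list[tuple[str, str]] = field(default_factory=list)
    covariances: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for latent, inds in self.latents.items():
            if not inds:
                raise ValueError(f"latent {latent!r} has no indicators")
            for ind in inds:
                if ind not in self.observed:
                    raise ValueError(f"indicator {ind!r} not in observed")
        indicator_of: dict[str, str] = {}
        for latent, inds in self.latents.items():
            for ind in inds:
                if ind in indicator_of:
                    raise ValueError(
                        f"indicator {ind!r} loads on more than one latent"
                    )
                indicator_of[ind] = latent
        self._assert_acyclic()

    @property
    def variables(self) -> list[str]:
        """All model variables, observed first then latents."""
        return self.observed + list(self.latents)

    def _assert_acyclic(self) -> None:
        edges = list(self.paths)
        order: dict[str, int] = {}
        variables = self.variables
        remaining = set(variables)
        incoming = {v: {s for s, d in edges if d == v and s in remaining}
                    for v in variables}
        rank = 0
        while remaining:
            free = [v for v in variables if v in remaining and not incoming[v]]
            if not free:
                raise ValueError(f"path graph of model {self.name!r} has a cycle")
            for v in free:
                order[v] = rank
                remaining.discard(v)
            for v in remaining:
                incoming[v] = {s for s, d in edges if d == v and s in remaining}
            rank += 1

    def endogenous(self) -> set[str]:
        dsts = {d for _, d in self.paths}
        dsts |= {i for inds in self.latents.values() for i in inds}
        return dsts

    def n_free_parameters(self) -> int:
        return len(_parameters(self))

    def degrees_of_freedom(self) -> int:
        p = len(self.observed)
        return p * (p + 1) // 2 - self.n_free_parameters()


def parse_model(text: str, name: str = "model") -> SemModelSpec:
    """Parse a small lavaan-style model language.

    ``latent =~ ind1 + ind2`` (measurement), ``y ~ x1 + x2`` (paths),
    ``a ~~ b`` (free covariance). Observed variables are collected
    automatically; '#' starts a comment.
    """
    latents: dict[str, list[str]] = {}
    paths: list[tuple[str, str]] = []
    covs: list[tuple[str, str]] = []
    mentioned: list[str] = []

    def note(v: str) -> None:
        if v not in mentioned:
            mentioned.append(v)

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=~" in line:
            lhs, rhs = line.split("=~")
            latent = lhs.strip()
            inds = [t.strip() for t in rhs.split("+")]
            latents[latent] = inds
            for i in inds:
                note(i)
        elif "~~" in line:
            lhs, rhs = line.split("~~")
            covs.append((lhs.strip(), rhs.strip()))
            note(lhs.strip())
            note(rhs.strip())
        elif "~" in line:
            lhs, rhs = line.split("~", 1)
            dst = lhs.strip()
            for src in (t.strip() for t in rhs.split("+")):
                paths.append((src, dst))
                note(src)
                note(dst)
        else:
            raise ValueError(f"unparseable model line: {raw!r}")
    observed = [v for v in mentioned if v not in latents]
    return SemModelSpec(name, observed, latents, paths, covs)


_STRUCTURAL = ("season", "age", "condition", "infection")


def default_models() -> dict[str, SemModelSpec]:
    """The three immune-compartment models.

    Structural part (shared): exogenous Season and Age (free covariance);
    Season, Age and Infection -> Condition; Season and Age -> Infection
    (infection is serological, i.e. historical, so Condition does not feed
    back into it); Season, Age, Condition and Infection -> ImmuneState.
    ImmuneState is measured by scaled CD4/CD8/CD19 counts (adaptive cellular),
    scaled NK/neutrophil/DC/macrophage counts (innate cellular), or IgG, IgE
    and IgA concentrations (humoral).
    """
    indicator_sets = {
        "adaptive": ["cd4", "cd8", "cd19"],
        "innate": ["nkp46", "ly6g", "cd11c", "f480"],
        "humoral": list(ANTIBODIES),
    }
    out = {}
    for name, indicators in indicator_sets.items():
        paths = [
            ("season", "condition"), ("age", "condition"),
            ("infection", "condition"),
            ("season", "infection"), ("age", "infection"),
            ("season", "immune_state"), ("age", "immune_state"),
            ("condition", "immune_state"), ("infection", "immune_state"),
        ]
        out[name] = SemModelSpec(
            name=name,
            observed=list(_STRUCTURAL) + indicators,
            latents={"immune_state": indicators},
            paths=paths,
            covariances=[("season", "age")],
        )
    return out


# ---------------------------------------------------------------------------
# parameters and implied covariance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Param:
    name: str
    kind: str      # 'loading' | 'path' | 'variance' | 'covariance'
    i: int         # row in A (dst) or S0
    j: int         # col in A (src) or S0
    start: float
    lower: float


def _parameters(spec: SemModelSpec) -> list[_Param]:
    cached = getattr(spec, "_param_cache", None)
    if cached is not None:
        return cached
    params = _build_parameters(spec)
    object.__setattr__(spec, "_param_cache", params)
    return params


def _build_parameters(spec: SemModelSpec) -> list[_Param]:
    variables = spec.variables
    idx = {v: k for k, v in enumerate(variables)}
    endo = spec.endogenous()
    params: list[_Param] = []
    for latent, inds in spec.latents.items():
        for ind in inds[1:]:
            params.append(_Param(
                f"{latent}=~{ind}", "loading", idx[ind], idx[latent], 1.0,
                -np.inf,
            ))
    for src, dst in spec.paths:
        params.append(_Param(
            f"{dst}~{src}", "path", idx[dst], idx[src], 0.0, -np.inf,
        ))
    for v in variables:
        label = f"{v}~~{v}"
        params.append(_Param(label, "variance", idx[v], idx[v], 1.0, 1e-8))
    for a, b in spec.covariances:
        if a in endo or b in endo:
            raise ValueError(
                f"free covariance {a}~~{b} involves an endogenous variable"
            )
        params.append(_Param(f"{a}~~{b}", "covariance", idx[a], idx[b], 0.0,
                             -np.inf))
    p = len(spec.observed)
    if len(params) > p * (p + 1) // 2:
        raise ValueError(
            f"model {spec.name!r} is not identified: {len(params)} free "
            f"parameters > {p * (p + 1) // 2} covariance moments"
        )
    return params


def _ram_matrices(spec: SemModelSpec, theta: np.ndarray):
    params = _parameters(spec)
    m = len(spec.variables)
    idx = {v: k for k, v in enumerate(spec.variables)}
    A = np.zeros((m, m))
    S0 = np.zeros((m, m))
    for latent, inds in spec.latents.items():
        A[idx[inds[0]], idx[latent]] = 1.0  # fixed first loading
    for prm, value in zip(params, theta):
        if prm.kind in ("loading", "path"):
            A[prm.i, prm.j] = value
        elif prm.kind == "variance":
            S0[prm.i, prm.i] = value
        else:
            S0[prm.i, prm.j] = S0[prm.j, prm.i] = value
    return A, S0


def implied_covariance(
    spec: SemModelSpec, theta: Sequence[float], full: bool = False
) -> np.ndarray:
    """Sigma(theta) over the observed variables (or all variables if full)."""
    theta = np.asarray(theta, dtype=float)
    params = _parameters(spec)
    if theta.shape != (len(params),):
        raise ValueError(
            f"theta has length {theta.size}, model has {len(params)} free "
            "parameters"
        )
    A, S0 = _ram_matrices(spec, theta)
    m = A.shape[0]
    eye = np.eye(m)
    try:
        G = np.linalg.solve(eye - A, eye)
    except np.linalg.LinAlgError as exc:
        raise ValueError("(I - A) is singular (cyclic model?)") from exc
    full_cov = G @ S0 @ G.T
    if full:
        return full_cov
    p = len(spec.observed)
    return full_cov[:p, :p]


def parameter_names(spec: SemModelSpec) -> list[str]:
    return [p.name for p in _parameters(spec)]


# ---------------------------------------------------------------------------
# ML fitting
# ---------------------------------------------------------------------------


def _fml_and_grad(spec: SemModelSpec, params, theta, S, logdet_S):
    p = len(spec.observed)
    A, S0 = _ram_matrices(spec, theta)
    m = A.shape[0]
    eye = np.eye(m)
    G = np.linalg.solve(eye - A, eye)
    full_cov = G @ S0 @ G.T
    sigma = full_cov[:p, :p]
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf, np.full(len(params), np.nan)
    sigma_inv = np.linalg.inv(sigma)
    fml = logdet + float(np.trace(S @ sigma_inv)) - logdet_S - p
    # dF = tr[W dSigma], W = Sigma^-1 - Sigma^-1 S Sigma^-1
    W = sigma_inv - sigma_inv @ S @ sigma_inv
    # embed W onto the full variable set through the selection of observed rows
    P = np.zeros((m, m))
    P[:p, :p] = W
    K = full_cov            # G S0 G^T over all variables
    M = G.T @ P @ G         # for S0 derivatives
    KPG = K @ P @ G         # for A derivatives
    grad = np.empty(len(params))
    for t, prm in enumerate(params):
        if prm.kind in ("loading", "path"):
            grad[t] = 2.0 * KPG[prm.j, prm.i]
        elif prm.kind == "variance":
            grad[t] = M[prm.i, prm.i]
        else:
            grad[t] = 2.0 * M[prm.i, prm.j]
    return fml, grad


@dataclass
class ParameterEstimate:
    name: str
    kind: str
    estimate: float
    se: float
    z: float
    p: float
    std_estimate: float


@dataclass
class SemFitResult:
    spec: SemModelSpec
    n: int
    estimates: list[ParameterEstimate]
    theta: np.ndarray
    fml: float
    chi2: float
    df: int
    chi2_p: float
    baseline_chi2: float
    baseline_df: int
    rmsea: float
    rmsea_ci: tuple[float, float]
    cfi: float
    srmr: float
    sample_cov: np.ndarray
    implied_cov: np.ndarray
    converged: bool
    gradient_norm: float
    warnings: list[str]
    rescale_exponents: dict[str, int]

    def estimate(self, name: str) -> ParameterEstimate:
        for e in self.estimates:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.estimates])


def _standardized(spec, params, theta, full_cov) -> np.ndarray:
    sd = np.sqrt(np.clip(np.diag(full_cov), 0, None))
    out = np.empty(len(params))
    for t, prm in enumerate(params):
        v = theta[t]
        if prm.kind in ("loading", "path"):
            out[t] = v * sd[prm.j] / sd[prm.i] if sd[prm.i] > 0 else np.nan
        elif prm.kind == "variance":
            out[t] = v / full_cov[prm.i, prm.i] if full_cov[prm.i, prm.i] > 0 else np.nan
        else:
            denom = sd[prm.i] * sd[prm.j]
            out[t] = v / denom if denom > 0 else np.nan
    return out


def _numeric_hessian(fun, x, h=1e-4):
    k = x.size
    steps = h * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = steps[i]
            ej[j] = steps[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return H


def fit_ml(
    spec: SemModelSpec,
    data: pd.DataFrame,
    rescale: bool = True,
    n_starts: int = 10,
    seed: int = 0,
) -> SemFitResult:
    """Fit the model by maximum likelihood on listwise-complete rows.

    ``rescale=True`` applies the power-of-ten rescaling to each observed
    column first (the exponents are reported; chi2 and the standardized
    solution are invariant to it). Optimization is quasi-Newton (L-BFGS-B
    with analytic gradients) from a unit start plus ``n_starts - 1`` seeded
    jittered starts; non-convergence of every start yields a flagged result.
    """
    cols = spec.observed
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ValueError(f"data lacks model variables: {missing_cols}")
    X = data[cols].astype(float).dropna()
    n = len(X)
    p = len(cols)
    if n <= p:
        raise ValueError(f"need n > {p} complete rows, got {n}")
    exponents: dict[str, int] = {}
    values = X.to_numpy().copy()
    if rescale:
        for j, c in enumerate(cols):
            values[:, j], k = pow10_rescale(np.abs(values[:, j])) if (
                values[:, j] >= 0).all() else (values[:, j], 0)
            exponents[c] = k
    S = np.cov(values, rowvar=False, ddof=1)
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise ValueError("sample covariance matrix is singular")

    params = _parameters(spec)
    warnings_list: list[str] = []
    start = np.array([prm.start for prm in params])
    for t, prm in enumerate(params):
        if prm.kind == "variance" and prm.i < p:
            start[t] = max(S[prm.i, prm.i] / 2.0, 0.05)
    bounds = [(prm.lower, None) if np.isfinite(prm.lower) else (None, None)
              for prm in params]
    rng = np.random.default_rng(seed)

    def objective(theta):
        return _fml_and_grad(spec, params, theta, S, logdet_S)

    best = None
    for trial in range(n_starts):
        x0 = start.copy()
        if trial > 0:
            x0 = x0 + rng.normal(0, 0.3, size=x0.size)
            x0 = np.array([
                max(x, prm.lower + 0.01) if np.isfinite(prm.lower) else x
                for x, prm in zip(x0, params)
            ])
        res = optimize.minimize(
            objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-10},
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None:
        raise RuntimeError(f"model {spec.name!r}: no optimizer start converged")
    theta = best.x

    # Newton polish: the quasi-Newton stops leave a small residual gradient on
    # this ill-conditioned surface; a few damped Newton steps with the numeric
    # Hessian tighten it by several orders of magnitude.
    def fml_value(x):
        return _fml_and_grad(spec, params, x, S, logdet_S)[0]

    fml, grad = objective(theta)
    for _ in range(4):
        if np.linalg.norm(grad) < 1e-9:
            break
        H_polish = _numeric_hessian(fml_value, theta)
        try:
            step = np.linalg.solve(H_polish, grad)
        except np.linalg.LinAlgError:
            break
        improved = False
        for damping in (1.0, 0.5, 0.25, 0.1):
            cand = theta - damping * step
            cand = np.array([
                max(x, prm.lower) if np.isfinite(prm.lower) else x
                for x, prm in zip(cand, params)
            ])
            f_cand, g_cand = objective(cand)
            if np.isfinite(f_cand) and (
                f_cand < fml or np.linalg.norm(g_cand) < np.linalg.norm(grad)
            ):
                theta, fml, grad = cand, f_cand, g_cand
                improved = True
                break
        if not improved:
            break
    gradient_norm = float(np.linalg.norm(grad))
    converged = gradient_norm < 1e-5
    if not converged:
        warnings_list.append(
            f"possible non-convergence: gradient norm {gradient_norm:.2e}"
        )

    chi2 = max((n - 1) * fml, 0.0)
    df = spec.degrees_of_freedom()
    chi2_p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    baseline_chi2 = (n - 1) * float(
        np.sum(np.log(np.diag(S))) - logdet_S
    )
    baseline_df = p * (p - 1) // 2
    sigma = implied_covariance(spec, theta)
    indices = fit_indices(chi2, df, baseline_chi2, baseline_df, n, S, sigma)

    # standard errors from the numeric Hessian of F_ML
    def fml_only(x):
        return _fml_and_grad(spec, params, x, S, logdet_S)[0]

    H = _numeric_hessian(fml_only, theta)
    ses = np.full(theta.size, np.nan)
    try:
        cov_theta = (2.0 / (n - 1)) * np.linalg.inv(H)
        diag = np.diag(cov_theta)
        if (diag < -1e-8).any():
            warnings_list.append("Hessian not positive definite at optimum")
        ses = np.sqrt(np.clip(diag, 0, None))
    except np.linalg.LinAlgError:
        warnings_list.append("singular Hessian: standard errors unavailable")

    full_cov = implied_covariance(spec, theta, full=True)
    std = _standardized(spec, params, theta, full_cov)
    estimates = []
    for t, prm in enumerate(params):
        se = float(ses[t])
        z = theta[t] / se if se > 0 else float("nan")
        pval = 2 * float(stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan")
        estimates.append(ParameterEstimate(
            prm.name, prm.kind, float(theta[t]), se, float(z), pval,
            float(std[t]),
        ))
    return SemFitResult(
        spec=spec, n=n, estimates=estimates, theta=theta, fml=float(fml),
        chi2=float(chi2), df=df, chi2_p=chi2_p,
        baseline_chi2=float(baseline_chi2), baseline_df=baseline_df,
        rmsea=indices["rmsea"], rmsea_ci=indices["rmsea_ci"],
        cfi=indices["cfi"], srmr=indices["srmr"],
        sample_cov=S, implied_cov=sigma, converged=converged,
        gradient_norm=gradient_norm, warnings=warnings_list,
        rescale_exponents=exponents,
    )


# ---------------------------------------------------------------------------
# fit indices and acceptance rules
# ---------------------------------------------------------------------------


def _ncx2_ci_bound(chi2: float, df: int, n: int, tail: float) -> float:
    """Noncentrality lambda with ncx2.cdf(chi2; df, lambda) = tail, as RMSEA."""
    if df <= 0 or n <= 1:
        return 0.0
    cdf0 = stats.chi2.cdf(chi2, df)
    if cdf0 <= tail:  # even lambda = 0 puts chi2 below the tail quantile
        return 0.0
    lo, hi = 0.0, max(4.0 * chi2, 10.0)
    while stats.ncx2.cdf(chi2, df, hi) > tail:
        hi *= 2
        if hi > 1e8:
            break
    lam = optimize.brentq(
        lambda l: stats.ncx2.cdf(chi2, df, l) - tail, lo, hi, xtol=1e-10
    )
    return math.sqrt(lam / (df * (n - 1)))


def fit_indices(
    chi2: float,
    df: int,
    baseline_chi2: float,
    baseline_df: int,
    n: int,
    S: np.ndarray,
    sigma: np.ndarray,
) -> dict:
    """RMSEA with 90% CI, CFI, and SRMR.

    RMSEA = sqrt(max(chi2 - df, 0) / (df (n - 1))); the CI inverts the
    noncentral-chi2 CDF at 0.95 / 0.05. CFI compares excess chi2 against the
    independence baseline. SRMR averages squared correlation-scale residuals
    over the p(p+1)/2 unique moments (diagonal included).
    """
    if df > 0:
        rmsea = math.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))
        ci = (_ncx2_ci_bound(chi2, df, n, 0.95), _ncx2_ci_bound(chi2, df, n, 0.05))
    else:
        rmsea, ci = 0.0, (0.0, 0.0)
    num = max(chi2 - df, 0.0)
    den = max(baseline_chi2 - baseline_df, num)
    cfi = 1.0 - num / den if den > 0 else 1.0
    d = np.sqrt(np.diag(S))
    resid = (S - sigma) / np.outer(d, d)
    iu = np.triu_indices(S.shape[0])
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    return {"rmsea": rmsea, "rmsea_ci": ci, "cfi": cfi, "srmr": srmr}


def acceptance_report(result: SemFitResult) -> dict:
    """Classify a fit as good / acceptable / not_good_fit.

    Rules: RMSEA and SRMR below 0.05 are a good fit; RMSEA above 0.05 is
    still accepted when the lower 90% confidence limit is 0.000. CFI above
    0.95 is a very good fit and above 0.80 acceptable. chi2 nonsignificance
    (p > 0.05) indicates acceptable fit but is flagged as unreliable at these
    sample sizes.
    """
    reasons: list[str] = []
    rmsea_ok = result.rmsea < 0.05
    if rmsea_ok:
        reasons.append(f"RMSEA {result.rmsea:.3f} < 0.05: good")
    elif result.rmsea_ci[0] < 5e-4:
        rmsea_ok = True
        reasons.append(
            f"RMSEA {result.rmsea:.3f} >= 0.05 but lower 90% CI "
            f"{result.rmsea_ci[0]:.3f} = 0.000: accepted"
        )
    else:
        reasons.append(
            f"RMSEA {result.rmsea:.3f} with lower 90% CI "
            f"{result.rmsea_ci[0]:.3f} > 0: not acceptable"
        )
    srmr_ok = result.srmr < 0.05
    reasons.append(
        f"SRMR {result.srmr:.3f} {'<' if srmr_ok else '>='} 0.05"
    )
    if result.cfi > 0.95:
        cfi_level = "very_good"
    elif result.cfi > 0.80:
        cfi_level = "acceptable"
    else:
        cfi_level = "poor"
    reasons.append(f"CFI {result.cfi:.3f}: {cfi_level}")
    chi2_ok = result.chi2_p > 0.05
    reasons.append(
        f"chi2 p = {result.chi2_p:.4g} "
        f"({'acceptable' if chi2_ok else 'not a significantly good fit'}; "
        "unreliable at these sample sizes)"
    )
    if rmsea_ok and srmr_ok and cfi_level == "very_good":
        verdict = "good"
    elif rmsea_ok and cfi_level in ("very_good", "acceptable"):
        verdict = "acceptable"
    else:
        verdict = "not_good_fit"
    if result.warnings:
        reasons.extend(result.warnings)
    return {"verdict": verdict, "reasons": reasons, "chi2_ok": chi2_ok}
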