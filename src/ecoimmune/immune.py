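"""Immunological distance and cohort infection descriptives.

The immunological distance between two mice is the Euclidean distance between
their scores on the first three principal components of 10 standardized
immune measures (7 scaled splenic cell counts; serum IgG and IgE; faecal
IgA). Distances are summarized within and among sampling sites, embedded for
plotting by classical (Torgerson) multidimensional scaling, and the cohort's
serological infection patterns are summarized alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .records import IMMUNE_MEASURES, MICROBES, MouseRecord, is_missing


@dataclass
class PcScores:
    """Scores, variance fractions and loadings of the retained components."""

    mouse_ids: list[str]
    scores: np.ndarray            # n x k
    variance_explained: np.ndarray  # k fractions, non-increasing
    loadings: np.ndarray          # p x k, orthonormal columns
    n_excluded: int               # mice dropped for incomplete measures

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores,
            columns=[f"pc{i + 1}" for i in range(self.scores.shape[1])],
        )
        df.insert(0, "mouse_id", self.mouse_ids)
        return df


@dataclass
class SiteDistanceSummary:
    site: str
    within_mean: float
    within_se: float | None
    n_mice: int
    n_pairs: int


def immune_pca(
    measures: pd.DataFrame | np.ndarray,
    mouse_ids: Sequence[str] | None = None,
    n_components: int = 3,
) -> PcScores:
    """PCA of the immune measures on the correlation (standardized) matrix.

    Rows with any missing measure are excluded (complete-case analysis; the
    count is reported on the result). Columns are standardized to zero mean,
    unit variance before eigendecomposition. Component signs follow a
    deterministic convention: the largest-magnitude loading of each component
    is positive.
    """
    if isinstance(measures, pd.DataFrame):
        if mouse_ids is None and "mouse_id" in measures.columns:
            mouse_ids = measures["mouse_id"].astype(str).tolist()
            measures = measures.drop(columns="mouse_id")
        X = measures.to_numpy(dtype=float)
    else:
        X = np.asarray(measures, dtype=float)
    n_total = X.shape[0]
    if mouse_ids is None:
        mouse_ids = [str(i) for i in range(n_total)]
    complete = ~np.isnan(X).any(axis=1)
    X = X[complete]
    ids = [m for m, ok in zip(mouse_ids, complete) if ok]
    if X.shape[0] < 4:
        raise ValueError(
            f"PCA needs at least 4 complete mice, got {X.shape[0]}"
        )
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = int(np.argmax(sd == 0))
        raise ValueError(f"constant column at index {bad}: PCA undefined")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    k = min(n_components, eigvec.shape[1])
    loadings = eigvec[:, :k]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = Z @ loadings
    frac = eigval[:k] / eigval.sum()
    return PcScores(ids, scores, frac, loadings, n_excluded=n_total - X.shape[0])


def measures_frame(records: Sequence[MouseRecord]) -> pd.DataFrame:
    """The mice x 10 immune-measure table (NaN for missing), with mouse ids."""
    data = {
        "mouse_id": [r.mouse_id for r in records],
    }
    for k in IMMUNE_MEASURES:
        data[k] = [
            np.nan if is_missing(r.immune_measures.get(k)) else r.immune_measures[k]
            for r in records
        ]
    return pd.DataFrame(data)


def immune_distance(pcs: PcScores | pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distance among mice in 3-component score space."""
    if isinstance(pcs, PcScores):
        ids, X = pcs.mouse_ids, pcs.scores
    else:
        cols = [c for c in ("pc1", "pc2", "pc3") if c in pcs.columns]
        if len(cols) != 3:
            raise ValueError("score table must have columns pc1, pc2, pc3")
        ids = pcs["mouse_id"].astype(str).tolist()
        X = pcs[cols].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("scores must be finite")
    return DistanceMatrix(squareform(pdist(X)), ids=ids)


def _pair_values(dm: DistanceMatrix, idx_a: np.ndarray, idx_b: np.ndarray | None):
    if idx_b is None:  # within-group pairs
        sub = dm.data[np.ix_(idx_a, idx_a)]
        iu = np.triu_indices(len(idx_a), k=1)
        return sub[iu]
    return dm.data[np.ix_(idx_a, idx_b)].ravel()


def site_distance_summary(
    dm: DistanceMatrix,
    sites: Mapping[str, str],
) -> tuple[list[SiteDistanceSummary], dict[str, float]]:
    """Within-/among-site decomposition of a mouse-level distance matrix.

    ``sites`` maps mouse id -> site. Sites with < 2 mice are excluded from the
    per-site summaries with a warning. Returns (per-site summaries, overall)
    where overall holds within/among means and SEs over the pooled pairs
    (SE = sd / sqrt(n_pairs), treating pairs as independent).
    """
    ids = list(dm.ids)
    by_site: dict[str, list[int]] = {}
    for i, m in enumerate(ids):
        if m not in sites:
            raise KeyError(f"mouse {m!r} has no site label")
        by_site.setdefault(sites[m], []).append(i)

    summaries = []
    within_all: list[np.ndarray] = []
    for site in sorted(by_site):
        idx = np.array(by_site[site])
        if idx.size < 2:
            warnings.warn(f"site {site} has < 2 mice; excluded from summary")
            continue
        vals = _pair_values(dm, idx, None)
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else None
        summaries.append(
            SiteDistanceSummary(site, float(vals.mean()), se, idx.size, vals.size)
        )
        within_all.append(vals)

    site_list = sorted(by_site)
    among_all = [
        _pair_values(dm, np.array(by_site[a]), np.array(by_site[b]))
        for i, a in enumerate(site_list) for b in site_list[i + 1:]
    ]
    overall: dict[str, float] = {}
    if within_all:
        w = np.concatenate(within_all)
        overall["within_mean"] = float(w.mean())
        overall["within_se"] = (float(w.std(ddof=1) / np.sqrt(w.size))
                                if w.size > 1 else float("nan"))
        overall["n_within_pairs"] = int(w.size)
    if among_all:
        a = np.concatenate(among_all)
        overall["among_mean"] = float(a.mean())
        overall["among_se"] = float(a.std(ddof=1) / np.sqrt(a.size))
        overall["n_among_pairs"] = int(a.size)
    return summaries, overall


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    undefined: bool = False


def within_distance_vs_n(
    summaries: Sequence[SiteDistanceSummary],
    n_perm: int = 999,
    seed: int | None = None,
) -> CorrelationResult:
    """Correlation of per-site within-site mean distance with site sample size.

    Two-sided permutation p (add-one convention). A constant vector makes r
    undefined; the result is flagged rather than raising.
    """
    if len(summaries) < 3:
        raise ValueError("need >= 3 sites")
    x = np.array([s.within_mean for s in summaries], dtype=float)
    y = np.array([s.n_mice for s in summaries], dtype=float)
    if x.std() == 0 or y.std() == 0:
        return CorrelationResult(float("nan"), float("nan"), len(x), undefined=True)
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        r_perm = float(np.corrcoef(x, rng.permutation(y))[0, 1])
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            hits += 1
    return CorrelationResult(r_obs, (hits + 1) / (n_perm + 1), len(x))


def classical_mds(dm: DistanceMatrix, k: int = 2) -> np.ndarray:
    """Torgerson scaling: double-center -0.5 D^2, top-k eigenpairs.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue). Negative
    eigenvalues (non-Euclidean input) are truncated with a warning; asking for
    more dimensions than there are positive eigenvalues is an error.
    """
    D = np.asarray(dm.data, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10, 1e-10 * abs(eigval[0])) if n else 0.0
    n_pos = int((eigval > tol).sum())
    if (eigval < -tol).any():
        warnings.warn(
            "distance matrix is not Euclidean-realizable; negative "
            "eigenvalues truncated"
        )
    if k > n_pos:
        raise ValueError(
            f"requested {k} dimensions but only {n_pos} positive eigenvalues"
        )
    return eigvec[:, :k] * np.sqrt(eigval[:k])


@dataclass
class InfectionDescriptives:
    burden: dict[str, int | None]              # mouse id -> 0..7
    prevalence: dict[str, float]               # per-microbe
    seroprevalence: float                      # >= 1 of the 7 microbes
    n_tested: int
    burden_age_by_sex: dict[str, CorrelationResult]
    worm_prevalence: float | None = None
    mite_prevalence: float | None = None


def infection_descriptives(records: Sequence[MouseRecord]) -> InfectionDescriptives:
    """Per-microbe prevalence, per-mouse burden and burden-age correlations.

    A mouse is positive for a microbe when its serological score is >= 1.
    Seroprevalence is the fraction of assayed mice positive for at least one
    of the 7 microbes.
    """
    burden = {r.mouse_id: r.infection_burden() for r in records}
    prevalence = {}
    for m in MICROBES:
        tested = [r for r in records if r.infection_scores.get(m) is not None]
        prevalence[m] = (
            float(np.mean([r.infection_scores[m] >= 1 for r in tested]))
            if tested else float("nan")
        )
    assayed = [r for r in records if burden[r.mouse_id] is not None]
    sero = (
        float(np.mean([burden[r.mouse_id] >= 1 for r in assayed]))
        if assayed else float("nan")
    )
    by_sex: dict[str, CorrelationResult] = {}
    for sex in ("female", "male"):
        sub = [
            r for r in assayed
            if r.sex == sex and not is_missing(r.age)
        ]
        if len(sub) >= 3:
            x = np.array([r.age for r in sub])
            y = np.array([burden[r.mouse_id] for r in sub], dtype=float)
            if x.std() > 0 and y.std() > 0:
                r_val, p = stats.pearsonr(x, y)
                by_sex[sex] = CorrelationResult(float(r_val), float(p), len(sub))

    def _prev(values):
        vals = [v for v in values if v is not None]
        return float(np.mean([v > 0 for v in vals])) if vals else None

    return InfectionDescriptives(
        burden=burden,
        prevalence=prevalence,
        seroprevalence=sero,
        n_tested=len(assayed),
        burden_age_by_sex=by_sex,
        worm_prevalence=_prev([r.worm_count for r in records]),
        mite_prevalence=_prev([r.mite_count_class for r in records]),
    )
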