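"""Population-genetic estimators for biallelic diploid genotype matrices.

Implements per-locus allele frequencies and heterozygosities (unbiased
expected heterozygosity 2pq * 2n/(2n-1)), the conditional Hardy-Weinberg
exact test (full enumeration and a Guo-Thompson-style Markov-chain Monte
Carlo estimate), Weir & Cockerham's theta (F_ST) from the a/b/c variance
components with ratio-of-sums combination across loci, multilocus F_IS,
allele-difference distances among individuals, and neighbour-joining trees
with locus-bootstrap support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .records import GenotypeMatrix


@dataclass
class LocusStats:
    locus_id: str
    site: str | None          # None = all individuals pooled
    n: int                    # genotyped individuals
    p: float                  # alt-allele frequency
    ho: float                 # observed heterozygosity
    he: float                 # unbiased expected heterozygosity
    hwe_p: float | None       # None for monomorphic loci (test undefined)
    monomorphic: bool


@dataclass
class FstResult:
    site_a: str
    site_b: str
    theta: float
    a: np.ndarray             # per-locus among-population component
    b: np.ndarray             # per-locus among-individual component
    c: np.ndarray             # per-locus within-individual component
    n_loci_used: int


def _genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """(n_ref_hom, n_het, n_alt_hom) over non-missing calls of one locus."""
    d = dosages[~np.isnan(dosages)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def unbiased_he(p: float, n: int) -> float:
    """Expected heterozygosity with Levene's small-sample correction."""
    if n < 1:
        return float("nan")
    return 2.0 * p * (1.0 - p) * (2 * n) / (2 * n - 1) if n > 0 else float("nan")


def locus_stats(
    g: GenotypeMatrix,
    per_site: bool = False,
    hwe: bool = True,
) -> list[LocusStats]:
    """Allele frequency, Ho, He and HWE exact-test p per locus (optionally per site).

    Missing calls are dropped per locus. Monomorphic loci are flagged and get
    no HWE p-value. HWE p-values use the full-enumeration exact test (see
    :func:`hwe_exact` / :func:`hwe_exact_mc` for the underlying tests).
    """
    groups: list[tuple[str | None, np.ndarray]]
    if per_site:
        groups = [(s, g.site_columns(s)) for s in g.site_names]
    else:
        groups = [(None, np.arange(g.n_individuals))]
    out = []
    for site, cols in groups:
        if cols.size < 2:
            raise ValueError(f"group {site!r} has fewer than 2 individuals")
        for i, locus in enumerate(g.locus_ids):
            n00, n01, n11 = _genotype_counts(g.dosages[i, cols])
            n = n00 + n01 + n11
            if n == 0:
                out.append(LocusStats(locus, site, 0, float("nan"),
                                      float("nan"), float("nan"), None, True))
                continue
            p = (n01 + 2 * n11) / (2 * n)
            mono = p in (0.0, 1.0)
            pval = None
            if hwe and not mono:
                pval = hwe_exact(n00, n01, n11)
            out.append(LocusStats(locus, site, n, p, n01 / n,
                                  unbiased_he(p, n), pval, mono))
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def _log_conditional_probs(n: int, n_alt: int) -> tuple[np.ndarray, np.ndarray]:
    """Log P(n_het | n, alt-allele count) for every admissible het count.

    The conditional distribution of genotype counts given allele counts under
    HWE: P(n_het) proportional to 2**n_het / (n_rr! n_het! n_aa!).
    Returns (het_counts, log_probs) normalized to sum 1.
    """
    n_het_max = min(n_alt, 2 * n - n_alt)
    hets = np.arange(n_het_max % 2, n_het_max + 1, 2)
    logs = np.array([
        h * math.log(2.0)
        - math.lgamma((n_alt - h) // 2 + 1)
        - math.lgamma(h + 1)
        - math.lgamma(n - (n_alt + h) // 2 + 1)
        for h in hets
    ])
    logs -= logs.max()
    logs -= math.log(np.exp(logs).sum())
    return hets, logs


def hwe_exact(n_ref_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Exact conditional HWE test by full enumeration of heterozygote counts.

    p = total probability of configurations no more probable than the
    observed one, given the allele counts.
    """
    n = n_ref_hom + n_het + n_alt_hom
    n_alt = n_het + 2 * n_alt_hom
    if n == 0 or n_alt in (0, 2 * n):
        raise ValueError("HWE test undefined for a monomorphic locus")
    hets, logs = _log_conditional_probs(n, n_alt)
    obs = logs[np.searchsorted(hets, n_het)]
    probs = np.exp(logs)
    return float(probs[logs <= obs + 1e-12].sum())


def hwe_exact_mc(
    n_ref_hom: int,
    n_het: int,
    n_alt_hom: int,
    chain_length: int = 1_000_000,
    seed: int | None = None,
    burn_in: int | None = None,
) -> tuple[float, float]:
    """Markov-chain Monte-Carlo estimate of the HWE exact-test p-value.

    A Metropolis chain on the heterozygote count (proposals +/-2, i.e. one
    pair of homozygotes exchanged against two heterozygotes, acceptance from
    the conditional-distribution ratio), in the spirit of the Guo-Thompson
    chain for multiallelic tables. Returns (p_estimate, mc_standard_error);
    the standard error comes from batch means over 50 batches.
    """
    n = n_ref_hom + n_het + n_alt_hom
    n_alt = n_het + 2 * n_alt_hom
    if n == 0 or n_alt in (0, 2 * n):
        raise ValueError("HWE test undefined for a monomorphic locus")
    hets, logs = _log_conditional_probs(n, n_alt)
    k = hets.size
    state = int(np.searchsorted(hets, n_het))
    obs_log = logs[state]
    if burn_in is None:
        burn_in = min(chain_length // 10, 10_000)
    rng = np.random.default_rng(seed)
    # precompute Metropolis acceptance for +1 / -1 state moves
    up = np.zeros(k)
    down = np.zeros(k)
    up[:-1] = np.minimum(1.0, np.exp(logs[1:] - logs[:-1]))
    down[1:] = np.minimum(1.0, np.exp(logs[:-1] - logs[1:]))
    extreme = logs <= obs_log + 1e-12

    total = burn_in + chain_length
    directions = rng.integers(0, 2, size=total)  # 1 = propose up
    accept_u = rng.random(size=total)
    hits = np.empty(chain_length, dtype=bool)
    for t in range(total):
        if directions[t]:
            if state < k - 1 and accept_u[t] < up[state]:
                state += 1
        else:
            if state > 0 and accept_u[t] < down[state]:
                state -= 1
        if t >= burn_in:
            hits[t - burn_in] = extreme[state]
    p = float(hits.mean())
    n_batches = 50
    usable = (chain_length // n_batches) * n_batches
    batch_means = hits[:usable].reshape(n_batches, -1).mean(axis=1)
    se = float(batch_means.std(ddof=1) / math.sqrt(n_batches))
    return p, se


# ---------------------------------------------------------------------------
# F-statistics
# ---------------------------------------------------------------------------


def _wc_components(
    g: GenotypeMatrix, cols_by_site: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) per-locus a, b, c components for r groups."""
    r = len(cols_by_site)
    L = g.n_loci
    a = np.zeros(L)
    b = np.zeros(L)
    c = np.zeros(L)
    for l in range(L):
        ns, ps, hs = [], [], []
        for cols in cols_by_site:
            n00, n01, n11 = _genotype_counts(g.dosages[l, cols])
            n_i = n00 + n01 + n11
            if n_i == 0:
                continue
            ns.append(n_i)
            ps.append((n01 + 2 * n11) / (2 * n_i))
            hs.append(n01 / n_i)
        if len(ns) < r:
            continue  # locus untyped in some group: contributes nothing
        ns = np.array(ns, dtype=float)
        ps = np.array(ps)
        hs = np.array(hs)
        n_bar = ns.mean()
        if n_bar <= 1:
            continue
        p_bar = float((ns * ps).sum() / (r * n_bar))
        if p_bar in (0.0, 1.0):
            continue  # monomorphic across the groups
        nc = (r * n_bar - (ns ** 2).sum() / (r * n_bar)) / (r - 1)
        s2 = float((ns * (ps - p_bar) ** 2).sum() / ((r - 1) * n_bar))
        h_bar = float((ns * hs).sum() / (r * n_bar))
        pq = p_bar * (1 - p_bar)
        a[l] = (n_bar / nc) * (
            s2 - (pq - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b[l] = (n_bar / (n_bar - 1)) * (
            pq - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c[l] = h_bar / 2
    return a, b, c


def pairwise_fst(g: GenotypeMatrix, site_a: str, site_b: str) -> FstResult:
    """Weir-Cockerham theta between two sites (ratio of sums across loci)."""
    cols_a = g.site_columns(site_a)
    cols_b = g.site_columns(site_b)
    if cols_a.size < 2 or cols_b.size < 2:
        raise ValueError("each site needs >= 2 genotyped individuals")
    a, b, c = _wc_components(g, [cols_a, cols_b])
    used = (a != 0) | (b != 0) | (c != 0)
    denom = (a + b + c).sum()
    theta = float(a.sum() / denom) if denom != 0 else float("nan")
    return FstResult(site_a, site_b, theta, a, b, c, int(used.sum()))


def fst_matrix(g: GenotypeMatrix, min_per_site: int = 2) -> DistanceMatrix:
    """Pairwise theta among all sites with >= min_per_site individuals.

    Negative pairwise estimates are clipped at 0 only for the distance-matrix
    representation (a DistanceMatrix cannot hold negatives); use
    :func:`pairwise_fst` for the raw values.
    """
    sites = [s for s in g.site_names if g.site_columns(s).size >= min_per_site]
    m = np.zeros((len(sites), len(sites)))
    for i, j in combinations(range(len(sites)), 2):
        theta = pairwise_fst(g, sites[i], sites[j]).theta
        m[i, j] = m[j, i] = max(theta, 0.0)
    return DistanceMatrix(m, ids=sites)


def average_fst(g: GenotypeMatrix, min_per_site: int = 2) -> float:
    """Unweighted mean of the pairwise theta values over all site pairs."""
    sites = [s for s in g.site_names if g.site_columns(s).size >= min_per_site]
    if len(sites) < 2:
        raise ValueError("need >= 2 sites with enough individuals")
    vals = [
        pairwise_fst(g, a, b).theta for a, b in combinations(sites, 2)
    ]
    return float(np.nanmean(vals))


def fis(g: GenotypeMatrix, per_site: bool = True) -> tuple[dict[str, float], float]:
    """Multilocus F_IS = 1 - sum(Ho) / sum(He) per site, and the site average.

    Loci with He = 0 (monomorphic within the site) contribute nothing to
    either sum.
    """
    groups = g.site_names if per_site else ["all"]
    per: dict[str, float] = {}
    for site in groups:
        cols = g.site_columns(site) if per_site else np.arange(g.n_individuals)
        ho_sum = he_sum = 0.0
        for l in range(g.n_loci):
            n00, n01, n11 = _genotype_counts(g.dosages[l, cols])
            n = n00 + n01 + n11
            if n < 2:
                continue
            p = (n01 + 2 * n11) / (2 * n)
            he = unbiased_he(p, n)
            if he == 0:
                continue
            ho_sum += n01 / n
            he_sum += he
        per[site] = 1.0 - ho_sum / he_sum if he_sum > 0 else float("nan")
    return per, float(np.nanmean(list(per.values())))


# ---------------------------------------------------------------------------
# individual distances and trees
# ---------------------------------------------------------------------------


def individual_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Allele-difference count between individuals.

    d(i, j) = sum over loci typed in both of |dosage_i - dosage_j|, rescaled
    by n_loci / n_shared so pairs with missing data stay comparable. A pair
    with no shared typed locus is an error.
    """
    D = g.dosages
    n = g.n_individuals
    L = g.n_loci
    present = ~np.isnan(D)
    out = np.zeros((n, n))
    for i in range(n):
        di = D[:, i][:, None]
        shared = present[:, i][:, None] & present[:, i + 1:]
        diff = np.abs(di - D[:, i + 1:])
        diff[~shared] = 0.0
        n_shared = shared.sum(axis=0)
        if (n_shared == 0).any():
            j = i + 1 + int(np.argmax(n_shared == 0))
            raise ValueError(
                f"individuals {g.individual_ids[i]!r} and "
                f"{g.individual_ids[j]!r} share no typed locus"
            )
        out[i, i + 1:] = diff.sum(axis=0) * (L / n_shared)
    out = out + out.T
    return DistanceMatrix(out, ids=g.individual_ids)


def nj_tree(dm: DistanceMatrix):
    """Saitou-Nei neighbour joining (negative branch lengths clamped to 0)."""
    if len(dm.ids) < 3:
        raise ValueError("NJ needs >= 3 taxa")
    return _skbio_nj(dm)


def _bipartitions(tree, tip_set: frozenset) -> set[frozenset]:
    """Non-trivial bipartitions of a tree, each as the smaller-side tip set."""
    parts = set()
    for node in tree.non_tips(include_self=False):
        sub = frozenset(t.name for t in node.tips())
        if 1 < len(sub) < len(tip_set) - 1:
            other = tip_set - sub
            parts.add(min(sub, other, key=lambda s: (len(s), sorted(s))))
    return parts


def nj_tree_with_support(
    g: GenotypeMatrix,
    bootstraps: int = 1000,
    seed: int | None = None,
):
    """NJ tree of individual distances with locus-bootstrap bipartition support.

    Loci are resampled with replacement; support for each internal bipartition
    of the full-data tree is the fraction of bootstrap trees containing it,
    written into the node names as ``support:<fraction>``.
    Returns (tree, support dict keyed by frozenset of tip ids).
    """
    tree = nj_tree(individual_distance(g))
    tips = frozenset(g.individual_ids)
    target = _bipartitions(tree, tips)
    counts = {part: 0 for part in target}
    rng = np.random.default_rng(seed)
    for _ in range(bootstraps):
        idx = rng.integers(0, g.n_loci, size=g.n_loci)
        boot = GenotypeMatrix(
            g.dosages[idx],
            [f"L{i}" for i in range(g.n_loci)],
            g.individual_ids,
            g.sites,
        )
        boot_parts = _bipartitions(nj_tree(individual_distance(boot)), tips)
        for part in target & boot_parts:
            counts[part] += 1
    support = {part: c / bootstraps for part, c in counts.items()} if bootstraps else {}
    for node in tree.non_tips(include_self=False):
        sub = frozenset(t.name for t in node.tips())
        key = min(sub, tips - sub, key=lambda s: (len(s), sorted(s)))
        if key in support:
            node.name = f"{support[key]:.3f}"
    return tree, support
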