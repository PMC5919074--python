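"""Synthetic cohorts and genotypes with known ground truth.

The generator emulates the statistical structure every downstream stage
assumes: 12 sampling sites of unequal size (profile follows the printed
per-site genotyping counts), a male-biased sex ratio (odds 1.18), a
right-skewed gamma age distribution (median 7.4 weeks, 75th percentile 12),
7 serological infections whose probability rises with age, a linear-Gaussian
structural system (season, age, condition, infection driving three latent
immune compartments measured by 10 indicators with site structure), a
mass-length power-law allometry so the scaled mass index is recoverable, and
Balding-Nichols genotypes with a controllable differentiation target F.

All randomness flows from one seed; per-site RNG streams are spawned from it
so adding a site does not perturb earlier sites' draws. The implied
covariance of the observed variables is available in closed form
(:func:`implied_covariance_observed`) for calibration tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .condition import LensCalibration
from .records import (
    ANTIBODIES,
    CELL_TYPES,
    GenotypeMatrix,
    IMMUNE_MEASURES,
    MICROBES,
    MouseRecord,
)

#: Printed per-site genotyping sample sizes (the only published site profile).
GENOTYPED_SITE_SIZES: dict[str, int] = {
    "HW": 167, "PH": 63, "JB": 36, "BM": 33, "GL": 30, "SK": 30,
    "WF": 18, "LU": 18, "ST": 15, "PF": 10, "WT": 7, "SP": 6,
}


def _scaled_site_sizes(total: int = 460) -> dict[str, int]:
    """Largest-remainder scaling of the genotyped-site profile to `total` mice."""
    base = GENOTYPED_SITE_SIZES
    s = sum(base.values())
    raw = {k: v * total / s for k, v in base.items()}
    sizes = {k: int(math.floor(v)) for k, v in raw.items()}
    remainder = total - sum(sizes.values())
    for k in sorted(raw, key=lambda k: raw[k] - sizes[k], reverse=True)[:remainder]:
        sizes[k] += 1
    return sizes


# structural coefficients; subscripts: s season, a age, c condition, i infection
_GAMMA = {
    "adaptive": {"s": -0.15, "a": -0.30, "c": 0.45, "i": 0.05},
    "innate": {"s": -0.15, "a": -0.30, "c": 0.45, "i": 0.05},
    "humoral": {"s": -0.05, "a": 0.35, "c": 0.0, "i": 0.25},
}

_COMPARTMENT_OF = {m: "adaptive" for m in ("cd4", "cd8", "cd19")}
_COMPARTMENT_OF.update({m: "innate" for m in ("nkp46", "ly6g", "cd11c", "f480")})
_COMPARTMENT_OF.update({m: "humoral" for m in ANTIBODIES})


@dataclass
class SyntheticConfig:
    """All generator parameters. Defaults are the study conditions."""

    seed: int = 0
    site_sizes: dict[str, int] = field(default_factory=_scaled_site_sizes)
    genotype_site_sizes: dict[str, int] = field(
        default_factory=lambda: dict(GENOTYPED_SITE_SIZES))
    sex_odds_male: float = 1.18

    # age: gamma matched to median 7.4 wk and 75th percentile 12 wk
    age_shape: float = 1.9174
    age_scale_wk: float = 4.6358

    # genotypes (Balding-Nichols)
    n_loci: int = 1168
    fst: float = 0.48
    panmictic: bool = False
    p_bar_range: tuple[float, float] = (0.1, 0.9)
    missing_call_rate: float = 0.01

    # season: minutes of daylight, uniform over the annual range
    day_length_range: tuple[float, float] = (450.0, 1010.0)

    # infection model: per-microbe baseline prevalence and per-SD-age slope
    infection_baseline: tuple[float, ...] = (0.55, 0.45, 0.40, 0.25, 0.30, 0.35, 0.20)
    infection_age_slope: float = 0.06
    infection_season_slope: float = 0.0

    # structural paths (condition equation) and residual SDs
    beta_condition_season: float = 0.10
    beta_condition_age: float = 0.35
    beta_condition_infection: float = -0.05
    sd_condition: float = 0.93
    gamma: dict = field(default_factory=lambda: {k: dict(v) for k, v in _GAMMA.items()})
    sd_compartment: dict = field(default_factory=lambda: {
        "adaptive": 0.70, "innate": 0.70, "humoral": 0.80})
    #: shared fraction of the adaptive/innate residuals (cells co-vary)
    cellular_residual_corr: float = 0.8
    site_sd: dict = field(default_factory=lambda: {
        "adaptive": 0.8, "innate": 0.8, "humoral": 0.5})

    # measurement model: loading and unique-noise SD per indicator (latent scale)
    loadings: dict = field(default_factory=lambda: {
        "cd4": 1.0, "cd8": 0.9, "cd19": 1.1,
        "nkp46": 1.0, "ly6g": 0.8, "cd11c": 0.9, "f480": 1.1,
        "igg": 1.0, "ige": 0.85, "iga": 0.30,
    })
    noise_sd: dict = field(default_factory=lambda: {
        **{k: 0.6 for k in CELL_TYPES}, "igg": 0.6, "ige": 0.6, "iga": 1.0})
    #: mean raw level per measure (cells: absolute splenocyte counts)
    measure_mean: dict = field(default_factory=lambda: {
        "cd4": 4.0e7, "cd8": 2.0e7, "cd19": 6.0e7, "nkp46": 5.0e6,
        "ly6g": 3.0e6, "cd11c": 2.0e6, "f480": 4.0e6,
        "igg": 5.0, "ige": 0.4, "iga": 2.0,
    })
    #: raw measure = mean * length-modulation * (1 + latent-core / core_scale)
    core_scale: float = 6.0
    cell_length_exponent: float = 1.7

    # morphometrics: lognormal length, power-law mass with condition effect
    ln_length_mean: float = math.log(82.0)   # mm
    ln_length_sd: float = 0.07
    mass_coefficient: float = 2.93e-5        # g per mm^b
    mass_exponent: float = 3.0
    mass_condition_effect: float = 0.08      # on ln mass per condition unit
    mass_noise_sd: float = 0.05
    lens_noise_sd_mg: float = 0.05

    def __post_init__(self) -> None:
        if not self.panmictic and not 0.0 < self.fst < 1.0:
            raise ValueError(
                "fst must be in (0, 1); use panmictic=True for the F -> 0 limit"
            )
        if any(n < 2 for n in self.site_sizes.values()):
            raise ValueError("site_sizes must all be >= 2")
        if self.sd_condition < 0 or any(
            v < 0 for v in list(self.sd_compartment.values())
            + list(self.noise_sd.values()) + list(self.site_sd.values())
        ):
            raise ValueError("residual SDs must be nonnegative")
        if not all(0 < b < 1 for b in self.infection_baseline):
            raise ValueError("infection baselines must be probabilities in (0,1)")


@dataclass
class CohortTruth:
    """Ground-truth latent values and noiseless cores for recovery tests."""

    condition: dict[str, float]
    compartments: dict[str, dict[str, float]]  # compartment -> mouse -> value
    indicator_core: dict[str, dict[str, float]]  # measure -> mouse -> core
    age_mean_wk: float
    age_sd_wk: float
    burden_mean: float


def _site_streams(seed: int, n: int) -> list[np.random.Generator]:
    seq = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in seq.spawn(n + 1)]


def gen_genotypes(config: SyntheticConfig):
    """Balding-Nichols genotypes: per-site allele frequencies drawn from
    Beta(p(1-F)/F, (1-p)(1-F)/F) around a global frequency p, genotypes in
    Hardy-Weinberg proportions within site.

    Returns (GenotypeMatrix, site -> true allele-frequency array).
    """
    sites = list(config.genotype_site_sizes)
    streams = _site_streams(config.seed, len(sites))
    global_rng, site_rngs = streams[0], streams[1:]
    lo, hi = config.p_bar_range
    p_bar = global_rng.uniform(lo, hi, size=config.n_loci)
    true_freqs: dict[str, np.ndarray] = {}
    columns, ids, site_labels = [], [], []
    for site, rng in zip(sites, site_rngs):
        n = config.genotype_site_sizes[site]
        if config.panmictic:
            p_site = p_bar.copy()
        else:
            F = config.fst
            a = p_bar * (1 - F) / F
            b = (1 - p_bar) * (1 - F) / F
            p_site = rng.beta(a, b)
        true_freqs[site] = p_site
        dosages = rng.binomial(2, p_site[:, None], size=(config.n_loci, n)).astype(float)
        if config.missing_call_rate > 0:
            mask = rng.random(dosages.shape) < config.missing_call_rate
            dosages[mask] = np.nan
        columns.append(dosages)
        ids.extend(f"{site}{i + 1:03d}" for i in range(n))
        site_labels.extend([site] * n)
    matrix = np.concatenate(columns, axis=1)
    g = GenotypeMatrix(
        matrix,
        [f"locus{i + 1:04d}" for i in range(config.n_loci)],
        ids,
        site_labels,
        chromosomes=[str(1 + i % 19) for i in range(config.n_loci)],
        positions=list(range(1, config.n_loci + 1)),
    )
    return g, true_freqs


def _season_sd(config: SyntheticConfig) -> float:
    lo, hi = config.day_length_range
    return (hi - lo) / math.sqrt(12.0)


def gen_cohort(config: SyntheticConfig) -> tuple[list[MouseRecord], CohortTruth]:
    """Generate the cohort; see the module docstring for the generating model.

    Site SK's faecal IgA is left missing (its sample was too small to assay),
    exercising the complete-case path downstream.
    """
    sites = list(config.site_sizes)
    streams = _site_streams(config.seed + 1, len(sites))
    site_rngs = streams[1:]
    cal = LensCalibration()
    age_mean = config.age_shape * config.age_scale_wk
    age_sd = math.sqrt(config.age_shape) * config.age_scale_wk
    burden_mean = float(sum(config.infection_baseline))
    lo, hi = config.day_length_range
    season_mid, season_sd = (lo + hi) / 2.0, _season_sd(config)

    records: list[MouseRecord] = []
    truth = CohortTruth({}, {c: {} for c in _GAMMA}, {m: {} for m in IMMUNE_MEASURES},
                        age_mean, age_sd, burden_mean)
    p_male = config.sex_odds_male / (1.0 + config.sex_odds_male)

    for site, rng in zip(sites, site_rngs):
        n = config.site_sizes[site]
        site_effect = {c: rng.normal(0.0, sd) for c, sd in config.site_sd.items()}
        for k in range(n):
            mid = f"{site}{k + 1:03d}"
            sex = "male" if rng.random() < p_male else "female"
            age = float(rng.gamma(config.age_shape, config.age_scale_wk))
            age_c = (age - age_mean) / age_sd
            day_length = float(rng.uniform(lo, hi))
            season_c = (day_length - season_mid) / season_sd

            probs = np.clip(
                np.array(config.infection_baseline)
                + config.infection_age_slope * age_c
                + config.infection_season_slope * season_c,
                0.01, 0.99,
            )
            positive = rng.random(len(MICROBES)) < probs
            scores = {
                m: int(rng.integers(1, 5)) if pos else 0
                for m, pos in zip(MICROBES, positive)
            }
            burden = int(positive.sum())
            burden_c = burden - burden_mean

            condition = (
                config.beta_condition_season * season_c
                + config.beta_condition_age * age_c
                + config.beta_condition_infection * burden_c
                + rng.normal(0.0, config.sd_condition)
            )
            zeta_shared = rng.normal()
            rho = config.cellular_residual_corr
            latents = {}
            for comp, g in config.gamma.items():
                drive = (g["s"] * season_c + g["a"] * age_c
                         + g["c"] * condition + g["i"] * burden_c)
                sd = config.sd_compartment[comp]
                if comp in ("adaptive", "innate"):
                    zeta = sd * (rho * zeta_shared
                                 + math.sqrt(1 - rho ** 2) * rng.normal())
                else:
                    zeta = rng.normal(0.0, sd)
                latents[comp] = drive + site_effect[comp] + zeta

            length = float(math.exp(rng.normal(config.ln_length_mean,
                                               config.ln_length_sd)))
            mass = float(config.mass_coefficient * length ** config.mass_exponent
                         * math.exp(config.mass_condition_effect * condition
                                    + rng.normal(0.0, config.mass_noise_sd)))
            modulation = (length / math.exp(config.ln_length_mean)) \
                ** config.cell_length_exponent

            measures: dict[str, float | None] = {}
            for m in IMMUNE_MEASURES:
                comp = _COMPARTMENT_OF[m]
                core = (config.loadings[m] * latents[comp]
                        + rng.normal(0.0, config.noise_sd[m]))
                level = 1.0 + core / config.core_scale
                mean = config.measure_mean[m]
                raw = mean * level
                if m in CELL_TYPES:
                    raw *= modulation
                measures[m] = max(raw, 0.0)
                truth.indicator_core[m][mid] = core
            if site == "SK":
                measures["iga"] = None

            lens = max(cal.lens_mg(age * 7.0)
                       + rng.normal(0.0, config.lens_noise_sd_mg), 0.1)
            fat = max(0.5 + 0.3 * condition + rng.normal(0.0, 0.3), 0.0)
            leptin = max(3.0 + 0.8 * fat + rng.normal(0.0, 1.0), 0.0)
            haemoglobin = float(rng.normal(140.0, 12.0))
            worms = 0 if rng.random() < 0.21 else 1 + int(rng.geometric(0.3))
            mites = 0 if rng.random() < 0.33 else 1 + int(rng.poisson(2.0))

            records.append(MouseRecord(
                mouse_id=mid, site=site, sex=sex, day_length=day_length,
                body_mass=mass, body_length=length, abdominal_fat=fat,
                lens_mass=lens, age=age, leptin=leptin,
                haemoglobin=haemoglobin, infection_scores=scores,
                mite_count_class=mites, worm_count=worms,
                immune_measures=measures,
            ))
            truth.condition[mid] = condition
            for comp, v in latents.items():
                truth.compartments[comp][mid] = v
    return records, truth


def site_coordinates(config: SyntheticConfig) -> dict[str, tuple[float, float]]:
    """Seeded site positions (km) in a 60 x 60 km region.

    Immune site effects are drawn independently of geography, so geographic
    distance carries no signal about immune distance — the null the matrix
    comparisons are expected to report.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7)))
    return {
        site: (float(x), float(y))
        for site, (x, y) in zip(
            config.site_sizes, rng.uniform(0.0, 60.0, size=(len(config.site_sizes), 2))
        )
    }


def geographic_distance_matrix(config: SyntheticConfig):
    """Pairwise Euclidean km distances between the seeded site positions."""
    from skbio import DistanceMatrix

    coords = site_coordinates(config)
    names = sorted(coords)
    m = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            m[i, j] = math.hypot(coords[a][0] - coords[b][0],
                                 coords[a][1] - coords[b][1])
    return DistanceMatrix(m, ids=names)


# ---------------------------------------------------------------------------
# closed-form covariance of the generating model
# ---------------------------------------------------------------------------


def implied_covariance_observed(config: SyntheticConfig):
    """Closed-form covariance of the observed variables of the linear system.

    Variables (in order): day_length, age, infection burden, condition, then
    the 10 raw immune measures (site effects set to their per-site values of
    zero mean; the returned covariance is the within-site covariance, i.e.
    site_sd contributes latent variance only when left at its default —
    here site effects are *included* as extra latent variance, matching a
    cohort pooled over infinitely many sites).

    The cell measures include the lognormal length modulation exactly
    (independent lognormal factor shared within a mouse). Returns (labels,
    covariance matrix, means).
    """
    labels = ["day_length", "age", "burden", "condition"] + list(IMMUNE_MEASURES)
    k = len(labels)
    age_sd = math.sqrt(config.age_shape) * config.age_scale_wk
    season_sd = _season_sd(config)
    baseline = np.array(config.infection_baseline)
    sa, ss = config.infection_age_slope, config.infection_season_slope
    m = len(baseline)

    # moments of the standardized drivers
    # burden = sum Bernoulli(p_m), p_m = b_m + sa*age_c + ss*season_c
    var_burden = (
        (m * sa) ** 2 * 1.0 + (m * ss) ** 2 * 1.0
        + float(np.sum(baseline - baseline ** 2 - sa ** 2 - ss ** 2))
    )
    cov_burden_age = m * sa        # with age_c
    cov_burden_season = m * ss     # with season_c

    bs, ba, bi = (config.beta_condition_season, config.beta_condition_age,
                  config.beta_condition_infection)
    cov_cond_season = bs + bi * cov_burden_season
    cov_cond_age = ba + bi * cov_burden_age
    cov_cond_burden = (bs * cov_burden_season + ba * cov_burden_age
                       + bi * var_burden)
    var_cond = (bs * cov_cond_season + ba * cov_cond_age
                + bi * cov_cond_burden + config.sd_condition ** 2)

    # latent compartments: L_x = gs*season + ga*age + gc*cond + gi*burden + site + zeta
    comps = list(config.gamma)
    cov_l_driver: dict[str, dict[str, float]] = {}
    var_l: dict[str, float] = {}
    for comp in comps:
        g = config.gamma[comp]
        cov_season = g["s"] + g["c"] * cov_cond_season + g["i"] * cov_burden_season
        cov_age = g["a"] + g["c"] * cov_cond_age + g["i"] * cov_burden_age
        cov_burd = (g["s"] * cov_burden_season + g["a"] * cov_burden_age
                    + g["c"] * cov_cond_burden + g["i"] * var_burden)
        cov_cond = (g["s"] * cov_cond_season + g["a"] * cov_cond_age
                    + g["c"] * var_cond + g["i"] * cov_cond_burden)
        var = (g["s"] * cov_season + g["a"] * cov_age + g["c"] * cov_cond
               + g["i"] * cov_burd + config.sd_compartment[comp] ** 2
               + config.site_sd[comp] ** 2)
        cov_l_driver[comp] = {
            "season": cov_season, "age": cov_age,
            "burden": cov_burd, "condition": cov_cond,
        }
        var_l[comp] = var

    # cross-compartment latent covariances
    def cov_ll(c1: str, c2: str) -> float:
        if c1 == c2:
            return var_l[c1]
        g = config.gamma[c1]
        d2 = cov_l_driver[c2]
        cov = (g["s"] * d2["season"] + g["a"] * d2["age"]
               + g["c"] * d2["condition"] + g["i"] * d2["burden"])
        if {c1, c2} == {"adaptive", "innate"}:
            rho = config.cellular_residual_corr
            cov += (rho ** 2) * (config.sd_compartment[c1]
                                 * config.sd_compartment[c2])
        return cov

    # indicator cores: core_m = lambda_m * L_comp(m) + eps_m
    lam = config.loadings
    noise = config.noise_sd

    def core_cov(m1: str, m2: str) -> float:
        c = lam[m1] * lam[m2] * cov_ll(_COMPARTMENT_OF[m1], _COMPARTMENT_OF[m2])
        if m1 == m2:
            c += noise[m1] ** 2
        return c

    def core_driver_cov(meas: str, driver: str) -> float:
        return lam[meas] * cov_l_driver[_COMPARTMENT_OF[meas]][driver]

    # lognormal length modulation g = exp(e * N(0, s^2)), e = cell exponent
    s2 = config.ln_length_sd ** 2
    e = config.cell_length_exponent
    Eg = math.exp(0.5 * e * e * s2)
    Eg2 = math.exp(2.0 * e * e * s2)

    cov = np.zeros((k, k))
    means = np.zeros(k)
    means[0] = sum(config.day_length_range) / 2.0
    means[1] = config.age_shape * config.age_scale_wk
    means[2] = float(baseline.sum())
    means[3] = 0.0

    cov[0, 0] = season_sd ** 2
    cov[1, 1] = age_sd ** 2
    cov[2, 2] = var_burden
    cov[3, 3] = var_cond
    cov[0, 1] = cov[1, 0] = 0.0
    cov[0, 2] = cov[2, 0] = cov_burden_season * season_sd
    cov[1, 2] = cov[2, 1] = cov_burden_age * age_sd
    cov[0, 3] = cov[3, 0] = cov_cond_season * season_sd
    cov[1, 3] = cov[3, 1] = cov_cond_age * age_sd
    cov[2, 3] = cov[3, 2] = cov_cond_burden

    driver_scale = {"season": season_sd, "age": age_sd,
                    "burden": 1.0, "condition": 1.0}
    driver_index = {"season": 0, "age": 1, "burden": 2, "condition": 3}
    for a_i, meas in enumerate(IMMUNE_MEASURES):
        i = 4 + a_i
        mean = config.measure_mean[meas]
        scale = mean / config.core_scale  # raw = mean + scale*core (x modulation)
        is_cell = meas in CELL_TYPES
        mod_mean = Eg if is_cell else 1.0
        means[i] = mean * mod_mean
        for driver, j in driver_index.items():
            c = scale * core_driver_cov(meas, driver) * driver_scale[driver]
            cov[i, j] = cov[j, i] = c * (Eg if is_cell else 1.0)
        for b_i, meas2 in enumerate(IMMUNE_MEASURES[:a_i + 1]):
            j = 4 + b_i
            scale2 = config.measure_mean[meas2] / config.core_scale
            cc = core_cov(meas, meas2)
            both_cells = is_cell and meas2 in CELL_TYPES
            if both_cells:
                # obs = g*(mean + scale*core); shared lognormal factor g
                m1 = mean + 0.0  # E core = 0
                m2 = config.measure_mean[meas2]
                c = Eg2 * (scale * scale2 * cc) + (Eg2 - Eg * Eg) * m1 * m2
            elif is_cell or meas2 in CELL_TYPES:
                c = Eg * scale * scale2 * cc
            else:
                c = scale * scale2 * cc
            cov[i, j] = cov[j, i] = c
    return labels, cov, means
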