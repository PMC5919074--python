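"""Condition and age indices.

Body condition is the scaled mass index (SMI): the standardized-major-axis
(SMA) exponent *b* of the mass-length allometry is fitted on natural-log axes,
and each animal's mass is standardized to the population mean length L0,

    SMI_i = M_i * (L0 / L_i) ** b .

The same scaling is applied to splenic immune-cell counts (mass replaced by
the count, exponent refitted per cell type), so that counts are comparable
across mice of different size. BMI is mass(kg) / length(m)^2. Age is derived
from dried eye-lens mass through a configurable monotone calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Hashable, Sequence

import numpy as np

from .records import MouseRecord, is_missing


@dataclass(frozen=True)
class AllometricFit:
    """SMA fit of ln(y) on ln(length): exponent, reference length, OLS r, n."""

    b_sma: float
    L0: float
    r_ols: float
    n: int


@dataclass(frozen=True)
class LensCalibration:
    """Log-linear eye-lens growth: lens_mg = alpha + beta * ln(age_days).

    The default coefficients are PROVISIONAL placeholders with the right
    shape (monotone, decelerating growth) and order of magnitude for house
    mice; substitute calibrated values for any real analysis.
    """

    alpha: float = -1.0
    beta: float = 2.0
    min_lens_mg: float = 0.5

    def age_days(self, lens_mass_mg: float) -> float:
        if lens_mass_mg <= 0:
            raise ValueError("lens mass must be positive")
        return math.exp((lens_mass_mg - self.alpha) / self.beta)

    def lens_mg(self, age_days: float) -> float:
        if age_days <= 0:
            raise ValueError("age must be positive")
        return self.alpha + self.beta * math.log(age_days)


def sma_slope(x: Sequence[float], y: Sequence[float]) -> float:
    """Standardized-major-axis slope: sign(r(x, y)) * sd(y) / sd(x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"SMA fit needs n >= 3, got n = {x.size}")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("SMA slope undefined: zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    sign = 1.0 if r >= 0 else -1.0
    return float(sign * sy / sx)


def _ols_r(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def _group_key(record: MouseRecord, group: str | None) -> Hashable:
    if group is None:
        return "all"
    value = getattr(record, group)
    return "missing" if value is None else value


def compute_smi(
    records: Sequence[MouseRecord],
    group: str | None = "sex",
) -> tuple[dict[str, float | None], dict[Hashable, AllometricFit]]:
    """Scaled mass index per mouse, with the per-group allometric fit.

    ``group`` names a MouseRecord attribute to partition the cohort by
    (default per sex; None fits the whole cohort). Mice with missing mass or
    length get a missing SMI. A group with fewer than 3 complete mice is an
    error naming the group.
    """
    return _smi_like(
        records,
        value=lambda r: r.body_mass,
        group=group,
        what="body mass",
    )


def _smi_like(
    records: Sequence[MouseRecord],
    value: Callable[[MouseRecord], float | None],
    group: str | None,
    what: str,
) -> tuple[dict[str, float | None], dict[Hashable, AllometricFit]]:
    groups: dict[Hashable, list[int]] = {}
    for i, r in enumerate(records):
        groups.setdefault(_group_key(r, group), []).append(i)

    fits: dict[Hashable, AllometricFit] = {}
    out: dict[str, float | None] = {r.mouse_id: None for r in records}
    for key, idx in groups.items():
        complete = [
            i for i in idx
            if not is_missing(records[i].body_length)
            and not is_missing(value(records[i]))
            and value(records[i]) > 0
        ]
        if len(complete) < 3:
            raise ValueError(
                f"group {key!r}: only {len(complete)} mice with complete "
                f"{what} and length (need >= 3 for the SMA fit)"
            )
        complete = sorted(complete, key=lambda i: records[i].mouse_id)
        lengths = np.array([records[i].body_length for i in complete])
        values = np.array([value(records[i]) for i in complete])
        ln_l, ln_v = np.log(lengths), np.log(values)
        L0 = float(lengths.mean())
        if ln_l.std(ddof=1) == 0:
            # all lengths equal: (L0/L)^b = 1 for any exponent; report b = 0
            b, r = 0.0, float("nan")
        else:
            b = sma_slope(ln_l, ln_v)
            r = _ols_r(ln_l, ln_v)
        fits[key] = AllometricFit(b, L0, r, len(complete))
        for i in idx:
            r = records[i]
            v = value(r)
            if is_missing(r.body_length) or is_missing(v):
                continue
            out[r.mouse_id] = float(v * (L0 / r.body_length) ** b)
    return out, fits


def scale_cell_counts(
    records: Sequence[MouseRecord],
    cell_type: str,
    group: str | None = None,
    b_override: float | None = None,
) -> tuple[dict[str, float | None], dict[Hashable, AllometricFit]]:
    """SMI-analogous scaling of one splenic cell count.

    Zero counts are excluded from the SMA fit (their log is undefined) but are
    still scaled with the fitted exponent (a zero count scales to zero).
    ``b_override`` forces the exponent (fit is skipped), e.g. b=0 leaves the
    raw counts unchanged.
    """
    def count(r: MouseRecord) -> float | None:
        return r.immune_measures.get(cell_type)

    nonzero = [
        r for r in records
        if not is_missing(count(r)) and count(r) > 0 and not is_missing(r.body_length)
    ]
    if b_override is not None:
        if not nonzero:
            raise ValueError(f"all {cell_type} counts are zero or missing")
        L0 = float(np.mean([r.body_length for r in nonzero]))
        fit = AllometricFit(float(b_override), L0, float("nan"), len(nonzero))
        out: dict[str, float | None] = {}
        for r in records:
            c = count(r)
            if is_missing(c) or is_missing(r.body_length):
                out[r.mouse_id] = None
            else:
                out[r.mouse_id] = float(c * (L0 / r.body_length) ** b_override)
        return out, {"all": fit}

    if not any(not is_missing(count(r)) and count(r) > 0 for r in records):
        raise ValueError(f"all {cell_type} counts are zero or missing")
    scaled, fits = _smi_like(nonzero, value=count, group=group, what=cell_type)
    # scale the zero-count mice with the fitted group exponents
    out = {}
    for r in records:
        c = count(r)
        if is_missing(c) or is_missing(r.body_length):
            out[r.mouse_id] = None
        elif r.mouse_id in scaled and scaled[r.mouse_id] is not None:
            out[r.mouse_id] = scaled[r.mouse_id]
        else:
            fit = fits.get(_group_key(r, group))
            if fit is None:
                out[r.mouse_id] = None
            else:
                out[r.mouse_id] = float(c * (fit.L0 / r.body_length) ** fit.b_sma)
    return out, fits


def compute_bmi(body_mass_g: float, body_length_mm: float) -> float:
    """Body mass index, kg/m^2, from mass in g and length in mm."""
    if body_mass_g <= 0 or body_length_mm <= 0:
        raise ValueError("mass and length must be positive")
    return (body_mass_g / 1000.0) / (body_length_mm / 1000.0) ** 2


def pow10_rescale(values: Sequence[float]) -> tuple[np.ndarray, int]:
    """Divide by 10**k with k chosen so the median nonzero value is in [1, 10).

    Idempotent; an all-zero vector is returned unchanged with k = 0.
    Returns (rescaled values, k).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    finite = values[np.isfinite(values)]
    if (finite < 0).any():
        raise ValueError("pow10_rescale expects nonnegative values")
    nonzero = finite[finite > 0]
    if nonzero.size == 0:
        return values.copy(), 0
    med = float(np.median(nonzero))
    k = int(math.floor(math.log10(med)))
    # guard against log10 rounding at decade boundaries (idempotence)
    if med / 10.0 ** k >= 10.0:
        k += 1
    elif med / 10.0 ** k < 1.0:
        k -= 1
    return values / 10.0 ** k, k


def lens_age(
    lens_mass_mg: float,
    calibration: LensCalibration | None = None,
) -> tuple[float, bool]:
    """Age in weeks from eye-lens mass (mg).

    Returns (age_weeks, extrapolated): ``extrapolated`` flags a lens mass
    below the calibration's support, where the inverted curve is unreliable.
    Strictly increasing in lens mass for beta > 0.
    """
    cal = calibration or LensCalibration()
    extrapolated = lens_mass_mg < cal.min_lens_mg
    return cal.age_days(lens_mass_mg) / 7.0, extrapolated
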