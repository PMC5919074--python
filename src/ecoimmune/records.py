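"""Core domain containers: per-mouse records and multilocus genotype matrices.

A :class:`MouseRecord` is one trapped mouse. Any field may be missing
(``None`` / NaN); missingness is always explicit and never encoded as 0 or a
negative sentinel. A :class:`GenotypeMatrix` holds biallelic diploid genotypes
as alt-allele dosage (0/1/2, NaN for a failed call), loci in rows and
individuals in columns, with a site label per individual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np

#: The 12 two-letter sampling-site designations, in numeric-code order.
SITE_CODE_MAP: dict[int, str] = {
    1: "BM", 2: "HW", 3: "LU", 4: "WF", 7: "GL", 8: "WT",
    9: "PF", 10: "ST", 11: "JB", 12: "PH", 13: "SP", 14: "SK",
}
SITES: tuple[str, ...] = tuple(SITE_CODE_MAP.values())
_SITE_TO_CODE = {v: k for k, v in SITE_CODE_MAP.items()}

#: Serologically assayed microbial infections, scored 0 (seronegative) to 4.
MICROBES: tuple[str, ...] = (
    "noro", "minute", "parvo", "sendai", "corona", "mhv", "m_pulmonis",
)

#: Splenic cell populations counted by flow cytometry (scaled like SMI downstream).
CELL_TYPES: tuple[str, ...] = (
    "cd4", "cd8", "cd19", "nkp46", "ly6g", "cd11c", "f480",
)

#: Antibody concentrations: serum IgG and IgE, faecal IgA.
ANTIBODIES: tuple[str, ...] = ("igg", "ige", "iga")

#: The 10 immune measures entering the immunological-distance PCA.
IMMUNE_MEASURES: tuple[str, ...] = CELL_TYPES + ANTIBODIES

SEXES: tuple[str, ...] = ("female", "male")


def site_from_code(code: int) -> str:
    """Map a numeric site code (supplementary-table convention) to its 2-letter id."""
    try:
        return SITE_CODE_MAP[int(code)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"unknown site code: {code!r}") from exc


def code_from_site(site: str) -> int:
    try:
        return _SITE_TO_CODE[site.upper()]
    except KeyError as exc:
        raise ValueError(f"unknown site designation: {site!r}") from exc


def is_missing(value) -> bool:
    """True for None or NaN; the only two missing encodings used internally."""
    if value is None:
        return True
    return isinstance(value, float) and math.isnan(value)


@dataclass
class MouseRecord:
    """One wild-caught mouse.

    Units: day_length minutes; masses g except lens_mass (mg); lengths mm;
    age weeks; leptin ng/mL; haemoglobin g/L. ``infection_scores`` maps each
    of the 7 assayed microbes to an integer 0–4 (0 = seronegative).
    ``immune_measures`` maps the 10 immune measures (7 scaled cell counts,
    IgG, IgE, IgA) to nonnegative reals.
    """

    mouse_id: str
    site: str | None = None
    sex: str | None = None
    day_length: float | None = None
    body_mass: float | None = None
    body_length: float | None = None
    abdominal_fat: float | None = None
    lens_mass: float | None = None
    age: float | None = None
    leptin: float | None = None
    haemoglobin: float | None = None
    infection_scores: dict[str, int | None] = field(default_factory=dict)
    mite_count_class: int | None = None
    worm_count: int | None = None
    immune_measures: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.site is not None and self.site not in SITES:
            raise ValueError(f"unknown site designation: {self.site!r}")
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        for name, score in self.infection_scores.items():
            if name not in MICROBES:
                raise ValueError(f"unknown microbe: {name!r}")
            if score is not None and score not in (0, 1, 2, 3, 4):
                raise ValueError(
                    f"infection score for {name} must be 0..4, got {score!r}"
                )
        for key in ("body_mass", "body_length"):
            v = getattr(self, key)
            if v is not None and not is_missing(v) and v <= 0:
                raise ValueError(f"{key} must be positive, got {v!r}")

    def infection_burden(self) -> int | None:
        """Count of the 7 microbes with a seropositive score (>= 1).

        None if no microbe was assayed for this mouse.
        """
        scores = [s for s in self.infection_scores.values() if s is not None]
        if not scores:
            return None
        return int(sum(s >= 1 for s in scores))


_SCALAR_FIELDS = (
    "site", "sex", "day_length", "body_mass", "body_length", "abdominal_fat",
    "lens_mass", "age", "leptin", "haemoglobin", "mite_count_class", "worm_count",
)


def records_to_frame(records: Sequence[MouseRecord]):
    """Flatten records into a pandas DataFrame (canonical column layout)."""
    import pandas as pd

    rows = []
    for r in records:
        row: dict = {"mouse_id": r.mouse_id}
        for f in _SCALAR_FIELDS:
            row[f] = getattr(r, f)
        for m in MICROBES:
            row[f"score_{m}"] = r.infection_scores.get(m)
        for k in IMMUNE_MEASURES:
            row[k] = r.immune_measures.get(k)
        rows.append(row)
    cols = (["mouse_id"] + list(_SCALAR_FIELDS)
            + [f"score_{m}" for m in MICROBES] + list(IMMUNE_MEASURES))
    return pd.DataFrame(rows, columns=cols)


def frame_to_records(df) -> list[MouseRecord]:
    """Inverse of :func:`records_to_frame`; NaN/empty cells become None."""
    out: list[MouseRecord] = []
    for _, row in df.iterrows():
        def get(col):
            if col not in row.index:
                return None
            v = row[col]
            if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
                return None
            return v

        scores = {}
        for m in MICROBES:
            v = get(f"score_{m}")
            scores[m] = None if v is None else int(v)
        measures = {}
        for k in IMMUNE_MEASURES:
            v = get(k)
            measures[k] = None if v is None else float(v)
        kwargs = {}
        for f in _SCALAR_FIELDS:
            v = get(f)
            if f in ("site", "sex"):
                kwargs[f] = None if v is None else str(v)
            elif f in ("mite_count_class", "worm_count"):
                kwargs[f] = None if v is None else int(v)
            else:
                kwargs[f] = None if v is None else float(v)
        out.append(MouseRecord(mouse_id=str(row["mouse_id"]),
                               infection_scores=scores,
                               immune_measures=measures, **kwargs))
    return out


class GenotypeMatrix:
    """Biallelic diploid genotypes, loci x individuals, dosage-coded.

    Dosage is the count of the alternate allele (0, 1 or 2); missing calls are
    NaN. Each individual carries a sampling-site label.
    """

    def __init__(
        self,
        dosages: np.ndarray,
        locus_ids: Sequence[str],
        individual_ids: Sequence[str],
        sites: Sequence[str],
        chromosomes: Sequence[str] | None = None,
        positions: Sequence[int] | None = None,
    ) -> None:
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (loci x individuals)")
        n_loci, n_ind = dosages.shape
        if len(locus_ids) != n_loci:
            raise ValueError("locus_ids length mismatch")
        if len(individual_ids) != n_ind or len(sites) != n_ind:
            raise ValueError("individual_ids/sites length mismatch")
        valid = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"genotype dosage must be 0/1/2 or missing; offending locus "
                f"{locus_ids[bad[0]]!r}, individual {individual_ids[bad[1]]!r}"
            )
        self.dosages = dosages
        self.locus_ids = list(map(str, locus_ids))
        self.individual_ids = list(map(str, individual_ids))
        self.sites = list(map(str, sites))
        self.chromosomes = (list(map(str, chromosomes))
                            if chromosomes is not None else ["NA"] * n_loci)
        self.positions = (list(map(int, positions))
                          if positions is not None else list(range(n_loci)))

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[1]

    @property
    def site_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s, None)
        return list(seen)

    def site_columns(self, site: str) -> np.ndarray:
        idx = np.array([i for i, s in enumerate(self.sites) if s == site], dtype=int)
        if idx.size == 0:
            raise KeyError(f"site {site!r} absent from genotype matrix")
        return idx

    def subset_sites(self, keep: Iterable[str]) -> "GenotypeMatrix":
        keep = set(keep)
        idx = [i for i, s in enumerate(self.sites) if s in keep]
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.locus_ids,
            [self.individual_ids[i] for i in idx],
            [self.sites[i] for i in idx],
            self.chromosomes,
            self.positions,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.locus_ids == other.locus_ids
            and self.individual_ids == other.individual_ids
            and self.sites == other.sites
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )
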