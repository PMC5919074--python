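"""Reading and writing the canonical tabular schemas.

The canonical on-disk format is CSV (UTF-8, '.' decimal). Four cohort schemas
are supported, mirroring the supplementary-table layouts the analyses consume:

``s1_infection``
    mouse id, site, the 7 serological infection scores (0-4), total number of
    microbial infections, mite count class, worm count.
``s3_pcs``
    mouse id, site (numeric code), and the first three principal-component
    scores of the 10 immune measures.
``s6_physical``
    mouse id, site (numeric code), day length (min), sex (1=female, 2=male),
    morphometrics, masses, eye-lens mass (mg), age (weeks), haemoglobin,
    leptin.
``canonical``
    the package's full per-mouse layout (every MouseRecord field), as written
    by :func:`write_cohort`.

Blank cells are missing values; internally missing is ``None``/NaN, never 0.
XLSX input is accepted through a thin conversion layer
(:func:`convert_xlsx_to_csv`). Unicode minus signs are normalized on read.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .records import (
    MICROBES,
    IMMUNE_MEASURES,
    GenotypeMatrix,
    MouseRecord,
    frame_to_records,
    records_to_frame,
    site_from_code,
    SITES,
)

_MISSING_TOKENS = {"", "na", "nan", "nd", "--", "?", "none", "."}

_S1_COLUMNS = (
    ["mouse_id", "site"] + [f"score_{m}" for m in MICROBES]
    + ["total_infections", "mite_count_class", "worm_count"]
)
_S3_COLUMNS = ["mouse_id", "site", "pc1", "pc2", "pc3"]
_S6_COLUMNS = [
    "mouse_id", "site", "day_length", "sex", "body_length", "skull_length",
    "skull_width", "body_mass", "abdominal_fat", "lens_mass", "age",
    "haemoglobin", "leptin", "bmi", "smi",
]

SCHEMAS = ("s1_infection", "s3_pcs", "s6_physical", "canonical")


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


def _normalize(text: str) -> str:
    # unicode minus / plus-minus seen in supplementary legends
    return text.replace("−", "-").replace("±", "").strip()


def _clean(value) -> str | None:
    if value is None:
        return None
    s = _normalize(str(value))
    if s.lower() in _MISSING_TOKENS:
        return None
    return s


def _to_float(value, *, context: str) -> float | None:
    s = _clean(value)
    if s is None:
        return None
    try:
        return float(s)
    except ValueError as exc:
        raise SchemaError(f"non-numeric value {value!r} in {context}") from exc


def _site_label(value, *, context: str) -> str | None:
    s = _clean(value)
    if s is None:
        return None
    if s.upper() in SITES:
        return s.upper()
    try:
        code = int(float(s))
    except ValueError:
        raise SchemaError(f"unknown site designation {value!r} in {context}")
    try:
        return site_from_code(code)
    except ValueError as exc:
        raise SchemaError(f"unknown site code {value!r} in {context}") from exc


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, dtype=object)
    else:
        df = pd.read_csv(path, dtype=object, keep_default_na=False)
    df.columns = [_normalize(str(c)).lower() for c in df.columns]
    return df


def convert_xlsx_to_csv(path, out_path, sheet: int | str = 0) -> Path:
    """Dump one sheet of an XLSX workbook to CSV, cell for cell."""
    df = pd.read_excel(path, sheet_name=sheet, dtype=object)
    out_path = Path(out_path)
    df.to_csv(out_path, index=False)
    return out_path


def read_cohort(path, schema: str = "canonical") -> list[MouseRecord]:
    """Read a cohort table into MouseRecords (fields outside the schema missing).

    For ``s3_pcs`` the principal-component scores themselves are not MouseRecord
    fields; use :func:`read_pc_scores` to obtain them.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"schema must be one of {SCHEMAS}, got {schema!r}")
    df = _read_table(path)
    if schema == "canonical":
        _require_columns(df, ["mouse_id"], schema)
        df = df.replace({"": None})
        for col in df.columns:
            if col in ("mouse_id", "site", "sex"):
                continue
            df[col] = [
                None if _clean(v) is None else float(_clean(v)) for v in df[col]
            ]
        recs = frame_to_records(df)
        _validate_positive(recs)
        return recs
    if schema == "s1_infection":
        return _read_s1(df)
    if schema == "s3_pcs":
        return [
            MouseRecord(mouse_id=str(row["mouse_id"]), site=row["site"])
            for _, row in read_pc_scores(path).iterrows()
        ]
    return _read_s6(df)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], schema: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema} table lacks required columns: {missing}")


def _validate_positive(records: Sequence[MouseRecord]) -> None:
    for r in records:
        for f in ("body_mass", "body_length"):
            v = getattr(r, f)
            if v is not None and v <= 0:
                raise SchemaError(f"{f} must be positive for mouse {r.mouse_id}")


def _read_s1(df: pd.DataFrame) -> list[MouseRecord]:
    _require_columns(df, _S1_COLUMNS[:2] + _S1_COLUMNS[2:9], "s1_infection")
    records = []
    for i, row in df.iterrows():
        ctx = f"s1_infection row {i + 2}"
        scores: dict[str, int | None] = {}
        for m in MICROBES:
            v = _to_float(row.get(f"score_{m}"), context=f"{ctx} column score_{m}")
            scores[m] = None if v is None else int(v)
        mites = _to_float(row.get("mite_count_class"), context=ctx)
        worms = _to_float(row.get("worm_count"), context=ctx)
        records.append(
            MouseRecord(
                mouse_id=str(_clean(row["mouse_id"])),
                site=_site_label(row["site"], context=f"{ctx} column site"),
                infection_scores=scores,
                mite_count_class=None if mites is None else int(mites),
                worm_count=None if worms is None else int(worms),
            )
        )
    return records


def _read_s6(df: pd.DataFrame) -> list[MouseRecord]:
    _require_columns(df, ["mouse_id", "site"], "s6_physical")
    records = []
    for i, row in df.iterrows():
        ctx = f"s6_physical row {i + 2}"
        sex_v = _to_float(row.get("sex"), context=f"{ctx} column sex")
        if sex_v is None:
            sex = None
        elif int(sex_v) in (1, 2):
            sex = "female" if int(sex_v) == 1 else "male"
        else:
            raise SchemaError(f"sex must be 1 or 2 in {ctx}, got {sex_v!r}")
        kwargs = {}
        for col in ("day_length", "body_length", "body_mass", "abdominal_fat",
                    "lens_mass", "age", "haemoglobin", "leptin"):
            kwargs[col] = _to_float(row.get(col), context=f"{ctx} column {col}")
        for col in ("body_mass", "body_length"):
            if kwargs[col] is not None and kwargs[col] <= 0:
                raise SchemaError(f"{col} must be positive in {ctx}")
        records.append(
            MouseRecord(
                mouse_id=str(_clean(row["mouse_id"])),
                site=_site_label(row["site"], context=f"{ctx} column site"),
                sex=sex,
                **kwargs,
            )
        )
    return records


def read_pc_scores(path) -> pd.DataFrame:
    """Read an ``s3_pcs`` table: mouse_id, site, pc1..pc3 (floats, site 2-letter)."""
    df = _read_table(path)
    _require_columns(df, _S3_COLUMNS, "s3_pcs")
    out = pd.DataFrame(
        {
            "mouse_id": [str(_clean(v)) for v in df["mouse_id"]],
            "site": [
                _site_label(v, context=f"s3_pcs row {i + 2} column site")
                for i, v in enumerate(df["site"])
            ],
        }
    )
    for c in ("pc1", "pc2", "pc3"):
        out[c] = [
            _to_float(v, context=f"s3_pcs column {c}") for v in df[c]
        ]
    return out


def write_cohort(records: Sequence[MouseRecord], path) -> Path:
    """Write records in the canonical schema; missing values become blank cells."""
    df = records_to_frame(records)
    path = Path(path)
    df.to_csv(path, index=False, na_rep="")
    return path


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

_GENO_META = ("locus_id", "chromosome", "position")


def _detect_dosage(values: list[str | None], locus_id: str) -> np.ndarray:
    """Auto-detect dosage (0/1/2) vs letter-pair (e.g. 'AG', 'A/G') encoding."""
    cleaned = [v for v in values if v is not None]
    numeric = True
    for v in cleaned:
        try:
            f = float(v)
        except ValueError:
            numeric = False
            break
        if f not in (0.0, 1.0, 2.0):
            raise SchemaError(
                f"locus {locus_id!r}: numeric genotype {v!r} is not 0/1/2"
            )
    out = np.full(len(values), np.nan)
    if numeric:
        for i, v in enumerate(values):
            if v is not None:
                out[i] = float(v)
        return out
    # letter encoding: each call is two allele letters, optionally separated
    alleles: set[str] = set()
    pairs: list[tuple[str, str] | None] = []
    for v in values:
        if v is None:
            pairs.append(None)
            continue
        s = v.replace("/", "").replace("|", "").upper()
        if len(s) != 2 or not s.isalpha():
            raise SchemaError(f"locus {locus_id!r}: unparseable genotype {v!r}")
        pairs.append((s[0], s[1]))
        alleles.update(s)
    if len(alleles) > 2:
        raise SchemaError(
            f"locus {locus_id!r} is not biallelic: alleles {sorted(alleles)}"
        )
    alt = sorted(alleles)[-1]  # alphabetically last allele counts as alt
    for i, p in enumerate(pairs):
        if p is not None:
            out[i] = (p[0] == alt) + (p[1] == alt)
    return out


def read_genotypes(path, site_map: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read a loci x individuals genotype CSV.

    First three columns are locus id, chromosome, position; remaining columns
    are individuals. An optional row whose locus id is ``site`` carries each
    individual's site label (as written by :func:`write_genotypes`); otherwise
    ``site_map`` must supply individual id -> site.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise SchemaError("empty genotype file")
    header = [_normalize(c) for c in rows[0]]
    if [h.lower() for h in header[:3]] != list(_GENO_META):
        raise SchemaError(
            f"genotype header must start with {_GENO_META}, got {header[:3]}"
        )
    individual_ids = header[3:]
    body = rows[1:]
    sites: list[str] | None = None
    data_rows = []
    for row in body:
        if row and row[0].strip().lower() == "site":
            sites = [_site_label(v, context="genotype site row") or "" for v in row[3:]]
            continue
        data_rows.append(row)
    if sites is None:
        if site_map is None:
            raise SchemaError("no site row in file and no site_map supplied")
        try:
            sites = [site_map[i] for i in individual_ids]
        except KeyError as exc:
            raise SchemaError(f"individual {exc.args[0]!r} absent from site map")
    locus_ids, chroms, poss, dosage_rows = [], [], [], []
    for row in data_rows:
        if not row or all(not c.strip() for c in row):
            continue
        locus_ids.append(row[0].strip())
        chroms.append(row[1].strip())
        poss.append(int(float(row[2])) if row[2].strip() else 0)
        values = [_clean(v) for v in row[3:]]
        if len(values) != len(individual_ids):
            raise SchemaError(f"locus {row[0]!r}: wrong number of genotype calls")
        dosage_rows.append(_detect_dosage(values, row[0]))
    return GenotypeMatrix(
        np.array(dosage_rows).reshape(len(locus_ids), len(individual_ids)),
        locus_ids, individual_ids, sites, chroms, poss,
    )


def write_genotypes(g: GenotypeMatrix, path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(list(_GENO_META) + g.individual_ids)
        w.writerow(["site", "", ""] + g.sites)
        for i in range(g.n_loci):
            calls = [
                "" if math.isnan(d) else str(int(d)) for d in g.dosages[i]
            ]
            w.writerow([g.locus_ids[i], g.chromosomes[i], g.positions[i]] + calls)
    return path


# ---------------------------------------------------------------------------
# distance matrices and trees
# ---------------------------------------------------------------------------


def read_distance_matrix(path, tol: float = 1e-9) -> DistanceMatrix:
    """Read a square labelled CSV distance matrix.

    Symmetry is enforced within ``tol`` (the symmetrized average is stored);
    asymmetry beyond tolerance or any negative entry is an error.
    """
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise SchemaError(f"distance matrix is not square: {values.shape}")
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise SchemaError("distance-matrix row labels differ from column labels")
    if (values < 0).any():
        raise SchemaError("distance matrix contains negative entries")
    asym = np.abs(values - values.T).max()
    if asym > tol:
        raise SchemaError(
            f"distance matrix asymmetric beyond tolerance: max |d_ij - d_ji| = {asym:g}"
        )
    sym = (values + values.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    return DistanceMatrix(sym, ids=labels)


def write_distance_matrix(dm: DistanceMatrix, path) -> Path:
    path = Path(path)
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path)
    return path


def write_tree(tree, path) -> Path:
    """Serialize a scikit-bio TreeNode as Newick with branch lengths."""
    path = Path(path)
    tree.write(str(path), format="newick")
    return path


def read_tree(path):
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")
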