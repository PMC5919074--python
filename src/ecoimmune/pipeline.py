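"""End-to-end orchestration: data in, condition, distance, popgen, SEM, report.

A :class:`PipelineConfig` selects synthetic or file input and the analysis
options; :func:`run_pipeline` executes every stage, writes CSV tables, Newick
trees, a machine-readable JSON summary and a run log into the output
directory, and returns the summary. All randomness flows from the single
configured seed; identical config + seed reproduces the bundle byte for
byte (wall times go to the log only).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import compare, condition, immune, io, popgen, sem, simulate
from .records import ANTIBODIES, CELL_TYPES, MouseRecord


@dataclass
class PipelineConfig:
    mode: str = "synthetic"                   # 'synthetic' | 'files'
    seed: int = 0
    out_dir: str = "ecoimmune_out"
    # files mode inputs
    cohort_path: str | None = None            # canonical or s6 schema
    cohort_schema: str = "canonical"
    infection_path: str | None = None         # s1 schema (files mode)
    genotype_path: str | None = None
    pc_scores_path: str | None = None         # s3 schema: bypasses the PCA
    geo_distance_path: str | None = None
    # analysis options
    n_perm: int = 999
    smi_group: str | None = "sex"
    sem_models: tuple[str, ...] = ("adaptive", "innate", "humoral")
    sem_sexes: tuple[str, ...] = ("female", "male")
    sem_site: str | None = None               # restrict SEM to one site
    nj_bootstraps: int = 0                    # locus bootstrap for the NJ tree
    build_nj_tree: bool = False               # O(n^3): off by default
    synthetic_overrides: dict = field(default_factory=dict)


def validate_config(config: PipelineConfig) -> list[str]:
    """Empty list iff the configuration is runnable."""
    problems = []
    if config.mode not in ("synthetic", "files"):
        problems.append(f"mode must be 'synthetic' or 'files', got {config.mode!r}")
    if config.n_perm < 99:
        problems.append(f"n_perm must be >= 99, got {config.n_perm}")
    if config.mode == "files":
        for name in ("cohort_path", "genotype_path"):
            if getattr(config, name) is None:
                problems.append(f"files mode requires {name}")
    unknown = set(config.sem_models) - {"adaptive", "innate", "humoral"}
    if unknown:
        problems.append(f"unknown SEM models: {sorted(unknown)}")
    return problems


class StageError(RuntimeError):
    def __init__(self, stage: str, entity: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {entity!r}: {cause}")
        self.stage = stage
        self.entity = entity


def _round_floats(obj, digits=10):
    if isinstance(obj, float):
        return round(obj, digits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), digits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    summary: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _round_floats({k: v for k, v in asdict(config).items()}),
    }
    summary["config_hash"] = hashlib.sha256(
        json.dumps(summary["config"], sort_keys=True).encode()
    ).hexdigest()[:16]

    def stage(name):
        t0 = time.perf_counter()

        def done():
            log_lines.append(f"stage {name}: {time.perf_counter() - t0:.2f}s")
        return done

    # ---- stage: data -----------------------------------------------------
    done = stage("data")
    try:
        if config.mode == "synthetic":
            scfg = simulate.SyntheticConfig(seed=config.seed,
                                            **config.synthetic_overrides)
            records, truth = simulate.gen_cohort(scfg)
            genotypes, _ = simulate.gen_genotypes(scfg)
            geo = simulate.geographic_distance_matrix(scfg)
            io.write_cohort(records, out / "cohort.csv")
            io.write_genotypes(genotypes, out / "genotypes.csv")
            io.write_distance_matrix(geo, out / "geographic_km.csv")
            pc_table = None
        else:
            records = io.read_cohort(config.cohort_path, config.cohort_schema)
            if config.infection_path:
                by_id = {r.mouse_id: r for r in records}
                for r in io.read_cohort(config.infection_path, "s1_infection"):
                    tgt = by_id.get(r.mouse_id)
                    if tgt is None:
                        records.append(r)
                        by_id[r.mouse_id] = r
                    else:
                        tgt.infection_scores = r.infection_scores
                        tgt.mite_count_class = r.mite_count_class
                        tgt.worm_count = r.worm_count
            genotypes = io.read_genotypes(config.genotype_path)
            geo = (io.read_distance_matrix(config.geo_distance_path)
                   if config.geo_distance_path else None)
            pc_table = (io.read_pc_scores(config.pc_scores_path)
                        if config.pc_scores_path else None)
    except Exception as exc:
        raise StageError("data", config.mode, exc)
    done()

    # ---- stage: condition ------------------------------------------------
    done = stage("condition")
    smi, fits = condition.compute_smi(records, group=config.smi_group)
    bmi = {
        r.mouse_id: (condition.compute_bmi(r.body_mass, r.body_length)
                     if r.body_mass and r.body_length else None)
        for r in records
    }
    scaled_counts: dict[str, dict[str, float | None]] = {}
    for cell in CELL_TYPES:
        try:
            scaled_counts[cell], _ = condition.scale_cell_counts(records, cell)
        except ValueError:
            scaled_counts[cell] = {r.mouse_id: None for r in records}
    smi_bmi = {}
    for sex in ("female", "male"):
        pairs = [
            (smi[r.mouse_id], bmi[r.mouse_id]) for r in records
            if r.sex == sex and smi[r.mouse_id] is not None
            and bmi[r.mouse_id] is not None
        ]
        if len(pairs) >= 3:
            x, y = np.array(pairs).T
            smi_bmi[sex] = {"r": float(np.corrcoef(x, y)[0, 1]), "n": len(pairs)}
    summary["condition"] = {
        "allometric_fits": {
            str(k): asdict(v) for k, v in fits.items()
        },
        "smi_bmi_correlation": smi_bmi,
    }
    done()

    # ---- stage: immune structure -----------------------------------------
    done = stage("immune")
    site_of = {r.mouse_id: r.site for r in records if r.site}
    if pc_table is not None:
        dm = immune.immune_distance(pc_table)
        pca_info = {"source": "supplied_pc_scores"}
        site_of = dict(zip(pc_table["mouse_id"], pc_table["site"]))
    else:
        mf = immune.measures_frame(records)
        for cell in CELL_TYPES:   # replace raw counts by allometric-scaled ones
            mf[cell] = [scaled_counts[cell][m] for m in mf["mouse_id"]]
        pcs = immune.immune_pca(mf)
        pcs.frame().to_csv(out / "pc_scores.csv", index=False)
        dm = immune.immune_distance(pcs)
        pca_info = {
            "source": "immune_pca",
            "variance_explained": [float(v) for v in pcs.variance_explained],
            "n_excluded_incomplete": pcs.n_excluded,
        }
    summaries, overall = immune.site_distance_summary(dm, site_of)
    pd.DataFrame([asdict(s) for s in summaries]).to_csv(
        out / "site_distance_summary.csv", index=False)
    wvn = immune.within_distance_vs_n(summaries, n_perm=config.n_perm,
                                      seed=config.seed + 11)
    among_imm = compare.among_site_distance(dm, site_of)
    io.write_distance_matrix(among_imm, out / "immune_distance_sites.csv")
    coords = immune.classical_mds(among_imm, k=2)
    pd.DataFrame(coords, index=list(among_imm.ids),
                 columns=["mds1", "mds2"]).to_csv(out / "site_mds.csv")
    infections = immune.infection_descriptives(records)
    summary["immune"] = {
        "pca": pca_info,
        "distance": {**overall,
                     "within_vs_n_r": wvn.r, "within_vs_n_p": wvn.p},
        "infection": {
            "seroprevalence": infections.seroprevalence,
            "n_tested": infections.n_tested,
            "prevalence": infections.prevalence,
            "worm_prevalence": infections.worm_prevalence,
            "mite_prevalence": infections.mite_prevalence,
            "burden_age_r": {
                k: {"r": v.r, "p": v.p, "n": v.n}
                for k, v in infections.burden_age_by_sex.items()
            },
        },
    }
    done()

    # ---- stage: popgen ---------------------------------------------------
    done = stage("popgen")
    try:
        fst_dm = popgen.fst_matrix(genotypes)
        io.write_distance_matrix(fst_dm, out / "fst_sites.csv")
        mean_fst = popgen.average_fst(genotypes)
        fis_per_site, fis_avg = popgen.fis(genotypes)
        if config.build_nj_tree:
            tree, _support = popgen.nj_tree_with_support(
                genotypes, bootstraps=config.nj_bootstraps,
                seed=config.seed + 13)
            io.write_tree(tree, out / "nj_individuals.nwk")
    except Exception as exc:
        raise StageError("popgen", "genotypes", exc)
    summary["popgen"] = {
        "mean_pairwise_fst": mean_fst,
        "mean_fis": fis_avg,
        "fis_per_site": fis_per_site,
        "n_loci": genotypes.n_loci,
        "n_individuals": genotypes.n_individuals,
    }
    done()

    # ---- stage: matrix comparison ----------------------------------------
    done = stage("compare")
    mantel_results = {}
    shared = [s for s in among_imm.ids if s in fst_dm.ids]
    if len(shared) >= 4:
        imm_f = among_imm.filter(shared)
        fst_f = fst_dm.filter(shared)
        res = compare.mantel(imm_f, fst_f, n_perm=config.n_perm,
                             seed=config.seed + 17)
        mantel_results["immune_vs_fst"] = {"r": res.r, "p": res.p}
        io.write_tree(compare.upgma(imm_f), out / "upgma_immune.nwk")
        io.write_tree(compare.upgma(fst_f), out / "upgma_fst.nwk")
    if geo is not None:
        shared = [s for s in among_imm.ids if s in geo.ids]
        if len(shared) >= 4:
            imm_f = among_imm.filter(shared)
            geo_f = geo.filter(shared)
            for transform in ("none", "log1p"):
                res = compare.mantel(imm_f, geo_f, n_perm=config.n_perm,
                                     seed=config.seed + 19,
                                     transform=transform)
                mantel_results[f"immune_vs_geography_{transform}"] = {
                    "r": res.r, "p": res.p}
            io.write_tree(compare.upgma(geo_f), out / "upgma_geography.nwk")
    summary["mantel"] = mantel_results
    done()

    # ---- stage: SEM ------------------------------------------------------
    done = stage("sem")
    sem_data = _sem_frame(records, smi, scaled_counts)
    if config.sem_site:
        sem_data = sem_data[sem_data["site"] == config.sem_site]
    models = sem.default_models()
    sem_summary = {}
    for model_name in config.sem_models:
        spec = models[model_name]
        for sex in config.sem_sexes:
            key = f"{model_name}_{sex}"
            sub = sem_data[sem_data["sex"] == sex]
            try:
                fit = sem.fit_ml(spec, sub, seed=config.seed + 23)
            except (ValueError, RuntimeError) as exc:
                sem_summary[key] = {"error": str(exc)}
                continue
            report = sem.acceptance_report(fit)
            fit.to_frame().to_csv(out / f"sem_{key}.csv", index=False)
            sem_summary[key] = {
                "n": fit.n, "chi2": fit.chi2, "df": fit.df,
                "chi2_p": fit.chi2_p, "rmsea": fit.rmsea,
                "rmsea_ci": list(fit.rmsea_ci), "cfi": fit.cfi,
                "srmr": fit.srmr, "verdict": report["verdict"],
            }
    summary["sem"] = sem_summary
    done()

    summary = _round_floats(summary)
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True))
    log_lines.append(f"config hash {summary['config_hash']}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


def _sem_frame(records: list[MouseRecord], smi: dict, scaled_counts: dict):
    """Per-mouse table of the SEM observed variables (NaN for missing)."""
    rows = []
    for r in records:
        row = {
            "mouse_id": r.mouse_id, "site": r.site, "sex": r.sex,
            "season": r.day_length, "age": r.age,
            "condition": smi.get(r.mouse_id),
            "infection": r.infection_burden(),
        }
        for cell in CELL_TYPES:
            row[cell] = scaled_counts.get(cell, {}).get(r.mouse_id)
        for ab in ANTIBODIES:
            row[ab] = r.immune_measures.get(ab)
        rows.append(row)
    df = pd.DataFrame(rows)
    for c in df.columns:
        if c not in ("mouse_id", "site", "sex"):
            df[c] = pd.to_numeric(df[c], errors="coerce")
    return df
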