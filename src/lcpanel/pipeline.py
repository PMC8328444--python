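"""Stage orchestration: each pipeline stage reads its inputs from a run
directory, computes, and writes tab-delimited outputs back, so stages can
be run separately from the CLI or chained with :func:`run_all`.

Stage graph (file products in parentheses):

    simulate  (reads.tsv, site_info.tsv, truth_sites.tsv, phenotypes.tsv)
    callsnps  (gl.beagle, sites.tsv)
    pca       (pca.tsv)
    scan      (scan.tsv)
    fst       (fst_sites.tsv, fst_windows.tsv, summary.tsv)
    select    (importance.tsv, ranked_fst.tsv)
    assign    (assign_grrf.tsv, assign_fst.tsv, curve tables)
    report    (plots, written by report.py)

Every stage logs its parameters and seed to ``run.log``; all numeric
output uses a fixed float format so a rerun with the same configuration
and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import assignment as asg
from . import fst as fst_mod
from . import selection as sel
from . import structure
from .io_formats import (GenotypeLikelihoodMatrix, read_beagle, read_table,
                         write_beagle, write_table)
from .likelihoods import FilterThresholds, call_snps, posterior_genotypes
from .synthetic import ReadCountMatrix, SimConfig, simulate_dataset

STAGES = ("simulate", "callsnps", "pca", "scan", "fst", "select", "assign",
          "report")


class MissingInputError(FileNotFoundError):
    """A stage was invoked before the stage that produces its input."""


def default_config() -> dict:
    return {
        "seed": 0,
        "sim": {},                      # overrides of SimConfig fields
        "filters": {},                  # overrides of FilterThresholds fields
        "scan": {"k": 2, "alpha": 0.05},
        "fst": {"win_bp": 1000, "step_bp": 100},
        "select": {
            "target": "group",          # phenotype column to predict
            "n_runs": 10,
            "n_trees": 500,
            "gamma": 0.3,
            "impute_iter": 10,
            "impute_trees": 200,
        },
        "assign": {"step": 5, "k_min": 2, "k_max": 10, "model": "pca_lda"},
    }


def _log(rundir: Path, stage: str, params: dict) -> None:
    with open(rundir / "run.log", "a") as fh:
        fh.write(f"{stage}\t{json.dumps(params, sort_keys=True, default=str)}\n")


def _need(rundir: Path, name: str, producer: str) -> Path:
    path = rundir / name
    if not path.exists():
        raise MissingInputError(
            f"missing input {name!r}: run the {producer!r} stage first"
        )
    return path


def _write_reads(reads: ReadCountMatrix, path: Path) -> None:
    S, N, _ = reads.counts.shape
    cols = {}
    for i in range(N):
        cols[f"Ind{i}_a1"] = reads.counts[:, i, 0]
        cols[f"Ind{i}_a2"] = reads.counts[:, i, 1]
    write_table(pd.DataFrame(cols), path)


def _read_reads(path: Path) -> ReadCountMatrix:
    df = read_table(path)
    N = df.shape[1] // 2
    counts = np.empty((len(df), N, 2), dtype=np.int32)
    for i in range(N):
        counts[:, i, 0] = df[f"Ind{i}_a1"]
        counts[:, i, 1] = df[f"Ind{i}_a2"]
    return ReadCountMatrix(counts)


def stage_simulate(rundir: Path, config: dict) -> None:
    cfg = SimConfig(**{**config.get("sim", {}), "seed": config.get("seed", 0)})
    reads, genotypes, truth, site_info = simulate_dataset(cfg)
    _write_reads(reads, rundir / "reads.tsv")
    write_table(site_info, rundir / "site_info.tsv")
    write_table(truth.sites, rundir / "truth_sites.tsv")
    pheno = truth.individuals.copy()
    pheno["group"] = np.where(pheno["population"] == 0, "spring", "winter")
    pheno["sex_label"] = np.where(pheno["sex"] == 1, "male", "female")
    write_table(pheno, rundir / "phenotypes.tsv")
    write_table(
        pd.DataFrame(genotypes, columns=pheno["individual_id"]),
        rundir / "truth_genotypes.tsv",
    )
    _log(rundir, "simulate", cfg.to_dict())


def stage_callsnps(rundir: Path, config: dict) -> None:
    reads = _read_reads(_need(rundir, "reads.tsv", "simulate"))
    site_info = read_table(_need(rundir, "site_info.tsv", "simulate"))
    cfg = SimConfig(**{**config.get("sim", {}), "seed": config.get("seed", 0)})
    thresholds = FilterThresholds(**config.get("filters", {}))
    gl, sites = call_snps(reads, site_info, cfg.error_rate, thresholds)
    retained = sites["retained"].to_numpy()
    write_table(sites, rundir / "sites.tsv")
    write_beagle(gl.subset_sites(retained), sites.loc[retained],
                 rundir / "gl.beagle")
    _log(rundir, "callsnps", dataclasses.asdict(thresholds))


def _load_called(rundir: Path):
    gl, bsites = read_beagle(_need(rundir, "gl.beagle", "callsnps"))
    sites = read_table(_need(rundir, "sites.tsv", "callsnps"))
    retained = sites[sites["retained"]].reset_index(drop=True)
    return gl, retained


def stage_pca(rundir: Path, config: dict) -> None:
    gl, sites = _load_called(rundir)
    k = int(config.get("scan", {}).get("k", 2))
    cov = structure.gl_covariance(gl, sites["maf"].to_numpy(), k=k)
    scores = cov.pc_scores
    df = pd.DataFrame({"individual_id": gl.individuals})
    for j in range(scores.shape[1]):
        df[f"PC{j + 1}"] = scores[:, j]
    write_table(df, rundir / "pca.tsv")
    np.save(rundir / "covariance.npy", cov.cov)
    write_table(
        pd.DataFrame({"variance_explained": cov.variance_explained}),
        rundir / "pca_variance.tsv",
    )
    _log(rundir, "pca", {"k": k, "n_iter": cov.n_iter})


def stage_scan(rundir: Path, config: dict) -> None:
    gl, sites = _load_called(rundir)
    scfg = config.get("scan", {})
    k = int(scfg.get("k", 2))
    alpha = float(scfg.get("alpha", 0.05))
    cov = structure.gl_covariance(gl, sites["maf"].to_numpy(), k=k)
    res = structure.pcadapt_scan(cov, gl, sites["maf"].to_numpy(), alpha=alpha)
    out = sites[["chrom", "pos"]].copy()
    out["stat"] = res.stat
    out["p"] = res.p
    out["significant"] = res.p < res.bonferroni
    write_table(out, rundir / "scan.tsv")
    _log(rundir, "scan",
         {"k": k, "lambda_gc": res.lambda_gc, "bonferroni": res.bonferroni})


def stage_fst(rundir: Path, config: dict) -> None:
    gl, sites = _load_called(rundir)
    pheno = read_table(_need(rundir, "phenotypes.tsv", "simulate"))
    groups = pheno["group"].to_numpy()
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("fst stage expects exactly two groups")
    g1 = groups == labels[0]
    saf1 = fst_mod.saf_likelihoods(gl.values[:, g1, :])
    saf2 = fst_mod.saf_likelihoods(gl.values[:, ~g1, :])
    sfs2d = fst_mod.estimate_2dsfs_em(saf1, saf2)
    a, b = fst_mod.persite_fst(saf1, saf2, sfs2d)
    comp = sites[["chrom", "pos"]].copy()
    comp["a"] = a
    comp["b"] = b
    comp["fst"] = np.clip(np.where(b > 0, a / np.maximum(b, 1e-300), 0.0),
                          -1.0, 1.0)
    write_table(comp, rundir / "fst_sites.tsv")
    fcfg = config.get("fst", {})
    windows = fst_mod.sliding_window_fst(
        comp, win_bp=int(fcfg.get("win_bp", 1000)),
        step_bp=int(fcfg.get("step_bp", 100)),
    )
    write_table(windows, rundir / "fst_windows.tsv")
    global_fst = fst_mod.global_weighted_fst(a, b)
    write_table(
        pd.DataFrame({"statistic": ["global_weighted_fst"], "value": [global_fst]}),
        rundir / "summary.tsv",
    )
    _log(rundir, "fst", {"groups": list(labels), "global_fst": global_fst})


def _feature_matrix(rundir: Path, target: str):
    """Hard-call dosage features over positive-FST loci + labels."""
    gl, sites = _load_called(rundir)
    comp = read_table(_need(rundir, "fst_sites.tsv", "fst"))
    pheno = read_table(_need(rundir, "phenotypes.tsv", "simulate"))
    y = pheno[target].to_numpy()
    _, hard, _ = posterior_genotypes(gl, sites["maf"].to_numpy())
    positive = (comp["b"].to_numpy() > 0) & (comp["a"].to_numpy() > 0)
    X = hard[positive].T  # individuals x loci, -1 = missing
    loci = (sites["chrom"].astype(str) + "_" + sites["pos"].astype(str)).to_numpy()
    return X, y, loci[positive], comp.loc[positive].reset_index(drop=True)


def stage_select(rundir: Path, config: dict) -> None:
    scfg = {**default_config()["select"], **config.get("select", {})}
    target = scfg["target"]
    X, y, loci, comp = _feature_matrix(rundir, target)
    seed = int(config.get("seed", 0))
    rng = np.random.default_rng([seed, 7])
    X_imp = sel.rf_impute(X, y, missing=X < 0,
                          n_iter=int(scfg["impute_iter"]),
                          n_trees=int(scfg["impute_trees"]), rng=rng)
    np.save(rundir / "features_imputed.npy", X_imp)
    pd.DataFrame({"locus": loci}).to_csv(rundir / "feature_loci.tsv",
                                         sep="\t", index=False)
    table = sel.grrf_select(
        X_imp, y, loci, n_runs=int(scfg["n_runs"]),
        n_trees=int(scfg["n_trees"]), gamma=float(scfg["gamma"]),
        rng=np.random.default_rng([seed, 11]),
    )
    write_table(table, rundir / "importance.tsv")
    ranked = sel.rank_fst_select(comp)
    write_table(ranked, rundir / "ranked_fst.tsv")
    _log(rundir, "select", scfg)


def stage_assign(rundir: Path, config: dict) -> None:
    acfg = {**default_config()["assign"], **config.get("assign", {})}
    scfg = {**default_config()["select"], **config.get("select", {})}
    target = scfg["target"]
    imp = read_table(_need(rundir, "importance.tsv", "select"))
    ranked = read_table(_need(rundir, "ranked_fst.tsv", "select"))
    feats_path = _need(rundir, "features_imputed.npy", "select")
    X = np.load(feats_path)
    loci = read_table(rundir / "feature_loci.tsv")["locus"].to_numpy()
    pheno = read_table(_need(rundir, "phenotypes.tsv", "simulate"))
    y = pheno[target].to_numpy()
    seed = int(config.get("seed", 0))
    k_range = range(int(acfg["k_min"]), int(acfg["k_max"]) + 1)
    locus_col = {lid: j for j, lid in enumerate(loci)}

    selected = imp[imp["selected"]]
    n_sel = len(selected)
    results = {}
    for name, locus_list in (
        ("grrf", selected["locus"].tolist()),
        ("fst", (ranked["chrom"].astype(str) + "_" +
                 ranked["pos"].astype(str)).head(max(n_sel, 5)).tolist()),
    ):
        cols = [locus_col[l] for l in locus_list if l in locus_col]
        if len(cols) == 0:
            continue
        ev = asg.evaluate_panels(
            cols, X, y, step=int(acfg["step"]), k_range=k_range,
            seed=seed, model=acfg["model"],
        )
        write_table(ev.rates, rundir / f"assign_{name}.tsv")
        write_table(ev.curve, rundir / f"assign_{name}_curve.tsv")
        results[name] = {"best_size": ev.best_size, "best_rate": ev.best_rate}
    _log(rundir, "assign", {**acfg, **results})


def stage_report(rundir: Path, config: dict) -> None:
    from . import report

    report.make_report(rundir)
    _log(rundir, "report", {})


_STAGE_FN = {
    "simulate": stage_simulate,
    "callsnps": stage_callsnps,
    "pca": stage_pca,
    "scan": stage_scan,
    "fst": stage_fst,
    "select": stage_select,
    "assign": stage_assign,
    "report": stage_report,
}


def run_stage(stage: str, rundir, config: dict) -> None:
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    if stage not in _STAGE_FN:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    _STAGE_FN[stage](rundir, config)


def run_all(rundir, config: dict, stages=STAGES) -> None:
    for stage in stages:
        run_stage(stage, rundir, config)
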