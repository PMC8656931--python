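"""End-to-end orchestration: CCF inference -> patterns -> model -> report.

``run_pipeline`` executes the full analysis on a cohort with a single
config: per-mutation CCF inference, gene-level matrix assembly, univariable
screens and CCF-pattern classification, two-step model selection on the
training subset, recursive-partition stratification, application to the
validation subset, time-dependent ROC evaluation (genetic, pathological and
combined models) and the discordant-stratum genotype-enrichment contrast.
All intermediate tables are written as TSV and the summary as JSON; every
number in the report is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import fisher_exact

from . import __version__
from .ccf import (build_gene_ccf_matrix, clonality_preference_test,
                  count_subclones_cohort, estimate_ccfs)
from .exceptions import PipelineError, ValidationError
from .io import Cohort, read_cohort, write_gene_ccf_matrix
from .model import CCFRiskModel, RiskModel
from .patterns import bh_adjust, classify_all_patterns, univariable_screen
from .survival import (DEFAULT_SEED, assign_groups, compare_auc_z,
                       cox_fit, km_estimate, logrank_test,
                       reverse_km_median_followup, td_auc)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seed for one pipeline run."""

    variants: str | None = None
    segments: str | None = None
    purity: str | None = None
    clinical: str | None = None
    outdir: str = "ccfrisk_out"
    endpoint: str = "dfs"                 # dfs | os
    clonal_ccf: float = 0.9
    clonal_prob: float = 0.5
    frequency_threshold: float = 0.05
    alpha: float = 0.05
    horizon: float = 36.0
    min_leaf: int = 15
    n_perm: int = 2000
    n_boot: int = 200
    n_lambda: int = 50
    cv_folds: int = 10
    run_patterns: bool = True
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        for v in (self.clonal_ccf, self.clonal_prob, self.frequency_threshold,
                  self.alpha):
            if not 0 <= v <= 1:
                raise ValidationError(f"threshold {v} outside [0, 1]")
        if self.horizon <= 0:
            raise ValidationError("horizon must be positive")
        if self.endpoint not in ("dfs", "os"):
            raise ValidationError("endpoint must be 'dfs' or 'os'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage rounded to the printed precision (e.g. 55/56 -> 98.2)."""
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    return round(100.0 * numerator / denominator, ndigits)


def subclonal_carrier_rate(ccf_table: pd.DataFrame, n_samples: int | None = None,
                           ndigits: int = 1) -> float:
    """Percent of patients carrying at least one subclonal mutation."""
    carriers = ccf_table.loc[~ccf_table["is_clonal"], "sample_id"].nunique()
    total = n_samples or ccf_table["sample_id"].nunique()
    return percent(carriers, total, ndigits)


def discordant_enrichment(groups: pd.Series, clinical: pd.DataFrame,
                          status_matrix: pd.DataFrame,
                          pn_column: str = "pN", high_pn: str = "N2-3",
                          risk_label: str = "low") -> pd.DataFrame:
    """Genotype enrichment in stage/genetics-discordant patients.

    Cross-tabulates the genetic risk group against the nodal stratum; among
    ``high_pn`` patients, compares mutation status gene-by-gene between the
    discordant subset (classified ``risk_label``) and the remaining
    concordant patients with Fisher's exact test, BH-adjusted.
    """
    if pn_column not in clinical.columns:
        raise ValidationError(f"clinical table lacks a {pn_column!r} column")
    common = groups.index.intersection(clinical.index)
    pn = clinical.loc[common, pn_column]
    grp = groups.loc[common]
    in_stratum = pn == high_pn
    discordant = in_stratum & (grp == risk_label).to_numpy()
    concordant = in_stratum & ~(grp == risk_label).to_numpy()
    n_disc, n_conc = int(discordant.sum()), int(concordant.sum())
    if n_disc == 0:
        logger.warning("no discordant (%s & %s risk) patients", high_pn,
                       risk_label)
        return pd.DataFrame(columns=["gene", "mut_discordant", "n_discordant",
                                     "mut_concordant", "n_concordant",
                                     "odds_ratio", "p_value", "fdr"])
    rows = []
    for gene in status_matrix.columns:
        status = status_matrix.loc[common, gene].astype(bool)
        a = int((status & discordant).sum())
        b = n_disc - a
        c = int((status & concordant).sum())
        d = n_conc - c
        odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((gene, a, n_disc, c, n_conc, odds, p))
    out = pd.DataFrame(rows, columns=["gene", "mut_discordant", "n_discordant",
                                      "mut_concordant", "n_concordant",
                                      "odds_ratio", "p_value"])
    out["fdr"] = bh_adjust(out["p_value"])
    return out.sort_values("p_value").reset_index(drop=True)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


def _split_cohort(clinical: pd.DataFrame, seed: int):
    """Training/validation split: honor a cohort column, else seeded 70/30."""
    if "cohort" in clinical.columns and clinical["cohort"].notna().all():
        train = clinical["cohort"].astype(str) == "training"
        return train.to_numpy()
    rng = np.random.default_rng(seed)
    n = len(clinical)
    idx = rng.permutation(n)
    train = np.zeros(n, dtype=bool)
    train[idx[: int(round(0.7 * n))]] = True
    logger.info("no cohort labels: seeded 70/30 training/validation split")
    return train


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> dict:
    """Execute all stages; returns the report dict (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config),
                    "version": __version__, "seed": config.seed}

    if cohort is None:
        if not all([config.variants, config.segments, config.purity,
                    config.clinical]):
            raise PipelineError("ccf", "variants/segments/purity/clinical "
                                "paths are all required")
        cohort = _stage("ccf")(read_cohort)(config.variants, config.segments,
                                            config.purity, config.clinical)

    # stage: CCF inference
    ccf_table = _stage("ccf")(estimate_ccfs)(cohort)
    ccf_table.to_csv(outdir / "ccf_estimates.tsv", sep="\t", index=False)
    preference = _stage("ccf")(clonality_preference_test)(ccf_table)
    preference.to_csv(outdir / "clonality_preference.tsv", sep="\t", index=False)
    subclones = _stage("ccf")(count_subclones_cohort)(ccf_table, seed=config.seed)
    subclones.to_csv(outdir / "subclone_counts.tsv", sep="\t", index=False)

    matrix = _stage("matrix")(build_gene_ccf_matrix)(ccf_table, cohort)
    write_gene_ccf_matrix(matrix, outdir / "gene_ccf_matrix.tsv")
    status = matrix.binarized()

    clinical = cohort.clinical_frame()
    clinical = clinical.loc[matrix.samples]
    tcol, ecol = f"{config.endpoint}_time", f"{config.endpoint}_event"
    time = clinical[tcol].to_numpy(dtype=float)
    event = clinical[ecol].to_numpy(dtype=int)

    report["n_patients"] = len(clinical)
    report["n_mutations"] = int(len(ccf_table))
    report["subclonal_fraction"] = (float((~ccf_table["is_clonal"]).mean())
                                    if len(ccf_table) else float("nan"))
    report["subclonal_carrier_rate_pct"] = (
        subclonal_carrier_rate(ccf_table, n_samples=len(clinical))
        if len(ccf_table) else float("nan"))
    med, lo, hi = reverse_km_median_followup(time, event)
    report["median_followup_months"] = {"median": med, "ci": [lo, hi]}

    # stage: screens and CCF patterns
    screen = _stage("patterns")(univariable_screen)(
        status, time, event, endpoint=config.endpoint.upper(),
        frequency_threshold=config.frequency_threshold)
    screen.to_csv(outdir / f"screen_{config.endpoint}.tsv", sep="\t", index=False)
    report["n_screen_hits_fdr05"] = int((screen["fdr"] < 0.05).sum()) if len(screen) else 0
    if config.run_patterns:
        pattern_table = _stage("patterns")(classify_all_patterns)(
            matrix.frame, time, event, endpoint=config.endpoint.upper(),
            alpha=config.alpha, n_perm=config.n_perm, seed=config.seed)
        pattern_table.to_csv(outdir / f"patterns_{config.endpoint}.tsv",
                             sep="\t", index=False)
        if len(pattern_table):
            report["pattern_counts"] = (
                pattern_table["pattern"].value_counts().to_dict())

    # stage: model fit on training subset
    train = _split_cohort(clinical, config.seed)
    fitter = _stage("fit")(CCFRiskModel)(
        matrix.frame.iloc[np.flatnonzero(train)], time[train], event[train],
        min_frequency=config.frequency_threshold)
    results = _stage("fit")(fitter.fit)(seed=config.seed, k=config.cv_folds,
                                        n_lambda=config.n_lambda)
    report["selected_genes"] = results.genes
    report["coefficients"] = results.params.round(4).to_dict()
    if results.genes:
        ph_stat, ph_p = results.ph_test()
        report["ph_test_p"] = round(ph_p, 4)
    results.summary().to_csv(outdir / "model_summary.tsv", sep="\t")

    # stage: stratify training, apply to validation
    rm, strat_train = _stage("stratify")(results.partition)(
        min_leaf=config.min_leaf)
    rm.to_file(outdir / "risk_model.tsv")
    report["cutoffs"] = list(rm.cutoffs) if rm.cutoffs else []
    scores_all = rm.score(matrix.frame)
    groups_all = (rm.stratify(scores_all) if rm.cutoffs
                  else assign_groups(scores_all, strat_train.cutoffs))
    pd.DataFrame({"risk_score": scores_all, "risk_group": groups_all,
                  "training": train}).to_csv(outdir / "risk_scores.tsv", sep="\t")

    def _group_summary(mask, label):
        g = groups_all[mask]
        t, e = time[mask], event[mask]
        entry = {"n": int(mask.sum()), "groups": {}}
        if g.nunique() >= 2:
            stat, p, _ = logrank_test(g.astype(str).to_numpy(), t, e)
            entry["logrank_p"] = p
        for lab in g.cat.categories:
            sel = (g == lab).to_numpy()
            if sel.sum() == 0:
                continue
            km = km_estimate(t[sel], e[sel])
            lo_ci, hi_ci = km.ci_at(config.horizon)
            entry["groups"][str(lab)] = {
                "n": int(sel.sum()),
                f"dfs_rate_{int(config.horizon)}mo":
                    round(100 * km.survival_at(config.horizon), 1),
                "ci": [round(100 * lo_ci, 1), round(100 * hi_ci, 1)]}
        report[f"stratification_{label}"] = entry

    _stage("stratify")(_group_summary)(train, "training")
    if (~train).sum() >= 10:
        _stage("stratify")(_group_summary)(~train, "validation")

    # stage: evaluate — tdAUC of genetic, pathological and combined models
    def _evaluate():
        genetic = td_auc(scores_all.to_numpy(), time, event,
                         horizon=config.horizon, n_boot=config.n_boot,
                         seed=config.seed, label="genetic")
        report["td_auc_genetic"] = round(genetic.auc, 3)
        if {"pN", "pT"}.issubset(clinical.columns):
            path_X = pd.get_dummies(clinical[["pN", "pT"]], drop_first=True)
            path_X = path_X.loc[:, path_X.nunique() > 1].astype(float)
            if path_X.shape[1]:
                tr = np.flatnonzero(train)
                fit_p = cox_fit(path_X.iloc[tr], time[train], event[train])
                lp_path = (path_X[fit_p.params.index].to_numpy()
                           @ fit_p.params.to_numpy())
                comb_X = path_X.assign(risk_score=scores_all.to_numpy())
                fit_c = cox_fit(comb_X.iloc[tr], time[train], event[train])
                lp_comb = (comb_X[fit_c.params.index].to_numpy()
                           @ fit_c.params.to_numpy())
                pathological = td_auc(lp_path, time, event,
                                      horizon=config.horizon,
                                      n_boot=config.n_boot, seed=config.seed,
                                      label="pathological")
                combined = td_auc(lp_comb, time, event, horizon=config.horizon,
                                  n_boot=config.n_boot, seed=config.seed,
                                  label="combined")
                z, p = compare_auc_z(combined, pathological)
                report["td_auc_pathological"] = round(pathological.auc, 3)
                report["td_auc_combined"] = round(combined.auc, 3)
                report["auc_z_combined_vs_pathological"] = {
                    "z": round(z, 3), "p": round(p, 5)}
    _stage("evaluate")(_evaluate)()

    # stage: discordant-stratum genotype enrichment
    if "pN" in clinical.columns:
        enrich = _stage("enrichment")(discordant_enrichment)(
            groups_all, clinical, status)
        enrich.to_csv(outdir / "discordant_enrichment.tsv", sep="\t",
                      index=False)
        if len(enrich):
            top = enrich.iloc[0]
            report["discordant_top_gene"] = {
                "gene": top["gene"], "p": float(top["p_value"]),
                "fdr": float(top["fdr"])}

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    logger.info("pipeline complete; report at %s", outdir / "report.json")
    return report
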