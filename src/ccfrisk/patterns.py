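"""Screening alterations for survival association and CCF-effect patterns.

A mutated gene's prognostic effect can relate to the size of the mutant
clone in three ways:

* **independent** — mutation status alone carries the effect, regardless of
  the fraction of tumor cells mutated;
* **dominant** — the effect switches on once the CCF exceeds a threshold
  (found by maximally selected rank statistics with permutation inference);
* **dose_dependent** — the log-hazard scales with the CCF among carriers.

The classification cascade tests the most specific pattern first:
(a) continuous-CCF Cox among mutants -> dose_dependent; (b) maxstat
permutation p -> dominant with that cutoff; (c) status log-rank ->
independent; (d) none. The cascade's constituent tests are not multiplicity
corrected; the flat univariable screens are BH-adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exceptions import ConvergenceError, ValidationError
from .survival import (DEFAULT_SEED, MaxstatResult, cox_fit, logrank_test,
                       maxstat_cutoff)

logger = logging.getLogger(__name__)

FREQUENCY_THRESHOLD = 0.05


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def univariable_screen(status_matrix: pd.DataFrame, time, event,
                       endpoint: str = "DFS",
                       frequency_threshold: float = FREQUENCY_THRESHOLD
                       ) -> pd.DataFrame:
    """Univariable Cox screen of binary alterations (SNV status or CNA calls).

    Alterations below the frequency threshold are excluded before testing;
    Wald p-values are BH-adjusted across the tested set. Alterations with a
    separated (monotone-likelihood) or non-convergent fit are skipped with a
    warning.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    freq = status_matrix.mean(axis=0)
    tested = [c for c in status_matrix.columns
              if freq[c] >= frequency_threshold]
    rows, skipped = [], []
    for alt in tested:
        x = status_matrix[[alt]].astype(float)
        try:
            fit = cox_fit(x, time, event)
        except ConvergenceError:
            skipped.append(alt)
            continue
        if fit.separated or alt not in fit.params.index:
            skipped.append(alt)
            continue
        ci = fit.conf_int()
        rows.append((alt, float(freq[alt]), float(fit.hazard_ratios[alt]),
                     float(ci.loc[alt, "ci_low"]), float(ci.loc[alt, "ci_high"]),
                     float(fit.pvalues[alt])))
    if skipped:
        logger.warning("screen skipped %d alteration(s) with degenerate "
                       "fits: %s", len(skipped), skipped[:5])
    out = pd.DataFrame(rows, columns=["alteration", "frequency",
                                      "hazard_ratio", "ci_low", "ci_high",
                                      "p_value"])
    if len(out):
        out["fdr"] = bh_adjust(out["p_value"])
    else:
        out["fdr"] = []
    out["endpoint"] = endpoint
    return out.sort_values("p_value").reset_index(drop=True)


@dataclass
class PatternResult:
    """CCF-effect pattern call for one gene at one endpoint."""

    gene: str
    endpoint: str
    pattern: str                 # independent | dominant | dose_dependent | none
    cutoff: float | None
    status_logrank_p: float
    ccf_cox_p: float
    ccf_cox_coef: float
    maxstat_p: float
    maxstat_statistic: float
    n_mutants: int


def classify_pattern(gene: str, ccf_values: pd.Series, time, event,
                     endpoint: str = "DFS", alpha: float = 0.05,
                     n_perm: int = 2000, seed: int = DEFAULT_SEED
                     ) -> PatternResult:
    """Classify one gene's prognostic effect pattern with respect to CCF.

    ``ccf_values`` holds the per-sample gene CCF (0 = wildtype). The gene
    should be mutated in at least 5% of samples; the decision cascade is
    described in the module docstring and yields exactly one label.
    """
    ccf = np.asarray(ccf_values, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    mutant = ccf > 0
    n_mut = int(mutant.sum())
    if n_mut / len(ccf) < FREQUENCY_THRESHOLD:
        logger.warning("%s mutated in <5%% of samples; pattern set to none",
                       gene)

    # status log-rank (mutant vs wildtype)
    if 0 < n_mut < len(ccf):
        _, status_p, _ = logrank_test(mutant.astype(int), time, event)
    else:
        status_p = 1.0

    # continuous-CCF Cox among mutants
    ccf_p, ccf_coef = 1.0, 0.0
    if n_mut >= 3 and np.ptp(ccf[mutant]) > 0:
        try:
            fit = cox_fit(pd.DataFrame({"ccf": ccf[mutant]}),
                          time[mutant], event[mutant])
            if not fit.separated and "ccf" in fit.params.index:
                ccf_p = float(fit.pvalues["ccf"])
                ccf_coef = float(fit.params["ccf"])
        except ConvergenceError:
            pass

    # maxstat among mutants
    ms = (maxstat_cutoff(ccf[mutant], time[mutant], event[mutant],
                         n_perm=n_perm, seed=seed)
          if n_mut >= 10 else MaxstatResult(None, 0.0, 1.0, n_mut, flagged=True))

    if ccf_p < alpha:
        pattern, cutoff = "dose_dependent", None
    elif (not ms.flagged) and ms.p_value < alpha:
        pattern, cutoff = "dominant", ms.cutoff
    elif status_p < alpha:
        pattern, cutoff = "independent", None
    else:
        pattern, cutoff = "none", None
    return PatternResult(
        gene=gene, endpoint=endpoint, pattern=pattern, cutoff=cutoff,
        status_logrank_p=float(status_p), ccf_cox_p=ccf_p,
        ccf_cox_coef=ccf_coef, maxstat_p=float(ms.p_value),
        maxstat_statistic=float(ms.statistic), n_mutants=n_mut)


def classify_all_patterns(ccf_matrix: pd.DataFrame, time, event,
                          endpoint: str = "DFS", alpha: float = 0.05,
                          n_perm: int = 2000, seed: int = DEFAULT_SEED
                          ) -> pd.DataFrame:
    """Pattern classification for every gene above the frequency threshold."""
    freq = (ccf_matrix > 0).mean(axis=0)
    rows = []
    for gene in ccf_matrix.columns:
        if freq[gene] < FREQUENCY_THRESHOLD:
            continue
        res = classify_pattern(gene, ccf_matrix[gene], time, event,
                               endpoint=endpoint, alpha=alpha,
                               n_perm=n_perm, seed=seed)
        rows.append(res.__dict__)
    return pd.DataFrame(rows)
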