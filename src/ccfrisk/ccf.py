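"""Cancer-cell-fraction inference from targeted-sequencing read counts.

The CCF of a mutation is the fraction of tumor cells that carry it. Given a
variant with ``alt`` of ``depth`` reads, tumor purity ``rho``, locus total
copy number ``CN_t`` (normal diploid, ``CN_n = 2``) and mutation multiplicity
``m`` (mutant copies per mutated cell), the expected VAF at CCF ``c`` is

    v(c) = c * m * rho / (rho * CN_t + (1 - rho) * 2)

A discrete posterior over the grid c = 0.01, 0.02, ..., 1.00 with a uniform
prior and a Binomial(alt | depth, v(c)) likelihood yields the point estimate
(posterior mode), the clonality probability P(CCF > 0.9), and the clonal call
(P > 0.5). This module also counts per-sample subclones (Gaussian mixture on
logit CCF, BIC-selected), tests per-gene clonal/subclonal preference against
the cohort-wide subclonal fraction with an exact binomial test, and assembles
the gene-level CCF matrix consumed by the survival models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import binomtest
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .io import Cohort, GeneCCFMatrix, SegmentIndex, VariantCall

logger = logging.getLogger(__name__)

CCF_GRID = np.round(np.arange(1, 101) / 100.0, 2)
CLONAL_CCF = 0.9          # CCF boundary between clonal and subclonal
CLONAL_PROB_THRESHOLD = 0.5   # call clonal when P(CCF > 0.9) exceeds this


@dataclass
class CCFEstimate:
    """Posterior over CCF for a single mutation."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    multiplicity: int
    ccf_grid: np.ndarray
    posterior: np.ndarray
    ccf_point: float
    p_clonal: float
    is_clonal: bool


@dataclass
class SubcloneModel:
    """Mixture decomposition of one sample's mutation CCFs into clones."""

    sample_id: str
    cluster_centers: np.ndarray   # CCF scale, in (0, 1]
    cluster_weights: np.ndarray
    assignments: np.ndarray       # per-mutation cluster index
    n_subclones: int              # clusters with center < CLONAL_CCF
    flagged: bool = False         # too few mutations for mixture fitting


def locus_copy_number(variant: VariantCall, index: SegmentIndex) -> tuple[float, bool]:
    """Total copy number of the segment covering the variant locus.

    Returns ``(total_cn, fallback)``; when no segment covers the locus the
    diploid fallback (2.0) is returned with ``fallback=True``.
    """
    seg = index.lookup(variant.sample_id, variant.chrom, variant.pos)
    if seg is None:
        return 2.0, True
    return float(seg.total_cn), False


def estimate_multiplicity(vaf: float, purity: float, total_cn: float) -> int:
    """Point estimate of mutation multiplicity, m = max(1, round(vaf*D/rho)).

    D = rho*CN_t + (1-rho)*2 is the average locus copy number in the
    specimen. The estimate is clamped to [1, max(1, round(CN_t))]: a mutation
    cannot occupy more copies than the locus carries.
    """
    if purity <= 0:
        raise ValidationError(f"purity must be positive, got {purity}")
    denom = purity * total_cn + (1.0 - purity) * 2.0
    m = int(round(vaf * denom / purity))
    upper = max(1, int(round(total_cn)))
    return int(min(max(1, m), upper))


def _posterior_stats(alt, depth, purity, total_cn, m):
    """Vectorized grid posterior; returns (posterior, ccf_point, p_clonal, m_used).

    All inputs are broadcastable 1-D arrays of equal length n; the posterior
    is an (n, 100) matrix with rows summing to 1.
    """
    alt = np.atleast_1d(np.asarray(alt, dtype=float))
    depth = np.atleast_1d(np.asarray(depth, dtype=float))
    purity = np.atleast_1d(np.asarray(purity, dtype=float))
    total_cn = np.atleast_1d(np.asarray(total_cn, dtype=float))
    m = np.atleast_1d(np.asarray(m, dtype=float))

    denom = purity * total_cn + (1.0 - purity) * 2.0
    # reduce m where even CCF=1 would imply VAF > 1 (inconsistent multiplicity)
    vmax = m * purity / denom
    bad = vmax > 1.0
    if np.any(bad):
        m = m.copy()
        m[bad] = np.maximum(1.0, np.floor(denom[bad] / purity[bad]))
        logger.warning("reduced multiplicity for %d variants with expected "
                       "VAF > 1 at CCF 1", int(bad.sum()))
    v = CCF_GRID[None, :] * (m * purity / denom)[:, None]
    v = np.clip(v, 1e-6, 1.0 - 1e-6)
    loglik = alt[:, None] * np.log(v) + (depth - alt)[:, None] * np.log1p(-v)
    loglik -= loglik.max(axis=1, keepdims=True)
    post = np.exp(loglik)
    post /= post.sum(axis=1, keepdims=True)
    ccf_point = CCF_GRID[np.argmax(post, axis=1)]
    p_clonal = post[:, CCF_GRID > CLONAL_CCF].sum(axis=1)
    return post, ccf_point, p_clonal, m.astype(int)


def ccf_posterior(alt: int, depth: int, purity: float, total_cn: float,
                  m: int, sample_id: str = "", gene: str = "",
                  chrom: str = "", pos: int = 0) -> CCFEstimate:
    """Grid posterior over CCF for a single mutation (uniform prior)."""
    if not 0 <= alt <= depth:
        raise ValidationError(f"alt={alt} outside [0, depth={depth}]")
    if m < 1:
        raise ValidationError("multiplicity must be >= 1")
    post, point, p_clonal, m_used = _posterior_stats(alt, depth, purity, total_cn, m)
    p = float(p_clonal[0])
    return CCFEstimate(
        sample_id=sample_id, gene=gene, chrom=chrom, pos=pos,
        multiplicity=int(m_used[0]), ccf_grid=CCF_GRID.copy(),
        posterior=post[0], ccf_point=float(point[0]), p_clonal=p,
        is_clonal=p > CLONAL_PROB_THRESHOLD)


def estimate_ccfs(cohort: Cohort) -> pd.DataFrame:
    """Per-mutation CCF estimates for a whole cohort.

    Returns a DataFrame with one row per variant: read counts, purity, locus
    copy number (with diploid-fallback flag), estimated multiplicity,
    ``ccf_point``, ``p_clonal`` and the clonal call.
    """
    variants = cohort.variants_frame()
    if variants.empty:
        return variants.assign(purity=[], total_cn=[], cn_fallback=[],
                               multiplicity=[], ccf_point=[], p_clonal=[],
                               is_clonal=[])
    purity_map = cohort.purity_map()
    index = SegmentIndex(cohort.segments)

    cn = np.empty(len(cohort.variants))
    fallback = np.zeros(len(cohort.variants), dtype=bool)
    for i, v in enumerate(cohort.variants):
        cn[i], fallback[i] = locus_copy_number(v, index)
    if fallback.any():
        logger.warning("%d variants had no covering segment; diploid fallback "
                       "used", int(fallback.sum()))
    purity = variants["sample_id"].map(purity_map).to_numpy(dtype=float)
    vaf = variants["vaf"].to_numpy(dtype=float)
    m = np.array([estimate_multiplicity(vaf[i], purity[i], cn[i])
                  for i in range(len(vaf))])
    _, point, p_clonal, m_used = _posterior_stats(
        variants["alt_reads"].to_numpy(), variants["total_depth"].to_numpy(),
        purity, cn, m)
    out = variants.copy()
    out["purity"] = purity
    out["total_cn"] = cn
    out["cn_fallback"] = fallback
    out["multiplicity"] = m_used
    out["ccf_point"] = point
    out["p_clonal"] = p_clonal
    out["is_clonal"] = p_clonal > CLONAL_PROB_THRESHOLD
    return out


def count_subclones(ccf_points: np.ndarray, sample_id: str = "",
                    max_clusters: int = 6, seed: int = 0) -> SubcloneModel:
    """Count subclones by a BIC-selected 1-D Gaussian mixture on logit(CCF).

    Clusters whose back-transformed center lies below the clonal boundary
    (0.9) count as subclones. Samples with fewer than 5 mutations return a
    flagged single-cluster model.
    """
    ccf_points = np.asarray(ccf_points, dtype=float)
    if len(ccf_points) < 5:
        center = float(np.clip(np.mean(ccf_points), 0.01, 1.0)) if len(ccf_points) else 1.0
        return SubcloneModel(
            sample_id=sample_id, cluster_centers=np.array([center]),
            cluster_weights=np.array([1.0]),
            assignments=np.zeros(len(ccf_points), dtype=int),
            n_subclones=int(center < CLONAL_CCF), flagged=True)
    z = logit(np.clip(ccf_points, 0.01, 0.99))[:, None]
    best, best_bic = None, np.inf
    kmax = min(max_clusters, len(np.unique(z)))
    for k in range(1, kmax + 1):
        # variance floor: grid-discretized CCFs carry point masses (e.g. the
        # clonal peak at exactly 1.0) that must not split into pseudo-clones
        gm = GaussianMixture(n_components=k, covariance_type="diag",
                             n_init=3, random_state=seed, reg_covar=0.05)
        gm.fit(z)
        bic = gm.bic(z)
        if bic < best_bic - 1e-9:
            best, best_bic = gm, bic
    centers = expit(best.means_.ravel())
    order = np.argsort(centers)[::-1]   # descending CCF: major clone first
    centers = centers[order]
    weights = best.weights_.ravel()[order]
    relabel = np.empty_like(order)
    relabel[order] = np.arange(len(order))
    assignments = relabel[best.predict(z)]
    # merge clusters closer than the minimum resolvable CCF separation:
    # the logit scale stretches near 1 and can split one clone in two
    min_sep = 0.1
    merged_to = np.arange(len(centers))
    for i in range(1, len(centers)):
        if centers[merged_to[i - 1]] - centers[i] < min_sep:
            merged_to[i] = merged_to[i - 1]
    if len(np.unique(merged_to)) < len(centers):
        new_ids = {old: new for new, old in enumerate(np.unique(merged_to))}
        groups = np.array([new_ids[m] for m in merged_to])
        k_new = len(new_ids)
        new_centers = np.empty(k_new)
        new_weights = np.empty(k_new)
        for g in range(k_new):
            sel = groups == g
            new_weights[g] = weights[sel].sum()
            new_centers[g] = np.average(centers[sel], weights=weights[sel])
        assignments = groups[assignments]
        centers, weights = new_centers, new_weights
    centers = np.clip(centers, 1e-6, 1.0)
    return SubcloneModel(
        sample_id=sample_id, cluster_centers=centers, cluster_weights=weights,
        assignments=assignments,
        n_subclones=int(np.sum(centers < CLONAL_CCF)), flagged=False)


def count_subclones_cohort(ccf_table: pd.DataFrame, max_clusters: int = 6,
                           seed: int = 0) -> pd.DataFrame:
    """Per-sample subclone counts for a cohort CCF table."""
    rows = []
    for sid, grp in ccf_table.groupby("sample_id"):
        model = count_subclones(grp["ccf_point"].to_numpy(), sample_id=sid,
                                max_clusters=max_clusters, seed=seed)
        rows.append((sid, len(model.cluster_centers), model.n_subclones,
                     model.flagged))
    return pd.DataFrame(rows, columns=["sample_id", "n_clusters",
                                       "n_subclones", "flagged"])


def clonality_preference_test(ccf_table: pd.DataFrame) -> pd.DataFrame:
    """Test each gene for clonal/subclonal mutation preference.

    Null: a gene's subclonal-mutation count is Binomial(n_mutations, f) with
    f the cohort-wide subclonal fraction. Two-sided exact binomial p-values,
    Benjamini-Hochberg adjusted across genes. Genes with zero mutations are
    excluded by construction.
    """
    subclonal = ~ccf_table["is_clonal"].to_numpy(dtype=bool)
    n_total = len(ccf_table)
    if n_total == 0:
        return pd.DataFrame(columns=["gene", "n_mutations", "n_subclonal",
                                     "subclonal_fraction", "p_value", "fdr"])
    global_fraction = subclonal.sum() / n_total
    rows = []
    for gene, grp in ccf_table.assign(subclonal=subclonal).groupby("gene"):
        n = len(grp)
        k = int(grp["subclonal"].sum())
        p = binomtest(k, n, global_fraction, alternative="two-sided").pvalue
        rows.append((gene, n, k, k / n, p))
    out = pd.DataFrame(rows, columns=["gene", "n_mutations", "n_subclonal",
                                      "subclonal_fraction", "p_value"])
    out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values("p_value").reset_index(drop=True)


def build_gene_ccf_matrix(ccf_table: pd.DataFrame, cohort: Cohort,
                          genes: list[str] | None = None) -> GeneCCFMatrix:
    """Assemble the samples x genes CCF matrix (max CCF per gene, 0 = wildtype).

    ``genes`` fixes the panel columns; by default the union of mutated genes
    is used. CCFs are capped at 1 before assembly.
    """
    samples = cohort.sample_ids()
    if genes is None:
        genes = sorted(ccf_table["gene"].unique()) if len(ccf_table) else []
    if len(ccf_table):
        pivot = (ccf_table.assign(ccf=ccf_table["ccf_point"].clip(upper=1.0))
                 .pivot_table(index="sample_id", columns="gene", values="ccf",
                              aggfunc="max"))
    else:
        pivot = pd.DataFrame(index=pd.Index([], name="sample_id"))
    frame = pivot.reindex(index=samples, columns=genes).fillna(0.0)
    frame.index.name = "sample_id"
    return GeneCCFMatrix(frame)


def binarize_matrix(matrix: GeneCCFMatrix) -> pd.DataFrame:
    """Binary mutation-status matrix from a CCF matrix (entry>0 -> 1)."""
    return matrix.binarized()


def estimate_purity_heuristic(ccf_or_variants: pd.DataFrame) -> pd.Series:
    """Crude per-sample purity guess: 2 x top-decile VAF on diploid loci.

    A fallback for cohorts lacking a purity column; heuristic only — assumes
    the highest-VAF mutations are clonal heterozygous on diploid segments.
    """
    frame = ccf_or_variants
    if "total_cn" in frame.columns:
        frame = frame[np.isclose(frame["total_cn"], 2.0)]
    est = frame.groupby("sample_id")["vaf"].quantile(0.9) * 2.0
    return est.clip(upper=1.0).rename("purity_estimate")
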