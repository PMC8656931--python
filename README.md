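# ccfrisk

Cancer-cell-fraction based recurrence risk modelling for targeted tumor
sequencing cohorts.

## The problem

Esophageal squamous cell carcinoma (ESCC) patients undergoing surgery alone
have highly variable outcomes that pathological TNM staging predicts only
coarsely. Tumors are mixtures of clones: a mutation may be carried by
essentially all tumor cells (clonal) or by a minor subpopulation
(subclonal). Treating mutations as binary mutant/wildtype discards this
structure. The **cancer cell fraction** (CCF) — the fraction of tumor cells
carrying a mutation, corrected for tumor purity and local copy number — is
a continuous measure of clone size, and it turns out to carry prognostic
information that mutation status alone does not.

`ccfrisk` implements a complete CCF-centred recurrence-prediction analysis
for targeted deep-sequencing cohorts (~550-gene panels at ~1000x):

1. **CCF inference** — for a variant with `alt`/`depth` reads, purity ρ,
   locus total copy number `CN_t` and multiplicity `m`, the expected VAF at
   CCF `c` is `v(c) = c·m·ρ / (ρ·CN_t + (1−ρ)·2)`. A discrete posterior on
   a 100-point CCF grid (uniform prior, binomial likelihood) yields a point
   estimate, `P(CCF > 0.9)`, and a clonal call when that probability
   exceeds 0.5. Per-sample subclone counts come from a BIC-selected
   Gaussian mixture on logit CCFs; per-gene clonal/subclonal preference is
   tested with an exact binomial test against the cohort-wide subclonal
   fraction (BH-adjusted).
2. **CCF-effect patterns** — each frequently mutated gene is classified as
   CCF-**independent** (status log-rank), CCF-**dominant** (a threshold
   found by maximally selected rank statistics with permutation inference),
   or CCF **dose-dependent** (continuous-CCF Cox among carriers).
3. **Risk model** — a gene-level CCF matrix (max CCF per gene, 0 =
   wildtype) feeds a two-step selection: SCAD-penalized Cox regression with
   10-fold cross-validation, then backward–forward stepwise Cox minimizing
   BIC (= −2·logPL + q·log(#events)). The fitted model is a plain linear
   risk score `Σ βg · CCFg`. Recursive partitioning of the score by
   log-rank statistic defines low / intermediate / high risk groups, and
   IPCW time-dependent ROC at 36 months evaluates discrimination, with a
   paired-bootstrap Z-test for AUC comparisons.
4. **Synthetic cohorts** — a fully specified simulator (clonal structure,
   binomial read sampling, proportional-hazards survival with planted
   coefficients, independent censoring) provides ground truth for every
   stage.

The package ships the published eight-gene ESCC model

```
risk score = 1.18·CCF_GPR98 + 1.31·CCF_LAMA1 + 1.42·CCF_IFT140
           + 1.18·CCF_MUC17 + 1.78·CCF_PTPRB − 1.37·CCF_AHNAK2
           − 2.78·CCF_PREX2 − 3.02·CCF_SPATA31D1
```

with risk-group cutoffs −0.0565 and 0.168.

## Worked example

```python
>>> import ccfrisk
>>> rm = ccfrisk.published_model()
>>> rm.score({"GPR98": 1.0})            # clonal GPR98 mutation only
1.18
>>> rm.score({"GPR98": 0.5, "PREX2": 1.0})
-2.19
>>> rm.stratify(__import__("pandas").Series([-1.0, 0.0, 1.0])).tolist()
['low', 'intermediate', 'high']
```

End-to-end on a simulated cohort:

```python
import ccfrisk

cohort, truth = ccfrisk.simulate_cohort(ccfrisk.preset_paper_like(seed=11))
table = ccfrisk.estimate_ccfs(cohort)                    # per-mutation CCFs
matrix = ccfrisk.build_gene_ccf_matrix(table, cohort)    # samples x genes
clin = cohort.clinical_frame().loc[matrix.samples]
model = ccfrisk.CCFRiskModel(matrix, clin["dfs_time"], clin["dfs_event"])
results = model.fit(seed=11)
print(results.summary())
risk_model, strat = results.partition()
print(risk_model.cutoffs, strat.group_sizes().to_dict())
```

On this cohort the two-step selection recovers planted genes such as
`IFT140`, `PREX2` and `SPATA31D1` with the correct coefficient signs, and
the three risk groups separate cleanly (36-month disease-free survival
roughly 74% / 9% / 0% from low to high risk; group log-rank p < 1e-16).

The same analysis runs from the shell:

```bash
ccfrisk simulate --preset paper --seed 11 --out cohort/
ccfrisk ccf --variants cohort/variants.tsv --segments cohort/segments.tsv \
        --purity cohort/purity.tsv --clinical cohort/clinical.tsv --out out/
ccfrisk fit --matrix out/gene_ccf_matrix.tsv --clinical cohort/clinical.tsv \
        --out model.tsv
ccfrisk predict --model published --matrix out/gene_ccf_matrix.tsv
```

## Layout

- `ccfrisk.io` — MAF/SEG/clinical TSV (and VCF) readers, cohort assembly,
  gene-CCF matrix I/O
- `ccfrisk.ccf` — CCF posteriors, clonality, subclone counting, preference
  tests, matrix assembly
- `ccfrisk.patterns` — univariable screens, maximally selected rank
  statistics, CCF-pattern classification
- `ccfrisk.survival` — Cox partial likelihood (Efron), SCAD/CV/stepwise,
  KM/log-rank, recursive partitioning, time-dependent ROC, PH diagnostics
- `ccfrisk.model` — `RiskModel` (deployable score) and
  `CCFRiskModel`/`CCFRiskResults` (statsmodels-style fit interface)
- `ccfrisk.simulate` — synthetic cohort generator with ground truth
- `ccfrisk.pipeline` — end-to-end orchestration and report
- `ccfrisk.cli` — `ccfrisk` command-line interface

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
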