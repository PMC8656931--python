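"""The CCF-based recurrence risk model (statsmodels-style model/results).

``RiskModel`` is the deployable artifact: an ordered gene list, Cox
coefficients, and two score cutoffs defining low / intermediate / high risk
groups. The risk score of a patient is the plain inner product of the
coefficients with the patient's per-gene CCFs (wildtype = 0, no intercept).
The published eight-gene model ships with the package and can be loaded
with :func:`published_model`.

``CCFRiskModel`` builds a new model from data: a gene-level CCF matrix plus
survival outcomes. ``fit()`` runs the two-step selection (SCAD-penalized Cox
with 10-fold cross-validation, then stepwise Cox minimizing BIC) and returns
a :class:`CCFRiskResults` carrying the refitted coefficients, their standard
errors, diagnostics and a ``summary()`` table; stratification, scoring and
time-dependent ROC evaluation hang off the results object.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import GeneCCFMatrix
from .survival import (DEFAULT_SEED, SCAD_A, CoxFit, ScadPath,
                       StratifiedCohort, TdRocResult, assign_groups,
                       partition_risk, ph_test, stability_selection, td_auc,
                       two_step_select)


@dataclass
class RiskModel:
    """A linear CCF risk score with optional three-group cutoffs."""

    genes: list[str]
    coefficients: np.ndarray
    cutoffs: tuple[float, float] | None = None

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.genes) != len(self.coefficients):
            raise ValidationError("genes and coefficients must align")
        if self.cutoffs is not None:
            lo, hi = self.cutoffs
            if not lo < hi:
                raise ValidationError("cutoffs must be strictly ascending")

    def score(self, ccf):
        """Risk score(s): inner product of coefficients with gene CCFs.

        ``ccf`` may be a mapping/Series (one patient) or a DataFrame
        (samples x genes). Genes absent from the input count as CCF 0.
        """
        if isinstance(ccf, GeneCCFMatrix):
            ccf = ccf.frame
        if isinstance(ccf, pd.DataFrame):
            cols = ccf.reindex(columns=self.genes, fill_value=0.0)
            return pd.Series(cols.to_numpy(dtype=float) @ self.coefficients,
                             index=ccf.index, name="risk_score")
        if isinstance(ccf, pd.Series):
            ccf = ccf.to_dict()
        vec = np.array([float(ccf.get(g, 0.0)) for g in self.genes])
        return float(vec @ self.coefficients)

    def stratify(self, scores) -> pd.Series:
        """Assign low/intermediate/high labels using the model cutoffs."""
        if self.cutoffs is None:
            raise ValidationError("model has no cutoffs; run partitioning first")
        return assign_groups(pd.Series(scores), list(self.cutoffs))

    # -- small text format: gene/coefficient rows + a cutoffs comment -------
    def to_file(self, path) -> None:
        lines = ["# CCF risk model"]
        if self.cutoffs is not None:
            lines.append(f"# cutoffs\t{self.cutoffs[0]:g}\t{self.cutoffs[1]:g}")
        lines.append("gene\tcoefficient")
        for g, c in zip(self.genes, self.coefficients):
            lines.append(f"{g}\t{c:g}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RiskModel":
        cutoffs = None
        genes, coefs = [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    parts = line.lstrip("# ").split("\t")
                    if parts[0] == "cutoffs" and len(parts) == 3:
                        cutoffs = (float(parts[1]), float(parts[2]))
                    continue
                g, c = line.split("\t")[:2]
                if g == "gene":
                    continue
                genes.append(g)
                coefs.append(float(c))
        if not genes:
            raise ValidationError(f"{path}: no gene/coefficient rows")
        return cls(genes=genes, coefficients=np.array(coefs), cutoffs=cutoffs)


def published_model() -> RiskModel:
    """The packaged eight-gene CCF recurrence model with its two cutoffs."""
    ref = resources.files("ccfrisk.data") / "published_model.tsv"
    with resources.as_file(ref) as path:
        return RiskModel.from_file(path)


def risk_score(model: RiskModel, ccf):
    """Functional alias for :meth:`RiskModel.score`."""
    return model.score(ccf)


class CCFRiskModel:
    """Two-step CCF-based recurrence model builder.

    Parameters
    ----------
    gene_ccf
        Samples x genes CCF matrix (``GeneCCFMatrix`` or DataFrame).
    time, event
        Survival endpoint (months, 0/1) aligned with the matrix rows.
    min_frequency
        Genes mutated in fewer than this fraction of samples are excluded
        from selection (default 5%).
    """

    def __init__(self, gene_ccf, time, event, min_frequency: float = 0.05):
        frame = gene_ccf.frame if isinstance(gene_ccf, GeneCCFMatrix) else gene_ccf
        self.X = frame.astype(float)
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        if len(self.time) != len(self.X):
            raise ValidationError("matrix rows and survival arrays must align")
        freq = (self.X > 0).mean(axis=0)
        self.eligible = list(self.X.columns[freq >= min_frequency])
        self.min_frequency = min_frequency

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, time_col: str,
                       event_col: str, **kwargs) -> "CCFRiskModel":
        genes = [c for c in frame.columns if c not in (time_col, event_col)]
        return cls(frame[genes], frame[time_col], frame[event_col], **kwargs)

    def fit(self, seed: int = DEFAULT_SEED, k: int = 10, n_lambda: int = 50,
            a: float = SCAD_A, lla_iters: int = 3) -> "CCFRiskResults":
        """Run CV-SCAD selection + stepwise BIC and refit the final Cox model."""
        if not self.eligible:
            raise ValidationError("no genes pass the frequency threshold")
        res = two_step_select(self.X[self.eligible], self.time, self.event,
                              seed=seed, k=k, n_lambda=n_lambda, a=a,
                              lla_iters=lla_iters)
        return CCFRiskResults(model=self, path=res["path"],
                              scad_genes=res["scad_genes"],
                              genes=res["genes"], fit=res["fit"],
                              bic=res["bic"], seed=seed)

    def stability(self, n_subsamples: int = 100, subsample_frac: float = 0.7,
                  seed: int = DEFAULT_SEED, **select_kwargs) -> pd.Series:
        """Gene selection frequencies over subsampled two-step selections."""
        return stability_selection(self.X[self.eligible], self.time,
                                   self.event, n_subsamples=n_subsamples,
                                   subsample_frac=subsample_frac, seed=seed,
                                   **select_kwargs)


@dataclass
class CCFRiskResults:
    """Fitted two-step selection: coefficients, diagnostics, deployment."""

    model: CCFRiskModel
    path: ScadPath
    scad_genes: list[str]
    genes: list[str]
    fit: CoxFit | None
    bic: float
    seed: int
    _risk_model: RiskModel | None = field(default=None, repr=False)

    @property
    def params(self) -> pd.Series:
        return self.fit.params if self.fit is not None else pd.Series(dtype=float)

    @property
    def bse(self) -> pd.Series:
        return self.fit.bse if self.fit is not None else pd.Series(dtype=float)

    def summary(self) -> pd.DataFrame:
        if self.fit is None:
            return pd.DataFrame()
        return self.fit.summary()

    def as_risk_model(self) -> RiskModel:
        if self._risk_model is None:
            self._risk_model = RiskModel(genes=list(self.params.index),
                                         coefficients=self.params.to_numpy())
        return self._risk_model

    def risk_scores(self, gene_ccf=None) -> pd.Series:
        """Scores for the training matrix or new samples."""
        X = self.model.X if gene_ccf is None else gene_ccf
        return self.as_risk_model().score(X)

    def partition(self, max_groups: int = 3, min_leaf: int = 15
                  ) -> tuple[RiskModel, StratifiedCohort]:
        """Recursive-partition the training scores into risk groups.

        Returns the deployable :class:`RiskModel` (with cutoffs installed)
        and the stratified training cohort.
        """
        scores = self.risk_scores()
        cutoffs, strat = partition_risk(scores, self.model.time,
                                        self.model.event,
                                        max_groups=max_groups,
                                        min_leaf=min_leaf)
        rm = self.as_risk_model()
        if len(cutoffs) == 2:
            rm = RiskModel(genes=rm.genes, coefficients=rm.coefficients,
                           cutoffs=(cutoffs[0], cutoffs[1]))
            self._risk_model = rm
        return rm, strat

    def td_auc(self, horizon: float = 36.0, gene_ccf=None, time=None,
               event=None, n_boot: int = 200, seed: int | None = None
               ) -> TdRocResult:
        scores = self.risk_scores(gene_ccf)
        t = self.model.time if time is None else np.asarray(time, float)
        e = self.model.event if event is None else np.asarray(event, int)
        return td_auc(scores.to_numpy(), t, e, horizon=horizon,
                      n_boot=n_boot, seed=self.seed if seed is None else seed,
                      label="ccf_risk_model")

    def ph_test(self):
        """Proportional-hazards diagnostic for the final fit."""
        if self.fit is None or not self.genes:
            raise ValidationError("no fitted covariates to test")
        return ph_test(self.fit, self.model.X[self.genes],
                       self.model.time, self.model.event)
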