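"""Genomic risk score (GRS) computation from z-scored expression.

Three scorer archetypes cover the published signature families:

* ``linear`` — a weighted sum of gene expression plus an offset, the shape of
  the Oncotype DX recurrence score and the EndoPredict molecular score;
* ``centroid`` — per-patient correlation against intrinsic-subtype reference
  profiles combined with class weights (risk-of-recurrence, ROR), optionally
  plus clinical terms (the "-C" variants such as ROR-C or an EPClin-like
  combination);
* ``template`` — correlation against a single good-prognosis template
  profile, the MammaPrint shape.

Published commercial coefficient sets are deliberately not hard-coded: each
signature is a declarative definition (an editable config file), and the
archetypes are the tested surface. A two-component Gaussian mixture supplies
surrogate binary status (e.g. KI67 from MKI67 expression).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata

from .cohort import ExpressionMatrix

logger = logging.getLogger(__name__)

ARCHETYPES = {"linear", "centroid", "template"}


class CoverageError(ValueError):
    """No signature gene is present in the expression matrix."""


@dataclass
class SignatureDefinition:
    """Declarative description of one genomic risk score.

    Exactly the fields of the declared archetype may be populated:
    ``gene_weights`` for linear, ``centroid_matrix``/``class_weights`` for
    centroid, ``template_vector`` for template. ``clinical_terms`` maps a
    clinical variable name (age, size_mm, nodes, grade) to a coefficient for
    clinically combined variants.
    """

    name: str
    archetype: str
    gene_weights: Optional[dict[str, float]] = None
    centroid_matrix: Optional[pd.DataFrame] = None      # genes x classes
    class_weights: Optional[dict[str, float]] = None
    template_vector: Optional[dict[str, float]] = None
    offset: float = 0.0
    scale_bounds: Optional[tuple[float, float]] = None
    clinical_terms: Optional[dict[str, float]] = None
    correlation: Optional[str] = None   # default: spearman (centroid), pearson (template)
    risk_threshold: Optional[float] = None  # template: higher correlation = good prognosis

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        required = {
            "linear": ["gene_weights"],
            "centroid": ["centroid_matrix", "class_weights"],
            "template": ["template_vector"],
        }[self.archetype]
        forbidden = {"gene_weights", "centroid_matrix", "class_weights",
                     "template_vector"} - set(required)
        for f_ in required:
            if getattr(self, f_) is None:
                raise ValueError(f"{self.name}: archetype {self.archetype} requires {f_}")
        for f_ in forbidden:
            if getattr(self, f_) is not None:
                raise ValueError(f"{self.name}: {f_} not allowed for archetype {self.archetype}")
        for genes in (self.gene_weights, self.template_vector):
            if genes is not None and len(genes) == 0:
                raise ValueError(f"{self.name}: empty gene list")
        if self.centroid_matrix is not None:
            if self.centroid_matrix.index.duplicated().any():
                raise ValueError(f"{self.name}: duplicate genes in centroid matrix")
            if len(self.centroid_matrix) == 0:
                raise ValueError(f"{self.name}: empty centroid matrix")
        if self.correlation is None:
            self.correlation = {"centroid": "spearman", "template": "pearson",
                                "linear": None}[self.archetype]

    @property
    def genes(self) -> list[str]:
        if self.archetype == "linear":
            return list(self.gene_weights)
        if self.archetype == "centroid":
            return list(self.centroid_matrix.index)
        return list(self.template_vector)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SignatureDefinition":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "centroid_matrix" in raw and raw["centroid_matrix"] is not None:
            raw["centroid_matrix"] = pd.DataFrame(raw["centroid_matrix"]).astype(float)
        if "scale_bounds" in raw and raw["scale_bounds"] is not None:
            raw["scale_bounds"] = tuple(raw["scale_bounds"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "name": self.name, "archetype": self.archetype, "offset": self.offset,
        }
        if self.gene_weights is not None:
            raw["gene_weights"] = {k: float(v) for k, v in self.gene_weights.items()}
        if self.centroid_matrix is not None:
            raw["centroid_matrix"] = {
                c: {g: float(v) for g, v in self.centroid_matrix[c].items()}
                for c in self.centroid_matrix.columns}
            raw["class_weights"] = {k: float(v) for k, v in self.class_weights.items()}
        if self.template_vector is not None:
            raw["template_vector"] = {k: float(v) for k, v in self.template_vector.items()}
        if self.scale_bounds is not None:
            raw["scale_bounds"] = list(self.scale_bounds)
        if self.clinical_terms is not None:
            raw["clinical_terms"] = {k: float(v) for k, v in self.clinical_terms.items()}
        if self.correlation is not None:
            raw["correlation"] = self.correlation
        if self.risk_threshold is not None:
            raw["risk_threshold"] = float(self.risk_threshold)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class GrsResult:
    """Continuous scores (and optional risk groups) for one signature."""

    signature_name: str
    scores: pd.Series                       # patient_id -> score
    risk_group: Optional[pd.Series] = None
    coverage: float = 1.0                   # fraction of signature genes present
    missing_genes: list[str] = field(default_factory=list)
    undefined: list[str] = field(default_factory=list)  # patients with undefined correlation

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"patient_id": self.scores.index,
                           "signature": self.signature_name,
                           "score": self.scores.values})
        df["risk_group"] = (self.risk_group.reindex(self.scores.index).values
                            if self.risk_group is not None else "")
        df["coverage"] = self.coverage
        return df


def _clinical_contribution(terms: dict[str, float], clinical: pd.DataFrame) -> pd.Series:
    contrib = pd.Series(0.0, index=clinical["patient_id"])
    for var, coef in terms.items():
        vals = pd.to_numeric(clinical[var], errors="coerce").fillna(0.0).to_numpy(float)
        contrib += coef * vals
    return contrib


def score_linear(expression: ExpressionMatrix, definition: SignatureDefinition) -> GrsResult:
    """Weighted sum over signature genes plus offset, clipped to scale bounds.

    Missing genes contribute zero — on z-scored data this imputes the cohort
    mean — and are logged; the coverage fraction is reported.
    """
    if definition.archetype != "linear":
        raise ValueError(f"{definition.name}: not a linear signature")
    weights = pd.Series(definition.gene_weights, dtype=float)
    present = weights.index.intersection(expression.values.index)
    missing = [g for g in weights.index if g not in set(present)]
    if len(present) == 0:
        raise CoverageError(f"{definition.name}: no signature genes present")
    if missing:
        logger.info("%s: %d signature gene(s) absent, contributing 0: %s",
                    definition.name, len(missing), missing[:10])
    sub = expression.values.loc[present]
    raw = definition.offset + sub.mul(weights.loc[present], axis=0).sum(axis=0)
    if definition.scale_bounds is not None:
        lo, hi = definition.scale_bounds
        raw = raw.clip(lo, hi)
    raw.index.name = "patient_id"
    return GrsResult(definition.name, raw, coverage=len(present) / len(weights),
                     missing_genes=missing)


def _patient_correlations(profile_matrix: np.ndarray, reference: np.ndarray,
                          method: str) -> np.ndarray:
    """Column-wise correlation of a genes x patients block against reference columns.

    Returns patients x classes; NaN where a patient profile is constant.
    """
    X = profile_matrix
    R = reference
    if method == "spearman":
        X = np.apply_along_axis(rankdata, 0, X)
        R = np.apply_along_axis(rankdata, 0, R)
    Xc = X - X.mean(axis=0, keepdims=True)
    Rc = R - R.mean(axis=0, keepdims=True)
    xs = np.sqrt((Xc ** 2).sum(axis=0))
    rs = np.sqrt((Rc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc.T @ Rc) / np.outer(xs, rs)
    corr[xs == 0, :] = np.nan
    return corr


def score_centroid(expression: ExpressionMatrix, definition: SignatureDefinition,
                   clinical: Optional[pd.DataFrame] = None) -> GrsResult:
    """Correlation against class centroids combined with class weights.

    score = offset + sum_k class_weight_k * corr(profile, centroid_k)
    (+ clinical terms for "-C" variants). Patients whose signature-gene
    profile is constant have an undefined correlation and are flagged, not
    silently scored.
    """
    if definition.archetype != "centroid":
        raise ValueError(f"{definition.name}: not a centroid signature")
    cm = definition.centroid_matrix
    shared = cm.index.intersection(expression.values.index)
    if len(shared) < 3:
        raise CoverageError(
            f"{definition.name}: need >=3 shared genes for correlation, have {len(shared)}")
    classes = [c for c in cm.columns if c in definition.class_weights]
    corr = _patient_correlations(
        expression.values.loc[shared].to_numpy(),
        cm.loc[shared, classes].to_numpy(),
        definition.correlation,
    )
    w = np.array([definition.class_weights[c] for c in classes])
    scores = definition.offset + corr @ w
    scores = pd.Series(scores, index=expression.sample_ids, name="score")
    scores.index.name = "patient_id"
    if definition.clinical_terms and clinical is not None:
        scores = scores + _clinical_contribution(
            definition.clinical_terms, clinical).reindex(scores.index).to_numpy()
    undefined = [pid for pid, bad in zip(scores.index, np.isnan(corr).any(axis=1)) if bad]
    if undefined:
        logger.warning("%s: %d patient(s) with undefined correlation", definition.name,
                       len(undefined))
    if definition.scale_bounds is not None:
        scores = scores.clip(*definition.scale_bounds)
    return GrsResult(definition.name, scores, coverage=len(shared) / len(cm),
                     missing_genes=[g for g in cm.index if g not in set(shared)],
                     undefined=undefined)


def score_template(expression: ExpressionMatrix,
                   definition: SignatureDefinition) -> GrsResult:
    """Correlation of each patient profile with a reference template.

    Higher correlation with the (good-prognosis) template means lower risk;
    an optional threshold assigns risk groups ("good" above, "poor" at or
    below).
    """
    if definition.archetype != "template":
        raise ValueError(f"{definition.name}: not a template signature")
    template = pd.Series(definition.template_vector, dtype=float)
    shared = template.index.intersection(expression.values.index)
    if len(shared) < 3:
        raise CoverageError(
            f"{definition.name}: need >=3 shared genes for correlation, have {len(shared)}")
    corr = _patient_correlations(
        expression.values.loc[shared].to_numpy(),
        template.loc[shared].to_numpy()[:, None],
        definition.correlation,
    )[:, 0]
    scores = pd.Series(definition.offset + corr, index=expression.sample_ids, name="score")
    scores.index.name = "patient_id"
    undefined = [pid for pid, bad in zip(scores.index, np.isnan(corr)) if bad]
    if undefined:
        logger.warning("%s: %d patient(s) with undefined correlation", definition.name,
                       len(undefined))
    risk_group = None
    if definition.risk_threshold is not None:
        risk_group = pd.Series(
            np.where(corr > definition.risk_threshold, "good", "poor"),
            index=scores.index)
    return GrsResult(definition.name, scores,
                     coverage=len(shared) / len(template),
                     missing_genes=[g for g in template.index if g not in set(shared)],
                     undefined=undefined, risk_group=risk_group)


def score(expression: ExpressionMatrix, definition: SignatureDefinition,
          clinical: Optional[pd.DataFrame] = None) -> GrsResult:
    """Dispatch to the scorer matching the definition's archetype."""
    if definition.archetype == "linear":
        return score_linear(expression, definition)
    if definition.archetype == "centroid":
        return score_centroid(expression, definition, clinical)
    return score_template(expression, definition)


@dataclass
class MixtureFit:
    """Two-component univariate Gaussian mixture fit for surrogate status."""

    status: pd.Series          # patient -> "pos" / "neg"
    posteriors: pd.Series      # P(higher-mean component | value)
    means: tuple[float, float]   # (low, high)
    sds: tuple[float, float]
    weight_high: float
    loglik: float
    loglik_path: list[float]
    converged: bool
    n_iter: int


def surrogate_status_mixture(values: pd.Series, tol: float = 1e-8,
                             max_iter: int = 500) -> MixtureFit:
    """Dichotomise a continuous marker by a two-component Gaussian mixture.

    EM with deterministic median-split initialisation; the component with the
    larger mean is labelled positive; status is positive iff the posterior of
    that component strictly exceeds 0.5 (an exact 0.5 tie is conservative:
    negative). The log-likelihood is non-decreasing across iterations; a run
    that fails to converge within ``max_iter`` returns the best iterate with
    ``converged=False`` and a warning.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 10:
        raise ValueError("need at least 10 finite values to fit a mixture")
    xf = x[finite]
    if np.ptp(xf) == 0:
        raise ValueError("degenerate input: all values identical")

    med = np.median(xf)
    lo, hi = xf[xf <= med], xf[xf > med]
    if len(hi) == 0:   # heavy ties at the median
        lo, hi = xf[xf < med], xf[xf >= med]
    floor = max(1e-8, 1e-6 * np.std(xf))
    mu = np.array([lo.mean(), hi.mean()])
    sd = np.maximum([lo.std() or floor, hi.std() or floor], floor)
    w = np.array([len(lo), len(hi)], dtype=float) / len(xf)

    def _loglik(mu, sd, w):
        comp = w * _normpdf(xf[:, None], mu, sd)
        return float(np.log(comp.sum(axis=1)).sum()), comp

    ll, comp = _loglik(mu, sd, w)
    path = [ll]
    converged = False
    for it in range(1, max_iter + 1):
        resp = comp / comp.sum(axis=1, keepdims=True)           # E-step
        nk = resp.sum(axis=0)
        mu = (resp * xf[:, None]).sum(axis=0) / nk              # M-step
        sd = np.sqrt((resp * (xf[:, None] - mu) ** 2).sum(axis=0) / nk)
        sd = np.maximum(sd, floor)
        w = nk / len(xf)
        ll_new, comp = _loglik(mu, sd, w)
        if ll_new < path[-1] - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        path.append(ll_new)
        if abs(ll_new - path[-2]) < tol:
            converged = True
            break
    if not converged:
        logger.warning("mixture EM did not converge in %d iterations", max_iter)

    high = int(np.argmax(mu))
    comp_all = w * _normpdf(np.where(finite, x, np.nan)[:, None], mu, sd)
    with np.errstate(invalid="ignore"):
        post_high = comp_all[:, high] / comp_all.sum(axis=1)
    index = values.index if isinstance(values, pd.Series) else pd.RangeIndex(len(x))
    posteriors = pd.Series(post_high, index=index)
    status = pd.Series(np.where(post_high > 0.5, "pos", "neg"), index=index)
    status[~finite] = ""
    order = np.argsort(mu)
    return MixtureFit(
        status=status, posteriors=posteriors,
        means=(float(mu[order[0]]), float(mu[order[1]])),
        sds=(float(sd[order[0]]), float(sd[order[1]])),
        weight_high=float(w[high]), loglik=path[-1], loglik_path=path,
        converged=converged, n_iter=len(path) - 1,
    )


def _normpdf(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
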