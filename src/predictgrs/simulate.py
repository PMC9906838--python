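"""Synthetic breast-cancer cohorts with a known proportional-hazards truth.

The generator emulates the structure of a large linked clinical/expression
cohort: marginal clinical distributions matching the study population it
imitates (76% ER-positive, 12% HER2-positive, 53% PR-positive, 47%
node-positive, grade mix 9/39/48, median age 61.8 years, median tumour size
23 mm, 20% second-generation chemotherapy, 61% hormone therapy), a z-scored
expression matrix whose signature-gene block is correlated with clinical
aggressiveness, and breast-cancer-specific event times drawn under a
proportional-hazards model with other-cause deaths and censoring.

Correlation between covariates is induced through a single latent
"aggressiveness" factor via a Gaussian copula, so marginals are preserved
exactly in distribution while grade, size, nodes, ER status and the
signature genes co-vary — the confounding that makes "independent prognostic
value" a non-trivial question. The returned truth record carries every
latent parameter, including the generating score coefficient, for recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import CLINICAL_COLUMNS, Cohort, ExpressionMatrix, zscore_normalise
from .predict_model import PredictModelSpec, prognostic_index, treatment_sum


@dataclass
class GeneratorConfig:
    """Cohort-generator parameters; defaults emulate the imitated population."""

    n: int = 1000
    seed: int = 0
    er_pos_frac: float = 0.76
    her2_pos_frac: float = 0.12
    pr_pos_frac: float = 0.53
    node_pos_frac: float = 0.47
    grade_probs: tuple[float, float, float] = (0.09, 0.39, 0.48)  # renormalised
    age_median: float = 61.8
    age_sd: float = 12.0
    age_range: tuple[float, float] = (21.9, 96.3)
    size_median_mm: float = 23.0
    size_log_sd: float = 0.60
    size_range: tuple[float, float] = (1.0, 403.0)
    chemo_probs: tuple[float, float, float] = (0.79, 0.20, 0.01)  # none/second/third
    hormone_frac: float = 0.61
    radio_frac: float = 0.59
    trastuzumab_frac: float = 0.0
    detection_probs: tuple[float, float, float] = (0.0, 0.0, 1.0)  # screen/sympt/unknown
    ki67_high_frac: float = 0.5
    # expression
    n_genes: int = 120
    n_signature_genes: int = 20
    signature_loading: float = 0.6
    mki67_separation: float = 2.4      # distance between latent KI67 modes (pre-z-score sd 1)
    # copula loadings on the latent aggressiveness factor
    rho_grade: float = 0.6
    rho_er: float = -0.4
    rho_size: float = 0.3
    rho_nodes: float = 0.35
    rho_chemo: float = 0.4
    rho_ki67: float = 0.5
    # survival truth
    true_beta_grs: float = 0.5
    pi_coefficients: dict = field(default_factory=lambda: {
        "grade_2": 0.40, "grade_3": 0.80, "log_size": 0.50,
        "log1p_nodes": 0.45, "her2_pos": 0.25})
    treatment_log_hrs: dict = field(default_factory=lambda: {
        "hormone": -0.39, "chemo_second": -0.25, "chemo_third": -0.45})
    baseline: str = "exponential"      # or "weibull"
    bc_rate_er_pos: float = 0.010      # events / year for the reference patient
    bc_rate_er_neg: float = 0.030
    weibull_shape: float = 1.0
    other_death_rate: float = 0.013
    censor_rate: float = 0.035
    admin_cutoff: float = 29.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name in ("er_pos_frac", "her2_pos_frac", "pr_pos_frac", "node_pos_frac",
                     "hormone_frac", "radio_frac", "trastuzumab_frac", "ki67_high_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("grade_probs", "chemo_probs", "detection_probs"):
            p = np.asarray(getattr(self, name), float)
            if np.any(p < 0) or p.sum() <= 0:
                raise ValueError(f"{name} must be non-negative with positive sum")
            setattr(self, name, tuple(p / p.sum()))


def signature_gene_signs(k: int) -> np.ndarray:
    """Loading sign pattern of the signature-gene block: first half +1, rest -1."""
    signs = np.ones(k)
    signs[(k + 1) // 2:] = -1.0
    return signs


def _copula_uniform(z: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform variates correlated with the latent factor z via a Gaussian copula."""
    eps = rng.standard_normal(len(z))
    return norm.cdf(rho * z + np.sqrt(1.0 - rho ** 2) * eps)


def _correlated_bernoulli(z: np.ndarray, rho: float, frac: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Bernoulli(frac) indicators; positive rho associates them with high z."""
    return _copula_uniform(z, rho, rng) > 1.0 - frac


def _categorical_from_uniform(u: np.ndarray, probs) -> np.ndarray:
    return np.searchsorted(np.cumsum(probs)[:-1], u, side="right")


def _generate_clinical(config: GeneratorConfig, rng: np.random.Generator,
                       force_er: Optional[str] = None):
    """Clinical covariates plus the latent factors behind them."""
    n = config.n
    z = rng.standard_normal(n)

    grade = 1 + _categorical_from_uniform(
        _copula_uniform(z, config.rho_grade, rng), config.grade_probs)
    er_pos = _correlated_bernoulli(z, config.rho_er, config.er_pos_frac, rng)
    if force_er == "positive":
        er_pos = np.ones(n, bool)
    elif force_er == "negative":
        er_pos = np.zeros(n, bool)
    pr_pos = np.where(er_pos,
                      rng.random(n) < min(1.0, config.pr_pos_frac / max(config.er_pos_frac, 1e-9) * 0.9),
                      rng.random(n) < 0.15)
    her2_pos = rng.random(n) < config.her2_pos_frac
    ki67_high = _correlated_bernoulli(z, config.rho_ki67, config.ki67_high_frac, rng)

    size = np.exp(np.log(config.size_median_mm)
                  + config.size_log_sd * (config.rho_size * z
                                          + np.sqrt(1 - config.rho_size ** 2)
                                          * rng.standard_normal(n)))
    size = np.clip(size, *config.size_range)

    node_pos = _correlated_bernoulli(z, config.rho_nodes, config.node_pos_frac, rng)
    nodes = np.where(node_pos, 1 + rng.poisson(np.exp(0.5 * np.clip(z, -3, 3))), 0)

    age = config.age_median + config.age_sd * rng.standard_normal(n)
    age = np.clip(age, *config.age_range)

    chemo_u = _copula_uniform(z, config.rho_chemo, rng)   # high z -> more chemo
    chemo = np.array(["none", "second", "third"])[
        _categorical_from_uniform(chemo_u, config.chemo_probs)]
    hormone_p = min(1.0, config.hormone_frac / max(config.er_pos_frac, 1e-9))
    hormone = np.where(er_pos, rng.random(n) < hormone_p, False)
    radio = rng.random(n) < config.radio_frac
    trastuzumab = her2_pos & (rng.random(n) < config.trastuzumab_frac)
    detection = np.array(["screen", "symptomatic", "unknown"])[
        _categorical_from_uniform(rng.random(n), config.detection_probs)]

    clinical = pd.DataFrame({
        "patient_id": [f"P{i + 1:06d}" for i in range(n)],
        "age": age,
        "er": np.where(er_pos, "pos", "neg"),
        "pr": np.where(pr_pos, "pos", "neg"),
        "her2": np.where(her2_pos, "pos", "neg"),
        "ki67": None,   # left missing: surrogate status is inferred downstream
        "grade": pd.array(grade, dtype="Int64"),
        "size_mm": size,
        "nodes": pd.array(nodes, dtype="Int64"),
        "detection": detection,
        "chemo": chemo,
        "hormone": hormone.astype(int),
        "radio": radio.astype(int),
        "trastuzumab": trastuzumab.astype(int),
    })
    return clinical, z, ki67_high


def _generate_expression(config: GeneratorConfig, rng: np.random.Generator,
                         z: np.ndarray, ki67_high: np.ndarray,
                         patient_ids) -> tuple[ExpressionMatrix, list[str]]:
    n = len(z)
    k = config.n_signature_genes
    lam = config.signature_loading
    sig_genes = [f"SIG{i + 1:03d}" for i in range(k)]
    filler = [f"GENE{i + 1:03d}" for i in range(config.n_genes - k - 1)]
    genes = sig_genes + ["MKI67"] + filler

    # half the block loads positively on aggressiveness, half negatively, so
    # correlation-based scorers (centroid/template archetypes) carry signal
    signs = signature_gene_signs(k)
    block = (lam * signs)[:, None] * z[None, :] \
        + np.sqrt(1 - lam ** 2) * rng.standard_normal((k, n))
    mki67 = (np.where(ki67_high, config.mki67_separation / 2, -config.mki67_separation / 2)
             + 0.45 * rng.standard_normal(n))
    noise = rng.standard_normal((len(filler), n))
    values = pd.DataFrame(np.vstack([block, mki67[None, :], noise]),
                          index=genes, columns=list(patient_ids))
    matrix = ExpressionMatrix(values)
    if n >= 2:
        matrix = zscore_normalise(matrix)
    return matrix, sig_genes


def _true_pi(config: GeneratorConfig, clinical: pd.DataFrame) -> np.ndarray:
    c = config.pi_coefficients
    grade = clinical["grade"].to_numpy(int)
    size = clinical["size_mm"].to_numpy(float)
    nodes = clinical["nodes"].to_numpy(int)
    her2 = (clinical["her2"] == "pos").to_numpy()
    return (c.get("grade_2", 0.0) * (grade == 2)
            + c.get("grade_3", 0.0) * (grade == 3)
            + c.get("log_size", 0.0) * np.log(size / config.size_median_mm)
            + c.get("log1p_nodes", 0.0) * np.log1p(nodes)
            + c.get("her2_pos", 0.0) * her2)


def _treatment_lhr(config: GeneratorConfig, clinical: pd.DataFrame) -> np.ndarray:
    t = config.treatment_log_hrs
    lhr = np.zeros(len(clinical))
    lhr += np.where(clinical["hormone"].to_numpy(int) == 1, t.get("hormone", 0.0), 0.0)
    chemo = clinical["chemo"].to_numpy()
    lhr += np.where(chemo == "second", t.get("chemo_second", 0.0), 0.0)
    lhr += np.where(chemo == "third", t.get("chemo_third", 0.0), 0.0)
    return lhr


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, dict]:
    """Generate a linked cohort and the truth record behind it.

    Reproducible for a fixed seed. Breast-cancer event times follow the
    configured baseline with hazard multiplier exp(PI_true + treatment terms
    + true_beta_grs * g), where g is the mean of the z-scored signature-gene
    block; other-cause deaths and random plus administrative censoring are
    overlaid. The truth record contains every latent parameter and the
    per-patient latent quantities.
    """
    rng = np.random.default_rng(config.seed)
    truth: dict = {"config": _config_dict(config)}
    if config.n == 0:
        empty_clin = pd.DataFrame(columns=CLINICAL_COLUMNS)
        empty_expr = ExpressionMatrix(pd.DataFrame(index=pd.Index([], name="gene_id")))
        cohort = Cohort(empty_clin, empty_expr)
        truth.update({"g": [], "pi_true": [], "eta": [], "grs_gene_weights": {}})
        return cohort, truth

    clinical, z, ki67_high = _generate_clinical(config, rng)
    expression, sig_genes = _generate_expression(config, rng, z, ki67_high,
                                                 clinical["patient_id"])
    signs = signature_gene_signs(len(sig_genes))
    g = (signs @ expression.values.loc[sig_genes].to_numpy()) / len(sig_genes)

    pi = _true_pi(config, clinical)
    eta = pi + _treatment_lhr(config, clinical) + config.true_beta_grs * g
    er_pos = (clinical["er"] == "pos").to_numpy()
    rate = np.where(er_pos, config.bc_rate_er_pos, config.bc_rate_er_neg)
    u = rng.random(config.n)
    if config.baseline == "weibull":
        t_bc = (-np.log(u) / (rate * np.exp(eta))) ** (1.0 / config.weibull_shape)
    else:
        t_bc = -np.log(u) / (rate * np.exp(eta))
    t_other = rng.exponential(1.0 / config.other_death_rate, config.n) \
        if config.other_death_rate > 0 else np.full(config.n, np.inf)
    t_cens = rng.exponential(1.0 / config.censor_rate, config.n) \
        if config.censor_rate > 0 else np.full(config.n, np.inf)
    t_cens = np.minimum(t_cens, config.admin_cutoff)

    t_obs = np.minimum.reduce([t_bc, t_other, t_cens])
    event = np.where(t_bc <= t_obs, "bc_death",
                     np.where(t_other <= t_obs, "other_death", "censored"))
    clinical = clinical.assign(time_years=t_obs, event=event)[CLINICAL_COLUMNS]

    cohort = Cohort(clinical, expression)
    truth.update({
        "g": g.tolist(), "pi_true": pi.tolist(), "eta": eta.tolist(),
        "true_beta_grs": config.true_beta_grs,
        "grs_gene_weights": {gene: float(s) / len(sig_genes)
                             for gene, s in zip(sig_genes, signs)},
        "ki67_high": ki67_high.astype(int).tolist(),
        "n_bc_deaths": int((event == "bc_death").sum()),
        "n_other_deaths": int((event == "other_death").sum()),
    })
    return cohort, truth


def simulate_from_predict_spec(spec: PredictModelSpec, config: GeneratorConfig,
                               ) -> tuple[Cohort, dict]:
    """Generate a cohort whose survival truth IS a given absolute-risk model.

    Clinical covariates are drawn as in :func:`generate_cohort` but forced to
    the spec's ER stratum; each patient's event time inverts the spec's own
    baseline survivor function at hazard multiplier exp(PI + received
    treatments), so the model is perfectly calibrated by construction. Used
    for self-calibration checks.
    """
    rng = np.random.default_rng(config.seed)
    clinical, z, ki67_high = _generate_clinical(config, rng, force_er=spec.er_stratum)
    expression, sig_genes = _generate_expression(config, rng, z, ki67_high,
                                                 clinical["patient_id"])
    clinical = clinical.assign(time_years=0.0, event="censored")[CLINICAL_COLUMNS]
    from .cohort import record_from_row
    records = [record_from_row(row) for _, row in clinical.iterrows()]
    eta = np.array([prognostic_index(r, spec) + treatment_sum(r, spec) for r in records])
    u = rng.random(config.n)
    s_target = u ** np.exp(-eta)
    t_bc = spec.baseline_survival.inverse(s_target)
    t_max = spec.baseline_survival.t_max
    t_cens = rng.exponential(1.0 / config.censor_rate, config.n) \
        if config.censor_rate > 0 else np.full(config.n, np.inf)
    t_cens = np.minimum(t_cens, t_max)
    t_obs = np.minimum(t_bc, t_cens)
    event = np.where(t_bc <= t_obs, "bc_death", "censored")
    clinical = clinical.assign(time_years=t_obs, event=event)
    cohort = Cohort(clinical, expression)
    truth = {"eta": eta.tolist(), "config": _config_dict(config),
             "n_bc_deaths": int((event == "bc_death").sum())}
    return cohort, truth


def _config_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


_PRINTED_TABLES = {
    # 3x3 counts, rows = standalone-model category, columns = modified-model
    # category, order low / intermediate / high
    "table4a": [[893, 19, 0], [27, 434, 7], [0, 21, 477]],     # + Oncotype DX
    "table4b": [[890, 22, 0], [46, 407, 15], [0, 49, 449]],    # + EndoPredict
    "table4c": [[873, 39, 0], [54, 380, 34], [0, 27, 471]],    # + MammaPrint
    "table4d": [[877, 34, 1], [60, 388, 20], [0, 68, 430]],    # + Prosigna
}


def generate_printed_fixture(name: str) -> np.ndarray:
    """Published reclassification count matrices, as test/report fixtures."""
    if name not in _PRINTED_TABLES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_PRINTED_TABLES)}")
    return np.array(_PRINTED_TABLES[name], dtype=int)
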