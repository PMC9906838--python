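"""Absolute-risk engine in the style of the PREDICT breast-cancer model.

The model is a proportional-hazards prognostic index (PI) over
clinicopathological covariates, an ER-stratum-specific baseline survival
curve S0(t), and fixed treatment log-hazard-ratios. Ten-year
breast-cancer-specific survival is S(10) = S0(10) ^ exp(PI + treatment
terms), and the absolute chemotherapy benefit is the difference in S(10)
with and without the second-generation-chemotherapy term.

The engine is fully described by a config object so it is exact-testable
against hand-computable toy specifications; the shipped default coefficient
files are illustrative transcription-style values, not the official
published constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .cohort import ClinicalRecord

logger = logging.getLogger(__name__)

TRANSFORMS = {
    "identity": lambda x: x,
    "log": np.log,
    "log1p": np.log1p,
    "sqrt": np.sqrt,
}


class ExtrapolationError(ValueError):
    """Requested time beyond the tabulated baseline range."""


class StratumMismatchError(ValueError):
    """Record's ER stratum does not match the model specification."""


@dataclass
class CovariateTerm:
    """One additive term of the prognostic index.

    Contribution = coefficient * (transform(feature) - centre), so a
    reference patient (every feature at its centred reference level)
    has PI = 0.
    """

    name: str
    coefficient: float
    transform: str = "identity"
    centre: float = 0.0

    def contribution(self, record: ClinicalRecord) -> tuple[float, bool]:
        """(term value, used-reference-level flag)."""
        raw, missing = extract_feature(record, self.name)
        if missing:
            return 0.0, True
        return self.coefficient * (TRANSFORMS[self.transform](raw) - self.centre), False


def extract_feature(record: ClinicalRecord, name: str) -> tuple[float, bool]:
    """Numeric feature by name; (value, missing-flag).

    Missing optional covariates (ki67, grade, detection=unknown when the spec
    has no unknown term) report missing=True so the caller can fall back to
    the reference level.
    """
    if name == "age":
        return float(record.age), False
    if name == "size_mm":
        return float(record.tumour_size), False
    if name == "nodes":
        return float(record.nodes_positive), False
    if name == "grade":
        return (float(record.grade), False) if record.grade is not None else (0.0, True)
    if name in ("grade_2", "grade_3"):
        if record.grade is None:
            return 0.0, True
        return float(record.grade == int(name[-1])), False
    if name == "her2_pos":
        return float(record.her2_status == "pos"), False
    if name == "pr_pos":
        if record.pr_status is None:
            return 0.0, True
        return float(record.pr_status == "pos"), False
    if name == "ki67_pos":
        if record.ki67_status is None:
            return 0.0, True
        return float(record.ki67_status == "pos"), False
    if name in ("detection_screen", "detection_symptomatic", "detection_unknown"):
        return float(record.detection_mode == name.split("_", 1)[1]), False
    raise KeyError(f"unknown covariate feature {name!r}")


@dataclass
class BaselineSurvival:
    """Tabulated baseline survivor function S0(t) on [0, t_max] years.

    Interpolation between knots is linear on the complementary log-log scale
    log(-log S0), which preserves the proportional-hazards structure between
    knots; on segments where S0 is still 1 the cumulative hazard is
    interpolated linearly instead. No extrapolation beyond the table.
    """

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times[0] != 0 or self.survival[0] != 1:
            raise ValueError("baseline table must start at (0, 1)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("baseline times must be strictly increasing")
        if np.any(np.diff(self.survival) > 0):
            raise ValueError("baseline survival must be non-increasing")
        if np.any(self.survival <= 0) or np.any(self.survival > 1):
            raise ValueError("baseline survival values must lie in (0, 1]")

    @property
    def t_max(self) -> float:
        return float(self.times[-1])

    def value_at(self, t) -> np.ndarray | float:
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr < 0) or np.any(t_arr > self.t_max + 1e-12):
            raise ExtrapolationError(
                f"time outside tabulated baseline range [0, {self.t_max}]")
        H = -np.log(self.survival)
        idx = np.clip(np.searchsorted(self.times, t_arr, side="right"), 1, len(self.times) - 1)
        t0, t1 = self.times[idx - 1], self.times[idx]
        H0, H1 = H[idx - 1], H[idx]
        frac = np.where(t1 > t0, (t_arr - t0) / np.where(t1 > t0, t1 - t0, 1.0), 0.0)
        out = np.empty_like(t_arr)
        both_pos = (H0 > 0) & (H1 > 0)
        with np.errstate(divide="ignore"):
            out[both_pos] = np.exp(-np.exp(
                np.log(H0[both_pos]) + frac[both_pos]
                * (np.log(H1[both_pos]) - np.log(H0[both_pos]))))
        lin = ~both_pos
        out[lin] = np.exp(-(H0[lin] + frac[lin] * (H1[lin] - H0[lin])))
        out[t_arr == 0] = 1.0
        return out if np.ndim(t) else float(out[0])

    def inverse(self, s) -> np.ndarray | float:
        """Smallest tabulated-range t with S0(t) <= s; t_max + inf beyond table.

        Inverts the same interpolation rule used by :meth:`value_at`. Values
        of s below S0(t_max) return +inf (the event falls beyond the table).
        """
        s_arr = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.empty_like(s_arr)
        H_target = -np.log(np.clip(s_arr, 1e-300, 1.0))
        H = -np.log(self.survival)
        beyond = s_arr < self.survival[-1]
        out[beyond] = np.inf
        ok = ~beyond
        idx = np.clip(np.searchsorted(H, H_target[ok], side="left"), 1, len(H) - 1)
        t0, t1 = self.times[idx - 1], self.times[idx]
        H0, H1 = H[idx - 1], H[idx]
        ht = H_target[ok]
        frac = np.zeros_like(ht)
        both_pos = (H0 > 0) & (H1 > H0)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac[both_pos] = ((np.log(ht[both_pos]) - np.log(H0[both_pos]))
                              / (np.log(H1[both_pos]) - np.log(H0[both_pos])))
        lin = ~both_pos & (H1 > H0)
        frac[lin] = (ht[lin] - H0[lin]) / (H1[lin] - H0[lin])
        out[ok] = t0 + np.clip(frac, 0, 1) * (t1 - t0)
        out[s_arr >= 1.0] = 0.0
        return out if np.ndim(s) else float(out[0])


@dataclass
class PredictModelSpec:
    """ER-stratified prognostic model: PI terms, treatment log-HRs, baseline S0."""

    er_stratum: str                                    # "positive" | "negative"
    covariate_terms: list[CovariateTerm]
    treatment_log_hrs: dict[str, float]                # hormone, chemo_second, chemo_third, trastuzumab
    baseline_survival: BaselineSurvival

    def __post_init__(self) -> None:
        if self.er_stratum not in ("positive", "negative"):
            raise ValueError("er_stratum must be 'positive' or 'negative'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PredictModelSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            er_stratum=raw["er_stratum"],
            covariate_terms=[CovariateTerm(**t) for t in raw["covariate_terms"]],
            treatment_log_hrs={k: float(v) for k, v in raw["treatment_log_hrs"].items()},
            baseline_survival=BaselineSurvival(
                times=raw["baseline_survival"]["times"],
                survival=raw["baseline_survival"]["survival"]),
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "er_stratum": self.er_stratum,
            "covariate_terms": [
                {"name": t.name, "coefficient": float(t.coefficient),
                 "transform": t.transform, "centre": float(t.centre)}
                for t in self.covariate_terms],
            "treatment_log_hrs": {k: float(v) for k, v in self.treatment_log_hrs.items()},
            "baseline_survival": {"times": [float(x) for x in self.baseline_survival.times],
                                  "survival": [float(x) for x in self.baseline_survival.survival]},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class RiskPrediction:
    """Per-patient absolute 10-year predictions and chemotherapy benefit."""

    patient_id: str
    pi: float
    s10_no_chemo: float
    s10_with_chemo: float

    @property
    def benefit(self) -> float:
        """Absolute chemotherapy benefit in percentage points."""
        return 100.0 * (self.s10_with_chemo - self.s10_no_chemo)


def prognostic_index(record: ClinicalRecord, spec: PredictModelSpec) -> float:
    """Sum of covariate term contributions; 0 for the reference patient.

    Missing optional covariates (ki67, grade, pr) fall back to the reference
    level with a logged flag. Raises if the record's ER stratum does not
    match the specification.
    """
    record_stratum = "positive" if record.er_status == "pos" else "negative"
    if record_stratum != spec.er_stratum:
        raise StratumMismatchError(
            f"{record.patient_id}: record is ER-{record_stratum}, spec is ER-{spec.er_stratum}")
    pi = 0.0
    for term in spec.covariate_terms:
        value, used_reference = term.contribution(record)
        if used_reference:
            logger.debug("%s: %s missing, using reference level", record.patient_id, term.name)
        pi += value
    return pi


def treatment_sum(record: ClinicalRecord, spec: PredictModelSpec,
                  include_chemo: bool = True) -> float:
    """Sum of log-HRs for the treatments the record received."""
    total = 0.0
    if record.hormone_therapy:
        total += spec.treatment_log_hrs.get("hormone", 0.0)
    if record.trastuzumab:
        total += spec.treatment_log_hrs.get("trastuzumab", 0.0)
    if include_chemo and record.chemo_generation != "none":
        total += spec.treatment_log_hrs.get(f"chemo_{record.chemo_generation}", 0.0)
    return total


def survival_at(t: float, pi: float, treatment_terms: float,
                spec: PredictModelSpec) -> float:
    """S(t) = S0(t) ^ exp(pi + treatment terms); no extrapolation beyond the table."""
    s0 = spec.baseline_survival.value_at(t)
    return float(s0 ** np.exp(pi + treatment_terms))


def chemo_benefit(record: ClinicalRecord, spec: PredictModelSpec,
                  grs_term: float = 0.0, t: float = 10.0) -> RiskPrediction:
    """Absolute benefit of second-generation chemotherapy at t years.

    S(t) is computed twice — without any chemotherapy term and with the
    second-generation chemotherapy log-HR — holding the patient's recorded
    non-chemotherapy treatments fixed. ``grs_term`` is an already-rescaled
    additional log-hazard term added to the PI in both arms.
    """
    pi = prognostic_index(record, spec) + grs_term
    base_terms = treatment_sum(record, spec, include_chemo=False)
    chemo_lhr = spec.treatment_log_hrs.get("chemo_second", 0.0)
    s_no = survival_at(t, pi, base_terms, spec)
    s_with = survival_at(t, pi, base_terms + chemo_lhr, spec)
    return RiskPrediction(record.patient_id, pi, s_no, s_with)


def cohort_predictions(records: list[ClinicalRecord], spec: PredictModelSpec,
                       grs_terms: Optional[dict[str, float]] = None,
                       t: float = 10.0) -> "pd.DataFrame":
    """Vector of RiskPredictions for all records in one ER stratum, as a frame.

    ``grs_terms`` maps patient_id to a rescaled GRS log-hazard term
    (default 0 — standalone model).
    """
    import pandas as pd

    rows = []
    for rec in records:
        g = 0.0 if grs_terms is None else float(grs_terms.get(rec.patient_id, 0.0))
        rp = chemo_benefit(rec, spec, grs_term=g, t=t)
        rows.append({"patient_id": rp.patient_id, "pi": rp.pi,
                     "s10_no_chemo": rp.s10_no_chemo,
                     "s10_with_chemo": rp.s10_with_chemo,
                     "benefit_pct": rp.benefit})
    return pd.DataFrame(rows)
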