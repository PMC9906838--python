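"""Model performance: calibration, discrimination and bootstrap optimism.

Calibration is the difference between cohort-mean predicted 10-year
breast-cancer-specific survival and the Kaplan–Meier estimate at 10 years,
in percentage points. Discrimination is Harrell's concordance over usable
pairs under censoring, with a confidence interval from the linearised
U-statistic variance. Optimism is estimated by the out-of-bag bootstrap:
refit on each resample, compare apparent performance with performance on the
observations left out of that resample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from lifelines import KaplanMeierFitter

logger = logging.getLogger(__name__)


@dataclass
class KaplanMeierCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray
    survival: np.ndarray

    def value_at(self, t: float) -> float:
        """Step value at t (last jump at or before t).

        Beyond the last observed time the last value is returned with a
        truncation warning.
        """
        if t > self.times[-1]:
            warnings.warn(f"t={t} beyond last observed time {self.times[-1]}; "
                          "returning the last estimate", stacklevel=2)
            return float(self.survival[-1])
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def kaplan_meier(times, events) -> KaplanMeierCurve:
    """Standard product-limit estimator (breast-cancer deaths as events)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if times.size == 0:
        raise ValueError("need at least one observation")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return KaplanMeierCurve(sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float))


def observed_survival_percent(times, events, t: float = 10.0) -> float:
    """Kaplan–Meier survival at t years, as a percent."""
    return 100.0 * kaplan_meier(times, events).value_at(t)


def calibration(predictions, km_observed_percent: float) -> float:
    """Mean predicted survival (percent) minus observed percent.

    ``predictions`` are per-patient survival probabilities in [0, 1];
    ``km_observed_percent`` is the observed Kaplan–Meier survival in [0, 100].
    Negative values mean the model underestimates survival.
    """
    p = np.asarray(predictions, dtype=float)
    if p.size == 0:
        raise ValueError("empty cohort")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("predictions must be probabilities in [0, 1]")
    return float(100.0 * p.mean() - km_observed_percent)


def _pair_counts(times, events, risk, chunk: int = 512):
    """Per-subject concordance components under Harrell's usability rule.

    A pair is usable when the earlier time has the event (or times tie with
    exactly one event, the event ordered first). Tied risks score 1/2.
    Returns (score_sum, pair_count, per-subject a_i, per-subject b_i).
    """
    t = np.asarray(times, float)
    e = np.asarray(events).astype(bool)
    r = np.asarray(risk, float)
    n = len(t)
    a = np.zeros(n)
    b = np.zeros(n)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        ti = t[sl][:, None]
        ei = e[sl][:, None]
        ri = r[sl][:, None]
        comparable = ((ti < t[None, :]) | ((ti == t[None, :]) & ~e[None, :])) & ei
        np.fill_diagonal(comparable[:, sl], False)
        score = np.where(ri > r[None, :], 1.0, np.where(ri == r[None, :], 0.5, 0.0))
        score = np.where(comparable, score, 0.0)
        a[sl] += score.sum(axis=1)
        b[sl] += comparable.sum(axis=1)
        a += score.sum(axis=0)
        b += comparable.sum(axis=0)
    return a.sum() / 2.0, b.sum() / 2.0, a, b


def harrell_c(times, events, risk_scores) -> tuple[float, tuple[float, float]]:
    """Harrell's concordance index with a 95% CI.

    Concordance over usable pairs (higher risk should fail earlier); ties in
    risk count 1/2. The CI is c +/- 1.96*se with se from the linearised
    (infinitesimal-jackknife) variance of the ratio-of-U-statistics
    estimator, clipped to [0, 1]. Invariant to strictly monotone transforms
    of the risk scores.
    """
    A, M, a, b = _pair_counts(times, events, risk_scores)
    if M == 0:
        raise ValueError("no comparable pairs")
    c = A / M
    var = float(((a - c * b) ** 2).sum()) / (M ** 2)
    se = np.sqrt(var)
    lo, hi = max(0.0, c - 1.96 * se), min(1.0, c + 1.96 * se)
    return float(c), (float(lo), float(hi))


@dataclass
class OptimismResult:
    """Out-of-bag bootstrap optimism of a c-index."""

    optimism: float
    apparent: np.ndarray
    test: np.ndarray
    n_skipped: int
    seed: int

    @property
    def n_used(self) -> int:
        return len(self.apparent)


def bootstrap_optimism(times, events, features,
                       fit_and_score: Callable,
                       B: int = 100, seed: int = 0) -> OptimismResult:
    """Out-of-bag bootstrap optimism of Harrell's c for a fitted risk model.

    ``fit_and_score(times_tr, events_tr, X_tr)`` fits on the training data
    and returns a callable mapping a feature matrix to risk scores. For each
    of B resamples (with replacement, size n) the c-index is computed on the
    resample (apparent) and on the out-of-bag complement (test); optimism is
    the mean of (apparent - test). A prespecified (non-fitted) score has
    optimism near zero. Replicates whose out-of-bag set has no comparable
    pairs are skipped and logged; all skipped is an error.

    Randomness derives from one master seed with per-replicate substreams,
    recorded in the result for exact reruns.
    """
    t = np.asarray(times, float)
    e = np.asarray(events).astype(int)
    X = np.asarray(features, float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(t)
    if B < 1:
        raise ValueError("B must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(B)
    apparent, test = [], []
    n_skipped = 0
    for b_idx in range(B):
        rng = np.random.default_rng(streams[b_idx])
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        try:
            scorer = fit_and_score(t[idx], e[idx], X[idx])
            c_app, _ = harrell_c(t[idx], e[idx], scorer(X[idx]))
            if len(oob) == 0:
                raise ValueError("empty out-of-bag set")
            c_test, _ = harrell_c(t[oob], e[oob], scorer(X[oob]))
        except ValueError as exc:
            logger.info("bootstrap replicate %d skipped: %s", b_idx, exc)
            n_skipped += 1
            continue
        apparent.append(c_app)
        test.append(c_test)
    if not apparent:
        raise RuntimeError("all bootstrap replicates skipped")
    apparent = np.asarray(apparent)
    test = np.asarray(test)
    return OptimismResult(float((apparent - test).mean()), apparent, test,
                          n_skipped, seed)


def apparent_optimism(times, events, features, fit_and_score: Callable,
                      B: int = 100, seed: int = 0) -> float:
    """Classic bootstrap optimism: mean(apparent_b - c(original data, model_b)).

    Implemented as an alternative to the default out-of-bag variant.
    """
    t = np.asarray(times, float)
    e = np.asarray(events).astype(int)
    X = np.asarray(features, float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(t)
    streams = np.random.SeedSequence(seed).spawn(B)
    diffs = []
    for b_idx in range(B):
        rng = np.random.default_rng(streams[b_idx])
        idx = rng.integers(0, n, size=n)
        scorer = fit_and_score(t[idx], e[idx], X[idx])
        c_app, _ = harrell_c(t[idx], e[idx], scorer(X[idx]))
        c_orig, _ = harrell_c(t, e, scorer(X))
        diffs.append(c_app - c_orig)
    return float(np.mean(diffs))


@dataclass
class EvaluationReport:
    """Calibration, discrimination and fit summary for one model."""

    model_name: str
    predicted_mean_s10: float      # percent
    observed_s10: float            # percent (Kaplan-Meier at 10 years)
    c_index: float
    c_index_ci: tuple[float, float]
    loglik: Optional[float] = None
    c_index_optimism: Optional[float] = None
    n: int = 0
    n_events: int = 0

    @property
    def calibration_diff(self) -> float:
        return self.predicted_mean_s10 - self.observed_s10

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "predicted_mean_s10": self.predicted_mean_s10,
            "observed_s10": self.observed_s10,
            "calibration_diff": self.calibration_diff,
            "c_index": self.c_index, "c_index_ci": list(self.c_index_ci),
            "c_index_optimism": self.c_index_optimism,
            "loglik": self.loglik, "n": self.n, "n_events": self.n_events,
        }


def evaluate_model(model_name: str, times, events, predictions_s10,
                   risk_scores, loglik: Optional[float] = None) -> EvaluationReport:
    """Assemble an EvaluationReport from predictions and a risk ordering."""
    observed = observed_survival_percent(times, events, 10.0)
    predicted = float(100.0 * np.mean(np.asarray(predictions_s10, float)))
    c, ci = harrell_c(times, events, risk_scores)
    e = np.asarray(events).astype(int)
    return EvaluationReport(model_name, predicted, observed, c, ci, loglik,
                            n=len(e), n_events=int(e.sum()))
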