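"""Cox proportional-hazards fitting with a fixed-coefficient offset.

External validation of a prognostic index proceeds by entering the index in
the Cox linear predictor as an offset — coefficient constrained to one — so
that only the candidate covariate (here a genomic risk score) is estimated.
The partial likelihood uses the Efron approximation for tied event times and
is maximised by Newton–Raphson with step-halving.

The fitted score term is made baseline-compatible by rescaling: subtracting
c = log(mean_i exp(beta * g_i)) so the cohort-average hazard ratio of the
added term is exactly one and the absolute baseline survival of the host
model remains appropriate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2, norm


class ConvergenceError(RuntimeError):
    """Newton–Raphson failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


@dataclass
class FittedGrsModel:
    """Offset Cox fit of one genomic risk score.

    ``loglik_null`` is the offset-only partial log-likelihood (no free
    parameters); ``rescale_c`` satisfies mean_i exp(beta*g_i - c) = 1.
    """

    signature_name: str
    beta: Optional[float]
    se_beta: Optional[float]
    ci_95: Optional[tuple[float, float]]
    loglik: float
    loglik_null: float
    lr_p: Optional[float]
    rescale_c: Optional[float] = None
    n: int = 0
    n_events: int = 0
    n_iter: int = 0
    converged: bool = True
    beta_vector: Optional[np.ndarray] = None
    cov_beta: Optional[np.ndarray] = None

    @property
    def hr(self) -> Optional[float]:
        return None if self.beta is None else float(np.exp(self.beta))

    @property
    def hr_ci(self) -> Optional[tuple[float, float]]:
        if self.ci_95 is None:
            return None
        return (float(np.exp(self.ci_95[0])), float(np.exp(self.ci_95[1])))

    def to_dict(self) -> dict:
        return {
            "signature": self.signature_name,
            "beta": self.beta, "se": self.se_beta, "ci": self.ci_95,
            "hr": self.hr, "hr_ci": self.hr_ci,
            "loglik": self.loglik, "loglik_null": self.loglik_null,
            "lr_p": self.lr_p, "c": self.rescale_c,
            "n": self.n, "n_events": self.n_events,
        }


def _prepare(time, event, offset, X):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    offset = np.zeros_like(time) if offset is None else np.asarray(offset, dtype=float)
    if not np.all(np.isfinite(offset)):
        raise ValueError("offset must be finite for every patient")
    order = np.argsort(time, kind="stable")
    time, event, offset = time[order], event[order], offset[order]
    if X is not None:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        X = X[order]
    return time, event, offset, X


def _efron_ll_grad_hess(time, event, offset, X, beta, ridge=0.0):
    """Efron partial log-likelihood, gradient and Hessian (of ll) at beta.

    Inputs are sorted ascending in time. Shift-invariance of the partial
    likelihood in the linear predictor is used for overflow protection.
    """
    n = len(time)
    p = 0 if X is None else X.shape[1]
    eta = offset + (X @ beta if p else 0.0)
    eta = eta - eta.max()
    w = np.exp(eta)
    # suffix sums over the risk set (time >= t)
    S0 = np.cumsum(w[::-1])[::-1]
    first_at_time = np.searchsorted(time, time, side="left")
    if p:
        wX = w[:, None] * X
        S1 = np.cumsum(wX[::-1], axis=0)[::-1]
        wXX = wX[:, :, None] * X[:, None, :]
        S2 = np.cumsum(wXX[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    ev_idx = np.flatnonzero(event == 1)
    ev_times = time[ev_idx]
    untied = len(ev_times) == len(np.unique(ev_times))
    if untied:
        # vectorised path: every event is its own Efron group
        i0 = first_at_time[ev_idx]
        phi = S0[i0]
        ll = eta[ev_idx].sum() - np.log(phi).sum()
        if p:
            U = S1[i0] / phi[:, None]
            grad = X[ev_idx].sum(axis=0) - U.sum(axis=0)
            hess = -((S2[i0] / phi[:, None, None]).sum(axis=0)
                     - np.einsum("li,lj->ij", U, U))
        if ridge and p:
            ll -= 0.5 * ridge * float(beta @ beta)
            grad -= ridge * beta
            hess -= ridge * np.eye(p)
        return ll, grad, hess
    # group tied events
    starts = np.flatnonzero(np.r_[True, np.diff(ev_times) != 0])
    groups = np.split(ev_idx, starts[1:])
    for g in groups:
        d = len(g)
        i0 = first_at_time[g[0]]
        s0r = S0[i0]
        ll += eta[g].sum()
        if d == 1:
            phi = s0r
            ll -= np.log(phi)
            if p:
                u = S1[i0] / phi
                grad += X[g[0]] - u
                hess -= S2[i0] / phi - np.outer(u, u)
        else:
            s0d = w[g].sum()
            frac = np.arange(d) / d
            phi = s0r - frac * s0d
            ll -= np.log(phi).sum()
            if p:
                s1r, s1d = S1[i0], wX[g].sum(axis=0)
                s2r, s2d = S2[i0], wXX[g].sum(axis=0)
                grad += X[g].sum(axis=0)
                for l in range(d):
                    u = (s1r - frac[l] * s1d) / phi[l]
                    grad -= u
                    hess -= (s2r - frac[l] * s2d) / phi[l] - np.outer(u, u)
    if ridge and p:
        ll -= 0.5 * ridge * float(beta @ beta)
        grad -= ridge * beta
        hess -= ridge * np.eye(p)
    return ll, grad, hess


def offset_loglik(time, event, offset) -> float:
    """Offset-only Efron partial log-likelihood (no free parameters)."""
    time, event, offset, _ = _prepare(time, event, offset, None)
    ll, _, _ = _efron_ll_grad_hess(time, event, offset, None, np.zeros(0))
    return float(ll)


def fit_offset_cox(time, event, offset=None, covariate=None,
                   signature_name: str = "", tol: float = 1e-9,
                   max_iter: int = 100, standardise: bool = False,
                   ridge: float = 0.0) -> FittedGrsModel:
    """Fit a Cox model with a fixed-coefficient-one offset and optional covariate.

    With no covariate the result carries only the offset-only partial
    log-likelihood. With a covariate (vector, or n x p matrix) Newton–Raphson
    maximises the Efron partial likelihood with step-halving on a likelihood
    decrease, reporting beta, its standard error from the observed
    information, the Wald 95% CI and the likelihood-ratio p against the
    offset-only model. ``standardise`` divides each covariate column by its
    standard deviation before fitting and maps the estimate back.
    """
    time_s, event_s, offset_s, X = _prepare(time, event, offset, covariate)
    n = len(time_s)
    n_events = int(event_s.sum())
    if n_events < 2:
        raise ValueError(f"need at least 2 events, have {n_events}")
    ll_null = float(_efron_ll_grad_hess(time_s, event_s, offset_s, None, np.zeros(0))[0])
    if X is None:
        return FittedGrsModel(signature_name, None, None, None, ll_null, ll_null,
                              None, None, n, n_events)
    sds = X.std(axis=0, ddof=0)
    if np.any(sds == 0):
        raise ValueError("no variation: constant covariate")
    scale = sds if standardise else np.ones_like(sds)
    Xs = X / scale
    p = Xs.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _efron_ll_grad_hess(time_s, event_s, offset_s, Xs, beta, ridge)
    trace = [(beta.copy(), ll)]
    converged = False
    for it in range(1, max_iter + 1):
        info = -hess
        delta = np.linalg.solve(info, grad)
        step = 1.0
        for _ in range(30):     # step-halving on likelihood decrease
            cand = beta + step * delta
            ll_new, grad_new, hess_new = _efron_ll_grad_hess(
                time_s, event_s, offset_s, Xs, cand, ridge)
            if ll_new >= ll - 1e-12:
                break
            step /= 2
        else:
            raise ConvergenceError("step-halving exhausted", trace)
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        trace.append((beta.copy(), ll))
        if np.max(np.abs(step * delta)) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"no convergence in {max_iter} iterations", trace)
    cov = np.linalg.inv(-hess)
    beta_orig = beta / scale
    cov_orig = cov / np.outer(scale, scale)
    se = np.sqrt(np.diag(cov_orig))
    z = norm.ppf(0.975)
    lr_stat = max(0.0, 2.0 * (ll - ll_null))
    lr_p = float(chi2.sf(lr_stat, df=p))
    b0, s0_ = float(beta_orig[0]), float(se[0])
    return FittedGrsModel(
        signature_name, b0, s0_, (b0 - z * s0_, b0 + z * s0_),
        float(ll), ll_null, lr_p, None, n, n_events, it, True,
        beta_vector=beta_orig, cov_beta=cov_orig,
    )


def rescale_grs_term(beta: float, scores) -> tuple[float, np.ndarray]:
    """Centre a fitted score term so its cohort-average hazard ratio is one.

    c = log(mean_i exp(beta * g_i)), computed via log-sum-exp so extreme
    beta*g cannot overflow; returns (c, beta*g - c) with
    mean_i exp(beta*g_i - c) = 1 to 1e-10. Preserves the ordering of
    patients' hazards.
    """
    g = np.asarray(scores, dtype=float)
    if g.size == 0:
        raise ValueError("empty score vector")
    if not np.all(np.isfinite(g)):
        raise ValueError("scores must be finite")
    terms = beta * g
    c = float(logsumexp(terms) - np.log(g.size))
    return c, terms - c


def compare_models(loglik_restricted: float, loglik_full: float, df: int) -> float:
    """Likelihood-ratio test of nested models: 2*(full - restricted) ~ chi2(df)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    lr = 2.0 * (loglik_full - loglik_restricted)
    if lr < -1e-8:
        raise ValueError(f"model nesting violated: LR statistic {lr} < 0")
    return float(chi2.sf(max(lr, 0.0), df=df))
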