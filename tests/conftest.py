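import numpy as np
import pandas as pd
import pytest

from predictgrs.cohort import ExpressionMatrix
from predictgrs.predict_model import BaselineSurvival, CovariateTerm, PredictModelSpec


CLINICAL_HEADER = ("patient_id,age,er,pr,her2,ki67,grade,size_mm,nodes,"
                   "detection,chemo,hormone,radio,trastuzumab,time_years,event")


def clinical_line(pid, age=55, er="pos", pr="pos", her2="neg", ki67="", grade=2,
                  size=20, nodes=0, detection="unknown", chemo="none", hormone=1,
                  radio=0, trast=0, time=5.0, event="censored"):
    return (f"{pid},{age},{er},{pr},{her2},{ki67},{grade},{size},{nodes},"
            f"{detection},{chemo},{hormone},{radio},{trast},{time},{event}")


@pytest.fixture
def tiny_cohort_files(tmp_path):
    """3-patient clinical CSV + 5-gene TSV with matching ids."""
    clinical = tmp_path / "clinical.csv"
    clinical.write_text("\n".join([
        CLINICAL_HEADER,
        clinical_line("P1", time=3.0, event="bc_death"),
        clinical_line("P2", time=6.0, event="censored"),
        clinical_line("P3", time=9.0, event="other_death", er="neg"),
    ]) + "\n")
    rng = np.random.default_rng(3)
    genes = [f"G{i}" for i in range(1, 6)]
    expr = tmp_path / "expression.tsv"
    rows = ["gene_id\tP1\tP2\tP3"]
    for g in genes:
        vals = rng.normal(size=3)
        rows.append(g + "\t" + "\t".join(f"{v:.6f}" for v in vals))
    expr.write_text("\n".join(rows) + "\n")
    return clinical, expr


@pytest.fixture
def toy_predict_spec():
    """Hand-computable ER-positive spec: one nodes term, S0(10) = 0.9."""
    return PredictModelSpec(
        er_stratum="positive",
        covariate_terms=[CovariateTerm("nodes", 0.3, "identity", 0.0)],
        treatment_log_hrs={"hormone": 0.0, "chemo_second": float(np.log(0.75))},
        baseline_survival=BaselineSurvival(
            times=[0.0, 10.0, 15.0], survival=[1.0, 0.9, 0.85]),
    )


def make_expression(values: dict[str, list[float]], genes: list[str],
                    normalised=False) -> ExpressionMatrix:
    """Genes-by-samples matrix from {sample_id: per-gene values}."""
    df = pd.DataFrame(values, index=genes)
    return ExpressionMatrix(df, normalised=normalised)


# ---------------------------------------------------------------------------
# independent oracles (brute-force reference implementations used in tests)

def brute_force_efron_loglik(time, event, eta):
    """Efron partial log-likelihood by explicit risk-set enumeration."""
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    eta = np.asarray(eta, float)
    ll = 0.0
    for t in sorted(set(time[event])):
        D = np.flatnonzero(event & (time == t))
        R = np.flatnonzero(time >= t)
        d = len(D)
        wR = np.exp(eta[R]).sum()
        wD = np.exp(eta[D]).sum()
        ll += eta[D].sum()
        for l in range(d):
            ll -= np.log(wR - (l / d) * wD)
    return ll


def brute_force_km(times, events, t_query):
    """Product-limit estimate at t_query by explicit risk-set enumeration."""
    times = np.asarray(times, float)
    events = np.asarray(events).astype(bool)
    s = 1.0
    for t in sorted(set(times[events])):
        if t > t_query:
            break
        d = int((events & (times == t)).sum())
        n_at_risk = int((times >= t).sum())
        s *= 1.0 - d / n_at_risk
    return s


def brute_force_harrell(times, events, risk):
    """Concordance by explicit pair enumeration under Harrell's usability rule."""
    times = np.asarray(times, float)
    events = np.asarray(events).astype(bool)
    risk = np.asarray(risk, float)
    n = len(times)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            usable = (times[i] < times[j] and events[i]) or (
                times[i] == times[j] and events[i] and not events[j])
            if not usable:
                continue
            den += 1
            if risk[i] > risk[j]:
                num += 1
            elif risk[i] == risk[j]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den
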