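"""End-to-end orchestration: score, fit, modify, evaluate, reclassify.

Per ER stratum the pipeline computes signature scores, fits offset Cox
models (the host model's prognostic index constrained to coefficient one),
rescales each fitted score term to cohort-mean hazard ratio one, rebuilds
absolute 10-year predictions with the added term, and reports calibration,
discrimination (with optional out-of-bag bootstrap optimism) and
chemotherapy-benefit reclassification. Each stage's output is written
before the next begins, so partial runs are inspectable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, read_cohort, write_cohort, zscore_normalise
from .coxfit import fit_offset_cox, rescale_grs_term
from .evaluation import bootstrap_optimism, evaluate_model, observed_survival_percent
from .predict_model import PredictModelSpec, cohort_predictions, prognostic_index
from .reclassification import build_table, categorize_benefits, summarize_all
from .signatures import SignatureDefinition, surrogate_status_mixture, score as score_signature
from .simulate import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Full-run configuration: exactly one input source (files xor generator)."""

    clinical_path: Optional[str] = None
    expression_path: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    signature_paths: list[str] = field(default_factory=list)
    predict_spec_erpos: Optional[str] = None
    predict_spec_erneg: Optional[str] = None
    bootstrap_B: int = 0
    seed: int = 0
    outdir: str = "results"
    transpose: bool = False
    include_er_negative_reclass: bool = False
    infer_ki67: bool = True

    def validate(self) -> None:
        has_files = self.clinical_path is not None or self.expression_path is not None
        has_gen = self.generator is not None
        if has_files and has_gen:
            raise ValueError("config sets both input files and a generator; choose one")
        if not has_files and not has_gen:
            raise ValueError("config must set either input files or a generator")
        if has_files and (self.clinical_path is None or self.expression_path is None):
            raise ValueError("both clinical and expression paths are required")
        for p in [self.clinical_path, self.expression_path,
                  self.predict_spec_erpos, self.predict_spec_erneg,
                  *self.signature_paths]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _sha256(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def load_cohort(config: RunConfig) -> tuple[Cohort, Optional[dict]]:
    if config.generator is not None:
        cohort, truth = generate_cohort(config.generator)
        return cohort, truth
    cohort = read_cohort(config.clinical_path, config.expression_path,
                         transpose=config.transpose)
    return cohort, None


def infer_surrogate_ki67(cohort: Cohort, gene: str = "MKI67") -> Cohort:
    """Fill missing KI67 status from a two-component mixture on one gene."""
    if gene not in cohort.expression.values.index:
        logger.info("gene %s absent; KI67 left missing", gene)
        return cohort
    fit = surrogate_status_mixture(cohort.expression.values.loc[gene])
    clin = cohort.clinical.copy()
    missing = clin["ki67"].isna() | (clin["ki67"].astype(object) == "") | clin["ki67"].isnull()
    clin.loc[missing, "ki67"] = fit.status.reindex(clin.loc[missing, "patient_id"]).values
    return Cohort(clin, cohort.expression, er_stratum=cohort.er_stratum)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the summary manifest (also written).

    Writes, under ``outdir``: scores.csv, table2.csv (fit + discrimination
    per signature and stratum), table3.csv (calibration), one
    table4_<signature>.csv per signature (ER-positive reclassification
    unless configured otherwise), and summary.json with versions, seeds and
    input hashes.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- stage: input -------------------------------------------------
    try:
        cohort, truth = load_cohort(config)
    except Exception as exc:
        raise PipelineError(f"input stage failed: {exc}") from exc
    if not cohort.expression.normalised and len(cohort) >= 2:
        cohort = Cohort(cohort.clinical, zscore_normalise(cohort.expression))
    if truth is not None:
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh)
        write_cohort(cohort, outdir / "clinical.csv", outdir / "expression.tsv")
    if config.infer_ki67:
        try:
            cohort = infer_surrogate_ki67(cohort)
        except ValueError as exc:
            logger.warning("surrogate KI67 inference skipped: %s", exc)

    # ---- stage: scoring -----------------------------------------------
    try:
        definitions = [SignatureDefinition.from_yaml(p) for p in config.signature_paths]
        results = {d.name: score_signature(cohort.expression, d, cohort.clinical)
                   for d in definitions}
    except Exception as exc:
        raise PipelineError(f"scoring stage failed: {exc}") from exc
    if results:
        pd.concat([r.to_frame() for r in results.values()]).to_csv(
            outdir / "scores.csv", index=False)

    specs = {}
    if config.predict_spec_erpos:
        specs["positive"] = PredictModelSpec.from_yaml(config.predict_spec_erpos)
    if config.predict_spec_erneg:
        specs["negative"] = PredictModelSpec.from_yaml(config.predict_spec_erneg)

    table2_rows, table3_rows, reclass_tables = [], [], {}
    for stratum, spec in specs.items():
        sub = cohort.er_subset(stratum)
        if len(sub) == 0:
            logger.info("no ER-%s patients; stratum skipped", stratum)
            continue
        times, events = sub.bc_survival
        if events.sum() < 2:
            logger.warning("ER-%s: fewer than 2 events; stratum skipped", stratum)
            continue
        records = sub.records
        pi = np.array([prognostic_index(r, spec) for r in records])
        pid = sub.patient_ids

        # ---- stage: fits ----------------------------------------------
        try:
            null_fit = fit_offset_cox(times, events, offset=pi)
            base_pred = cohort_predictions(records, spec)
            observed = observed_survival_percent(times, events)
            base_eval = evaluate_model(f"PREDICT [{stratum}]", times, events,
                                       base_pred["s10_no_chemo"], pi,
                                       loglik=null_fit.loglik_null)
            table3_rows.append(base_eval.to_dict())
            table2_rows.append({
                "er_stratum": stratum, "signature": "PREDICT (offset)",
                "hr": np.e ** 1.0, "hr_ci": None, "beta": 1.0, "se": None,
                "loglik": null_fit.loglik_null, "lr_p": None,
                "c_index": base_eval.c_index,
                "c_index_ci": list(base_eval.c_index_ci),
                "c_index_optimism": None,
            })
            for name, res in results.items():
                g = res.scores.reindex(pid).to_numpy(float)
                uni = fit_offset_cox(times, events, offset=None, covariate=g,
                                     signature_name=name)
                multi = fit_offset_cox(times, events, offset=pi, covariate=g,
                                       signature_name=name)
                c_const, adjusted = rescale_grs_term(multi.beta, g)
                multi.rescale_c = c_const
                grs_terms = dict(zip(pid, adjusted))
                pred = cohort_predictions(records, spec, grs_terms=grs_terms)
                optimism = None
                if config.bootstrap_B > 0:
                    feats = np.column_stack([pi, g])

                    def _fit_and_score(t_tr, e_tr, X_tr):
                        fit = fit_offset_cox(t_tr, e_tr, offset=X_tr[:, 0],
                                             covariate=X_tr[:, 1])
                        return lambda X: X[:, 0] + fit.beta * X[:, 1]

                    optimism = bootstrap_optimism(
                        times, events, feats, _fit_and_score,
                        B=config.bootstrap_B, seed=config.seed).optimism
                mod_eval = evaluate_model(
                    f"PREDICT + {name} [{stratum}]", times, events,
                    pred["s10_no_chemo"], pi + adjusted, loglik=multi.loglik)
                mod_eval.c_index_optimism = optimism
                table3_rows.append(mod_eval.to_dict())
                table2_rows.append({
                    "er_stratum": stratum, "signature": name,
                    "hr": multi.hr, "hr_ci": list(multi.hr_ci),
                    "beta": multi.beta, "se": multi.se_beta,
                    "loglik": multi.loglik, "lr_p": multi.lr_p,
                    "c_index": mod_eval.c_index,
                    "c_index_ci": list(mod_eval.c_index_ci),
                    "c_index_optimism": optimism,
                    "rescale_c": c_const,
                    "loglik_univariable": uni.loglik,
                    "lr_p_univariable": uni.lr_p,
                })
                # ---- stage: reclassification --------------------------
                if stratum == "positive" or config.include_er_negative_reclass:
                    cats_a = categorize_benefits(
                        pd.Series(base_pred["benefit_pct"].values, index=pid))
                    cats_b = categorize_benefits(
                        pd.Series(pred["benefit_pct"].values, index=pid))
                    key = name if stratum == "positive" else f"{name} [{stratum}]"
                    reclass_tables[key] = build_table(
                        cats_a, cats_b, model_a="PREDICT", model_b=f"PREDICT + {name}")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"model stage failed (ER-{stratum}): {exc}") from exc

    if table2_rows:
        pd.DataFrame(table2_rows).to_csv(outdir / "table2.csv", index=False)
    if table3_rows:
        pd.DataFrame(table3_rows).to_csv(outdir / "table3.csv", index=False)
    for name, table in reclass_tables.items():
        safe = name.replace(" ", "_").replace("[", "").replace("]", "")
        table.to_frame().to_csv(outdir / f"table4_{safe}.csv")
    reclass_summary = (summarize_all(reclass_tables).to_dict(orient="records")
                       if reclass_tables else [])

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_patients": len(cohort),
        "signatures": [d.name for d in definitions],
        "input_hashes": {
            p: _sha256(p) for p in
            filter(None, [config.clinical_path, config.expression_path])
        },
        "table2": table2_rows,
        "table3": table3_rows,
        "reclassification": reclass_summary,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
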