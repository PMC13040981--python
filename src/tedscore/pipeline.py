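"""End-to-end orchestration: simulate -> screen -> select -> score -> validate.

The discovery stage generates (or ingests) a protein-abundance matrix, runs
the differential-abundance screen and the candidate funnel, and writes the
DAP table and candidate report. The validation stage generates (or ingests) a
patient cohort, fits the penalized logistic path with cross-validated
lambda_min and bootstrap stability, applies the 3-factor composite score, and
reports responder rates, discrimination and the percentile-bootstrap CI. Both
stages are runnable independently; the composite score's components are fixed
a priori and are not gated on the discovery output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np

from . import dap, lasso, roc, score, stats
from .synthetic import (CohortTable, DiscoveryDesign, TED_NONRESPONDER,
                        TED_RESPONDER, ValidationDesign,
                        expand_quartile_fixture, expand_score_fixture,
                        generate_discovery_matrix, generate_validation_cohort,
                        load_fixtures, read_cohort_csv, read_matrix_csv,
                        write_cohort_csv, write_matrix_csv)

__all__ = ["PipelineConfig", "run_discovery", "run_validation",
           "run_fixture_validation", "run_fixture_acceptance"]

log = logging.getLogger("tedscore")

DEFAULT_THRESHOLDS = {
    "fold_change": 2.0,
    "p": 0.05,
    "detection_min": 9,
    "detection_of": 10,
    "fgl2_cutoff": 39.5,
    "tsab_q4_boundary": 2597.0,
}


@dataclass
class PipelineConfig:
    seeds: dict[str, int] = field(default_factory=lambda: {
        "discovery": 0, "cohort": 1, "cv": 2, "bootstrap": 3})
    discovery_design: DiscoveryDesign = field(default_factory=DiscoveryDesign)
    validation_design: ValidationDesign = field(default_factory=ValidationDesign)
    thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    bootstrap_b: int = 1000
    cv_folds: int = 5
    output_dir: str = "tedscore_out"

    def __post_init__(self) -> None:
        missing = {"discovery", "cohort", "cv", "bootstrap"} - set(self.seeds)
        if missing:
            raise ValueError(f"missing seeds: {sorted(missing)}")
        if any(v <= 0 for k, v in self.thresholds.items()):
            raise ValueError("thresholds must be positive")
        if self.bootstrap_b < 1 or self.cv_folds < 2:
            raise ValueError("bootstrap_b >= 1 and cv_folds >= 2 required")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        if "discovery_design" in raw:
            raw["discovery_design"] = DiscoveryDesign(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["discovery_design"].items()})
        if "validation_design" in raw:
            def _t(v):
                return tuple(_t(x) for x in v) if isinstance(v, list) else v
            raw["validation_design"] = ValidationDesign(**{
                k: _t(v) for k, v in raw["validation_design"].items()})
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


# ---------------------------------------------------------------------------
# discovery stage
# ---------------------------------------------------------------------------

def run_discovery(
    config: PipelineConfig,
    matrix=None,
    write: bool = True,
) -> tuple[list[dap.DapRecord], dap.CandidateReport]:
    """Screen a (synthetic or supplied) discovery matrix for candidates.

    Funnel: differential abundance -> DAP status -> Ig-fragment exclusion ->
    detection filter over the TED samples -> four-group specificity filter.
    """
    out = _outdir(config) if write else None
    if matrix is None:
        matrix, truth = generate_discovery_matrix(
            config.discovery_design, config.seeds["discovery"])
        log.info("generated discovery matrix: %d proteins x %d samples "
                 "(%d planted DAPs, %d planted biomarkers)",
                 len(matrix.protein_ids), len(matrix.sample_ids),
                 len(truth["dap_ids"]), len(truth["biomarker_ids"]))
        if write:
            write_matrix_csv(matrix, out / "discovery_matrix")
            (out / "planted_truth.json").write_text(json.dumps(truth, indent=2))

    records = dap.differential_abundance(
        matrix,
        log2_fc_threshold=math.log2(config.thresholds["fold_change"]),
        p_threshold=config.thresholds["p"])
    volcano = dap.volcano_table(records)
    log.info("differential abundance: %d up / %d down / %d not significant",
             volcano["n_up"], volcano["n_down"], volcano["n_ns"])

    dap_ids = {r.protein_id for r in records
               if r.direction != dap.NS}
    n_ted = int(matrix.sample_index([TED_RESPONDER, TED_NONRESPONDER]).sum())
    detected = dap.detection_filter(
        matrix, [TED_RESPONDER, TED_NONRESPONDER],
        int(config.thresholds["detection_min"]), n_ted)
    non_ig = dap.exclude_ig_fragments(matrix.protein_ids, matrix.annotations)
    stage1 = sorted(dap_ids & detected & non_ig)
    log.info("candidate funnel: %d DAPs -> %d after detection filter -> "
             "%d after Ig exclusion (stage 1)",
             len(dap_ids), len(dap_ids & detected), len(stage1))

    report = dap.four_group_filter(matrix, stage1)
    log.info("four-group filter: %d -> %d candidates (stage 2)",
             len(report.stage1_ids), len(report.stage2_ids))
    if write:
        dap.write_dap_csv(records, out / "dap_table.csv")
        volcano["coordinates"].to_csv(out / "volcano.csv", index=False)
        report.to_json(out / "candidate_report.json")
    return records, report


# ---------------------------------------------------------------------------
# validation stage
# ---------------------------------------------------------------------------

def run_validation(
    config: PipelineConfig,
    cohort: CohortTable | None = None,
    write: bool = True,
) -> dict[str, Any]:
    """Penalized selection + composite scoring on a validation cohort."""
    out = _outdir(config) if write else None
    if cohort is None:
        cohort = generate_validation_cohort(
            config.validation_design, config.seeds["cohort"])
        if write:
            write_cohort_csv(cohort, out / "cohort.csv")
    log.info("cohort: %d responders / %d non-responders",
             cohort.n_responders, cohort.n_nonresponders)

    X, y = lasso.cohort_design_matrix(cohort)
    Xs, means, sds = lasso.standardize(X)
    cv = lasso.cv_lambda_min(Xs, y, folds=config.cv_folds,
                             seed=config.seeds["cv"])
    model = lasso.fit_lasso_logistic(Xs, y, cv.lambda_min)
    lasso._back_transform(model, means, sds)
    stability = lasso.bootstrap_stability(Xs, y, config.bootstrap_b,
                                          config.seeds["bootstrap"],
                                          cv.lambda_min)
    log.info("lambda_min=%.5f, non-zero: %s", cv.lambda_min,
             [n for n, c in zip(lasso.PREDICTOR_NAMES, model.coefficients)
              if c != 0.0])

    definition = score.default_score_definition(
        fgl2_cutoff=config.thresholds["fgl2_cutoff"])
    scores = np.array([score.composite_score(r, definition)
                       for r in cohort.records], dtype=float)
    responder = np.array([r.responder for r in cohort.records])
    rate_table = score.responder_rate_by_score(cohort, definition)
    result = score.evaluate_score(scores, responder)
    ci = score.bootstrap_auc_ci(scores, responder, b=config.bootstrap_b,
                                seed=config.seeds["bootstrap"])

    report = {
        "provenance": {"config_hash": config.config_hash(),
                       "seeds": config.seeds,
                       "cohort": cohort.provenance},
        "lasso": {
            "lambda_min": cv.lambda_min,
            "intercept": model.intercept_original,
            "coefficients": {
                n: float(c) for n, c in zip(lasso.PREDICTOR_NAMES,
                                            model.coefficients_original)},
            "selection_frequency": {
                n: float(f) for n, f in zip(lasso.PREDICTOR_NAMES,
                                            stability.selection_frequency)},
            "converged": model.converged,
        },
        "score": {
            "responder_rate_by_score": {
                str(k): {"responders": v[0], "total": v[1], "rate": v[2]}
                for k, v in rate_table.responder_rate_by_score.items()},
            "auc": result.auc,
            "cutoff": result.optimal_cutoff.cutoff,
            "sensitivity": result.optimal_cutoff.sensitivity,
            "specificity": result.optimal_cutoff.specificity,
            "bootstrap_ci": [ci.ci_lower, ci.ci_upper],
            "bootstrap_b": ci.b,
        },
        "warnings": {
            "bootstrap_redraws": ci.n_redrawn + stability.n_redrawn,
            "lasso_converged": model.converged,
        },
    }
    if write:
        (out / "validation_report.json").write_text(
            json.dumps(report, indent=2))
        np.savetxt(out / "bootstrap_auc.csv", ci.auc_samples,
                   header="auc", comments="", delimiter=",")
    return report


def run_fixture_validation(config: PipelineConfig | None = None,
                           write: bool = False) -> dict[str, Any]:
    """Score-level validation on the exact published 31-patient tables."""
    config = config or PipelineConfig()
    bundle = load_fixtures()
    recs = expand_score_fixture(bundle)
    scores = np.array([r[0] for r in recs], dtype=float)
    responder = np.array([r[1] for r in recs])
    result = score.evaluate_score(scores, responder)
    ci = score.bootstrap_auc_ci(scores, responder, b=config.bootstrap_b,
                                seed=config.seeds["bootstrap"])
    report = {
        "provenance": {"cohort": "fixture", "seeds": config.seeds},
        "score": {
            "auc": result.auc,
            "cutoff": result.optimal_cutoff.cutoff,
            "sensitivity": result.optimal_cutoff.sensitivity,
            "specificity": result.optimal_cutoff.specificity,
            "bootstrap_ci": [ci.ci_lower, ci.ci_upper],
            "bootstrap_b": ci.b,
            "responder_rate_by_score": {
                str(k): {"responders": v[0], "total": v[1], "rate": v[2]}
                for k, v in result.responder_rate_by_score.items()},
        },
    }
    if write:
        out = _outdir(config)
        (out / "fixture_report.json").write_text(json.dumps(report, indent=2))
    return report


# ---------------------------------------------------------------------------
# published-value acceptance table
# ---------------------------------------------------------------------------

def run_fixture_acceptance(bootstrap_seed: int = 2025,
                           bootstrap_b: int = 1000) -> list[dict[str, Any]]:
    """Recompute every published-table-anchored quantity and compare.

    Returns one row per check: name, computed, printed, pass flag.
    """
    bundle = load_fixtures()
    srecs = expand_score_fixture(bundle)
    s = np.array([r[0] for r in srecs], dtype=float)
    lab = ~np.array([r[1] for r in srecs])
    qrecs = expand_quartile_fixture(bundle)
    q = np.array([r[0] for r in qrecs], dtype=float)
    qlab = ~np.array([r[1] for r in qrecs])

    curve = roc.roc_curve(s, lab)
    cut = roc.youden_optimal(curve)
    tsab_at_q4 = roc.sens_spec_at(q, qlab, 4)
    ci = score.bootstrap_auc_ci(s, ~lab, b=bootstrap_b, seed=bootstrap_seed)
    smoking_p = stats.chi2_2x2([[3, 18], [5, 5]]).p_value

    rows = [
        ("composite AUC", round(curve.auc, 2), 0.86, "exact"),
        ("composite Youden cutoff", cut.cutoff, 1.0, "exact"),
        ("composite sensitivity", round(cut.sensitivity, 2), 1.0, "exact"),
        ("composite specificity", round(cut.specificity, 2), 0.52, "exact"),
        ("TSAb ordinal AUC", round(roc.auc(q, qlab), 2), 0.71, "exact"),
        ("TSAb sensitivity at Q4", round(tsab_at_q4.sensitivity, 2), 0.50, "exact"),
        ("TSAb specificity at Q4", round(tsab_at_q4.specificity, 2), 0.86, "exact"),
        ("smoking chi-square p", round(smoking_p, 3), 0.034, "exact"),
        ("bootstrap CI lower", round(ci.ci_lower, 2), 0.74, "stochastic"),
        ("bootstrap CI upper", round(ci.ci_upper, 2), 0.96, "stochastic"),
    ]
    table = []
    for name, computed, printed, kind in rows:
        tol = 0.0 if kind == "exact" else 0.03
        table.append({
            "check": name, "computed": computed, "printed": printed,
            "kind": kind, "pass": bool(abs(computed - printed) <= tol),
        })
    return table
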