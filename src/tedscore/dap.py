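"""Discovery-phase screening of differentially abundant proteins (DAPs).

Per-protein differential testing between the two TED arms on log2
intensities (Welch t by default, Mann-Whitney optional), volcano
classification at fold change > 2 (|log2FC| > 1, strict) and p < 0.05, BH
q-values over all tested proteins, and the three-stage candidate filter:

1. DAP status + not an immunoglobulin-derived fragment + consistently
   detected in >= 9 of the 10 TED discovery samples (stage 1);
2. four-group comparison (Kruskal-Wallis then Dunn): a candidate survives only
   when its abundance is significantly higher in non-responders than in
   responders AND than in both control groups (stage 2).

Candidates are selected on nominal p-values; q-values are reported but not
used as a filter (at this arm size FDR control over thousands of proteins is
expected to retain nothing, so the screen is hypothesis-generating by design).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import stats
from .synthetic import (AbundanceMatrix, GRAVES, HEALTHY, TED_NONRESPONDER,
                        TED_RESPONDER)

__all__ = ["DapRecord", "CandidateReport", "differential_abundance",
           "detection_filter", "exclude_ig_fragments", "four_group_filter",
           "volcano_table", "write_dap_csv"]

UP = "up_in_nonresponder"
DOWN = "down_in_nonresponder"
NS = "not_significant"

LOG2_FC_THRESHOLD = 1.0   # fold change > 2, strict
P_THRESHOLD = 0.05


@dataclass(frozen=True)
class DapRecord:
    protein_id: str
    log2_fc: float            # mean(log2 NR) - mean(log2 R), NaN if untestable
    p_value: float            # NaN when untested
    q_value: float
    direction: str
    n_detected: tuple[int, int]  # (responder, non-responder) non-missing counts
    tested: bool


@dataclass(frozen=True)
class CandidateReport:
    stage1_ids: tuple[str, ...]
    stage2_ids: tuple[str, ...]
    four_group_p: dict[str, float]
    posthoc_pass: dict[str, dict[str, bool]]

    def __post_init__(self) -> None:
        if not set(self.stage2_ids) <= set(self.stage1_ids):
            raise ValueError("stage2 candidates must be a subset of stage 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "stage1_ids": list(self.stage1_ids),
            "stage2_ids": list(self.stage2_ids),
            "four_group_p": self.four_group_p,
            "posthoc_pass": self.posthoc_pass,
        }, indent=2))


def _arm_values(matrix: AbundanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    r_cols = matrix.sample_index([TED_RESPONDER])
    nr_cols = matrix.sample_index([TED_NONRESPONDER])
    if not r_cols.any() or not nr_cols.any():
        raise ValueError("matrix must contain both TED arms")
    return r_cols, nr_cols


def differential_abundance(
    matrix: AbundanceMatrix,
    test: str = "welch_t",
    log2_fc_threshold: float = LOG2_FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> list[DapRecord]:
    """Per-protein non-responder vs responder comparison on log2 intensities.

    Proteins with fewer than 2 non-missing values in either arm are reported
    untested (NaN p and q, direction not significant); no imputation is done.
    Both thresholds are strict inequalities.
    """
    if test not in ("welch_t", "mann_whitney"):
        raise ValueError(f"unknown test: {test!r}")
    r_cols, nr_cols = _arm_values(matrix)

    raw: list[dict] = []
    for i, pid in enumerate(matrix.protein_ids):
        row = matrix.values[i]
        xr = row[r_cols]
        xnr = row[nr_cols]
        xr = xr[~np.isnan(xr)]
        xnr = xnr[~np.isnan(xnr)]
        n_det = (int(xr.size), int(xnr.size))
        lfc = float(xnr.mean() - xr.mean()) if xr.size and xnr.size else math.nan
        if xr.size < 2 or xnr.size < 2:
            raw.append(dict(pid=pid, lfc=lfc, p=math.nan, n=n_det, tested=False))
            continue
        if test == "welch_t":
            res = stats.welch_t(xr, xnr)
        else:
            res = stats.mann_whitney_u(xr, xnr, mode="auto")
        raw.append(dict(pid=pid, lfc=lfc, p=res.p_value, n=n_det, tested=True))

    tested_p = [r["p"] for r in raw if r["tested"]]
    q_iter = iter(stats.bh_fdr(tested_p).q_values) if tested_p else iter(())

    records: list[DapRecord] = []
    for r in raw:
        if r["tested"]:
            q = next(q_iter)
            if abs(r["lfc"]) > log2_fc_threshold and r["p"] < p_threshold:
                direction = UP if r["lfc"] > 0 else DOWN
            else:
                direction = NS
        else:
            q = math.nan
            direction = NS
        records.append(DapRecord(r["pid"], r["lfc"], r["p"], q, direction,
                                 r["n"], r["tested"]))
    return records


def detection_filter(
    matrix: AbundanceMatrix,
    group_subset: Sequence[str],
    min_detected: int,
    of_total: int,
) -> set[str]:
    """Proteins with non-missing values in >= min_detected of the subset samples."""
    if not group_subset:
        raise ValueError("group_subset must be non-empty")
    cols = matrix.sample_index(group_subset)
    n_sub = int(cols.sum())
    if of_total != n_sub:
        raise ValueError(f"of_total={of_total} but the subset has {n_sub} samples")
    if min_detected > of_total:
        raise ValueError("min_detected exceeds the subset size")
    detected = (~np.isnan(matrix.values[:, cols])).sum(axis=1)
    return {pid for pid, d in zip(matrix.protein_ids, detected)
            if d >= min_detected}


def exclude_ig_fragments(
    ids: Iterable[str], annotations: dict[str, bool]
) -> set[str]:
    """Drop proteins annotated as immunoglobulin-derived fragments."""
    out = set()
    for pid in ids:
        if pid not in annotations:
            raise ValueError(f"unannotated protein id: {pid}")
        if not annotations[pid]:
            out.add(pid)
    return out


def four_group_filter(
    matrix: AbundanceMatrix, candidate_ids: Iterable[str]
) -> CandidateReport:
    """Kruskal-Wallis + Dunn across the four groups for each candidate.

    A candidate passes when the omnibus p < 0.05 and the non-responder arm
    sits significantly above responders, Graves' patients and healthy
    controls: one-sided Dunn contrasts (the hypothesis is directional),
    BH-adjusted over the three non-responder-versus-other comparisons — the
    family the filter actually consults. The power ceiling here is low by
    design of the experiment, not of the code: against a control arm of 3
    samples the Dunn z cannot exceed ~2.2 even under complete separation, so
    adjusting two-sided over all six pairs would make the filter
    unsatisfiable, and even the directional version fails a sizeable
    fraction of genuinely elevated proteins.
    """
    order = (TED_NONRESPONDER, TED_RESPONDER, GRAVES, HEALTHY)
    col_masks = [matrix.sample_index([g]) for g in order]
    if any(not m.any() for m in col_masks):
        raise ValueError("matrix must contain all four groups")

    candidate_ids = list(candidate_ids)
    known = set(matrix.protein_ids)
    missing = [c for c in candidate_ids if c not in known]
    if missing:
        raise ValueError(f"candidate ids absent from matrix: {missing}")

    four_group_p: dict[str, float] = {}
    posthoc_pass: dict[str, dict[str, bool]] = {}
    stage2: list[str] = []
    for pid in candidate_ids:
        row = matrix.row(pid)
        groups = []
        for m in col_masks:
            vals = row[m]
            vals = vals[~np.isnan(vals)]
            groups.append(vals)
        if any(g.size == 0 for g in groups):
            four_group_p[pid] = math.nan
            posthoc_pass[pid] = {}
            continue
        kw = stats.kruskal_wallis(groups)
        four_group_p[pid] = kw.p_value
        table = stats.dunn_posthoc(groups, adjustment="none")
        # pairs are indexed into `order`; NR is group 0, so NR-vs-X pairs are
        # (0, j) and a positive z means the NR rank mean is higher
        nr_pairs = [(pair, z) for pair, z in
                    zip(table.pairs, table.statistics) if pair[0] == 0]
        one_sided = [float(ndtr(-z)) for _, z in nr_pairs]  # H1: NR higher
        adj = stats.bh_fdr(one_sided).q_values
        flags: dict[str, bool] = {}
        for ((_, j), z), p_adj in zip(nr_pairs, adj):
            flags[f"nr_gt_{order[j].lower()}"] = bool(z > 0 and p_adj < 0.05)
        posthoc_pass[pid] = flags
        if kw.p_value < 0.05 and flags and all(flags.values()):
            stage2.append(pid)

    return CandidateReport(tuple(candidate_ids), tuple(stage2),
                           four_group_p, posthoc_pass)


def volcano_table(records: Sequence[DapRecord]) -> dict:
    """Direction counts plus (log2FC, -log10 p) coordinates for plotting."""
    n_up = sum(r.direction == UP for r in records)
    n_down = sum(r.direction == DOWN for r in records)
    n_ns = sum(r.direction == NS for r in records)
    coords = pd.DataFrame({
        "protein_id": [r.protein_id for r in records],
        "log2_fc": [r.log2_fc for r in records],
        "neg_log10_p": [-math.log10(r.p_value)
                        if r.tested and r.p_value > 0 else math.nan
                        for r in records],
        "direction": [r.direction for r in records],
    })
    return {"n_up": n_up, "n_down": n_down, "n_ns": n_ns, "coordinates": coords}


def write_dap_csv(records: Sequence[DapRecord], path: str | Path) -> None:
    pd.DataFrame([{
        "protein_id": r.protein_id,
        "log2_fc": r.log2_fc,
        "p_value": r.p_value,
        "q_value": r.q_value,
        "direction": r.direction,
        "n_detected_responder": r.n_detected[0],
        "n_detected_nonresponder": r.n_detected[1],
        "tested": int(r.tested),
    } for r in records]).to_csv(path, index=False)
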