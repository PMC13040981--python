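"""Synthetic discovery matrices, synthetic validation cohorts, and the exact
published summary tables used as fixtures.

Two generators cover the two phases of the study design:

* :func:`generate_discovery_matrix` emulates a serum DIA-proteomics
  quantification table — proteins x samples log2 intensities across four
  groups (healthy controls, Graves' disease, TED responders, TED
  non-responders to intravenous glucocorticoids) — with planted differentially
  abundant proteins, planted non-responder-specific biomarkers,
  immunoglobulin-fragment annotations, and intensity-dependent logistic
  dropout.

* :func:`generate_validation_cohort` emulates the ELISA validation cohort —
  per-patient serum FGL2 concentration, thyroid-stimulating-antibody (TSAb)
  quartile, smoking, thyroid status, age, sex, and the binary responder
  outcome — with group-separated FGL2 and outcome-conditional categorical
  frequencies.

:func:`load_fixtures` returns the published score-by-outcome, TSAb-quartile,
smoking and FGL2 summary tables verbatim, so that the downstream ROC/score
machinery can be exercised on the exact 31-patient validation cohort those
tables describe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HEALTHY", "GRAVES", "TED_RESPONDER", "TED_NONRESPONDER", "GROUPS",
    "TSAB_QUARTILE_BOUNDS",
    "AbundanceMatrix", "PatientRecord", "CohortTable",
    "DiscoveryDesign", "ValidationDesign", "FixtureBundle",
    "generate_discovery_matrix", "generate_validation_cohort",
    "load_fixtures", "expand_score_fixture", "expand_quartile_fixture",
    "tsab_quartile_of", "write_matrix_csv", "read_matrix_csv",
    "write_cohort_csv", "read_cohort_csv",
]

HEALTHY = "HEALTHY"
GRAVES = "GRAVES"
TED_RESPONDER = "TED_RESPONDER"
TED_NONRESPONDER = "TED_NONRESPONDER"
GROUPS = (TED_RESPONDER, TED_NONRESPONDER, GRAVES, HEALTHY)

# TSAb quartile boundaries (%) as fixed constants: Q1 <= 489, Q2 490-984,
# Q3 985-2597, Q4 > 2597 (upper cap used when simulating continuous values).
TSAB_QUARTILE_BOUNDS = (489.0, 984.0, 2597.0)
TSAB_CAP = 10_000.0


def tsab_quartile_of(tsab_percent: float) -> int:
    """Quartile (1-4) of a TSAb titer under the fixed boundaries."""
    for q, bound in enumerate(TSAB_QUARTILE_BOUNDS, start=1):
        if tsab_percent <= bound:
            return q
    return 4


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """Proteins x samples log2-intensity table with missingness (NaN).

    ``annotations`` maps protein id -> is_ig_fragment; ``sample_groups`` holds
    one label from :data:`GROUPS` per sample.
    """

    protein_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_proteins, n_samples), NaN = missing
    annotations: dict[str, bool]
    sample_groups: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match id lists")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("protein ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if len(self.sample_groups) != len(self.sample_ids):
            raise ValueError("one group label per sample required")
        bad = set(self.sample_groups) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    def sample_index(self, groups: Sequence[str]) -> np.ndarray:
        wanted = set(groups)
        return np.array([g in wanted for g in self.sample_groups])

    def row(self, protein_id: str) -> np.ndarray:
        return self.values[self.protein_ids.index(protein_id)]


@dataclass(frozen=True)
class PatientRecord:
    """One validation-cohort patient."""

    fgl2: float                    # serum FGL2, ng/mL
    tsab_quartile: int             # 1..4 under the fixed boundaries
    smoking: bool                  # current smoker
    hyperthyroid: bool
    age: float                     # years
    female: bool
    responder: bool
    tsab_percent: float | None = None

    def __post_init__(self) -> None:
        if self.fgl2 < 0:
            raise ValueError("FGL2 concentration must be non-negative")
        if self.tsab_quartile not in (1, 2, 3, 4):
            raise ValueError("TSAb quartile must be in 1..4")
        if self.tsab_percent is not None:
            if tsab_quartile_of(self.tsab_percent) != self.tsab_quartile:
                raise ValueError("TSAb quartile inconsistent with titer")


@dataclass(frozen=True)
class CohortTable:
    records: tuple[PatientRecord, ...]
    provenance: str = "synthetic"  # "synthetic" | "fixture"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("cohort must be non-empty")

    @property
    def n_responders(self) -> int:
        return sum(r.responder for r in self.records)

    @property
    def n_nonresponders(self) -> int:
        return len(self.records) - self.n_responders


@dataclass(frozen=True)
class DiscoveryDesign:
    """Configuration of the synthetic discovery (proteomics) experiment.

    Defaults emulate the study's 6 responder / 4 non-responder / 3 Graves /
    3 healthy design at a 2,000-protein desk scale, with 50 planted
    differentially abundant proteins at |log2 effect| 2 and 3 planted
    biomarkers elevated in non-responders only.
    """

    n_proteins: int = 2000
    group_sizes: tuple[int, int, int, int] = (6, 4, 3, 3)  # R, NR, GD, HC
    n_planted_dap: int = 50
    planted_log2_effect: float = 2.0
    n_biomarker: int = 3
    ig_fraction: float = 0.10
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.5
    dropout_midpoint: float | None = 15.0  # None disables dropout
    dropout_steepness: float = 1.0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if self.group_sizes[0] <= 0 or self.group_sizes[1] <= 0:
            raise ValueError("both TED arms need at least one sample")
        if any(g < 0 for g in self.group_sizes):
            raise ValueError("group sizes must be non-negative")
        if self.n_planted_dap + self.n_biomarker > self.n_proteins:
            raise ValueError("planted effect counts exceed n_proteins")
        if self.baseline_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.ig_fraction <= 1.0:
            raise ValueError("ig_fraction must lie in [0, 1]")


#: per-outcome parameters reproduce the published validation cohort:
#: FGL2 means/SDs from the ELISA summary, categorical frequencies and age from
#: the background-characteristics table (responders n=21, non-responders n=10).
@dataclass(frozen=True)
class ValidationDesign:
    n_per_outcome: tuple[int, int] = (21, 10)  # (responders, non-responders)
    fgl2_params: tuple[tuple[float, float], tuple[float, float]] = (
        (27.8, 17.8),  # responders: mean, sd ng/mL
        (44.8, 18.0),  # non-responders
    )
    fgl2_family: str = "lognormal_moment_matched"
    tsab_quartile_probs: tuple[tuple[float, ...], tuple[float, ...]] = (
        (7 / 21, 5 / 21, 6 / 21, 3 / 21),
        (1 / 10, 2 / 10, 2 / 10, 5 / 10),
    )
    smoking_prob: tuple[float, float] = (3 / 21, 5 / 10)
    hyperthyroid_prob: tuple[float, float] = (3 / 21, 5 / 10)
    age_params: tuple[tuple[float, float], tuple[float, float]] = (
        (54.0, 14.0), (47.0, 13.0)
    )
    female_prob: tuple[float, float] = (12 / 21, 5 / 10)

    def __post_init__(self) -> None:
        if self.fgl2_family not in ("truncated_normal", "lognormal_moment_matched"):
            raise ValueError(f"unknown fgl2_family: {self.fgl2_family!r}")
        if min(self.n_per_outcome) <= 0:
            raise ValueError("both outcome arms need at least one patient")
        for mean, sd in self.fgl2_params + self.age_params:
            if sd < 0:
                raise ValueError("negative sd")
        for probs in self.tsab_quartile_probs:
            if len(probs) != 4 or any(p < 0 for p in probs):
                raise ValueError("quartile probabilities must be a 4-vector >= 0")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("quartile probabilities must sum to 1")
        for p_pair in (self.smoking_prob, self.hyperthyroid_prob, self.female_prob):
            if any(not 0.0 <= p <= 1.0 for p in p_pair):
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class FixtureBundle:
    """Published summary tables, each as (responders, non-responders) counts."""

    score_outcome_table: dict[int, tuple[int, int]]
    tsab_quartile_table: dict[int, tuple[int, int]]
    smoking_table: tuple[tuple[int, int], tuple[int, int]]  # rows: non/smoker? see load_fixtures
    fgl2_summary: dict[str, tuple[int, float, float]]


# ---------------------------------------------------------------------------
# discovery-phase generator
# ---------------------------------------------------------------------------

def generate_discovery_matrix(
    design: DiscoveryDesign, seed: int
) -> tuple[AbundanceMatrix, dict[str, list[str]]]:
    """Seeded synthetic proteomics matrix plus ground-truth planted ids.

    Model per entry: value = protein baseline N(baseline_mean, baseline_sd)
    + group effect + N(0, noise_sd). Planted DAPs are shifted by
    +/-planted_log2_effect in non-responder samples (alternating sign);
    planted biomarkers are shifted upward in non-responders only, so they
    differ from responders AND both control groups. Each entry then drops out
    independently with probability logistic in its true intensity (lower
    intensity -> more missing).

    Returns ``(matrix, truth)`` with ``truth = {"dap_ids": [...],
    "biomarker_ids": [...]}`` (biomarkers are not double-counted as DAPs).
    """
    rng = np.random.default_rng(seed)
    n = design.n_proteins
    n_r, n_nr, n_gd, n_hc = design.group_sizes
    sample_ids = (
        [f"R{i+1}" for i in range(n_r)]
        + [f"NR{i+1}" for i in range(n_nr)]
        + [f"GD{i+1}" for i in range(n_gd)]
        + [f"HC{i+1}" for i in range(n_hc)]
    )
    groups = ([TED_RESPONDER] * n_r + [TED_NONRESPONDER] * n_nr
              + [GRAVES] * n_gd + [HEALTHY] * n_hc)
    protein_ids = [f"P{i:05d}" for i in range(n)]

    chosen = rng.choice(n, size=design.n_planted_dap + design.n_biomarker,
                        replace=False)
    dap_idx = chosen[: design.n_planted_dap]
    bio_idx = chosen[design.n_planted_dap :]

    baseline = rng.normal(design.baseline_mean, design.baseline_sd, size=n)
    effect = np.zeros((n, len(sample_ids)))
    nr_cols = np.array([g == TED_NONRESPONDER for g in groups])
    for k, i in enumerate(dap_idx):
        sign = 1.0 if k % 2 == 0 else -1.0
        effect[i, nr_cols] = sign * design.planted_log2_effect
    for i in bio_idx:
        effect[i, nr_cols] = design.planted_log2_effect

    true_intensity = baseline[:, None] + effect
    values = true_intensity + rng.normal(0.0, design.noise_sd,
                                         size=true_intensity.shape)

    if design.dropout_midpoint is not None:
        # decreasing logistic in intensity: P(missing) = expit(-s*(x - mid))
        p_miss = 1.0 / (1.0 + np.exp(
            design.dropout_steepness * (true_intensity - design.dropout_midpoint)
        ))
        values = np.where(rng.random(values.shape) < p_miss, np.nan, values)

    # Ig-fragment flags drawn from non-biomarker proteins (planted biomarkers
    # are, by construction, the non-Ig candidates the screen should recover)
    n_ig = int(round(design.ig_fraction * n))
    eligible = np.setdiff1d(np.arange(n), bio_idx)
    ig_idx = rng.choice(eligible, size=min(n_ig, len(eligible)), replace=False)
    ig_flags = np.zeros(n, dtype=bool)
    ig_flags[ig_idx] = True
    annotations = {pid: bool(flag) for pid, flag in zip(protein_ids, ig_flags)}

    matrix = AbundanceMatrix(protein_ids, sample_ids, values, annotations, groups)
    truth = {
        "dap_ids": [protein_ids[i] for i in sorted(dap_idx)],
        "biomarker_ids": [protein_ids[i] for i in sorted(bio_idx)],
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# validation-phase generator
# ---------------------------------------------------------------------------

def _draw_fgl2(rng: np.random.Generator, mean: float, sd: float,
               family: str, size: int) -> np.ndarray:
    if sd == 0.0:
        return np.full(size, mean)
    if family == "lognormal_moment_matched":
        mu = math.log(mean**2 / math.sqrt(mean**2 + sd**2))
        sigma = math.sqrt(math.log(1.0 + sd**2 / mean**2))
        return rng.lognormal(mu, sigma, size=size)
    # truncated normal by redraw (rejection), avoiding a point mass at 0
    out = rng.normal(mean, sd, size=size)
    while True:
        neg = out < 0
        if not neg.any():
            return out
        out[neg] = rng.normal(mean, sd, size=int(neg.sum()))


def generate_validation_cohort(design: ValidationDesign, seed: int) -> CohortTable:
    """Seeded synthetic ELISA validation cohort.

    FGL2 is drawn independently of TSAb within each outcome arm (the two
    markers were reported uncorrelated), so the composite score's components
    carry independent information in the synthetic cohort.
    """
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    for arm, responder in ((0, True), (1, False)):
        n = design.n_per_outcome[arm]
        mean, sd = design.fgl2_params[arm]
        fgl2 = _draw_fgl2(rng, mean, sd, design.fgl2_family, n)
        quartiles = rng.choice(4, size=n, p=design.tsab_quartile_probs[arm]) + 1
        # continuous titer drawn uniformly within the drawn quartile's bounds
        lows = np.array([0.0, *TSAB_QUARTILE_BOUNDS])
        highs = np.array([*TSAB_QUARTILE_BOUNDS, TSAB_CAP])
        tsab = rng.uniform(lows[quartiles - 1], highs[quartiles - 1])
        smoking = rng.random(n) < design.smoking_prob[arm]
        hyper = rng.random(n) < design.hyperthyroid_prob[arm]
        female = rng.random(n) < design.female_prob[arm]
        age = rng.normal(*design.age_params[arm], size=n)
        for i in range(n):
            records.append(PatientRecord(
                fgl2=float(fgl2[i]),
                tsab_quartile=int(quartiles[i]),
                tsab_percent=float(tsab[i]),
                smoking=bool(smoking[i]),
                hyperthyroid=bool(hyper[i]),
                age=float(age[i]),
                female=bool(female[i]),
                responder=responder,
            ))
    return CohortTable(tuple(records), provenance="synthetic", seed=seed)


# ---------------------------------------------------------------------------
# published fixtures
# ---------------------------------------------------------------------------

def load_fixtures() -> FixtureBundle:
    """The published validation summary tables, verbatim.

    * score_outcome_table: (responders, non-responders) at composite score
      0..3 — 11/0, 9/5, 1/3, 0/2 (totals 21 and 10).
    * tsab_quartile_table: quartile -> (responders, non-responders).
    * smoking_table: rows (responders, non-responders) x columns
      (non-smoker, smoker).
    * fgl2_summary: group -> (n, mean ng/mL, sd ng/mL) from the ELISA panel.
    """
    bundle = FixtureBundle(
        score_outcome_table={0: (11, 0), 1: (9, 5), 2: (1, 3), 3: (0, 2)},
        tsab_quartile_table={1: (7, 1), 2: (5, 2), 3: (6, 2), 4: (3, 5)},
        smoking_table=((18, 3), (5, 5)),
        fgl2_summary={
            "healthy": (14, 17.5, 11.2),
            "graves": (14, 21.1, 17.2),
            "responder": (21, 27.8, 17.8),
            "non_responder": (10, 44.8, 18.0),
        },
    )
    _check_fixture_totals(bundle)
    return bundle


def _check_fixture_totals(bundle: FixtureBundle) -> None:
    r = sum(v[0] for v in bundle.score_outcome_table.values())
    nr = sum(v[1] for v in bundle.score_outcome_table.values())
    if (r, nr) != (21, 10):
        raise ValueError("score table totals must be 21 responders / 10 non-responders")
    r = sum(v[0] for v in bundle.tsab_quartile_table.values())
    nr = sum(v[1] for v in bundle.tsab_quartile_table.values())
    if (r, nr) != (21, 10):
        raise ValueError("quartile table totals must be 21 / 10")
    if sum(bundle.smoking_table[0]) + sum(bundle.smoking_table[1]) != 31:
        raise ValueError("smoking table must total 31 patients")


def expand_score_fixture(
    bundle: FixtureBundle,
) -> list[tuple[int, bool]]:
    """One (composite score, responder) record per patient, 31 in total."""
    for score, (n_r, n_nr) in bundle.score_outcome_table.items():
        if n_r < 0 or n_nr < 0:
            raise ValueError("inconsistent fixture counts")
    out: list[tuple[int, bool]] = []
    for score in sorted(bundle.score_outcome_table):
        n_r, n_nr = bundle.score_outcome_table[score]
        out.extend((score, True) for _ in range(n_r))
        out.extend((score, False) for _ in range(n_nr))
    return out


def expand_quartile_fixture(
    bundle: FixtureBundle,
) -> list[tuple[int, bool]]:
    """One (TSAb quartile, responder) record per patient, ordinal score 1-4."""
    out: list[tuple[int, bool]] = []
    for q in sorted(bundle.tsab_quartile_table):
        n_r, n_nr = bundle.tsab_quartile_table[q]
        out.extend((q, True) for _ in range(n_r))
        out.extend((q, False) for _ in range(n_nr))
    return out


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def write_matrix_csv(matrix: AbundanceMatrix, prefix: str | Path) -> None:
    """Write the matrix trio: <prefix>.csv (intensities, empty cell = missing),
    <prefix>.annotations.csv and <prefix>.groups.csv."""
    prefix = Path(prefix)
    df = pd.DataFrame(matrix.values, index=matrix.protein_ids,
                      columns=matrix.sample_ids)
    df.index.name = "protein_id"
    df.to_csv(prefix.with_suffix(".csv"))
    ann = pd.DataFrame({
        "protein_id": matrix.protein_ids,
        "is_ig_fragment": [int(matrix.annotations[p]) for p in matrix.protein_ids],
    })
    ann.to_csv(prefix.with_suffix(".annotations.csv"), index=False)
    grp = pd.DataFrame({"sample_id": matrix.sample_ids,
                        "group": matrix.sample_groups})
    grp.to_csv(prefix.with_suffix(".groups.csv"), index=False)


def read_matrix_csv(prefix: str | Path) -> AbundanceMatrix:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".csv"), index_col="protein_id")
    ann = pd.read_csv(prefix.with_suffix(".annotations.csv"))
    grp = pd.read_csv(prefix.with_suffix(".groups.csv"))
    annotations = {str(r.protein_id): bool(r.is_ig_fragment)
                   for r in ann.itertuples()}
    groups_by_sample = {str(r.sample_id): str(r.group) for r in grp.itertuples()}
    sample_ids = [str(c) for c in df.columns]
    return AbundanceMatrix(
        protein_ids=[str(i) for i in df.index],
        sample_ids=sample_ids,
        values=df.to_numpy(dtype=float),
        annotations=annotations,
        sample_groups=[groups_by_sample[s] for s in sample_ids],
    )


COHORT_COLUMNS = ["fgl2_ng_ml", "tsab_percent", "tsab_quartile", "smoking",
                  "hyperthyroid", "age", "female", "responder"]


def write_cohort_csv(cohort: CohortTable, path: str | Path) -> None:
    rows = []
    for r in cohort.records:
        rows.append({
            "fgl2_ng_ml": r.fgl2,
            "tsab_percent": "" if r.tsab_percent is None else r.tsab_percent,
            "tsab_quartile": r.tsab_quartile,
            "smoking": int(r.smoking),
            "hyperthyroid": int(r.hyperthyroid),
            "age": r.age,
            "female": int(r.female),
            "responder": int(r.responder),
        })
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def read_cohort_csv(path: str | Path, provenance: str = "synthetic") -> CohortTable:
    df = pd.read_csv(path)
    records = []
    for r in df.itertuples():
        tsab = getattr(r, "tsab_percent", None)
        tsab = None if tsab is None or (isinstance(tsab, float) and math.isnan(tsab)) else float(tsab)
        records.append(PatientRecord(
            fgl2=float(r.fgl2_ng_ml),
            tsab_percent=tsab,
            tsab_quartile=int(r.tsab_quartile),
            smoking=bool(r.smoking),
            hyperthyroid=bool(r.hyperthyroid),
            age=float(r.age),
            female=bool(r.female),
            responder=bool(r.responder),
        ))
    return CohortTable(tuple(records), provenance=provenance)
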