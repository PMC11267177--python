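"""Synthetic claims-data generator with known comorbidity ground truth.

Emits a longitudinal visit-level EMR table shaped like a national
claims-database extract: heart-failure cases carry a target-code (428x)
emergency/inpatient record at their index date; every subject carries each
comorbidity category independently, controls with their specified baseline
prevalence and cases with the probability implied by a planted odds ratio,

    p_case = OR * odds_ctrl / (1 + OR * odds_ctrl),   odds_ctrl = p/(1-p),

so the generator's case-control odds ratio per code is exactly the planted
value in expectation.  Each carried category becomes one or two dated visit
records inside the lead window before the index date.  The default cohort
mirrors the source database's scale (8500 cases, 21786 controls, ~1:2.56)
and the default universe spans 122 categories: twelve strong signals (odds
ratios 2-12), thirty mild ones straddling the feature-selection threshold,
and eighty null codes.  A lognormal subject-level utilization factor (and,
optionally, within-block correlation) gives subjects the overdispersed
code burdens characteristic of claims data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .emr import Cohort, EMRTable
from .stats import alpha_index, contingency, odds_ratio, prevalence

__all__ = [
    "SimSpec",
    "GroundTruth",
    "default_code_table",
    "generate_cohort",
    "recover_planted_effects",
]

# Strongly HF-associated categories: (control prevalence, planted odds ratio),
# mirroring the geometry of published claims-data feature tables (rare codes
# with large ORs, prevalent codes with moderate ones).
_STRONG = {
    "514": (0.02, 12.0),
    "425": (0.01, 8.0),
    "410": (0.03, 6.0),
    "518": (0.05, 6.0),
    "412": (0.02, 5.0),
    "403": (0.05, 4.0),
    "584": (0.03, 3.5),
    "427": (0.08, 3.0),
    "511": (0.04, 2.5),
    "414": (0.12, 2.5),
    "250": (0.15, 2.0),
    "496": (0.06, 2.0),
}
# Mildly associated cardiometabolic/renal/pulmonary neighbours: true ORs
# straddle the selection threshold of 2, so their inclusion is stochastic.
_MILD_CODES = [
    "244", "272", "274", "276", "278", "285", "305", "327", "332", "340",
    "345", "357", "362", "365", "386", "401", "416", "424", "426", "433",
    "437", "440", "443", "453", "458", "482", "486", "491", "585", "593",
]
_MILD_ORS = [1.3, 1.6, 1.9, 2.1, 2.4]
_MILD_PREV = [0.015, 0.03, 0.06, 0.10, 0.18]
# Null background: codes unrelated to HF at a spread of baseline prevalences.
_NULL_CODES = [
    "009", "034", "041", "053", "070", "078", "110", "117", "131", "135",
    "153", "174", "185", "193", "211", "216", "226", "235", "300", "311",
    "346", "366", "372", "380", "381", "388", "389", "461", "462", "465",
    "473", "477", "490", "530", "531", "535", "550", "558", "564", "571",
    "574", "575", "590", "592", "595", "599", "600", "611", "616", "620",
    "680", "682", "691", "692", "696", "700", "703", "704", "706", "708",
    "715", "716", "719", "721", "722", "723", "724", "726", "727", "729",
    "780", "781", "784", "786", "787", "788", "789", "790", "795", "924",
]
_NULL_PREV = [0.003, 0.006, 0.01, 0.02, 0.04, 0.08, 0.15]
_FILLER_CODE = "V700"  # routine-exam visit for subjects carrying no study code
_TARGET_CODE = "4280"


def default_code_table() -> dict[str, tuple[float, float]]:
    """Default (control prevalence, planted OR) per comorbidity category.

    122 categories: 12 strongly associated, 30 mild (ORs 1.3-2.4) and 80
    null, cycling through fixed prevalence ladders — a desk-scale sketch of
    the 999-category single-disease landscape the method targets.
    """
    table = dict(_STRONG)
    for i, code in enumerate(_MILD_CODES):
        table[code] = (_MILD_PREV[i % len(_MILD_PREV)], _MILD_ORS[i % len(_MILD_ORS)])
    for i, code in enumerate(_NULL_CODES):
        table[code] = (_NULL_PREV[i % len(_NULL_PREV)], 1.0)
    return table


@dataclass(frozen=True)
class SimSpec:
    """Shape and ground truth of a simulated case-control claims cohort."""

    n_cases: int = 8500
    n_controls: int = 21786
    control_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {c: p for c, (p, _) in default_code_table().items()}
    )
    planted_or: Mapping[str, float] = field(
        default_factory=lambda: {c: o for c, (_, o) in default_code_table().items()}
    )
    lead_years: int = 1
    sex_split: float = 0.493  # proportion male
    age_distribution: tuple[float, float] = (58.0, 16.0)  # mean, sd (years)
    visit_type_mix: tuple[float, float, float] = (0.70, 0.10, 0.20)  # out/emerg/inpat
    index_date: str = "2012-07-01"
    utilization_sd: float = 1.0  # SD of the lognormal subject effect on carriage odds
    block_correlation: float = 0.0  # within-disease-block carriage correlation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("cohort sizes must be positive")
        if set(self.planted_or) != set(self.control_prevalence):
            raise ValueError("planted_or and control_prevalence must share codes")
        for code, p in self.control_prevalence.items():
            if not 0 < p < 1:
                raise ValueError(f"control prevalence for {code} must be in (0,1)")
            if self.planted_or[code] <= 0:
                raise ValueError(f"planted OR for {code} must be positive")
        if not 0 <= self.sex_split <= 1:
            raise ValueError("sex_split must be in [0,1]")
        if not 0 <= self.block_correlation < 1:
            raise ValueError("block_correlation must be in [0,1)")
        if self.utilization_sd < 0:
            raise ValueError("utilization_sd must be non-negative")

    @property
    def codes(self) -> list[str]:
        return sorted(self.control_prevalence)

    def case_prevalence(self, code: str) -> float:
        """Invert the odds relation: the case carriage probability a planted
        OR implies given the control baseline."""
        p = self.control_prevalence[code]
        o = self.planted_or[code] * p / (1 - p)
        pc = o / (1 + o)
        if pc >= 1:
            raise ValueError(f"derived case prevalence for {code} reaches 1")
        return pc


@dataclass
class GroundTruth:
    """What was planted and what was realised, recomputable from the EMR."""

    spec: SimSpec
    subjects: pd.DataFrame  # subject_id, label, index_date, sex, age
    carriage: pd.DataFrame  # subject_id x code boolean matrix

    def realized_prevalence(self, code: str) -> tuple[float, float]:
        is_case = (self.subjects["label"] == "case").to_numpy()
        col = self.carriage[code].to_numpy()
        return float(col[is_case].mean()), float(col[~is_case].mean())

    def realized_or(self, code: str, correction: float = 0.5) -> float:
        is_case = (self.subjects["label"] == "case").to_numpy()
        col = self.carriage[code].to_numpy()
        a = int(col[is_case].sum())
        b = int(col[~is_case].sum())
        c = int(is_case.sum()) - a
        d = int((~is_case).sum()) - b
        from .stats import TwoByTwo

        return odds_ratio(TwoByTwo(a, b, c, d), correction)


def generate_cohort(spec: SimSpec) -> tuple[EMRTable, GroundTruth]:
    """Simulate the claims table and its ground truth; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases + spec.n_controls
    index_date = pd.Timestamp(spec.index_date)
    lead_days = 365 * spec.lead_years

    sids = np.array([f"P{i:06d}" for i in range(n)])
    labels = np.array(["case"] * spec.n_cases + ["control"] * spec.n_controls)
    sex = np.where(rng.random(n) < spec.sex_split, "M", "F")
    mean, sd = spec.age_distribution
    age = mean + sd * rng.standard_normal(n)
    while True:  # truncate to [20, 95] by redrawing
        out = (age < 20) | (age > 95)
        if not out.any():
            break
        age[out] = mean + sd * rng.standard_normal(int(out.sum()))
    birth = index_date - pd.to_timedelta(np.round(age * 365.25).astype(int), unit="D")

    codes = spec.codes
    p = np.empty((n, len(codes)))
    for j, code in enumerate(codes):
        pc, p0 = spec.case_prevalence(code), spec.control_prevalence[code]
        p[:, j] = np.where(labels == "case", pc, p0)
    if spec.utilization_sd > 0:
        # Healthcare-utilization heterogeneity: a lognormal subject factor
        # (median 1, identically distributed in both groups) multiplies every
        # carriage odds, so recorded diagnosis burden varies across subjects
        # the way claims data do.  Null codes stay null; planted ORs for
        # associated codes are attenuated somewhat at the margin, as in real
        # overdispersed data.
        u = np.exp(spec.utilization_sd * rng.standard_normal(n))[:, None]
        odds = p / (1 - p) * u
        p = odds / (1 + odds)
    if spec.block_correlation > 0:
        # Shared latent Bernoulli factor per ICD disease block: with weight
        # rho a code fires only when its block is "active" (prob pi), with
        # weight 1-rho it fires independently; the marginal carriage
        # probability (hence the planted OR) is preserved in expectation.
        from .emr import default_group_map

        gm = default_group_map()
        blocks = np.array([gm.lookup(c) for c in codes])
        pi, rho = 0.3, spec.block_correlation
        p_eff = np.empty_like(p)
        for blk in np.unique(blocks):
            cols = blocks == blk
            z = (rng.random(n) < pi).astype(float)[:, None]
            p_eff[:, cols] = np.clip(
                (1 - rho) * p[:, cols] + rho * z * p[:, cols] / pi, 0.0, 1.0
            )
        carried = rng.random((n, len(codes))) < p_eff
    else:
        carried = rng.random((n, len(codes))) < p

    vt_names = np.array(["outpatient", "emergency", "inpatient"])
    rows: list[dict] = []
    subj_idx, code_idx = np.nonzero(carried)
    n_rec = np.where(rng.random(len(subj_idx)) < 0.2, 2, 1)  # occasional duplicate
    for (i, j, reps) in zip(subj_idx, code_idx, n_rec):
        for _ in range(reps):
            day = int(rng.integers(1, lead_days + 1))
            code = codes[j]
            if rng.random() < 0.5:  # emit at 4-digit depth half the time
                code = code + str(rng.integers(0, 10))
            rows.append(
                {
                    "subject_id": sids[i],
                    "sex": sex[i],
                    "birth_date": birth[i],
                    "visit_date": index_date - pd.Timedelta(days=day),
                    "visit_type": vt_names[rng.choice(3, p=spec.visit_type_mix)],
                    "icd9_code": code,
                }
            )
    # cases: the qualifying target-code record at the index date
    emerg_share = spec.visit_type_mix[1] / (spec.visit_type_mix[1] + spec.visit_type_mix[2])
    for i in range(spec.n_cases):
        rows.append(
            {
                "subject_id": sids[i],
                "sex": sex[i],
                "birth_date": birth[i],
                "visit_date": index_date,
                "visit_type": "emergency" if rng.random() < emerg_share else "inpatient",
                "icd9_code": _TARGET_CODE,
            }
        )
    # controls carrying nothing still need a record to exist in the table
    seen = set(sids[subj_idx]) | set(sids[: spec.n_cases])
    for i in range(n):
        if sids[i] not in seen:
            rows.append(
                {
                    "subject_id": sids[i],
                    "sex": sex[i],
                    "birth_date": birth[i],
                    "visit_date": index_date - pd.Timedelta(days=int(rng.integers(1, lead_days + 1))),
                    "visit_type": "outpatient",
                    "icd9_code": _FILLER_CODE,
                }
            )

    df = (
        pd.DataFrame(rows)
        .sort_values(["subject_id", "visit_date", "icd9_code"], kind="mergesort")
        .reset_index(drop=True)
    )
    emr = EMRTable(df)
    truth = GroundTruth(
        spec=spec,
        subjects=pd.DataFrame(
            {
                "subject_id": sids,
                "label": labels,
                "index_date": index_date,
                "sex": sex,
                "age": age,
            }
        ),
        carriage=pd.DataFrame(carried, columns=codes).assign(subject_id=sids)
        .set_index("subject_id")[codes],
    )
    return emr, truth


def recover_planted_effects(
    cohort: Cohort,
    truth: GroundTruth,
    or_min: float = 2.0,
    prevalence_min: float = 0.01,
    correction: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Estimate each planted effect from a built cohort and summarise recovery.

    Returns a per-code table (planted vs estimated OR, relative error,
    selection flag) and a summary with the planted-vs-estimated log-OR
    correlation, feature-set recall on strong signals (planted OR >= 6) and
    the false-inclusion rate among null codes (planted OR = 1).
    """
    per_code = []
    for code in truth.spec.codes:
        t = contingency(cohort, code)
        est = odds_ratio(t, correction)
        case_prev, ctrl_prev = prevalence(t)
        planted = truth.spec.planted_or[code]
        per_code.append(
            {
                "code": code,
                "planted_or": planted,
                "estimated_or": est,
                "rel_error": abs(est - planted) / planted,
                "alpha": alpha_index(t, correction),
                "case_prevalence": case_prev,
                "control_prevalence": ctrl_prev,
                "selected": est >= or_min and case_prev >= prevalence_min,
            }
        )
    table = pd.DataFrame(per_code)

    log_planted = np.log(table["planted_or"])
    log_est = np.log(table["estimated_or"])
    corr = float(np.corrcoef(log_planted, log_est)[0, 1])
    strong = table["planted_or"] >= 6.0
    null = table["planted_or"] == 1.0
    summary = {
        "log_or_correlation": corr,
        "strong_recall": float(table.loc[strong, "selected"].mean()) if strong.any() else float("nan"),
        "null_false_inclusion": float(table.loc[null, "selected"].mean()) if null.any() else 0.0,
    }
    return table, summary
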