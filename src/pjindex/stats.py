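"""Per-comorbidity association statistics and feature-set selection.

For each candidate comorbidity code a case-control 2x2 table is formed:
``a`` cases carrying the code, ``b`` controls carrying it, ``c``/``d`` the
complements.  The odds ratio is the cross-product ratio (a*d)/(b*c), with an
optional Haldane-Anscombe continuity correction adding 0.5 to every cell to
guard against zero cells.  The alpha index is the log odds ratio expressed
through the carriage proportions P1 = a/(a+c), P2 = b/(b+d); with matching
correction it is algebraically identical to ln(OR).  Selected features are
z-scored (population SD) and T-transformed to serve as weights for the
weighted Jaccard indices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .emr import Cohort

__all__ = [
    "TwoByTwo",
    "FeatureStat",
    "FeatureSet",
    "contingency",
    "odds_ratio",
    "alpha_index",
    "prevalence",
    "zscore_normalize",
    "tscore",
    "t_critical",
    "select_feature_set",
]

TScoreStyle = Literal["sqrt_n_over_C", "classic_50_plus_10z"]


@dataclass(frozen=True)
class TwoByTwo:
    """Case-control contingency table for one comorbidity code.

    a: cases with the comorbidity; b: controls with it;
    c: cases without; d: controls without.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def case_total(self) -> float:
        return self.a + self.c

    @property
    def control_total(self) -> float:
        return self.b + self.d

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


def contingency(cohort: Cohort, code: str) -> TwoByTwo:
    """Tabulate carriage of ``code`` against case/control status."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    a = b = 0
    for sid, label in zip(cohort.subjects["subject_id"], cohort.subjects["label"]):
        if code in cohort.codes[sid]:
            if label == "case":
                a += 1
            else:
                b += 1
    return TwoByTwo(a, b, cohort.n_cases - a, cohort.n_controls - b)


def odds_ratio(t: TwoByTwo, correction: float = 0.5) -> float:
    """Cross-product odds ratio ((a+k)(d+k)) / ((b+k)(c+k)) with correction k."""
    if correction < 0:
        raise ValueError("correction must be non-negative")
    denom = (t.b + correction) * (t.c + correction)
    if denom == 0:
        raise ZeroDivisionError(
            "zero cell with correction=0; use a positive continuity correction"
        )
    return (t.a + correction) * (t.d + correction) / denom


def alpha_index(t: TwoByTwo, correction: float = 0.5) -> float:
    """Log odds ratio of the case vs control carriage proportions.

    P1 = (a+k)/(a+c+2k), P2 = (b+k)/(b+d+2k); returns
    ln((P1/(1-P1)) / (P2/(1-P2))), which equals ln(odds_ratio) at equal
    correction.
    """
    if correction < 0:
        raise ValueError("correction must be non-negative")
    p1 = (t.a + correction) / (t.case_total + 2 * correction)
    p2 = (t.b + correction) / (t.control_total + 2 * correction)
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        raise ZeroDivisionError(
            "degenerate proportion with correction=0; use a positive correction"
        )
    return math.log((p1 / (1 - p1)) / (p2 / (1 - p2)))


def prevalence(t: TwoByTwo, pseudo_count: float = 1.0) -> tuple[float, float]:
    """(case, control) carriage proportions, pseudo-counted only at zero.

    The pseudo-count replaces a zero numerator so a never-observed code still
    has a non-null proportion; non-zero counts are untouched.
    """
    if t.case_total <= 0 or t.control_total <= 0:
        raise ValueError("both margins must be positive")
    a = t.a if t.a > 0 else pseudo_count
    b = t.b if t.b > 0 else pseudo_count
    return a / t.case_total, b / t.control_total


def zscore_normalize(values: Sequence[float], clip: bool = False) -> np.ndarray:
    """Population-SD z-scores; optionally clipped to [-1, 1] (off by default)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values to z-score")
    sd = arr.std()  # population SD
    if sd == 0:
        raise ValueError("degenerate distribution: zero standard deviation")
    z = (arr - arr.mean()) / sd
    return np.clip(z, -1.0, 1.0) if clip else z


def t_critical(n: int, confidence: float = 0.975) -> float:
    """Two-sided t critical value at n-1 degrees of freedom."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(sps.t.ppf(confidence, n - 1))


def tscore(
    z: float,
    n: int,
    C: float | None = None,
    style: TScoreStyle = "sqrt_n_over_C",
) -> float:
    """Transform a z-score into a T-score weight.

    Default form is z*sqrt(n)/C with C the two-sided 97.5% t critical value
    at n-1 df (strictly increasing in z, grows with sample size); the
    ``classic_50_plus_10z`` style is the conventional educational T = 50+10z.
    """
    if style == "classic_50_plus_10z":
        return 50.0 + 10.0 * z
    if n < 2:
        raise ValueError("n must be >= 2")
    if C is None:
        C = t_critical(n)
    if C <= 0:
        raise ValueError("critical value C must be positive")
    return z * math.sqrt(n) / C


@dataclass(frozen=True)
class FeatureStat:
    """Association profile of one comorbidity code."""

    code: str
    table: TwoByTwo
    odds_ratio: float
    alpha: float
    case_prevalence: float
    control_prevalence: float
    or_z: float = float("nan")
    or_t: float = float("nan")
    alpha_z: float = float("nan")
    alpha_t: float = float("nan")


@dataclass
class FeatureSet:
    """The comorbidity panel passing the OR and prevalence thresholds.

    Members are sorted by odds ratio, descending; z/T weights are computed
    over the selected members' own OR and alpha distributions.
    """

    stats: list[FeatureStat]
    thresholds: tuple[float, float]
    pseudo_count: float = 1.0
    correction: float = 0.5

    def __post_init__(self) -> None:
        or_min, prev_min = self.thresholds
        for s in self.stats:
            if s.odds_ratio < or_min or s.case_prevalence < prev_min:
                raise ValueError(f"feature {s.code} violates the selection thresholds")

    def __len__(self) -> int:
        return len(self.stats)

    def __iter__(self):
        return iter(self.stats)

    @property
    def codes(self) -> list[str]:
        return [s.code for s in self.stats]

    def weights(self, kind: Literal["OPJI", "APJI"]) -> dict[str, float]:
        attr = "or_t" if kind == "OPJI" else "alpha_t"
        return {s.code: getattr(s, attr) for s in self.stats}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": [s.code for s in self.stats],
                "a": [s.table.a for s in self.stats],
                "c": [s.table.c for s in self.stats],
                "b": [s.table.b for s in self.stats],
                "d": [s.table.d for s in self.stats],
                "alpha": [s.alpha for s in self.stats],
                "odds_ratio": [s.odds_ratio for s in self.stats],
                "case_prevalence": [s.case_prevalence for s in self.stats],
                "control_prevalence": [s.control_prevalence for s in self.stats],
                "or_t": [s.or_t for s in self.stats],
                "alpha_t": [s.alpha_t for s in self.stats],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _contingency_all(cohort: Cohort, codes: Iterable[str]) -> dict[str, TwoByTwo]:
    """Vectorised carriage tabulation for many codes at once."""
    codes = sorted(set(codes))
    pos = {c: i for i, c in enumerate(codes)}
    a = np.zeros(len(codes), dtype=int)
    b = np.zeros(len(codes), dtype=int)
    for sid, label in zip(cohort.subjects["subject_id"], cohort.subjects["label"]):
        tgt = a if label == "case" else b
        for code in cohort.codes[sid]:
            i = pos.get(code)
            if i is not None:
                tgt[i] += 1
    mA, mB = cohort.n_cases, cohort.n_controls
    return {c: TwoByTwo(a[i], b[i], mA - a[i], mB - b[i]) for c, i in pos.items()}


def select_feature_set(
    cohort: Cohort,
    or_min: float = 2.0,
    prevalence_min: float = 0.01,
    correction: float = 0.5,
    pseudo_count: float = 1.0,
    tscore_style: TScoreStyle = "sqrt_n_over_C",
    clip_z: bool = False,
) -> FeatureSet:
    """Select the comorbidity feature set from a labelled cohort.

    Every distinct code observed among cases is profiled; codes with
    odds_ratio >= or_min and case prevalence >= prevalence_min survive.
    z-scores (and the T weights derived from them, with n the cohort size)
    are computed over the selected members only.
    """
    if cohort.n_cases < 1 or cohort.n_controls < 1:
        raise ValueError("cohort needs at least one case and one control")
    candidates: set[str] = set()
    for sid in cohort.case_ids:
        candidates |= cohort.codes[sid]
    tables = _contingency_all(cohort, candidates)

    kept: list[FeatureStat] = []
    for code in sorted(candidates):
        t = tables[code]
        orr = odds_ratio(t, correction)
        case_prev, ctrl_prev = prevalence(t, pseudo_count)
        if orr >= or_min and case_prev >= prevalence_min:
            kept.append(
                FeatureStat(
                    code=code,
                    table=t,
                    odds_ratio=orr,
                    alpha=alpha_index(t, correction),
                    case_prevalence=case_prev,
                    control_prevalence=ctrl_prev,
                )
            )
    if not kept:
        raise ValueError(
            "no comorbidity passed the thresholds; consider relaxing or_min/prevalence_min"
        )

    n = len(cohort)
    ors = [s.odds_ratio for s in kept]
    alphas = [s.alpha for s in kept]
    try:
        or_z = zscore_normalize(ors, clip=clip_z)
        alpha_z = zscore_normalize(alphas, clip=clip_z)
    except ValueError:
        warnings.warn(
            "degenerate feature-set weight distribution; using zero z-scores",
            stacklevel=2,
        )
        or_z = np.zeros(len(kept))
        alpha_z = np.zeros(len(kept))

    C = t_critical(n) if tscore_style == "sqrt_n_over_C" else None
    enriched = [
        FeatureStat(
            code=s.code,
            table=s.table,
            odds_ratio=s.odds_ratio,
            alpha=s.alpha,
            case_prevalence=s.case_prevalence,
            control_prevalence=s.control_prevalence,
            or_z=float(zo),
            or_t=tscore(float(zo), n, C, tscore_style),
            alpha_z=float(za),
            alpha_t=tscore(float(za), n, C, tscore_style),
        )
        for s, zo, za in zip(kept, or_z, alpha_z)
    ]
    enriched.sort(key=lambda s: (-s.odds_ratio, s.code))
    return FeatureSet(enriched, (or_min, prevalence_min), pseudo_count, correction)
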