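"""The proportional Jaccard family of comorbidity-pattern similarity indices.

Four indices compare two disease-code profiles A and B:

* JI  — classical Jaccard, |A∩B| / |A∪B| over unweighted code sets.
* PJI — proportional Jaccard: each shared code contributes the mean of its
  within-group proportions, q_k = (pA+pB)/2; each exclusive code contributes
  its own proportion (s_k from A, r_k from B); the index is
  Σq / (Σq + Σs + Σr).
* OPJI / APJI — PJI with every code's mass additionally multiplied by a
  T-score-normalised odds ratio (OPJI) or alpha/log-odds index (APJI).
  T-score weights can be negative after z-scoring, so they are floored at a
  small positive epsilon to keep the ratio a valid mass comparison; the
  indices are invariant to a common positive rescaling of the weights.

A subject is featurised as a uniform-proportion profile over their
feature-set comorbidities and compared against the case-group and
control-group proportion profiles, yielding two features per index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .emr import Cohort
from .stats import FeatureSet

__all__ = [
    "WEIGHT_FLOOR",
    "IndexKind",
    "GroupProfile",
    "SimilarityResult",
    "jaccard",
    "pji",
    "weighted_pji",
    "subject_profile",
    "cohort_group_profile",
    "featurize_cohort",
]

WEIGHT_FLOOR = 1e-6
IndexKind = Literal["JI", "PJI", "OPJI", "APJI"]


@dataclass(frozen=True)
class GroupProfile:
    """A set of disease codes with normalised proportions (sum to 1)."""

    proportions: Mapping[str, float]

    def __post_init__(self) -> None:
        props = dict(self.proportions)
        if any(v <= 0 for v in props.values()):
            raise ValueError("all proportions must be positive")
        if props and abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        object.__setattr__(self, "proportions", props)

    @classmethod
    def from_counts(cls, counts: Mapping[str, float]) -> "GroupProfile":
        total = sum(counts.values())
        if total <= 0:
            return cls({})
        return cls({c: n / total for c, n in counts.items() if n > 0})

    @classmethod
    def uniform(cls, codes: Iterable[str]) -> "GroupProfile":
        codes = sorted(set(codes))
        if not codes:
            return cls({})
        return cls({c: 1.0 / len(codes) for c in codes})

    @property
    def support(self) -> frozenset[str]:
        return frozenset(self.proportions)

    def __len__(self) -> int:
        return len(self.proportions)

    def __getitem__(self, code: str) -> float:
        return self.proportions[code]


@dataclass(frozen=True)
class SimilarityResult:
    index_kind: IndexKind
    value: float
    shared_codes: frozenset[str]
    exclusive_a: frozenset[str]
    exclusive_b: frozenset[str]


def jaccard(set_a: Iterable[str], set_b: Iterable[str]) -> SimilarityResult:
    """Classical Jaccard index over unweighted code sets (empty vs empty -> 0)."""
    a, b = frozenset(set_a), frozenset(set_b)
    shared, only_a, only_b = a & b, a - b, b - a
    union = len(a | b)
    value = len(shared) / union if union else 0.0
    return SimilarityResult("JI", value, shared, only_a, only_b)


def _masses(
    profile_a: GroupProfile,
    profile_b: GroupProfile,
    weights: Mapping[str, float] | None,
) -> tuple[float, float, float, frozenset[str], frozenset[str], frozenset[str]]:
    sa, sb = profile_a.support, profile_b.support
    shared, only_a, only_b = sa & sb, sa - sb, sb - sa

    def w(code: str) -> float:
        if weights is None:
            return 1.0
        try:
            return max(weights[code], WEIGHT_FLOOR)
        except KeyError:
            raise KeyError(f"no weight defined for code {code!r}") from None

    q = sum((profile_a[c] + profile_b[c]) / 2 * w(c) for c in shared)
    s = sum(profile_a[c] * w(c) for c in only_a)
    r = sum(profile_b[c] * w(c) for c in only_b)
    return q, s, r, shared, only_a, only_b


def pji(profile_a: GroupProfile, profile_b: GroupProfile) -> SimilarityResult:
    """Proportional Jaccard index between two normalised code profiles."""
    q, s, r, shared, only_a, only_b = _masses(profile_a, profile_b, None)
    denom = q + s + r
    value = q / denom if denom > 0 else 0.0
    return SimilarityResult("PJI", value, shared, only_a, only_b)


def weighted_pji(
    profile_a: GroupProfile,
    profile_b: GroupProfile,
    weights: Mapping[str, float],
    kind: Literal["OPJI", "APJI"] = "OPJI",
) -> SimilarityResult:
    """OPJI/APJI: proportional Jaccard with per-code multiplicative weights.

    Weights (T-scored odds ratios for OPJI, T-scored alphas for APJI) are
    floored at ``WEIGHT_FLOOR`` so every mass stays positive; the value is
    invariant to scaling all weights by a positive constant.
    """
    if kind not in ("OPJI", "APJI"):
        raise ValueError(f"kind must be OPJI or APJI, got {kind!r}")
    q, s, r, shared, only_a, only_b = _masses(profile_a, profile_b, weights)
    denom = q + s + r
    value = q / denom if denom > 0 else 0.0
    return SimilarityResult(kind, value, shared, only_a, only_b)


def subject_profile(subject_codes: Iterable[str], feature_set: FeatureSet) -> GroupProfile:
    """Uniform-proportion profile over the subject's feature-set comorbidities."""
    retained = frozenset(subject_codes) & frozenset(feature_set.codes)
    return GroupProfile.uniform(retained)


def cohort_group_profile(
    cohort: Cohort,
    label: Literal["case", "control"],
    feature_set: FeatureSet,
    subject_ids: Iterable[str] | None = None,
) -> GroupProfile:
    """Carriage-count profile of one cohort group over the feature-set codes.

    N_i = number of group members carrying code i, normalised to sum to 1
    (codes carried by nobody in the group drop out of the support).
    ``subject_ids`` restricts the group, e.g. to a training fold.
    """
    if subject_ids is None:
        ids = cohort.case_ids if label == "case" else cohort.control_ids
    else:
        wanted = set(subject_ids)
        labelled = cohort.case_ids if label == "case" else cohort.control_ids
        ids = [s for s in labelled if s in wanted]
    fs_codes = set(feature_set.codes)
    counts: dict[str, int] = {}
    for sid in ids:
        for code in cohort.codes[sid] & fs_codes:
            counts[code] = counts.get(code, 0) + 1
    return GroupProfile.from_counts(counts)


def _profile_vector(profile: GroupProfile, codes: list[str]) -> np.ndarray:
    vec = np.zeros(len(codes))
    for i, c in enumerate(codes):
        vec[i] = profile.proportions.get(c, 0.0)
    return vec


def _pairwise_values(
    S: np.ndarray, p: np.ndarray, kind: IndexKind, w: np.ndarray | None
) -> np.ndarray:
    """Vectorised index of every row-profile of S against reference p."""
    A = S > 0
    P = p > 0
    if kind == "JI":
        inter = (A & P).sum(axis=1)
        union = (A | P).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    wv = np.ones_like(p) if w is None else np.maximum(w, WEIGHT_FLOOR)
    q = (((S + p) / 2) * wv * (A & P)).sum(axis=1)
    s = (S * wv * (A & ~P)).sum(axis=1)
    r = (p * wv * (~A & P)).sum(axis=1)
    denom = q + s + r
    return np.where(denom > 0, q / np.maximum(denom, 1e-300), 0.0)


def featurize_cohort(
    cohort: Cohort,
    feature_set: FeatureSet,
    case_profile: GroupProfile,
    control_profile: GroupProfile,
    index_kind: IndexKind,
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Two similarity features per subject: vs the case and control profiles.

    The reference profiles must be built from training subjects only when
    the output feeds cross-validated models (leakage guard).  Returns a
    frame with columns subject_id, label, sim_to_case, sim_to_control.
    """
    if index_kind in ("OPJI", "APJI") and weights is None:
        weights = feature_set.weights(index_kind)
    codes = sorted(feature_set.codes)
    pos = {c: i for i, c in enumerate(codes)}

    n = len(cohort)
    M = np.zeros((n, len(codes)))
    for row, sid in enumerate(cohort.subjects["subject_id"]):
        for code in cohort.codes[sid]:
            i = pos.get(code)
            if i is not None:
                M[row, i] = 1.0
    k = M.sum(axis=1, keepdims=True)
    S = np.divide(M, k, out=np.zeros_like(M), where=k > 0)  # uniform subject profiles

    w = None
    if index_kind in ("OPJI", "APJI"):
        assert weights is not None
        missing = [c for c in codes if c not in weights]
        if missing:
            raise KeyError(f"no weight defined for code {missing[0]!r}")
        w = np.array([weights[c] for c in codes])

    p_case = _profile_vector(case_profile, codes)
    p_ctrl = _profile_vector(control_profile, codes)
    return pd.DataFrame(
        {
            "subject_id": cohort.subjects["subject_id"],
            "label": cohort.subjects["label"],
            "sim_to_case": _pairwise_values(S, p_case, index_kind, w),
            "sim_to_control": _pairwise_values(S, p_ctrl, index_kind, w),
        }
    )
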