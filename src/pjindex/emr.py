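"""Claims-style EMR tables, ICD-9-CM code levels, and case/control cohorts.

The raw input is a longitudinal visit-level table: one row per (subject,
visit, diagnosis code), with the visit type distinguishing outpatient,
emergency and inpatient encounters.  Cases of the target disease (heart
failure by default, ICD-9-CM prefix 428) are identified from emergency and
inpatient records only; controls have no target-code record of any type.
Comorbidity codes are collected from *all* visit types inside a lead-time
window strictly before the index date.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EMR_COLUMNS",
    "VISIT_TYPES",
    "EMRTable",
    "CohortSpec",
    "Cohort",
    "GroupMap",
    "parse_emr_table",
    "default_group_map",
    "icd9_category",
    "map_code_level",
    "build_cohort",
]

EMR_COLUMNS = ("subject_id", "sex", "birth_date", "visit_date", "visit_type", "icd9_code")
VISIT_TYPES = frozenset({"outpatient", "emergency", "inpatient"})
SEXES = frozenset({"F", "M"})

# ICD-9-CM: plain codes are 3-5 digits; V codes V + 2-4 digits; E codes E + 3-4 digits.
_CODE_RE = re.compile(r"^(?:\d{3,5}|V\d{2,4}|E\d{3,4})$")


def _valid_code(code: str) -> bool:
    return bool(_CODE_RE.match(code))


def icd9_category(code: str) -> str:
    """Truncate an ICD-9-CM code to its category ("single disease") level.

    Plain and V codes truncate to 3 characters ("4280" -> "428",
    "V720" -> "V72"); E codes keep 4 ("E8170" -> "E817").
    """
    if not _valid_code(code):
        raise ValueError(f"invalid ICD-9-CM code: {code!r}")
    return code[:4] if code.startswith("E") else code[:3]


def _code_sort_key(category: str) -> tuple[int, int]:
    # Orders 001..999 < V01..V91 < E800..E999 so V/E ranges never capture digits.
    if category.startswith("V"):
        return (1, int(category[1:]))
    if category.startswith("E"):
        return (2, int(category[1:]))
    return (0, int(category))


class GroupMap:
    """Range table mapping ICD-9 categories to disease-group identifiers.

    Ranges are closed intervals over category codes within one letter class
    (digits, V, E).  The bundled default partitions ICD-9-CM into its
    standard block-level sub-chapters.
    """

    def __init__(self, ranges: Iterable[tuple[str, str, str]]):
        self._ranges: list[tuple[tuple[int, int], tuple[int, int], str]] = []
        for start, end, gid in ranges:
            ks, ke = _code_sort_key(start), _code_sort_key(end)
            if ks[0] != ke[0] or ks > ke:
                raise ValueError(f"malformed range {start}-{end}")
            self._ranges.append((ks, ke, gid))
        self._ranges.sort()
        self._cache: dict[str, str] = {}

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroupMap":
        df = pd.read_csv(path, dtype=str)
        need = {"range_start", "range_end", "group_id"}
        if not need.issubset(df.columns):
            raise ValueError(f"group map must have columns {sorted(need)}")
        return cls(df[["range_start", "range_end", "group_id"]].itertuples(index=False))

    def lookup(self, category: str) -> str:
        try:
            return self._cache[category]
        except KeyError:
            pass
        key = _code_sort_key(category)
        for ks, ke, gid in self._ranges:
            if ks <= key <= ke:
                self._cache[category] = gid
                return gid
        raise KeyError(f"ICD-9 category {category!r} not covered by the group map")

    def __len__(self) -> int:
        return len(self._ranges)


def default_group_map() -> GroupMap:
    """The bundled ICD-9-CM block-level range table (~148 groups)."""
    with resources.as_file(resources.files("pjindex") / "data" / "icd9_groups.csv") as p:
        return GroupMap.from_csv(p)


def map_code_level(
    code: str,
    level: Literal["single", "group"],
    group_map: GroupMap | None = None,
) -> str:
    """Map a raw ICD-9-CM code to the requested granularity.

    ``single`` is the 3-character category (4 for E codes); ``group`` is the
    disease-block identifier containing that category.  Idempotent at
    ``single`` level.
    """
    category = icd9_category(code)
    if level == "single":
        return category
    if level == "group":
        gm = group_map if group_map is not None else default_group_map()
        return gm.lookup(category)
    raise ValueError(f"unknown code level {level!r}")


class EMRTable:
    """Longitudinal visit-level diagnosis records, one row per code mention."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        if validate:
            df = _validate_frame(df)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()

    def to_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        for col in ("birth_date", "visit_date"):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EMRTable):
            return NotImplemented
        return self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EMR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"EMR table missing columns: {missing}")
    df = df.loc[:, list(EMR_COLUMNS)].copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["icd9_code"] = df["icd9_code"].astype(str).str.strip()

    for col in ("birth_date", "visit_date"):
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0])
            raise ValueError(f"row {row}: malformed {col} {df[col][bad].iloc[0]!r}")
        if parsed.isna().any():
            row = int(df.index[parsed.isna()][0])
            raise ValueError(f"row {row}: missing {col}")
        df[col] = parsed

    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        row = int(df.index[bad_sex][0])
        raise ValueError(f"row {row}: sex must be F or M, got {df['sex'][bad_sex].iloc[0]!r}")

    bad_vt = ~df["visit_type"].isin(VISIT_TYPES)
    if bad_vt.any():
        row = int(df.index[bad_vt][0])
        raise ValueError(f"row {row}: unknown visit_type {df['visit_type'][bad_vt].iloc[0]!r}")

    bad_code = ~df["icd9_code"].map(_valid_code)
    if bad_code.any():
        row = int(df.index[bad_code][0])
        raise ValueError(f"row {row}: invalid ICD-9-CM code {df['icd9_code'][bad_code].iloc[0]!r}")

    early = df["visit_date"] < df["birth_date"]
    if early.any():
        row = int(df.index[early][0])
        raise ValueError(f"row {row}: visit_date before birth_date")

    # A subject's demographics must be constant across their records.
    demo = df.groupby("subject_id")[["sex", "birth_date"]].nunique()
    bad = demo[(demo["sex"] > 1) | (demo["birth_date"] > 1)]
    if len(bad):
        raise ValueError(f"inconsistent sex/birth_date for subject {bad.index[0]!r}")
    return df


def parse_emr_table(path: str | Path, dialect: Mapping | None = None) -> EMRTable:
    """Read a delimited EMR file (CSV by default) into a validated table.

    The header must name the six standard fields; dates are ISO-8601.
    Malformed rows raise with the offending (0-based data) row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    kwargs = dict(dialect or {})
    kwargs.setdefault("sep", ",")
    df = pd.read_csv(path, dtype=str, **kwargs)
    return EMRTable(df)


@dataclass(frozen=True)
class CohortSpec:
    """What defines a case, the lead-time window, and the code granularity."""

    target_codes: frozenset[str] = frozenset({"428"})
    case_visit_types: frozenset[str] = frozenset({"emergency", "inpatient"})
    lead_years: int = 1
    code_level: Literal["single", "group"] = "single"

    def __post_init__(self) -> None:
        if not self.target_codes:
            raise ValueError("target_codes must be non-empty")
        if self.lead_years < 1:
            raise ValueError("lead_years must be >= 1")
        if not self.case_visit_types <= VISIT_TYPES:
            raise ValueError(f"case_visit_types must be within {sorted(VISIT_TYPES)}")


@dataclass
class Cohort:
    """Labelled subjects with index dates and lead-window comorbidity sets."""

    subjects: pd.DataFrame  # subject_id, label, index_date, sex, birth_date
    codes: dict[str, frozenset[str]]
    spec: CohortSpec

    def __post_init__(self) -> None:
        self.subjects = self.subjects.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def labels(self) -> pd.Series:
        return self.subjects["label"]

    @property
    def case_ids(self) -> list[str]:
        return list(self.subjects.loc[self.subjects["label"] == "case", "subject_id"])

    @property
    def control_ids(self) -> list[str]:
        return list(self.subjects.loc[self.subjects["label"] == "control", "subject_id"])

    @property
    def n_cases(self) -> int:
        return int((self.subjects["label"] == "case").sum())

    @property
    def n_controls(self) -> int:
        return int((self.subjects["label"] == "control").sum())

    def codes_of(self, subject_id: str) -> frozenset[str]:
        return self.codes[subject_id]

    def age_at_index(self) -> pd.Series:
        days = (self.subjects["index_date"] - self.subjects["birth_date"]).dt.days
        return days / 365.25

    def subset(self, mask: np.ndarray | pd.Series) -> "Cohort":
        sub = self.subjects.loc[np.asarray(mask)].reset_index(drop=True)
        codes = {sid: self.codes[sid] for sid in sub["subject_id"]}
        return Cohort(sub, codes, self.spec)

    def to_csv(self, path: str | Path) -> None:
        out = self.subjects.copy()
        out["index_date"] = out["index_date"].dt.strftime("%Y-%m-%d")
        out["birth_date"] = out["birth_date"].dt.strftime("%Y-%m-%d")
        out["codes"] = [";".join(sorted(self.codes[s])) for s in out["subject_id"]]
        out.to_csv(path, index=False)


def _is_target(codes: pd.Series, target_prefixes: Iterable[str]) -> pd.Series:
    mask = pd.Series(False, index=codes.index)
    for prefix in target_prefixes:
        mask |= codes.str.startswith(prefix)
    return mask


def build_cohort(
    emr: EMRTable,
    spec: CohortSpec,
    control_ratio: float = 2.5,
    match_on: Literal["age_sex", "none"] = "age_sex",
    seed: int = 0,
    group_map: GroupMap | None = None,
) -> Cohort:
    """Define cases and matched controls and collect lead-window comorbidities.

    A case's index date is the first target-code visit of a qualifying visit
    type (emergency/inpatient by default); a subject whose only target-code
    records are outpatient is neither case nor control.  Controls are drawn
    without replacement from subjects with no target-code record of any type,
    matched on sex and 5-year age band when ``match_on="age_sex"``, and
    inherit their matched case's index date so the lead windows are
    calendar-comparable.  Comorbidity codes come from all visit types within
    the half-open window [index_date - lead_years, index_date), exclude the
    target codes, and are mapped to ``spec.code_level``.
    """
    df = emr.df
    if df.empty:
        raise ValueError("EMR table is empty")
    rng = np.random.default_rng(seed)
    if spec.code_level == "group" and group_map is None:
        group_map = default_group_map()

    target = _is_target(df["icd9_code"], spec.target_codes)
    qualifying = df[target & df["visit_type"].isin(spec.case_visit_types)]
    if qualifying.empty:
        raise ValueError("no cases: no target-code record of a qualifying visit type")
    case_index = qualifying.groupby("subject_id")["visit_date"].min()

    demo = df.groupby("subject_id").agg(sex=("sex", "first"), birth_date=("birth_date", "first"))
    tainted = set(df.loc[target, "subject_id"])  # any target record disqualifies a control
    pool = demo.loc[~demo.index.isin(tainted)].copy()

    cases = demo.loc[case_index.index].copy()
    cases["index_date"] = case_index

    def age_band(birth: pd.Series, at: pd.Timestamp | pd.Series) -> pd.Series:
        days = (at - birth).dt.days if isinstance(at, pd.Series) else (at - birth).dt.days
        return (days / 365.25 // 5).astype(int)

    chosen: list[tuple[str, pd.Timestamp]] = []
    if match_on == "age_sex":
        cases["band"] = age_band(cases["birth_date"], cases["index_date"])
        for (sex, band), grp in cases.groupby(["sex", "band"], sort=True):
            ref_date = grp["index_date"].sort_values().iloc[len(grp) // 2]
            cand = pool[(pool["sex"] == sex)
                        & (age_band(pool["birth_date"], ref_date) == band)]
            quota = int(round(control_ratio * len(grp)))
            take = min(quota, len(cand))
            picked = rng.choice(cand.index.to_numpy(), size=take, replace=False)
            # cycle the stratum's case index dates over its controls
            dates = grp["index_date"].to_numpy()
            chosen.extend((sid, pd.Timestamp(dates[i % len(dates)]))
                          for i, sid in enumerate(sorted(picked)))
            pool = pool.drop(index=picked)
    else:
        quota = int(round(control_ratio * len(cases)))
        take = min(quota, len(pool))
        picked = rng.choice(pool.index.to_numpy(), size=take, replace=False)
        dates = rng.choice(cases["index_date"].to_numpy(), size=take, replace=True)
        chosen.extend((sid, pd.Timestamp(d)) for sid, d in zip(sorted(picked), dates))

    want = int(round(control_ratio * len(cases)))
    if len(chosen) < want:
        warnings.warn(
            f"insufficient matchable controls: requested {want}, found {len(chosen)}",
            stacklevel=2,
        )

    rows = [
        {"subject_id": sid, "label": "case", "index_date": cases.loc[sid, "index_date"],
         "sex": cases.loc[sid, "sex"], "birth_date": cases.loc[sid, "birth_date"]}
        for sid in cases.index
    ] + [
        {"subject_id": sid, "label": "control", "index_date": idx,
         "sex": demo.loc[sid, "sex"], "birth_date": demo.loc[sid, "birth_date"]}
        for sid, idx in chosen
    ]
    subjects = pd.DataFrame(rows).sort_values(["label", "subject_id"]).reset_index(drop=True)

    index_by_sid = dict(zip(subjects["subject_id"], subjects["index_date"]))
    window = df[df["subject_id"].isin(index_by_sid) & ~target].copy()
    idx_dates = window["subject_id"].map(index_by_sid)
    start = idx_dates - pd.DateOffset(years=spec.lead_years)  # type: ignore[operator]
    in_window = (window["visit_date"] >= start) & (window["visit_date"] < idx_dates)
    window = window[in_window]

    if spec.code_level == "single":
        mapped = window["icd9_code"].map(icd9_category)
    else:
        assert group_map is not None
        mapped = window["icd9_code"].map(lambda c: group_map.lookup(icd9_category(c)))
    grouped = mapped.groupby(window["subject_id"]).agg(frozenset)
    codes = {sid: grouped.get(sid, frozenset()) for sid in subjects["subject_id"]}

    return Cohort(subjects, codes, spec)
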