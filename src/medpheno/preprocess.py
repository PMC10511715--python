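"""MAR cleaning and binary patient x medication matrix construction.

Raw MAR extracts contain one row per administration event, decorated with an
action label ("Given", "Missed", "Held", ...).  Only actions that denote an
actual administration are informative for phenotyping; free-text rows,
duplicates and incomplete rows are noise.  Medication names carry dose and
route decorations ("Cefepime 1gm", "cefepime 2gm") that must collapse to a
single generic feature ("cefepime") before binarization.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "KEEP_ACTIONS",
    "BinaryMedicationMatrix",
    "select_index_admissions",
    "filter_mar_actions",
    "clean_records",
    "normalize_medication_names",
    "build_binary_matrix",
    "recode_outcomes",
    "preprocess_records",
]

#: Actions that denote an administered medication.  Matching is
#: case-insensitive after whitespace trimming.
KEEP_ACTIONS = frozenset({"given", "new bag", "restarted", "rate change"})

#: dose token: number followed (optionally after whitespace) by a unit
_DOSE_RE = re.compile(r"\b\d+(?:\.\d+)?\s*(?:gm|g|mg|mcg|units?|%)(?=\b|\s|$)")
_ROUTE_WORDS = frozenset({"iv", "po", "im", "sc", "sl", "pr", "inhaled"})

_MANDATORY_FIELDS = ("patient_id", "medication_name", "action")

#: recode map for categorical outcome labels; missing/unknown collapse to "no"
_BINARY_LABEL_MAP = {
    "yes": 1, "y": 1, "true": 1, "1": 1, "positive": 1, "present": 1,
    "no": 0, "n": 0, "false": 0, "0": 0, "negative": 0, "absent": 0,
    "unknown": 0, "missing": 0, "na": 0, "n/a": 0, "": 0,
}

BINARY_OUTCOMES = ["mortality", "delirium", "aki", "mv_present", "fluid_overload"]
CONTINUOUS_OUTCOMES = [
    "hosp_los_days",
    "icu_los_days",
    "vasopressor_days",
    "mv_days",
    "apache2_24h",
    "mrcicu_24h",
]


def _blank(series: pd.Series) -> pd.Series:
    return series.isna() | (series.astype(str).str.strip() == "")


def select_index_admissions(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only each patient's earliest (index) ICU admission.

    If ``admission_index`` is absent it is derived from timestamps: an
    admission break is assumed wherever a patient's events are separated by
    more than 30 days.
    """
    records = records.copy()
    if "admission_index" not in records.columns:
        ts = pd.to_datetime(records["timestamp"])
        order = records.assign(_ts=ts).sort_values(["patient_id", "_ts"])
        gap = order.groupby("patient_id")["_ts"].diff() > pd.Timedelta(days=30)
        records.loc[order.index, "admission_index"] = 1 + gap.groupby(order["patient_id"]).cumsum()
        records["admission_index"] = records["admission_index"].astype(int)
    first = records.groupby("patient_id")["admission_index"].transform("min")
    kept = records[records["admission_index"] == first].reset_index(drop=True)
    n_dropped_pat = records["patient_id"].nunique() - kept["patient_id"].nunique()
    if n_dropped_pat:  # pragma: no cover - defensive, index filter keeps every patient
        logger.warning("index-admission filter dropped %d patients entirely", n_dropped_pat)
    logger.info(
        "select_index_admissions: %d -> %d rows (%d patients)",
        len(records), len(kept), kept["patient_id"].nunique(),
    )
    return kept


def filter_mar_actions(records: pd.DataFrame, keep_actions=None) -> pd.DataFrame:
    """Keep only rows whose MAR action denotes an administered medication.

    Default keep set: Given, New Bag, Restarted, Rate Change (free-text and
    not-administered actions such as Missed/Held are discarded).
    """
    if keep_actions is None:
        keep = KEEP_ACTIONS
    else:
        keep = frozenset(str(a).strip().lower() for a in keep_actions)
    norm = records["action"].astype(str).str.strip().str.lower()
    out = records[norm.isin(keep)].reset_index(drop=True)
    logger.info("filter_mar_actions: %d -> %d rows", len(records), len(out))
    return out


def clean_records(records: pd.DataFrame) -> pd.DataFrame:
    """Drop incomplete rows and collapse exact duplicates (first kept).

    A row is incomplete when patient_id, medication_name or action is empty.
    Duplicates are identical on all columns, timestamp included.
    """
    mask = np.ones(len(records), dtype=bool)
    for col in _MANDATORY_FIELDS:
        mask &= ~_blank(records[col]).to_numpy()
    out = records[mask].drop_duplicates(keep="first").reset_index(drop=True)
    logger.info("clean_records: %d -> %d rows", len(records), len(out))
    return out


def _normalize_name(name: str) -> str:
    s = str(name).lower()
    s = _DOSE_RE.sub(" ", s)
    tokens = [t for t in s.split() if t not in _ROUTE_WORDS]
    return " ".join(tokens)


def normalize_medication_names(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse medication names to generic form.

    Lowercases, strips trailing/embedded dose tokens (``1gm``, ``10 units``,
    ``0.5 mg``...) and route words (IV, PO, IM, SC, SL, PR, inhaled), and
    collapses internal whitespace, so "Cefepime 1gm" and "cefepime 2gm" both
    become "cefepime".
    """
    out = records.copy()
    out["medication_name"] = out["medication_name"].map(_normalize_name)
    return out


@dataclass
class BinaryMedicationMatrix:
    """Patients x medications indicator matrix with labelled axes.

    ``values`` is a DataFrame indexed by patient_id with one column per
    collapsed generic medication name; entries are exactly 0 or 1.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        arr = v.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("matrix entries must be exactly 0 or 1")
        if v.index.has_duplicates or v.columns.has_duplicates:
            raise ValueError("patient and medication labels must be unique")
        if (arr.sum(axis=0) == 0).any():
            empties = list(v.columns[arr.sum(axis=0) == 0])
            raise ValueError(f"all-empty medication columns: {empties[:5]}")

    @property
    def patient_ids(self) -> list:
        return list(self.values.index)

    @property
    def medication_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="patient_id")

    @classmethod
    def from_tsv(cls, path) -> "BinaryMedicationMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="patient_id"))


def build_binary_matrix(records: pd.DataFrame) -> BinaryMedicationMatrix:
    """Binarize cleaned records: entry (p, m) = 1 iff patient p has >= 1
    retained record of medication m.

    Columns are sorted lexicographically and rows by patient id so the
    matrix (and everything seeded downstream) is reproducible.
    """
    if len(records) == 0:
        raise ValueError("cannot build a medication matrix from an empty record set")
    tab = pd.crosstab(records["patient_id"], records["medication_name"])
    tab = (tab > 0).astype(np.int8)
    tab = tab.sort_index(axis=0).sort_index(axis=1)
    tab.index.name = "patient_id"
    tab.columns.name = "medication_name"
    logger.info("build_binary_matrix: %d patients x %d medications", *tab.shape)
    return BinaryMedicationMatrix(tab)


def recode_outcomes(raw_outcomes: pd.DataFrame) -> pd.DataFrame:
    """Map categorical outcome labels to {0,1}; unknown/missing become 0.

    Continuous fields pass through as floats.  An unmappable non-missing
    label raises, listing the offending labels.
    """
    out = raw_outcomes.copy()
    for col in BINARY_OUTCOMES:
        if col not in out.columns:
            continue
        s = out[col]
        if pd.api.types.is_numeric_dtype(s):
            vals = s.fillna(0)
            if not vals.isin([0, 1]).all():
                bad = sorted(vals[~vals.isin([0, 1])].unique().tolist())
                raise ValueError(f"unmappable labels in {col!r}: {bad}")
            out[col] = vals.astype(int)
            continue
        norm = s.astype(str).str.strip().str.lower().where(~s.isna(), "")
        unmapped = sorted(set(norm) - set(_BINARY_LABEL_MAP))
        if unmapped:
            raise ValueError(f"unmappable labels in {col!r}: {unmapped}")
        out[col] = norm.map(_BINARY_LABEL_MAP).astype(int)
        mapping = {lab: _BINARY_LABEL_MAP[lab] for lab in sorted(set(norm))}
        logger.info("recode_outcomes: %s mapped %s", col, mapping)
    for col in CONTINUOUS_OUTCOMES:
        if col in out.columns:
            out[col] = pd.to_numeric(out[col], errors="raise").astype(float)
    return out


def preprocess_records(
    records: pd.DataFrame, keep_actions=None
) -> tuple[pd.DataFrame, BinaryMedicationMatrix]:
    """Full cleaning chain: index admission -> action filter -> clean ->
    name normalization -> binary matrix.  Returns (clean records, matrix)."""
    r = select_index_admissions(records)
    r = filter_mar_actions(r, keep_actions)
    r = clean_records(r)
    r = normalize_medication_names(r)
    return r, build_binary_matrix(r)
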