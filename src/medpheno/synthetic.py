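"""Synthetic ICU cohort generator with planted latent structure.

Real MAR extracts from an EHR are protected data, so the package ships a
generator that emulates their statistical shape: ~1,000 patients, ~30k
administration events over ~440 unique medications, block-structured
medication co-occurrence driven by latent patient archetypes, heterogeneous
MAR action labels (including discardable free-text entries), planted
duplicate and incomplete rows, occasional repeat ICU admissions, and
archetype-linked clinical outcomes (e.g. mortality spanning roughly 2.5% to
22% across archetypes).

Because the archetype of every patient and the block of every medication
are returned as ground truth, the whole downstream pipeline — cleaning, RBM
medication clustering, patient phenotyping, outcome validation — can be
benchmarked for recovery of known structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ACTION_LABELS",
    "MAR_COLUMNS",
    "OUTCOME_COLUMNS",
    "CohortSpecError",
    "OutcomeParams",
    "CohortSpec",
    "CohortTruth",
    "generate_cohort",
    "corrupt_records",
]

#: MAR action labels emitted by the generator.  Only the first four denote an
#: actual administration; "free-text" rows are clinician notes.
ACTION_LABELS = (
    "Given",
    "New Bag",
    "Restarted",
    "Rate Change",
    "Missed",
    "Held",
    "free-text",
)

MAR_COLUMNS = ["patient_id", "admission_index", "medication_name", "action", "timestamp"]

OUTCOME_COLUMNS = [
    "patient_id",
    "mortality",
    "hosp_los_days",
    "icu_los_days",
    "delirium",
    "aki",
    "vasopressor_days",
    "mv_present",
    "mv_days",
    "fluid_overload",
    "apache2_24h",
    "mrcicu_24h",
]

#: Dose / route decorations appended to medication names when
#: ``decorate_names`` is on; exactly the grammar the cleaner strips.
NAME_DECORATIONS = (" 1gm", " 2gm", " IV", " PO")


class CohortSpecError(ValueError):
    """Raised when a cohort specification field is invalid; names the field."""


def _default_block_usage(n_archetypes: int, n_blocks: int, on: float = 0.4, off: float = 0.02) -> np.ndarray:
    usage = np.full((n_archetypes, n_blocks), off, dtype=float)
    for a in range(n_archetypes):
        usage[a, a % n_blocks] = on
    return usage


@dataclass
class OutcomeParams:
    """Per-archetype clinical outcome parameters.

    All arrays have one entry per archetype.  Length-of-stay draws are
    log-normal (parameterised by the target arithmetic mean in days and a
    log-scale SD); durations are exponential; severity scores are truncated
    normal.  Defaults mirror the outcome gradient of a five-phenotype ICU
    cohort in which one phenotype carries ~22% mortality and the others
    range from ~2.5% to ~9%.
    """

    mortality: tuple = (0.026, 0.090, 0.026, 0.220, 0.082)
    hosp_los_mean: tuple = (8.8, 14.6, 4.8, 15.9, 9.6)
    icu_los_mean: tuple = (4.2, 6.2, 2.4, 7.3, 3.7)
    los_log_sd: float = 0.8
    delirium: tuple = (0.19, 0.40, 0.09, 0.53, 0.29)
    aki: tuple = (0.09, 0.19, 0.03, 0.30, 0.09)
    mv_present: tuple = (0.23, 0.44, 0.03, 0.49, 0.23)
    fluid_overload: tuple = (0.045, 0.14, 0.04, 0.24, 0.086)
    vasopressor_days_mean: tuple = (1.3, 1.8, 1.0, 1.8, 1.3)
    mv_days_mean: tuple = (1.6, 5.3, 2.7, 8.4, 3.5)
    apache2_mean: tuple = (13.0, 15.4, 11.3, 16.3, 13.7)
    apache2_sd: float = 6.0
    mrcicu_mean: tuple = (9.7, 12.3, 5.5, 12.5, 8.7)
    mrcicu_sd: float = 7.0

    def n_archetypes(self) -> int:
        return len(self.mortality)

    def validate(self, n_archetypes: int) -> None:
        for name in (
            "mortality",
            "hosp_los_mean",
            "icu_los_mean",
            "delirium",
            "aki",
            "mv_present",
            "fluid_overload",
            "vasopressor_days_mean",
            "mv_days_mean",
            "apache2_mean",
            "mrcicu_mean",
        ):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.shape != (n_archetypes,):
                raise CohortSpecError(
                    f"outcome_params.{name}: expected {n_archetypes} entries, got {vals.size}"
                )
            if np.any(vals < 0):
                raise CohortSpecError(f"outcome_params.{name}: negative entry")
        for name in ("mortality", "delirium", "aki", "mv_present", "fluid_overload"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if np.any(vals > 1):
                raise CohortSpecError(f"outcome_params.{name}: probability above 1")

    @classmethod
    def for_archetypes(cls, n_archetypes: int) -> "OutcomeParams":
        """Default parameters cycled/truncated to ``n_archetypes`` groups."""
        base = cls()
        if n_archetypes == base.n_archetypes():
            return base
        idx = [a % base.n_archetypes() for a in range(n_archetypes)]
        kw = {}
        for name in base.__dataclass_fields__:
            val = getattr(base, name)
            kw[name] = tuple(np.asarray(val)[idx]) if isinstance(val, tuple) else val
        return cls(**kw)


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    Defaults describe the reference world: 1,000 patients, 440 unique
    medications of which five planted co-occurrence blocks of 20 carry the
    archetype signal (own-block usage 0.4 vs 0.02 elsewhere) on top of 340
    rarely-used background medications (receipt probability 0.025).
    Patients then average ~18 distinct medications, the cohort ~30k
    administration events, and most medications end up in the residual
    cluster downstream — the shape of a real ICU formulary.  ~1% of
    patients carry a repeat admission.

    ``block_size=None`` splits medications evenly over the blocks; an
    explicit block size is capped at the even split so small simulations
    remain valid.
    """

    n_patients: int = 1000
    n_medications: int = 440
    n_blocks: int = 5
    n_archetypes: int = 5
    block_size: int | None = 20
    block_usage: np.ndarray | None = None
    background_rate: float = 0.025
    action_probs: dict[str, float] = field(
        default_factory=lambda: {
            "Given": 0.62,
            "New Bag": 0.10,
            "Restarted": 0.04,
            "Rate Change": 0.08,
            "Missed": 0.05,
            "Held": 0.06,
            "free-text": 0.05,
        }
    )
    duplicate_rate: float = 0.02
    incomplete_rate: float = 0.01
    events_per_med_mean: float = 1.7
    repeat_admission_rate: float = 0.01
    unknown_label_rate: float = 0.03
    outcome_params: OutcomeParams | None = None
    decorate_names: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outcome_params is None:
            self.outcome_params = OutcomeParams.for_archetypes(self.n_archetypes)
        if self.block_usage is None:
            self.block_usage = _default_block_usage(self.n_archetypes, self.n_blocks)
        else:
            self.block_usage = np.asarray(self.block_usage, dtype=float)

    # -- validation ---------------------------------------------------------
    def resolved_block_size(self) -> int:
        even = self.n_medications // self.n_blocks
        if self.block_size is not None:
            return min(int(self.block_size), even)
        return even

    def validate(self) -> None:
        for name in ("n_patients", "n_medications", "n_blocks", "n_archetypes"):
            if int(getattr(self, name)) < 1:
                raise CohortSpecError(f"{name}: must be >= 1")
        bs = self.resolved_block_size()
        if bs < 1:
            raise CohortSpecError("block_size: must be >= 1")
        if self.n_blocks * bs > self.n_medications:
            raise CohortSpecError(
                f"block_size: n_blocks * block_size = {self.n_blocks * bs} exceeds "
                f"n_medications = {self.n_medications}"
            )
        if self.block_usage.shape != (self.n_archetypes, self.n_blocks):
            raise CohortSpecError(
                f"block_usage: expected shape ({self.n_archetypes}, {self.n_blocks}), "
                f"got {self.block_usage.shape}"
            )
        if np.any(self.block_usage < 0) or np.any(self.block_usage > 1):
            raise CohortSpecError("block_usage: entries must lie in [0, 1]")
        for name in (
            "background_rate",
            "duplicate_rate",
            "incomplete_rate",
            "repeat_admission_rate",
            "unknown_label_rate",
        ):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise CohortSpecError(f"{name}: must lie in [0, 1]")
        probs = np.array([self.action_probs.get(a, 0.0) for a in ACTION_LABELS], dtype=float)
        if set(self.action_probs) - set(ACTION_LABELS):
            raise CohortSpecError(
                f"action_probs: unknown labels {sorted(set(self.action_probs) - set(ACTION_LABELS))}"
            )
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
            raise CohortSpecError("action_probs: must be nonnegative and sum to 1")
        if self.events_per_med_mean < 1.0:
            raise CohortSpecError("events_per_med_mean: must be >= 1 (every receipt spawns an event)")
        self.outcome_params.validate(self.n_archetypes)

    def with_(self, **kw) -> "CohortSpec":
        return replace(self, **kw)


@dataclass
class CohortTruth:
    """Planted ground truth: one archetype per patient, one block per medication.

    ``medication_block`` is 0 for background medications.
    """

    patient_archetype: pd.Series  # index: patient_id, values in 1..n_archetypes
    medication_block: pd.Series  # index: undecorated medication name, values in 0..n_blocks

    def to_frame(self) -> pd.DataFrame:
        """Long two-column representation for writing to delimited text."""
        pat = pd.DataFrame(
            {"kind": "patient", "id": self.patient_archetype.index, "label": self.patient_archetype.values}
        )
        med = pd.DataFrame(
            {"kind": "medication", "id": self.medication_block.index, "label": self.medication_block.values}
        )
        return pd.concat([pat, med], ignore_index=True)


def _medication_names(n: int) -> list[str]:
    return [f"drug{i:03d}" for i in range(1, n + 1)]


def _sample_outcomes(
    rng: np.random.Generator, archetype: np.ndarray, params: OutcomeParams, unknown_rate: float
) -> pd.DataFrame:
    """Raw (pre-recoding) outcome table: binary fields as yes/no/Unknown strings."""
    a = archetype - 1
    n = a.size

    def binary(p_by_arch, allow_unknown: bool) -> np.ndarray:
        p = np.asarray(p_by_arch, dtype=float)[a]
        vals = np.where(rng.random(n) < p, "yes", "no").astype(object)
        if allow_unknown and unknown_rate > 0:
            vals[rng.random(n) < unknown_rate] = "Unknown"
        return vals

    hosp_mu = np.log(np.asarray(params.hosp_los_mean)[a]) - params.los_log_sd**2 / 2
    icu_mu = np.log(np.asarray(params.icu_los_mean)[a]) - params.los_log_sd**2 / 2
    hosp_los = np.round(np.exp(rng.normal(hosp_mu, params.los_log_sd)), 1)
    icu_los = np.round(np.exp(rng.normal(icu_mu, params.los_log_sd)), 1)
    # hospital stay contains the ICU stay
    hosp_los = np.maximum(hosp_los, icu_los)

    mv = binary(params.mv_present, allow_unknown=False)
    mv_days = np.where(
        mv == "yes", np.round(rng.exponential(np.asarray(params.mv_days_mean)[a]), 1), 0.0
    )
    vaso_days = np.round(
        rng.exponential(np.asarray(params.vasopressor_days_mean)[a]) * (rng.random(n) < 0.5), 1
    )
    apache = np.round(np.clip(rng.normal(np.asarray(params.apache2_mean)[a], params.apache2_sd), 0, None), 1)
    mrc = np.round(np.clip(rng.normal(np.asarray(params.mrcicu_mean)[a], params.mrcicu_sd), 0, None), 1)

    return pd.DataFrame(
        {
            "mortality": binary(params.mortality, allow_unknown=False),
            "hosp_los_days": hosp_los,
            "icu_los_days": icu_los,
            "delirium": binary(params.delirium, allow_unknown=True),
            "aki": binary(params.aki, allow_unknown=True),
            "vasopressor_days": vaso_days,
            "mv_present": mv,
            "mv_days": mv_days,
            "fluid_overload": binary(params.fluid_overload, allow_unknown=True),
            "apache2_24h": apache,
            "mrcicu_24h": mrc,
        }
    )


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Simulate a cohort: MAR event table, raw outcome table, ground truth.

    Medication receipt is Bernoulli: probability ``block_usage[archetype,
    block]`` for block medications and ``background_rate`` for background
    medications.  Every received medication spawns at least one
    administration event with an action drawn from ``action_probs``; the
    first event of every patient is forced to "Given" so each patient
    survives the action filter.  Duplicate and incomplete rows are injected
    at the configured rates, and a small fraction of patients receive a
    second (non-index) admission.  Fully reproducible from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_pat, n_med = spec.n_patients, spec.n_medications
    patient_ids = [f"P{i:05d}" for i in range(1, n_pat + 1)]
    med_names = _medication_names(n_med)

    block_size = spec.resolved_block_size()
    med_block = np.zeros(n_med, dtype=int)
    for b in range(spec.n_blocks):
        med_block[b * block_size : (b + 1) * block_size] = b + 1

    archetype = rng.integers(1, spec.n_archetypes + 1, size=n_pat)

    # receipt probabilities: [patient, med]
    prob = np.empty((n_pat, n_med), dtype=float)
    bg = med_block == 0
    prob[:, bg] = spec.background_rate
    for b in range(1, spec.n_blocks + 1):
        cols = med_block == b
        prob[:, cols] = spec.block_usage[archetype - 1, b - 1][:, None]
    receipt = rng.random((n_pat, n_med)) < prob

    # guarantee every patient receives at least one medication
    empty = ~receipt.any(axis=1)
    if empty.any():
        logger.warning(
            "%d patients drew an empty medication profile; forcing one receipt each",
            int(empty.sum()),
        )
        forced = rng.integers(0, n_med, size=int(empty.sum()))
        receipt[np.flatnonzero(empty), forced] = True

    outcomes = _sample_outcomes(rng, archetype, spec.outcome_params, spec.unknown_label_rate)
    outcomes.insert(0, "patient_id", patient_ids)

    action_names = list(ACTION_LABELS)
    action_p = np.array([spec.action_probs.get(nm, 0.0) for nm in action_names])

    base = pd.Timestamp("2024-01-01")
    rows: list[tuple] = []
    pat_idx, med_idx = np.nonzero(receipt)
    n_events = 1 + rng.poisson(spec.events_per_med_mean - 1.0, size=pat_idx.size)
    los = outcomes["icu_los_days"].to_numpy(dtype=float).clip(min=0.25)
    for j in range(pat_idx.size):
        p, m = int(pat_idx[j]), int(med_idx[j])
        pid = patient_ids[p]
        for e in range(int(n_events[j])):
            name = med_names[m]
            if spec.decorate_names:
                if rng.random() < 0.5:
                    name = name.capitalize()
                if rng.random() < 0.3:
                    name = name + NAME_DECORATIONS[int(rng.integers(len(NAME_DECORATIONS)))]
            act = action_names[int(rng.choice(len(action_names), p=action_p))]
            ts = base + pd.Timedelta(days=float(rng.random() * los[p]))
            rows.append((pid, 1, name, act, ts.isoformat()))

    records = pd.DataFrame(rows, columns=MAR_COLUMNS)

    # force one "Given" per patient: first event of each patient
    first_rows = records.groupby("patient_id", sort=False).head(1).index
    records.loc[first_rows, "action"] = "Given"

    # repeat admissions: duplicate a handful of events under admission_index 2
    n_repeat = int(rng.binomial(n_pat, spec.repeat_admission_rate))
    if n_repeat:
        repeat_pats = rng.choice(patient_ids, size=n_repeat, replace=False)
        extra = records[records["patient_id"].isin(repeat_pats)].groupby("patient_id").head(3).copy()
        extra["admission_index"] = 2
        extra["timestamp"] = (
            pd.to_datetime(extra["timestamp"]) + pd.Timedelta(days=60)
        ).map(pd.Timestamp.isoformat)
        records = pd.concat([records, extra], ignore_index=True)

    records = corrupt_records(records, spec.duplicate_rate, spec.incomplete_rate, rng=rng)

    truth = CohortTruth(
        patient_archetype=pd.Series(archetype, index=pd.Index(patient_ids, name="patient_id"), name="archetype"),
        medication_block=pd.Series(med_block, index=pd.Index(med_names, name="medication_name"), name="block"),
    )
    return records, outcomes, truth


def corrupt_records(
    records: pd.DataFrame,
    duplicate_rate: float,
    incomplete_rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Append exact duplicates and blanked-field copies of existing rows.

    Original rows are preserved; a Binomial(n, rate) number of duplicates
    and incomplete rows (empty medication name or empty action) is appended.
    """
    for name, rate in (("duplicate_rate", duplicate_rate), ("incomplete_rate", incomplete_rate)):
        if not 0.0 <= rate <= 1.0:
            raise CohortSpecError(f"{name}: must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(records)
    out = [records]
    if n and duplicate_rate > 0:
        dup_mask = rng.random(n) < duplicate_rate
        out.append(records.loc[dup_mask].copy())
    if n and incomplete_rate > 0:
        inc_mask = rng.random(n) < incomplete_rate
        inc = records.loc[inc_mask].copy()
        if len(inc):
            blank_med = rng.random(len(inc)) < 0.5
            inc.loc[blank_med, "medication_name"] = ""
            inc.loc[~blank_med, "action"] = ""
            out.append(inc)
    return pd.concat(out, ignore_index=True) if len(out) > 1 else records.copy()
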