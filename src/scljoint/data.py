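"""Linked longitudinal + survival tables for a transplant drug-monitoring cohort.

The package works on two delimited-text tables: a long-format table of repeated
serum drug-level measurements (one row per visit) and a one-row-per-subject
table with the follow-up time, death indicator and baseline covariates.  Raw
biomarker values are stored in ng/mL; on reading they are divided by a
``scale_factor`` (default 1000, i.e. the model works in µg/mL) so that the
fitted coefficients are of order one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DISEASE_LEVELS = ("pulmonary_fibrosis", "bronchiectasis", "copd")
DISEASE_REFERENCE = "pulmonary_fibrosis"

LONGITUDINAL_COLUMNS = ("subject_id", "time", "y_raw")
SUBJECT_COLUMNS = (
    "subject_id", "event_time", "event",
    "sex", "age", "bmi", "ar", "cmv", "disease",
)

#: binary covariates of SubjectRecord, in canonical order
BINARY_COVARIATES = ("sex", "ar", "cmv")


class SchemaError(ValueError):
    """A required column is missing or has an unusable dtype."""


class ReferentialError(ValueError):
    """A measurement refers to a subject_id absent from the subject table."""


class ValidationError(ValueError):
    """A value violates a domain invariant (times, indicators, categories)."""


@dataclass(frozen=True)
class LongitudinalRecord:
    """One biomarker measurement: subject, months since transplant, value.

    ``y`` is on the model scale (raw ng/mL divided by the dataset's
    scale_factor).
    """

    subject_id: str
    time: float
    y: float


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject survival outcome and baseline covariates.

    event_time is months from transplant to death (event=1) or administrative
    censoring (event=0).  ``disease`` is the 3-level underlying-disease
    category with pulmonary_fibrosis as the reference level.
    """

    subject_id: str
    event_time: float
    event: int
    sex: int
    age: float
    bmi: float
    ar: int
    cmv: int
    disease: str


@dataclass
class Dataset:
    """A validated cohort: subjects plus their repeated measurements."""

    subjects: tuple[SubjectRecord, ...]
    measurements: tuple[LongitudinalRecord, ...]
    scale_factor: float = 1000.0
    n_dropped_post_event: int = field(default=0, compare=False)

    # -- container basics -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return len(self.measurements)

    def subject_frame(self) -> pd.DataFrame:
        cols = {c: [getattr(s, c) for s in self.subjects] for c in SUBJECT_COLUMNS}
        return pd.DataFrame(cols)

    def measurement_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [m.subject_id for m in self.measurements],
                "time": [m.time for m in self.measurements],
                "y": [m.y for m in self.measurements],
            }
        )

    def measurements_of(self, subject_id: str) -> tuple[LongitudinalRecord, ...]:
        return tuple(m for m in self.measurements if m.subject_id == subject_id)

    def counts_per_subject(self) -> dict[str, int]:
        counts = {s.subject_id: 0 for s in self.subjects}
        for m in self.measurements:
            counts[m.subject_id] += 1
        return counts

    # -- validation --------------------------------------------------------
    def validate(self) -> "Dataset":
        """Check all domain invariants; raise on the first violation."""
        if self.scale_factor <= 0:
            raise ValidationError("scale_factor must be positive")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate subject_id in subject table")
        event_time = {}
        for s in self.subjects:
            if not np.isfinite(s.event_time) or s.event_time <= 0:
                raise ValidationError(f"subject {s.subject_id}: event_time must be > 0")
            if s.event not in (0, 1):
                raise ValidationError(f"subject {s.subject_id}: event must be 0 or 1")
            if s.disease not in DISEASE_LEVELS:
                raise ValidationError(
                    f"subject {s.subject_id}: disease {s.disease!r} not in {DISEASE_LEVELS}"
                )
            if s.sex not in (0, 1) or s.ar not in (0, 1) or s.cmv not in (0, 1):
                raise ValidationError(f"subject {s.subject_id}: binary covariate not in {{0,1}}")
            for name in ("age", "bmi"):
                if not np.isfinite(getattr(s, name)):
                    raise ValidationError(f"subject {s.subject_id}: non-finite {name}")
            event_time[s.subject_id] = s.event_time
        seen: set[tuple[str, float]] = set()
        for m in self.measurements:
            if m.subject_id not in event_time:
                raise ReferentialError(
                    f"measurement refers to unknown subject_id {m.subject_id!r}"
                )
            if not np.isfinite(m.time) or m.time <= 0:
                raise ValidationError(f"subject {m.subject_id}: measurement time must be > 0")
            if not np.isfinite(m.y):
                raise ValidationError(f"subject {m.subject_id}: non-finite biomarker value")
            if m.time > event_time[m.subject_id]:
                raise ValidationError(
                    f"subject {m.subject_id}: measurement at t={m.time} after "
                    f"event_time={event_time[m.subject_id]}"
                )
            key = (m.subject_id, m.time)
            if key in seen:
                raise ValidationError(f"duplicate (subject_id, time) pair {key}")
            seen.add(key)
        return self


# -- construction helpers --------------------------------------------------

def dataset_from_frames(
    subject_df: pd.DataFrame,
    measurement_df: pd.DataFrame,
    scale_factor: float = 1000.0,
    *,
    y_column: str = "y",
    validate: bool = True,
    n_dropped_post_event: int = 0,
) -> Dataset:
    """Build a Dataset from in-memory frames (``y_column`` already model scale)."""
    subjects = tuple(
        SubjectRecord(
            subject_id=str(r.subject_id),
            event_time=float(r.event_time),
            event=int(r.event),
            sex=int(r.sex),
            age=float(r.age),
            bmi=float(r.bmi),
            ar=int(r.ar),
            cmv=int(r.cmv),
            disease=str(r.disease),
        )
        for r in subject_df.itertuples()
    )
    measurements = tuple(
        LongitudinalRecord(
            subject_id=str(r.subject_id),
            time=float(r.time),
            y=float(getattr(r, y_column)),
        )
        for r in measurement_df.itertuples()
    )
    ds = Dataset(subjects, measurements, float(scale_factor),
                 n_dropped_post_event=n_dropped_post_event)
    if validate:
        ds.validate()
    return ds


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_dataset(
    longitudinal_path,
    subject_path,
    scale_factor: float = 1000.0,
) -> Dataset:
    """Read and validate the two CSV tables.

    Raw biomarker values (column ``y_raw``, ng/mL) are divided by
    ``scale_factor``.  Measurements recorded after a subject's event/censoring
    time are dropped with a logged warning; the dropped count is available as
    ``Dataset.n_dropped_post_event``.
    """
    if scale_factor <= 0:
        raise ValidationError("scale_factor must be positive")
    long_df = pd.read_csv(longitudinal_path)
    subj_df = pd.read_csv(subject_path)
    _require_columns(long_df, LONGITUDINAL_COLUMNS, longitudinal_path)
    _require_columns(subj_df, SUBJECT_COLUMNS, subject_path)

    subj_df = subj_df.copy()
    subj_df["subject_id"] = subj_df["subject_id"].astype(str)
    long_df = long_df.copy()
    long_df["subject_id"] = long_df["subject_id"].astype(str)

    known = set(subj_df["subject_id"])
    unknown = sorted(set(long_df["subject_id"]) - known)
    if unknown:
        raise ReferentialError(
            f"{longitudinal_path}: measurements for unknown subject_id(s) {unknown[:5]}"
        )
    if (long_df["time"] <= 0).any():
        raise ValidationError(f"{longitudinal_path}: non-positive measurement time")
    if (subj_df["event_time"] <= 0).any():
        raise ValidationError(f"{subject_path}: non-positive event_time")

    event_time = subj_df.set_index("subject_id")["event_time"]
    limit = long_df["subject_id"].map(event_time)
    post_event = long_df["time"] > limit
    n_dropped = int(post_event.sum())
    if n_dropped:
        logger.warning(
            "dropping %d measurement(s) recorded after the subject's event/censoring time",
            n_dropped,
        )
        long_df = long_df.loc[~post_event]

    long_df["y"] = long_df["y_raw"] / scale_factor
    return dataset_from_frames(
        subj_df, long_df, scale_factor,
        n_dropped_post_event=n_dropped,
    )


def write_dataset(dataset: Dataset, longitudinal_path, subject_path) -> None:
    """Write the two CSV tables (header row, times in months, y back in ng/mL)."""
    mdf = dataset.measurement_frame()
    mdf["y_raw"] = mdf["y"] * dataset.scale_factor
    mdf[list(LONGITUDINAL_COLUMNS)].to_csv(
        longitudinal_path, index=False, float_format="%.12g"
    )
    dataset.subject_frame()[list(SUBJECT_COLUMNS)].to_csv(
        subject_path, index=False, float_format="%.12g"
    )


# -- cohort summary ---------------------------------------------------------

def summarize_dataset(dataset: Dataset) -> dict:
    """Cohort summary in the layout of a baseline-characteristics table.

    Returns counts, covariate means/SDs, category percentages (of subjects),
    the per-subject measurement count range, and follow-up/event totals.
    """
    dataset.validate()
    sdf = dataset.subject_frame()
    counts = np.array(list(dataset.counts_per_subject().values())) if dataset.n_subjects else np.array([0])
    n = dataset.n_subjects

    def pct(mask) -> float:
        return 100.0 * float(np.mean(mask)) if n else float("nan")

    summary = {
        "n_subjects": n,
        "n_measurements": dataset.n_obs,
        "measurements_per_subject_min": int(counts.min()) if n else 0,
        "measurements_per_subject_max": int(counts.max()) if n else 0,
        "male_pct": pct(sdf["sex"] == 1) if n else float("nan"),
        "age_mean": float(sdf["age"].mean()) if n else float("nan"),
        "age_sd": float(sdf["age"].std(ddof=1)) if n > 1 else float("nan"),
        "bmi_mean": float(sdf["bmi"].mean()) if n else float("nan"),
        "bmi_sd": float(sdf["bmi"].std(ddof=1)) if n > 1 else float("nan"),
        "ar_pct": pct(sdf["ar"] == 1) if n else float("nan"),
        "cmv_pct": pct(sdf["cmv"] == 1) if n else float("nan"),
        "disease_pct": {
            level: pct(sdf["disease"] == level) if n else float("nan")
            for level in DISEASE_LEVELS
        },
        "n_events": int(sdf["event"].sum()) if n else 0,
        "follow_up_mean_months": float(sdf["event_time"].mean()) if n else float("nan"),
        "follow_up_sd_months": float(sdf["event_time"].std(ddof=1)) if n > 1 else float("nan"),
    }
    return summary
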