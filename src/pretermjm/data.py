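"""Cohort data containers and CSV I/O.

A cohort is two tables:

``longitudinal`` (long format, one row per glucose reading)
    ``id`` (subject), ``day`` (gestational day), ``log_glucose``.

``subjects`` (one row per woman)
    ``id``, ``age_lmp`` (age at last menstrual period, years),
    ``age_onset`` (age at diabetes onset, years), ``nephropathy`` (0/1),
    ``delivery_day`` (gestational day of delivery), ``preterm`` (0/1,
    derived: delivery before day 259 = 37 completed weeks).

Validation enforces the structural facts the models rely on: every
reading on or before its woman's delivery day, a reading present on the
delivery day itself (delivery-day glucose is observed for every woman),
at least one reading per woman, and the preterm flag consistent with the
threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CohortData", "PRETERM_THRESHOLD_DAY", "CohortValidationError"]

PRETERM_THRESHOLD_DAY = 259.0  # 37 completed weeks of gestation

LONG_COLUMNS = ["id", "day", "log_glucose"]
SUBJ_COLUMNS = ["id", "age_lmp", "age_onset", "nephropathy", "delivery_day", "preterm"]


class CohortValidationError(ValueError):
    """A cohort table violates a structural invariant."""


@dataclass
class CohortData:
    """Observed cohort: longitudinal glucose readings plus subject table."""

    longitudinal: pd.DataFrame
    subjects: pd.DataFrame
    provenance: dict | None = field(default=None)

    def __post_init__(self) -> None:
        self.longitudinal = self.longitudinal.reset_index(drop=True)
        self.subjects = self.subjects.reset_index(drop=True)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self, threshold_day: float = PRETERM_THRESHOLD_DAY) -> None:
        errs: list[str] = []
        for col in LONG_COLUMNS:
            if col not in self.longitudinal.columns:
                errs.append(f"longitudinal table missing column {col!r}")
        for col in SUBJ_COLUMNS:
            if col not in self.subjects.columns:
                errs.append(f"subjects table missing column {col!r}")
        if errs:
            raise CohortValidationError("; ".join(errs))
        subj = self.subjects
        if subj["id"].duplicated().any():
            dup = subj.loc[subj["id"].duplicated(), "id"].tolist()
            # fatal immediately: later checks index by id
            raise CohortValidationError(f"duplicate subject ids {dup}")
        ids = set(subj["id"])
        orphan = ~self.longitudinal["id"].isin(ids)
        if orphan.any():
            rows = self.longitudinal.index[orphan].tolist()[:5]
            errs.append(f"readings for unknown subject ids at rows {rows}")
        delivery = subj.set_index("id")["delivery_day"]
        merged_delivery = self.longitudinal["id"].map(delivery)
        late = self.longitudinal["day"] > merged_delivery + 1e-9
        if late.any():
            rows = self.longitudinal.index[late].tolist()[:5]
            errs.append(f"readings after delivery at rows {rows}")
        counts = self.longitudinal.groupby("id").size()
        missing = ids - set(counts.index)
        if missing:
            errs.append(f"subjects with no readings: {sorted(missing)[:5]}")
        # a reading must exist on the delivery day
        last_day = self.longitudinal.groupby("id")["day"].max()
        for sid, ddate in delivery.items():
            if sid in last_day.index and abs(last_day[sid] - ddate) > 1e-9:
                errs.append(
                    f"subject {sid}: no reading on delivery day "
                    f"(last reading day {last_day[sid]}, delivery {ddate})"
                )
                if len(errs) > 8:
                    break
        bad_flag = subj["preterm"].astype(bool) != (subj["delivery_day"] < threshold_day)
        if bad_flag.any():
            errs.append(
                f"preterm flag inconsistent with delivery day for ids "
                f"{subj.loc[bad_flag, 'id'].tolist()[:5]}"
            )
        if errs:
            raise CohortValidationError("; ".join(errs))

    # ------------------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_readings(self) -> int:
        return len(self.longitudinal)

    def reading_counts(self) -> pd.Series:
        return self.longitudinal.groupby("id").size()

    def preterm_fraction(self) -> float:
        return float(self.subjects["preterm"].mean())

    def subject(self, sid) -> pd.Series:
        row = self.subjects[self.subjects["id"] == sid]
        if row.empty:
            raise KeyError(f"unknown subject id {sid!r}")
        return row.iloc[0]

    def readings_for(self, sid) -> pd.DataFrame:
        if sid not in set(self.subjects["id"]):
            raise KeyError(f"unknown subject id {sid!r}")
        return self.longitudinal[self.longitudinal["id"] == sid]

    # -- I/O ------------------------------------------------------------
    def write(self, directory, stem: str = "cohort") -> dict[str, Path]:
        """Write longitudinal/subject CSVs plus a JSON provenance sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "longitudinal": directory / f"{stem}_longitudinal.csv",
            "subjects": directory / f"{stem}_subjects.csv",
            "provenance": directory / f"{stem}_provenance.json",
        }
        self.longitudinal.to_csv(paths["longitudinal"], index=False)
        self.subjects.to_csv(paths["subjects"], index=False)
        with open(paths["provenance"], "w") as fh:
            json.dump(self.provenance or {}, fh, indent=2, default=float)
        return paths

    @classmethod
    def read(cls, longitudinal_path, subjects_path, provenance_path=None) -> "CohortData":
        """Load and validate a cohort from its two CSV files."""
        longitudinal = pd.read_csv(longitudinal_path)
        subjects = pd.read_csv(subjects_path)
        prov = None
        if provenance_path is not None and Path(provenance_path).exists():
            with open(provenance_path) as fh:
                prov = json.load(fh)
        return cls(longitudinal=longitudinal, subjects=subjects, provenance=prov)

    @classmethod
    def from_frames(
        cls, longitudinal: pd.DataFrame, subjects: pd.DataFrame, provenance=None
    ) -> "CohortData":
        return cls(longitudinal=longitudinal, subjects=subjects, provenance=provenance)

    def pooled_days(self) -> np.ndarray:
        return self.longitudinal["day"].to_numpy(dtype=float)
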