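"""Shared data model for the trial pipeline.

Glucose time series, per-patient trial records, infection events and the
analysis configuration are the containers every downstream stage (variability
metrics, insulin protocol, nutrition accounting, epidemiology) consumes.
Time is real-valued hours since ICU admission; "ICU day k" is the half-open
interval [24*(k-1), 24*k).  Glucose is stored in mg/dL throughout; conversion
to mmol/L happens only inside the lability index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

#: grams-per-mole of glucose divided by 10: mg/dL per mmol/L.
MGDL_PER_MMOL = 18.0182

ARMS = ("A", "B", "C")
GLUCOSE_SOURCES = ("capillary", "plasma")
INFECTION_KINDS = ("vap", "tracheobronchitis", "catheter_bsi", "primary_bsi", "uti")


class GlycotrialError(Exception):
    """Base class for all package errors."""


class SchemaError(GlycotrialError):
    """A file is missing required columns or has an unusable header."""


class DataValidationError(GlycotrialError):
    """Input rows violate the data model (with row/line context)."""


class ConfigError(GlycotrialError):
    """A configuration document is contradictory or malformed."""


class DomainError(GlycotrialError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


@dataclass(frozen=True)
class GlucoseReading:
    """One timestamped glucose measurement."""

    patient_id: str
    time_h: float
    value_mgdl: float
    source: str = "capillary"

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise DataValidationError(
                f"{self.patient_id}: time_h must be >= 0, got {self.time_h}"
            )
        if self.value_mgdl <= 0:
            raise DataValidationError(
                f"{self.patient_id}: glucose must be > 0 mg/dL, got {self.value_mgdl}"
            )
        if self.source not in GLUCOSE_SOURCES:
            raise DataValidationError(
                f"{self.patient_id}: unknown source {self.source!r}"
            )


class GlucoseSeries:
    """One patient's time-ordered glucose readings.

    Stores times (hours since ICU admission) and values (mg/dL) as numpy
    arrays.  Times must be strictly increasing: duplicate timestamps are
    rejected rather than averaged because the lability index divides by
    inter-reading gaps.
    """

    __slots__ = ("patient_id", "time_h", "value_mgdl", "source")

    def __init__(
        self,
        patient_id: str,
        time_h: Sequence[float],
        value_mgdl: Sequence[float],
        source: str | Sequence[str] = "capillary",
    ) -> None:
        t = np.asarray(time_h, dtype=float)
        v = np.asarray(value_mgdl, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise DataValidationError(
                f"{patient_id}: time and value arrays must be 1-D and equal length"
            )
        order = np.argsort(t, kind="stable")
        t, v = t[order], v[order]
        if isinstance(source, str):
            src = np.full(t.shape, source, dtype=object)
        else:
            src = np.asarray(source, dtype=object)[order]
        if t.size and t[0] < 0:
            raise DataValidationError(f"{patient_id}: negative time_h {t[0]}")
        if np.any(v <= 0):
            bad = v[v <= 0][0]
            raise DataValidationError(f"{patient_id}: non-positive glucose {bad}")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            i = int(np.argmax(np.diff(t) <= 0))
            raise DataValidationError(
                f"{patient_id}: duplicate timestamp at t={t[i]} h "
                "(ties are rejected, not averaged)"
            )
        self.patient_id = patient_id
        self.time_h = t
        self.value_mgdl = v
        self.source = src

    @property
    def n(self) -> int:
        return int(self.time_h.size)

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[GlucoseReading]:
        for t, v, s in zip(self.time_h, self.value_mgdl, self.source):
            yield GlucoseReading(self.patient_id, float(t), float(v), str(s))

    def day_slice(self, day: int) -> "GlucoseSeries":
        """Readings with time in [24*(day-1), 24*day); day is 1-based."""
        if day < 1:
            raise DomainError(f"day must be >= 1, got {day}")
        lo, hi = 24.0 * (day - 1), 24.0 * day
        mask = (self.time_h >= lo) & (self.time_h < hi)
        return self._subset(mask)

    def window_slice(self, first_day: int, last_day: int) -> "GlucoseSeries":
        """Readings falling in ICU days first_day..last_day inclusive."""
        if first_day < 1 or last_day < first_day:
            raise DomainError(f"bad day window ({first_day}, {last_day})")
        lo, hi = 24.0 * (first_day - 1), 24.0 * last_day
        mask = (self.time_h >= lo) & (self.time_h < hi)
        return self._subset(mask)

    def _subset(self, mask: np.ndarray) -> "GlucoseSeries":
        out = object.__new__(GlucoseSeries)
        out.patient_id = self.patient_id
        out.time_h = self.time_h[mask]
        out.value_mgdl = self.value_mgdl[mask]
        out.source = self.source[mask]
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"GlucoseSeries({self.patient_id!r}, n={self.n})"


@dataclass(frozen=True)
class InfectionEvent:
    """An ICU infection with onset in hours since admission.

    Events with onset >= 48 h count as ICU-acquired (see
    ``analysis.acquired_filter``); earlier onsets are community/admission
    infections and are retained in the record but excluded from acquired
    rates.
    """

    patient_id: str
    kind: str
    onset_h: float

    def __post_init__(self) -> None:
        if self.kind not in INFECTION_KINDS:
            raise DataValidationError(f"unknown infection kind {self.kind!r}")
        if self.onset_h < 0:
            raise DataValidationError(f"negative onset_h {self.onset_h}")


@dataclass
class PatientRecord:
    """One randomized patient: arm, exposures, insulin, infections, outcomes."""

    patient_id: str
    arm: str
    center_id: str
    ventilator_days: float = 0.0
    en_days: float = 0.0
    icu_days: float = 0.0
    daily_insulin_iu: list[float] = field(default_factory=list)
    infection_events: list[InfectionEvent] = field(default_factory=list)
    death_day_28: bool = False
    death_6mo: bool = False
    closed_early: bool = False
    closed_early_reason: str = ""
    age: float | None = None
    bmi: float | None = None
    weight_kg: float | None = None
    diabetes: bool | None = None
    diagnostic_group: str | None = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise DataValidationError(
                f"{self.patient_id}: arm must be one of {ARMS}, got {self.arm!r}"
            )
        for name in ("ventilator_days", "en_days", "icu_days"):
            if getattr(self, name) < 0:
                raise DataValidationError(f"{self.patient_id}: negative {name}")
        if any(x < 0 for x in self.daily_insulin_iu):
            raise DataValidationError(f"{self.patient_id}: negative daily insulin")
        # discharge bookkeeping varies between centers; warn, do not reject
        if self.ventilator_days > self.icu_days > 0:
            warnings.warn(
                f"{self.patient_id}: ventilator_days ({self.ventilator_days}) "
                f"exceed icu_days ({self.icu_days})",
                stacklevel=2,
            )


@dataclass(frozen=True)
class AnalysisConfig:
    """Clinical thresholds and numerical conventions for every stage.

    Defaults encode the trial protocol: glycemic target 110-150 mg/dL,
    insulin started at >=150 mg/dL, severe hypoglycemia <50 mg/dL, moderate
    hypoglycemia 50-80 mg/dL, variability reported over ICU days 1-7 and
    1-28, and 8-h feeding/insulin interruptions starting days 3, 7, 14, 21
    and 28.
    """

    target_low: float = 110.0
    target_high: float = 150.0
    insulin_start_threshold: float = 150.0
    hypo_severe_upper: float = 50.0
    hypo_moderate_bounds: tuple[float, float] = (50.0, 80.0)
    windows: tuple[tuple[int, int], ...] = ((1, 7), (1, 28))
    max_pair_gap_h: float = 12.0
    mgdl_per_mmol: float = MGDL_PER_MMOL
    interruption_days: tuple[int, ...] = (3, 7, 14, 21, 28)
    interruption_start_h: float = 0.0
    interruption_len_h: float = 8.0
    acquired_onset_h: float = 48.0
    reporting_precision: int = 2

    def __post_init__(self) -> None:
        if not self.target_low < self.target_high:
            raise ConfigError(
                f"target_low ({self.target_low}) must be < target_high "
                f"({self.target_high})"
            )
        lo, hi = self.hypo_moderate_bounds
        if not 0 < lo <= hi:
            raise ConfigError(f"bad hypo_moderate_bounds {self.hypo_moderate_bounds}")
        for name in (
            "insulin_start_threshold",
            "hypo_severe_upper",
            "max_pair_gap_h",
            "mgdl_per_mmol",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for a, b in self.windows:
            if a < 1 or b < a:
                raise ConfigError(f"bad day window ({a}, {b})")

    def interruption_windows(self) -> list[tuple[float, float]]:
        """Absolute-hour [start, end) intervals of the feeding interruptions."""
        out = []
        for d in self.interruption_days:
            start = 24.0 * (d - 1) + self.interruption_start_h
            out.append((start, start + self.interruption_len_h))
        return out

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)
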