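"""CSV interchange and configuration loading.

Schemas (documented here and in the README):

* ``glucose.csv``:    patient_id, time_h, value_mgdl, source
* ``patients.csv``:   patient_id, arm, center_id, ventilator_days, en_days,
                      icu_days, death_day_28, death_6mo, closed_early
                      (optional: weight_kg, age, bmi, diabetes,
                      diagnostic_group, closed_early_reason)
* ``infections.csv``: patient_id, kind, onset_h
* ``insulin.csv``:    patient_id, day, insulin_iu
* ``volumes.csv``:    patient_id, day, volume_prescribed_ml,
                      volume_administered_ml, formula, extra_kcal

Validation is total: malformed inputs raise structured errors carrying line
numbers; there is never a partial silent result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .model import (
    ARMS,
    GLUCOSE_SOURCES,
    AnalysisConfig,
    ConfigError,
    DataValidationError,
    GlucoseSeries,
    InfectionEvent,
    PatientRecord,
    SchemaError,
)

log = logging.getLogger("glycotrial")

GLUCOSE_COLUMNS = ["patient_id", "time_h", "value_mgdl", "source"]
PATIENT_COLUMNS = [
    "patient_id",
    "arm",
    "center_id",
    "ventilator_days",
    "en_days",
    "icu_days",
    "death_day_28",
    "death_6mo",
    "closed_early",
]
INFECTION_COLUMNS = ["patient_id", "kind", "onset_h"]
VOLUME_COLUMNS = [
    "patient_id",
    "day",
    "volume_prescribed_ml",
    "volume_administered_ml",
    "formula",
    "extra_kcal",
]


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    return df


def read_glucose_csv(
    path: str | Path, source: str | None = "capillary"
) -> dict[str, GlucoseSeries]:
    """Load glucose readings into one time-sorted series per patient.

    By default only capillary readings are kept (the bedside monitoring
    stream every downstream metric uses); pass ``source=None`` to keep all,
    in which case same-time readings from different sources are rejected.
    Rows are validated individually and reported with 1-based line numbers
    (header = line 1).
    """
    df = _read_table(path, GLUCOSE_COLUMNS)
    errors: list[str] = []
    t = pd.to_numeric(df["time_h"], errors="coerce")
    v = pd.to_numeric(df["value_mgdl"], errors="coerce")
    for idx in df.index[t.isna() | v.isna()]:
        errors.append(f"line {idx + 2}: non-numeric time_h/value_mgdl")
    for idx in df.index[~df["source"].isin(GLUCOSE_SOURCES)]:
        errors.append(f"line {idx + 2}: unknown source {df.loc[idx, 'source']!r}")
    dup = df.duplicated(subset=["patient_id", "time_h", "source"], keep=False)
    for idx in df.index[dup & ~df.duplicated(["patient_id", "time_h", "source"])]:
        errors.append(
            f"line {idx + 2}: duplicate (patient, time, source) "
            f"({df.loc[idx, 'patient_id']}, {df.loc[idx, 'time_h']})"
        )
    if errors:
        raise DataValidationError(f"{Path(path).name}: " + "; ".join(errors))
    if source is not None:
        df = df[df["source"] == source]
    out: dict[str, GlucoseSeries] = {}
    for pid, grp in df.groupby("patient_id", sort=False):
        try:
            out[str(pid)] = GlucoseSeries(
                str(pid),
                grp["time_h"].to_numpy(float),
                grp["value_mgdl"].to_numpy(float),
                grp["source"].to_numpy(object),
            )
        except DataValidationError as exc:
            raise DataValidationError(f"{Path(path).name}: {exc}") from exc
    log.info("read %d series (%d readings) from %s", len(out), len(df), path)
    return out


def write_glucose_csv(series: dict[str, GlucoseSeries], path: str | Path) -> None:
    rows = [
        (s.patient_id, t, v, src)
        for s in series.values()
        for t, v, src in zip(s.time_h, s.value_mgdl, s.source)
    ]
    pd.DataFrame(rows, columns=GLUCOSE_COLUMNS).to_csv(path, index=False)


def read_infections_csv(path: str | Path) -> dict[str, list[InfectionEvent]]:
    df = _read_table(path, INFECTION_COLUMNS)
    errors = []
    out: dict[str, list[InfectionEvent]] = {}
    for idx, row in df.iterrows():
        try:
            ev = InfectionEvent(
                str(row["patient_id"]), str(row["kind"]), float(row["onset_h"])
            )
        except (DataValidationError, ValueError) as exc:
            errors.append(f"line {idx + 2}: {exc}")
            continue
        out.setdefault(ev.patient_id, []).append(ev)
    if errors:
        raise DataValidationError(f"{Path(path).name}: " + "; ".join(errors))
    return out


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in {"true", "1", "yes"}
    return bool(x)


def read_patient_csv(
    path: str | Path,
    infections_path: str | Path | None = None,
    insulin_path: str | Path | None = None,
) -> list[PatientRecord]:
    """Load patient records, optionally joining infection and insulin tables.

    Infection rows referencing a patient absent from ``patients.csv`` are a
    referential error.
    """
    df = _read_table(path, PATIENT_COLUMNS)
    infections = read_infections_csv(infections_path) if infections_path else {}
    insulin: dict[str, list[float]] = {}
    if insulin_path is not None:
        idf = _read_table(insulin_path, ["patient_id", "day", "insulin_iu"])
        for pid, grp in idf.groupby("patient_id", sort=False):
            insulin[str(pid)] = (
                grp.sort_values("day")["insulin_iu"].astype(float).tolist()
            )

    errors = []
    records: list[PatientRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        pid = str(row["patient_id"])
        if pid in seen:
            errors.append(f"line {idx + 2}: duplicate patient_id {pid}")
            continue
        seen.add(pid)
        try:
            rec = PatientRecord(
                patient_id=pid,
                arm=str(row["arm"]),
                center_id=str(row["center_id"]),
                ventilator_days=float(row["ventilator_days"]),
                en_days=float(row["en_days"]),
                icu_days=float(row["icu_days"]),
                daily_insulin_iu=insulin.get(pid, []),
                infection_events=infections.get(pid, []),
                death_day_28=_as_bool(row["death_day_28"]),
                death_6mo=_as_bool(row["death_6mo"]),
                closed_early=_as_bool(row["closed_early"]),
                closed_early_reason=str(row.get("closed_early_reason", "") or ""),
                weight_kg=(
                    float(row["weight_kg"]) if "weight_kg" in df.columns else None
                ),
            )
        except (DataValidationError, ValueError) as exc:
            errors.append(f"line {idx + 2}: {exc}")
            continue
        records.append(rec)
    orphans = set(infections) - seen
    if orphans:
        errors.append(f"infection rows reference absent patients: {sorted(orphans)}")
    if errors:
        raise DataValidationError(f"{Path(path).name}: " + "; ".join(errors))
    return records


def write_patient_csv(records: list[PatientRecord], path: str | Path) -> None:
    cols = PATIENT_COLUMNS + ["closed_early_reason", "weight_kg"]
    rows = [
        (
            r.patient_id,
            r.arm,
            r.center_id,
            r.ventilator_days,
            r.en_days,
            r.icu_days,
            r.death_day_28,
            r.death_6mo,
            r.closed_early,
            r.closed_early_reason,
            r.weight_kg,
        )
        for r in records
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_infections_csv(records: list[PatientRecord], path: str | Path) -> None:
    rows = [
        (ev.patient_id, ev.kind, ev.onset_h)
        for r in records
        for ev in r.infection_events
    ]
    pd.DataFrame(rows, columns=INFECTION_COLUMNS).to_csv(path, index=False)


def write_insulin_csv(records: list[PatientRecord], path: str | Path) -> None:
    rows = [
        (r.patient_id, day, iu)
        for r in records
        for day, iu in enumerate(r.daily_insulin_iu, start=1)
    ]
    pd.DataFrame(rows, columns=["patient_id", "day", "insulin_iu"]).to_csv(
        path, index=False
    )


_CONFIG_KEYS = {
    "target_low",
    "target_high",
    "insulin_start_threshold",
    "hypo_severe_upper",
    "hypo_moderate_bounds",
    "windows",
    "max_pair_gap_h",
    "mgdl_per_mmol",
    "interruption_days",
    "interruption_start_h",
    "interruption_len_h",
    "acquired_onset_h",
    "reporting_precision",
}


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load an AnalysisConfig from a YAML/JSON key-value document.

    Absent fields fall back to the protocol defaults (110-150 mg/dL target,
    insulin start at 150, severe hypoglycemia <50, moderate 50-80).  An
    empty or missing document yields the pure defaults.
    """
    if path is None:
        return AnalysisConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    if "hypo_moderate_bounds" in raw:
        raw["hypo_moderate_bounds"] = tuple(raw["hypo_moderate_bounds"])
    if "windows" in raw:
        raw["windows"] = tuple(tuple(w) for w in raw["windows"])
    if "interruption_days" in raw:
        raw["interruption_days"] = tuple(raw["interruption_days"])
    return AnalysisConfig(**raw)


@dataclass
class TrialData:
    """A coherent trial dataset: glucose series, patient records, volumes.

    ``volumes`` is the long-format daily nutrition table (see module
    docstring); it may be empty for glucose-only analyses.
    """

    glucose: dict[str, GlucoseSeries]
    patients: list[PatientRecord]
    volumes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=VOLUME_COLUMNS)
    )

    def __post_init__(self) -> None:
        known = {p.patient_id for p in self.patients}
        orphan = set(self.glucose) - known
        if orphan:
            raise DataValidationError(
                f"glucose series for unknown patients: {sorted(orphan)[:5]}"
            )
        if len(self.volumes):
            vorph = set(self.volumes["patient_id"].astype(str)) - known
            if vorph:
                raise DataValidationError(
                    f"volume rows for unknown patients: {sorted(vorph)[:5]}"
                )

    def by_arm(self) -> dict[str, list[PatientRecord]]:
        out: dict[str, list[PatientRecord]] = {a: [] for a in ARMS}
        for p in self.patients:
            out[p.arm].append(p)
        return out

    @classmethod
    def from_dir(cls, path: str | Path) -> "TrialData":
        path = Path(path)
        glucose = read_glucose_csv(path / "glucose.csv")
        inf = path / "infections.csv"
        ins = path / "insulin.csv"
        patients = read_patient_csv(
            path / "patients.csv",
            infections_path=inf if inf.exists() else None,
            insulin_path=ins if ins.exists() else None,
        )
        vol = path / "volumes.csv"
        volumes = (
            _read_table(vol, VOLUME_COLUMNS)
            if vol.exists()
            else pd.DataFrame(columns=VOLUME_COLUMNS)
        )
        return cls(glucose=glucose, patients=patients, volumes=volumes)

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        write_glucose_csv(self.glucose, path / "glucose.csv")
        write_patient_csv(self.patients, path / "patients.csv")
        write_infections_csv(self.patients, path / "infections.csv")
        write_insulin_csv(self.patients, path / "insulin.csv")
        self.volumes.to_csv(path / "volumes.csv", index=False)
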