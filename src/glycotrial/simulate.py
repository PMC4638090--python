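"""Synthetic three-arm trial generator.

Emits a coherent dataset (glucose series, insulin traces, nutrition volumes,
infection events, outcomes) with the statistical structure the analysis
stages assume, so the full pipeline runs with no external data.

The latent capillary glucose of each patient follows a discretized
Ornstein-Uhlenbeck (mean-reverting AR(1)) process: the simplest process with
independently tunable mean, stationary variance and autocorrelation — the
three properties the lability index is sensitive to.  Insulin feedback is a
linear steady-state set-point depression (``insulin_sensitivity`` mg/dL per
IU/h), a minimal closed loop that exercises the protocol engine without any
pharmacokinetic claim.  Readings occur at random 1-4-h intervals, carry
glucometer noise, and are never emitted inside the 8-h blood-test
interruption windows on days 3, 7, 14, 21 and 28.  Infections arrive as
Poisson processes over ventilator time (respiratory) or ICU time (others),
with onsets uniform beyond the 48-h acquired-infection cutoff.

All randomness flows from one integer seed through per-patient sub-streams,
so datasets are reproducible and stable under patient re-ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import TrialData, VOLUME_COLUMNS
from .model import (
    ARMS,
    AnalysisConfig,
    ConfigError,
    GlucoseSeries,
    InfectionEvent,
    PatientRecord,
)
from .nutrition import load_formulas, prescribe_calories
from .protocol import (
    InsulinProtocol,
    InsulinTrace,
    default_protocol,
    protocol_step,
    run_protocol,
)


@dataclass(frozen=True)
class ArmParameters:
    """Generative parameters for one randomization arm."""

    label: str
    n_patients: int
    setpoint_mgdl: float
    between_sd_mgdl: float
    within_sd_mgdl: float
    reversion_per_h: float
    noise_sd_mgdl: float
    insulin_sensitivity: float
    hazard_tracheobronchitis_per_1000vd: float
    hazard_vap_per_1000vd: float
    hazard_catheter_bsi_per_100icud: float
    hazard_primary_bsi_per_100icud: float
    hazard_uti_per_100icud: float
    vent_days_lognorm: tuple[float, float]
    icu_days_lognorm: tuple[float, float]
    en_days_lognorm: tuple[float, float]
    mortality_28d: float
    mortality_6mo: float

    def __post_init__(self) -> None:
        for name in (
            "between_sd_mgdl",
            "within_sd_mgdl",
            "reversion_per_h",
            "noise_sd_mgdl",
            "insulin_sensitivity",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"arm {self.label}: {name} must be >= 0")
        for name in ("mortality_28d", "mortality_6mo"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"arm {self.label}: {name} must be in [0, 1]")


@dataclass(frozen=True)
class TrialDesign:
    """Three arms plus randomization and monitoring structure."""

    arms: tuple[ArmParameters, ArmParameters, ArmParameters]
    n_centers: int = 9
    block_size: int = 6
    horizon_days: int = 28
    sampling_interval_h: tuple[float, float] = (1.0, 4.0)
    interruption_days: tuple[int, ...] = (3, 7, 14, 21, 28)
    interruption_len_h: float = 8.0
    closed_early_prob: float = 0.07
    propofol_prob: float = 0.12
    # sliding-scale overrides (e.g. max_rate) applied to the default table;
    # the simulated trial's consensus scale is gentler than the library default
    protocol_overrides: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.block_size % len(self.arms):
            raise ConfigError("block_size must be divisible by the number of arms")
        if tuple(a.label for a in self.arms) != ARMS:
            raise ConfigError(f"arms must be labelled {ARMS} in order")
        lo, hi = self.sampling_interval_h
        if not 0 < lo <= hi:
            raise ConfigError("bad sampling_interval_h")

    @property
    def n_patients(self) -> int:
        return sum(a.n_patients for a in self.arms)

    def arm(self, label: str) -> ArmParameters:
        return self.arms[ARMS.index(label)]

    def analysis_config(self) -> AnalysisConfig:
        return AnalysisConfig(
            interruption_days=self.interruption_days,
            interruption_len_h=self.interruption_len_h,
        )

    def protocol(self) -> InsulinProtocol:
        return replace(default_protocol(), **dict(self.protocol_overrides))


def load_design(path: str | Path | None = None) -> TrialDesign:
    """Load a TrialDesign from YAML; default is the bundled calibration."""
    if path is None:
        text = (resources.files("glycotrial.data") / "trial_arms.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    arms = []
    for label in ARMS:
        if label not in raw.get("arms", {}):
            raise ConfigError(f"design file missing arm {label}")
        spec = dict(raw["arms"][label])
        for k in ("vent_days_lognorm", "icu_days_lognorm", "en_days_lognorm"):
            spec[k] = tuple(spec[k])
        arms.append(ArmParameters(label=label, **spec))
    return TrialDesign(
        arms=tuple(arms),
        n_centers=int(raw.get("n_centers", 9)),
        block_size=int(raw.get("block_size", 6)),
        horizon_days=int(raw.get("horizon_days", 28)),
        sampling_interval_h=tuple(raw.get("sampling_interval_h", (1.0, 4.0))),
        interruption_days=tuple(raw.get("interruption_days", (3, 7, 14, 21, 28))),
        interruption_len_h=float(raw.get("interruption_len_h", 8.0)),
        protocol_overrides=tuple(
            sorted((str(k), float(v)) for k, v in raw.get("protocol", {}).items())
        ),
    )


def parameter_recovery_design(n_per_arm: int = 500) -> TrialDesign:
    """A validation design for parameter-recovery checks.

    Set-points sit below the 150 mg/dL insulin trigger and the feedback gain
    is zero, so the configured set-point is exactly the stationary mean of
    the observed readings — the estimand a recovery check needs.  Hazards and
    exposure distributions are kept at arm-A-like values with distinct
    per-arm set-points.
    """
    base = load_design()
    arms = []
    for label, sp in zip(ARMS, (120.0, 130.0, 140.0)):
        arms.append(
            replace(
                base.arm(label),
                n_patients=n_per_arm,
                setpoint_mgdl=sp,
                between_sd_mgdl=10.0,
                within_sd_mgdl=15.0,
                noise_sd_mgdl=3.0,
                insulin_sensitivity=0.0,
            )
        )
    return replace(base, arms=tuple(arms))


def randomize_blocks(
    design: TrialDesign, seed: int
) -> list[tuple[str, str, str]]:
    """Center-stratified blocked randomization.

    Returns ``(patient_id, arm, center_id)`` triples.  Within every complete
    block of ``block_size`` at a center each arm appears exactly
    ``block_size / 3`` times; incomplete center tails are filled from a
    shuffled global remainder pool constructed so the per-arm totals equal
    the configured arm sizes.
    """
    rng = np.random.default_rng([int(seed), 0])
    total = design.n_patients
    per_center = [total // design.n_centers] * design.n_centers
    for i in range(total % design.n_centers):
        per_center[i] += 1
    n_blocks = sum(n // design.block_size for n in per_center)
    per_block = design.block_size // len(ARMS)
    consumed = n_blocks * per_block
    pool: list[str] = []
    for arm in design.arms:
        spare = arm.n_patients - consumed
        if spare < 0:
            raise ConfigError(
                f"arm {arm.label}: n_patients ({arm.n_patients}) too small for "
                f"{n_blocks} complete blocks"
            )
        pool.extend([arm.label] * spare)
    pool_order = rng.permutation(len(pool))
    pool = [pool[i] for i in pool_order]

    out: list[tuple[str, str, str]] = []
    pid = 0
    block_template = [label for label in ARMS for _ in range(per_block)]
    for c, n_c in enumerate(per_center):
        center = f"C{c + 1:02d}"
        labels: list[str] = []
        for _ in range(n_c // design.block_size):
            block = list(block_template)
            rng.shuffle(block)
            labels.extend(block)
        for _ in range(n_c % design.block_size):
            labels.append(pool.pop())
        for lab in labels:
            pid += 1
            out.append((f"P{pid:03d}", lab, center))
    return out


def _draw_interval(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(rng.uniform(lo, hi))


def simulate_glucose_trajectory(
    arm: ArmParameters,
    design: TrialDesign,
    rng: np.random.Generator,
    patient_id: str = "P000",
    stay_h: float | None = None,
    protocol: InsulinProtocol | None = None,
) -> tuple[GlucoseSeries, InsulinTrace]:
    """Closed-loop glucose/insulin simulation for one patient.

    The latent level reverts toward (patient set-point - sensitivity x
    current infusion rate); readings add glucometer noise and are floored at
    20 mg/dL.  No reading falls inside an interruption window.  The returned
    trace is ``run_protocol`` applied to the emitted series, so simulated
    feedback and accounted insulin are identical by construction.
    """
    protocol = protocol or default_protocol()
    config = design.analysis_config()
    if stay_h is None:
        stay_h = 24.0 * design.horizon_days
    stay_h = min(stay_h, 24.0 * design.horizon_days)
    windows = config.interruption_windows()
    lo, hi = design.sampling_interval_h
    theta = arm.reversion_per_h
    setpoint = arm.setpoint_mgdl + arm.between_sd_mgdl * rng.standard_normal()
    latent = setpoint + arm.within_sd_mgdl * rng.standard_normal()
    rate, active = 0.0, False
    times: list[float] = []
    values: list[float] = []
    t = 0.0
    while True:
        t_next = t + _draw_interval(rng, lo, hi)
        for w0, w1 in windows:
            if w0 <= t_next < w1:
                t_next = w1
                break
        if t_next > stay_h:
            break
        dt = t_next - t
        m_eff = setpoint - arm.insulin_sensitivity * rate
        if theta > 0:
            phi = math.exp(-theta * dt)
            latent = (
                m_eff
                + (latent - m_eff) * phi
                + arm.within_sd_mgdl
                * math.sqrt(max(0.0, 1.0 - phi * phi))
                * rng.standard_normal()
            )
        else:
            latent = m_eff
        reading = max(20.0, latent + arm.noise_sd_mgdl * rng.standard_normal())
        rate, active = protocol_step(rate, reading, protocol, active)
        times.append(t_next)
        values.append(reading)
        t = t_next
    series = GlucoseSeries(patient_id, times, values, "capillary")
    trace = run_protocol(series, protocol, config, end_h=stay_h)
    return series, trace


_INFECTION_EXPOSURE = {
    "tracheobronchitis": ("vent", 1000.0, "hazard_tracheobronchitis_per_1000vd"),
    "vap": ("vent", 1000.0, "hazard_vap_per_1000vd"),
    "catheter_bsi": ("icu", 100.0, "hazard_catheter_bsi_per_100icud"),
    "primary_bsi": ("icu", 100.0, "hazard_primary_bsi_per_100icud"),
    "uti": ("icu", 100.0, "hazard_uti_per_100icud"),
}


def simulate_infections(
    patient_id: str,
    vent_days: float,
    icu_days: float,
    arm: ArmParameters,
    rng: np.random.Generator,
    acquired_onset_h: float = 48.0,
) -> list[InfectionEvent]:
    """Poisson infection events over the appropriate exposure time.

    Counts are Poisson with mean hazard x exposure / scale; onsets are
    uniform over the exposure interval beyond the acquired cutoff (events
    cannot arise in a patient whose exposure ends before 48 h).
    """
    if min(vent_days, icu_days) < 0:
        raise ConfigError("exposures must be >= 0")
    events: list[InfectionEvent] = []
    for kind, (basis, scale, attr) in _INFECTION_EXPOSURE.items():
        exposure_d = vent_days if basis == "vent" else icu_days
        end_h = exposure_d * 24.0
        lam = getattr(arm, attr) * exposure_d / scale
        if lam <= 0 or end_h <= acquired_onset_h:
            continue
        for _ in range(int(rng.poisson(lam))):
            events.append(
                InfectionEvent(
                    patient_id, kind, float(rng.uniform(acquired_onset_h, end_h))
                )
            )
    return sorted(events, key=lambda e: e.onset_h)


def _lognormal(rng: np.random.Generator, mu_sigma: tuple[float, float]) -> float:
    mu, sigma = mu_sigma
    return float(rng.lognormal(mu, sigma))


def simulate_trial(
    design: TrialDesign | None = None,
    seed: int = 0,
    protocol: InsulinProtocol | None = None,
) -> TrialData:
    """Generate a complete, validated trial dataset.

    Deterministic for a given (design, seed); per-patient randomness is keyed
    by the patient's enrolment index so re-ordering patients cannot perturb
    other patients' data.
    """
    design = design or load_design()
    protocol = protocol or design.protocol()
    formulas, arm_map = load_formulas()
    assignment = randomize_blocks(design, seed)

    patients: list[PatientRecord] = []
    glucose: dict[str, GlucoseSeries] = {}
    volume_rows: list[tuple] = []
    for i, (pid, arm_label, center) in enumerate(assignment):
        rng = np.random.default_rng([int(seed), 1, i])
        arm = design.arm(arm_label)
        icu_days = min(_lognormal(rng, arm.icu_days_lognorm), design.horizon_days)
        vent_days = min(_lognormal(rng, arm.vent_days_lognorm), icu_days)
        en_days = min(_lognormal(rng, arm.en_days_lognorm), icu_days)
        series, trace = simulate_glucose_trajectory(
            arm, design, rng, pid, stay_h=icu_days * 24.0, protocol=protocol
        )
        infections = simulate_infections(pid, vent_days, icu_days, arm, rng)
        weight = float(np.clip(rng.normal(75.0, 12.0), 45.0, 120.0))
        death28 = bool(rng.random() < arm.mortality_28d)
        p_extra = (
            (arm.mortality_6mo - arm.mortality_28d) / (1.0 - arm.mortality_28d)
            if arm.mortality_28d < 1.0
            else 0.0
        )
        death6 = death28 or bool(rng.random() < max(0.0, p_extra))
        closed = bool(rng.random() < design.closed_early_prob)

        formula = formulas[arm_map[arm_label]]
        presc_ml = prescribe_calories(weight) / formula.caloric_density_kcal_per_ml
        on_propofol = rng.random() < design.propofol_prob
        n_days = max(1, math.ceil(en_days))
        for day in range(1, n_days + 1):
            frac = min(1.0, en_days - (day - 1))
            vr = float(np.clip(rng.normal(0.805, 0.15), 0.2, 1.0))
            extra = (
                float(rng.uniform(50.0, 300.0))
                if on_propofol and day <= 7
                else 0.0
            )
            volume_rows.append(
                (pid, day, presc_ml * frac, presc_ml * frac * vr, formula.name, extra)
            )

        daily_iu = trace.daily_totals[: max(1, math.ceil(icu_days))]
        patients.append(
            PatientRecord(
                patient_id=pid,
                arm=arm_label,
                center_id=center,
                ventilator_days=vent_days,
                en_days=en_days,
                icu_days=icu_days,
                daily_insulin_iu=[float(x) for x in daily_iu],
                infection_events=infections,
                death_day_28=death28,
                death_6mo=death6,
                closed_early=closed,
                closed_early_reason="complication" if closed else "",
                weight_kg=weight,
            )
        )
        glucose[pid] = series

    volumes = pd.DataFrame(volume_rows, columns=VOLUME_COLUMNS)
    return TrialData(glucose=glucose, patients=patients, volumes=volumes)
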