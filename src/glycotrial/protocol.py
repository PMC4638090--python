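"""Sliding-scale continuous insulin infusion as a table-driven rule engine.

The consensus bedside algorithm is a band table: the current capillary
glucose selects a band, and the band's action updates the infusion rate
(absolute set, delta, proportional scale, hold, or stop).  Infusion starts
only once glucose reaches the start threshold (>=150 mg/dL); a severe
hypoglycemia reading (<50 mg/dL) stops the pump and de-arms it until glucose
again reaches the restart threshold.  The rate is held constant between
capillary checks (zero-order hold) because the infusion is continuous and
only adjusted at measurement times.

The shipped default band table is a reconstruction around the protocol's
published anchor points (start at >=150; stepwise escalation by 50-mg/dL
bands; halve below 110; stop below 80 pending recheck; stop and de-arm
below 50).  The true multicenter table was never published in full, so every
boundary and action is overridable from a YAML band file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .model import AnalysisConfig, ConfigError, DomainError, GlucoseSeries

_ACTIONS = ("stop", "hold", "set", "delta", "scale")


@dataclass(frozen=True)
class ProtocolBand:
    """Glucose interval [low, high) mapped to a rate action."""

    low: float
    high: float  # math.inf for the open top band
    action: str
    amount: float = 0.0

    def __post_init__(self) -> None:
        if self.action not in _ACTIONS:
            raise ConfigError(f"unknown band action {self.action!r}")
        if not self.low < self.high:
            raise ConfigError(f"empty band [{self.low}, {self.high})")
        if self.action in ("set", "scale") and self.amount < 0:
            raise ConfigError(f"{self.action} amount must be >= 0")


@dataclass(frozen=True)
class InsulinProtocol:
    """A validated band table plus arming thresholds."""

    bands: tuple[ProtocolBand, ...]
    start_threshold: float = 150.0
    restart_threshold: float = 150.0
    severe_threshold: float = 50.0
    max_rate: float = 4.0  # IU/h safety ceiling of the syringe-pump scale

    def __post_init__(self) -> None:
        if self.max_rate <= 0:
            raise ConfigError("max_rate must be positive")
        bands = tuple(sorted(self.bands, key=lambda b: b.low))
        object.__setattr__(self, "bands", bands)
        if not bands or bands[0].low != 0.0 or not math.isinf(bands[-1].high):
            raise ConfigError("bands must cover [0, inf)")
        for a, b in zip(bands, bands[1:]):
            if a.high != b.low:
                raise ConfigError(
                    f"bands must partition [0, inf): gap/overlap at {a.high}/{b.low}"
                )

    def band_for(self, glucose: float) -> ProtocolBand:
        for b in self.bands:
            if b.low <= glucose < b.high:
                return b
        raise DomainError(f"glucose {glucose} outside band table")  # pragma: no cover


def default_protocol() -> InsulinProtocol:
    """The bundled reconstruction of the consensus sliding scale."""
    return load_bands(resources.files("glycotrial.data") / "default_bands.yaml")


def load_bands(path: str | Path) -> InsulinProtocol:
    """Load a band table from YAML (schema in data/default_bands.yaml)."""
    raw = yaml.safe_load(Path(str(path)).read_text())
    if not isinstance(raw, dict) or "bands" not in raw:
        raise ConfigError(f"{path}: band file must contain a 'bands' list")
    bands = []
    for i, b in enumerate(raw["bands"]):
        try:
            high = b["high"]
            bands.append(
                ProtocolBand(
                    low=float(b["low"]),
                    high=math.inf if high in (None, ".inf", "inf") else float(high),
                    action=str(b["action"]),
                    amount=float(b.get("amount", 0.0)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: bad band #{i}: {exc}") from exc
    return InsulinProtocol(
        bands=tuple(bands),
        start_threshold=float(raw.get("start_threshold", 150.0)),
        restart_threshold=float(raw.get("restart_threshold", 150.0)),
        severe_threshold=float(raw.get("severe_threshold", 50.0)),
        max_rate=float(raw.get("max_rate", 4.0)),
    )


def protocol_step(
    current_rate: float,
    glucose_mgdl: float,
    protocol: InsulinProtocol,
    active: bool = True,
) -> tuple[float, bool]:
    """One titration decision at a capillary check.

    Returns ``(new_rate, active)``.  ``active=False`` models the pump before
    the start trigger or after a severe-hypoglycemia de-arm: the rate stays 0
    until glucose reaches the (re)start threshold.
    """
    if glucose_mgdl <= 0:
        raise DomainError(f"glucose must be > 0, got {glucose_mgdl}")
    if current_rate < 0:
        raise DomainError(f"rate must be >= 0, got {current_rate}")
    if glucose_mgdl < protocol.severe_threshold:
        return 0.0, False  # stop and de-arm
    if not active:
        if glucose_mgdl < max(protocol.start_threshold, protocol.restart_threshold):
            return 0.0, False
        active = True
    band = protocol.band_for(glucose_mgdl)
    if band.action == "stop":
        return 0.0, True
    if band.action == "hold":
        rate = current_rate
    elif band.action == "set":
        rate = band.amount
    elif band.action == "scale":
        rate = current_rate * band.amount
    else:  # delta
        rate = current_rate + band.amount
    return min(protocol.max_rate, max(0.0, rate)), True


def _integrate_step(
    times: np.ndarray,
    rates: np.ndarray,
    a: float,
    b: float,
    suspensions: list[tuple[float, float]],
    hold_until: float | None = None,
) -> float:
    """Exact integral over [a, b) of the zero-order-hold rate trace.

    The rate is 0 before the first step and inside any suspension window;
    each trace rate holds from its step time to the next step (the last one
    until ``hold_until``, default ``b``).
    """
    total = 0.0
    last_end = b if hold_until is None else max(b, hold_until)
    for i, (t, r) in enumerate(zip(times, rates)):
        if r == 0.0:
            continue
        t_next = times[i + 1] if i + 1 < len(times) else last_end
        lo, hi = max(a, float(t)), min(b, float(t_next))
        if hi <= lo:
            continue
        seg = hi - lo
        for w0, w1 in suspensions:
            seg -= max(0.0, min(hi, w1) - max(lo, w0))
        total += r * seg
    return total


@dataclass
class InsulinTrace:
    """Piecewise-constant infusion-rate history for one patient."""

    patient_id: str
    times: np.ndarray  # step times, h
    glucose: np.ndarray  # reading that triggered each step, mg/dL
    rates: np.ndarray  # IU/h holding from each step time
    daily_totals: list[float] = field(default_factory=list)  # IU per ICU day

    @property
    def total_iu(self) -> float:
        return float(sum(self.daily_totals))


def run_protocol(
    series: GlucoseSeries,
    protocol: InsulinProtocol | None = None,
    config: AnalysisConfig | None = None,
    end_h: float | None = None,
) -> InsulinTrace:
    """Apply the sliding scale to a glucose series.

    The rate changes only at reading times and is held in between; daily
    totals are exact integrals of the resulting step function over each ICU
    day, with the infusion suspended (contributing zero) during the
    configured 8-h blood-test interruption windows.  Integration runs to
    ``end_h`` (default: the last reading time).
    """
    protocol = protocol or default_protocol()
    config = config or AnalysisConfig()
    rate, active = 0.0, False
    rates = np.empty(series.n)
    for i, g in enumerate(series.value_mgdl):
        rate, active = protocol_step(rate, float(g), protocol, active)
        rates[i] = rate
    end = float(end_h) if end_h is not None else (
        float(series.time_h[-1]) if series.n else 0.0
    )
    suspensions = config.interruption_windows()
    n_days = max(1, math.ceil(end / 24.0)) if end > 0 else 1
    daily = []
    for d in range(n_days):
        lo, hi = 24.0 * d, min(24.0 * (d + 1), end)
        # only steps whose hold interval overlaps this day contribute
        i0 = max(0, int(np.searchsorted(series.time_h, lo, side="right")) - 1)
        i1 = int(np.searchsorted(series.time_h, hi, side="left"))
        daily.append(
            _integrate_step(
                series.time_h[i0:i1], rates[i0:i1], lo, hi, suspensions,
                hold_until=(
                    float(series.time_h[i1]) if i1 < series.n else end
                ),
            )
        )
    return InsulinTrace(
        patient_id=series.patient_id,
        times=series.time_h.copy(),
        glucose=series.value_mgdl.copy(),
        rates=rates,
        daily_totals=daily,
    )


def hypoglycemia_episodes(
    series: GlucoseSeries, config: AnalysisConfig | None = None
) -> tuple[int, int]:
    """Per-measurement (severe, moderate) hypoglycemia counts.

    Consecutive in-band readings count separately, matching per-measurement
    episode reporting.
    """
    config = config or AnalysisConfig()
    v = series.value_mgdl
    lo, hi = config.hypo_moderate_bounds
    severe = int(np.count_nonzero(v < config.hypo_severe_upper))
    moderate = int(np.count_nonzero((v >= lo) & (v <= hi)))
    return severe, moderate
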