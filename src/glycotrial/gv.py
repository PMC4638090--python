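"""Glycemic-control and variability indices on irregular capillary series.

The central statistic is the glycemic lability index (GLI), a Ryan-type sum
of squared consecutive glucose changes (in mmol/L) weighted by the
inter-reading interval, corrected for the number of blood extractions:

    GLI = sum over consecutive pairs (g_n - g_{n+1})^2 / ((N - 1) * (h_{n+1} - h_n))

with g in mmol/L, h in hours and N the number of readings participating that
day; units (mmol/L)^2 h^-1 day^-1.  The extraction correction (the N - 1
factor) makes the index comparable between patients monitored at different
frequencies.  Alongside it the module computes daily mean/SD, the coefficient
of variation Glu_CV = Glu_SD * 100 / Glu_M, mean capillary glycemia on ICU
day 1, peak glucose, and glycemic band occupancy (target 110-150 mg/dL,
moderate hypoglycemia 50-80, severe <50).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AnalysisConfig, DomainError, GlucoseSeries, MGDL_PER_MMOL


def mgdl_to_mmol(value_mgdl, mgdl_per_mmol: float = MGDL_PER_MMOL):
    """Convert glucose from mg/dL to mmol/L (default constant 18.0182)."""
    arr = np.asarray(value_mgdl, dtype=float)
    if np.any(arr < 0):
        raise DomainError("glucose must be non-negative")
    out = arr / mgdl_per_mmol
    return float(out) if np.isscalar(value_mgdl) else out


@dataclass(frozen=True)
class DailyStats:
    """Sample mean/SD (n-1 denominator) of one ICU day's readings.

    ``sd`` is None when fewer than two readings make it undefined.
    """

    mean: float | None
    sd: float | None
    count: int


def daily_stats(series: GlucoseSeries, day: int) -> DailyStats:
    """Mean, SD and count of readings with time in [24*(day-1), 24*day)."""
    vals = series.day_slice(day).value_mgdl
    n = vals.size
    if n == 0:
        return DailyStats(None, None, 0)
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if n >= 2 else None
    return DailyStats(mean, sd, int(n))


def coefficient_of_variation(glu_sd: float, glu_m: float) -> float:
    """Glu_CV = Glu_SD * 100 / Glu_M, in percent."""
    if glu_m <= 0:
        raise DomainError(f"mean glucose must be > 0, got {glu_m}")
    if glu_sd < 0:
        raise DomainError(f"SD must be >= 0, got {glu_sd}")
    return glu_sd * 100.0 / glu_m


def _gli_from_arrays(
    times_h: np.ndarray, mmol: np.ndarray, max_pair_gap_h: float
) -> float:
    """Vectorized GLI on one day's converted readings (times strictly increasing)."""
    if times_h.size < 2:
        return 0.0
    gaps = np.diff(times_h)
    ok = gaps <= max_pair_gap_h
    if not np.any(ok):
        return 0.0
    # N counts the readings actually participating in at least one kept pair
    part = np.zeros(times_h.size, dtype=bool)
    part[:-1] |= ok
    part[1:] |= ok
    n_eff = int(np.count_nonzero(part))
    diffs = np.diff(mmol)
    return float(np.sum(diffs[ok] ** 2 / ((n_eff - 1) * gaps[ok])))


def glycemic_lability_index(
    series: GlucoseSeries,
    day: int,
    max_pair_gap_h: float = 12.0,
    mgdl_per_mmol: float = MGDL_PER_MMOL,
) -> float:
    """Extraction-corrected GLI for one ICU day, (mmol/L)^2 h^-1 day^-1.

    Consecutive-pair gaps longer than ``max_pair_gap_h`` (e.g. spanning a
    blood-test feeding interruption) are excluded and N reduced to the
    readings still participating.  Returns 0.0 when fewer than two eligible
    readings remain; window summaries flag that as an absent value.
    """
    if max_pair_gap_h <= 0:
        raise DomainError("max_pair_gap_h must be positive")
    sub = series.day_slice(day)
    return _gli_from_arrays(
        sub.time_h, mgdl_to_mmol(sub.value_mgdl, mgdl_per_mmol), max_pair_gap_h
    )


@dataclass(frozen=True)
class GVSummary:
    """Per-patient variability summary over a day window (inclusive).

    glu_m    mean of all readings in the window, mg/dL
    glu_sd   mean of the defined daily SDs, mg/dL
    glu_cv   glu_sd * 100 / glu_m, percent
    gli      mean of the defined daily GLIs, (mmol/L)^2 h^-1 day^-1
    mcg_day1 mean capillary glycemia on ICU day 1 (full stay), mg/dL
    peak     highest reading of the full stay, mg/dL
    """

    patient_id: str
    window: tuple[int, int]
    glu_m: float | None
    glu_sd: float | None
    glu_cv: float | None
    gli: float | None
    mcg_day1: float | None
    peak: float | None
    n_readings: int
    n_per_patient_day: float | None


def window_summary(
    series: GlucoseSeries,
    window: tuple[int, int],
    config: AnalysisConfig | None = None,
) -> GVSummary:
    """Aggregate daily statistics over ICU days window[0]..window[1].

    Daily SDs and GLIs are averaged unweighted over the days on which they
    are defined (>= 2 readings); days without readings contribute nothing.
    An empty window yields a summary full of absent statistics, not an
    exception.  ``mcg_day1`` and ``peak`` always refer to the full stay.
    """
    config = config or AnalysisConfig()
    first, last = window
    sub = series.window_slice(first, last)
    daily_sds, daily_glis = [], []
    days_with_readings = 0
    for day in range(first, last + 1):
        st = daily_stats(series, day)
        if st.count > 0:
            days_with_readings += 1
        if st.sd is not None:
            daily_sds.append(st.sd)
            daily_glis.append(
                glycemic_lability_index(
                    series, day, config.max_pair_gap_h, config.mgdl_per_mmol
                )
            )
    glu_m = float(np.mean(sub.value_mgdl)) if sub.n else None
    glu_sd = float(np.mean(daily_sds)) if daily_sds else None
    glu_cv = (
        coefficient_of_variation(glu_sd, glu_m)
        if glu_sd is not None and glu_m and glu_m > 0
        else None
    )
    gli = float(np.mean(daily_glis)) if daily_glis else None
    d1 = daily_stats(series, 1)
    return GVSummary(
        patient_id=series.patient_id,
        window=(first, last),
        glu_m=glu_m,
        glu_sd=glu_sd,
        glu_cv=glu_cv,
        gli=gli,
        mcg_day1=d1.mean,
        peak=float(np.max(series.value_mgdl)) if series.n else None,
        n_readings=sub.n,
        n_per_patient_day=(
            sub.n / days_with_readings if days_with_readings else None
        ),
    )


@dataclass(frozen=True)
class BandCounts:
    """Reading counts (and percentages of n_total) per glycemic band.

    Band edges follow the protocol's printed ranges: severe hypoglycemia
    strictly <50 mg/dL, moderate [50, 80], the reported control band
    (80, 150], hyperglycemia >150, and the insulin-titration target
    [110, 150] (overlapping the control band, counted separately).
    """

    severe_hypo: int
    moderate_hypo: int
    band_80_150: int
    above_150: int
    in_target: int
    n_total: int

    def pct(self, count: int) -> float | None:
        return 100.0 * count / self.n_total if self.n_total else None

    @property
    def pct_severe(self):
        return self.pct(self.severe_hypo)

    @property
    def pct_moderate(self):
        return self.pct(self.moderate_hypo)

    @property
    def pct_band_80_150(self):
        return self.pct(self.band_80_150)

    @property
    def pct_in_target(self):
        return self.pct(self.in_target)


def classify_readings(
    series: GlucoseSeries, config: AnalysisConfig | None = None
) -> BandCounts:
    """Count readings per glycemic band; empty series gives all-zero counts."""
    config = config or AnalysisConfig()
    v = series.value_mgdl
    mod_lo, mod_hi = config.hypo_moderate_bounds
    severe = int(np.count_nonzero(v < config.hypo_severe_upper))
    moderate = int(np.count_nonzero((v >= mod_lo) & (v <= mod_hi)))
    band = int(np.count_nonzero((v > mod_hi) & (v <= config.target_high)))
    above = int(np.count_nonzero(v > config.target_high))
    target = int(
        np.count_nonzero((v >= config.target_low) & (v <= config.target_high))
    )
    return BandCounts(severe, moderate, band, above, target, int(v.size))
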