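"""Trial-level epidemiology and intention-to-treat group comparisons.

Infection burden is expressed as events over exposure time (per 1000
ventilator-days for respiratory infections, per 100 treatment-days
otherwise), compared between arms with a Poisson score chi-squared test on
counts with exposure offsets.  Patient-level infection risk uses 2x2 odds
ratios with Woolf (log-normal) confidence intervals.  Group comparisons
dispatch on variable kind and normality (Lilliefors/Kolmogorov-Smirnov
screen): one-way ANOVA with Tukey post-hoc tests, or Kruskal-Wallis with
Bonferroni-corrected pairwise Mann-Whitney tests; categorical tables use
chi-squared, switching to an exact conditional (Fisher) test when any
expected cell is below 5.  The variability-infection relationship is a
group-level Pearson correlation across the three arms (n = 3; flagged as
such wherever it is reported).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from statsmodels.stats.diagnostic import kstest_normal

from .gv import classify_readings, window_summary
from .io import TrialData
from .model import (
    ARMS,
    AnalysisConfig,
    DataValidationError,
    DomainError,
    InfectionEvent,
)
from .nutrition import daily_intake, load_formulas, volume_ratio

Z_95 = 1.959963984540054  # two-sided 95 % normal quantile


@dataclass(frozen=True)
class RateEstimate:
    """Events over exposure, expressed per `scale` exposure-days."""

    events: int
    exposure_days: float
    scale: float
    rate: float

    def rescaled(self, scale: float) -> "RateEstimate":
        return incidence_rate(self.events, self.exposure_days, scale)


def incidence_rate(
    events: int, exposure_days: float, scale: float = 1000.0
) -> RateEstimate:
    """rate = events / exposure x scale (e.g. per 1000 ventilator-days)."""
    if exposure_days <= 0:
        raise DomainError(f"exposure must be > 0 days, got {exposure_days}")
    if events < 0:
        raise DomainError("events must be >= 0")
    return RateEstimate(
        int(events), float(exposure_days), float(scale),
        events / exposure_days * scale,
    )


@dataclass(frozen=True)
class OddsRatioResult:
    """2x2 odds ratio with Woolf 95 % CI.

    Cell layout: group-1 events a, non-events b; group-2 events c,
    non-events d; OR = (a d)/(b c) = odds(group 1)/odds(group 2).
    """

    a: float
    b: float
    c: float
    d: float
    oddsratio: float
    ci_low: float
    ci_high: float
    orientation: str
    continuity_corrected: bool = False

    def inverse(self) -> "OddsRatioResult":
        lab = "/".join(reversed(self.orientation.split("/")))
        return OddsRatioResult(
            self.c, self.d, self.a, self.b,
            1.0 / self.oddsratio, 1.0 / self.ci_high, 1.0 / self.ci_low,
            lab, self.continuity_corrected,
        )


def odds_ratio(
    a: int, b: int, c: int, d: int, orientation: str = "group1/group2"
) -> OddsRatioResult:
    """Odds ratio with Woolf log-normal CI; Haldane-Anscombe 0.5 on zeros.

    Raises DomainError when a whole margin is zero (OR undefined even with
    the correction's support).
    """
    if min(a, b, c, d) < 0:
        raise DomainError("2x2 counts must be >= 0")
    if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (
        b == 0 and d == 0
    ):
        raise DomainError("odds ratio undefined: an entire margin is zero")
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (x + 0.5 if corrected else x for x in (a, b, c, d))
    orr = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    return OddsRatioResult(
        a, b, c, d, orr,
        math.exp(math.log(orr) - Z_95 * se),
        math.exp(math.log(orr) + Z_95 * se),
        orientation, corrected,
    )


def compare_rates(rate1: RateEstimate, rate2: RateEstimate) -> float:
    """Two-sample Poisson score chi-squared test (exposure offsets), p-value.

    Under H0 the common rate is (x1+x2)/(T1+T2); the statistic is the usual
    sum of (observed - expected)^2 / expected over the two exposure strata,
    with 1 df.  Degenerate zero-event inputs give p = 1.
    """
    x1, t1 = rate1.events, rate1.exposure_days
    x2, t2 = rate2.events, rate2.exposure_days
    total = x1 + x2
    if total == 0:
        return 1.0
    e1 = total * t1 / (t1 + t2)
    e2 = total * t2 / (t1 + t2)
    chi2 = (x1 - e1) ** 2 / e1 + (x2 - e2) ** 2 / e2
    return float(stats.chi2.sf(chi2, df=1))


def acquired_filter(
    events: list[InfectionEvent], onset_h: float = 48.0
) -> list[InfectionEvent]:
    """Keep ICU-acquired events: onset at or beyond 48 h after admission."""
    return [e for e in events if e.onset_h >= onset_h]


def _fisher_exact_rxc(table: np.ndarray) -> float:
    """Exact conditional (Fisher) p-value for a small r x c count table.

    Enumerates all tables with the observed margins and sums the
    probabilities of those no more probable than the observed table under
    the multivariate hypergeometric null.  Intended for the small expected
    counts that trigger the Fisher branch; complexity grows with the margins.
    """
    table = np.asarray(table, dtype=int)
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    n = int(table.sum())

    def log_fact(k):
        return math.lgamma(k + 1)

    log_const = (
        sum(log_fact(r) for r in row_sums)
        + sum(log_fact(c) for c in col_sums)
        - log_fact(n)
    )

    def table_logp(t):
        return log_const - sum(log_fact(x) for x in t.flat)

    obs_logp = table_logp(table)
    rows, cols = table.shape
    p_total = 0.0

    def recurse(r, remaining_cols, partial):
        nonlocal p_total
        if r == rows - 1:
            last = remaining_cols
            if np.all(last >= 0) and last.sum() == row_sums[-1]:
                t = np.vstack(partial + [last])
                lp = table_logp(t)
                if lp <= obs_logp + 1e-9:
                    p_total += math.exp(lp)
            return
        # enumerate row r with the right row sum and column headroom
        def fill(c, left, row):
            if c == cols - 1:
                if 0 <= left <= remaining_cols[c]:
                    recurse(
                        r + 1,
                        remaining_cols - np.array(row + [left]),
                        partial + [np.array(row + [left])],
                    )
                return
            for v in range(min(left, remaining_cols[c]) + 1):
                fill(c + 1, left - v, row + [v])

        fill(0, int(row_sums[r]), [])

    recurse(0, col_sums.copy(), [])
    return min(1.0, p_total)


@dataclass(frozen=True)
class GroupComparisonResult:
    """Dispatch result for a per-arm variable comparison."""

    variable: str
    kind: str  # continuous | categorical
    test: str  # anova | kruskal | chi2 | fisher
    p_value: float
    per_arm: dict
    posthoc: dict | None = None  # pairwise label -> p


def group_compare(
    values_by_arm: dict[str, np.ndarray] | np.ndarray,
    kind: str,
    variable: str = "",
    alpha_normality: float = 0.05,
) -> GroupComparisonResult:
    """Compare a variable across arms, choosing the test the data admit.

    Continuous input is a mapping arm -> 1-D values: each arm is screened for
    normality (Lilliefors corrected Kolmogorov-Smirnov); if every arm passes,
    one-way ANOVA with Tukey HSD post-hoc, otherwise Kruskal-Wallis with
    Bonferroni-corrected pairwise Mann-Whitney U.  Categorical input is an
    arms x levels count table: chi-squared, or the exact conditional test
    when any expected cell is below 5.
    """
    if kind == "continuous":
        arms = {k: np.asarray(v, dtype=float) for k, v in values_by_arm.items()}
        for label, v in arms.items():
            if v.size < 2:
                raise DataValidationError(
                    f"{variable}: arm {label} has <2 observations"
                )
        samples = list(arms.values())
        normal = all(
            v.size < 4 or kstest_normal(v)[1] > alpha_normality
            for v in arms.values()
        )
        per_arm = {
            k: {"n": int(v.size), "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)),
                "median": float(np.median(v)),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75))}
            for k, v in arms.items()
        }
        labels = list(arms)
        if normal:
            p = float(stats.f_oneway(*samples).pvalue)
            tuk = stats.tukey_hsd(*samples)
            posthoc = {
                f"{labels[i]}/{labels[j]}": float(tuk.pvalue[i, j])
                for i, j in itertools.combinations(range(len(labels)), 2)
            }
            return GroupComparisonResult(variable, kind, "anova", p, per_arm, posthoc)
        p = float(stats.kruskal(*samples).pvalue)
        m = len(labels) * (len(labels) - 1) // 2
        posthoc = {
            f"{labels[i]}/{labels[j]}": float(
                min(1.0, stats.mannwhitneyu(samples[i], samples[j]).pvalue * m)
            )
            for i, j in itertools.combinations(range(len(labels)), 2)
        }
        return GroupComparisonResult(variable, kind, "kruskal", p, per_arm, posthoc)

    if kind == "categorical":
        table = np.asarray(values_by_arm, dtype=float)
        if table.ndim != 2 or np.any(table < 0):
            raise DataValidationError(f"{variable}: need a non-negative 2-D table")
        if np.any(table.sum(axis=1) == 0):
            empty = [i for i, s in enumerate(table.sum(axis=1)) if s == 0]
            raise DataValidationError(f"{variable}: empty arm rows {empty}")
        per_arm = {"table": table.astype(int).tolist()}
        if np.all(table.sum(axis=0) > 0):
            expected = stats.contingency.expected_freq(table)
        else:  # a level nobody hit: drop it for the expected-count screen
            keep = table.sum(axis=0) > 0
            expected = stats.contingency.expected_freq(table[:, keep])
            table = table[:, keep]
        if np.any(expected < 5):
            if table.shape == (2, 2):
                p = float(stats.fisher_exact(table)[1])
            else:
                p = _fisher_exact_rxc(table)
            return GroupComparisonResult(variable, kind, "fisher", p, per_arm)
        p = float(stats.chi2_contingency(table, correction=False)[1])
        return GroupComparisonResult(variable, kind, "chi2", p, per_arm)

    raise DomainError(f"unknown variable kind {kind!r}")


def gv_infection_correlation(
    group_gv: np.ndarray, group_rates: np.ndarray
) -> tuple[float, float]:
    """Group-level Pearson r between an arm GV index and arm infection rates.

    With three arms this is an n = 3 correlation (1 df for the t transform);
    reports must carry the "group-level, n=3" flag.  Zero variance in either
    vector makes r undefined (DomainError).
    """
    x = np.asarray(group_gv, dtype=float)
    y = np.asarray(group_rates, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DomainError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _round_half_up(x: float, digits: int) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def build_report(
    data: TrialData, config: AnalysisConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Assemble the per-arm report tables from a validated dataset.

    Returns analogues of the published trial tables: ``nutrients`` (daily
    intake per arm), ``glycemic_control`` (insulin, glucose, variability,
    band occupancy), ``infections`` (counts, exposure rates, odds ratios),
    ``correlations`` (group-level GV vs respiratory-infection rates,
    flagged n=3) and ``outcomes`` (exposures and mortality).  Every number
    is computed by the upstream operations of this package; rounding is
    half-up at the configured precision.
    """
    config = config or AnalysisConfig()
    by_arm = data.by_arm()
    for label in ARMS:
        if not by_arm[label]:
            raise DataValidationError(f"arm {label} is empty")
    prec = config.reporting_precision
    formulas, _ = load_formulas()

    def arm_row(fn) -> dict[str, float | str]:
        return {label: fn(by_arm[label]) for label in ARMS}

    # ---- nutrients ----------------------------------------------------
    nut_rows = []
    if len(data.volumes):
        vol = data.volumes
        arm_of = {p.patient_id: p.arm for p in data.patients}
        vol = vol.assign(arm=vol["patient_id"].map(arm_of))
        per_day = []
        for _, row in vol.iterrows():
            f = formulas[row["formula"]]
            di = daily_intake(row["volume_administered_ml"], f, row["extra_kcal"])
            per_day.append(
                {
                    "arm": row["arm"],
                    "vr": volume_ratio(
                        row["volume_administered_ml"], row["volume_prescribed_ml"]
                    ),
                    "kcal_total": di.kcal_total,
                    "protein_g": di.protein_g,
                    "carbohydrate_g": di.carbohydrate_g,
                    "fat_g": di.fat_g,
                    "fiber_g": di.fiber_g,
                }
            )
        pdf = pd.DataFrame(per_day)
        for name, col in [
            ("volume_ratio_pct", "vr"),
            ("total_kcal_per_day", "kcal_total"),
            ("protein_g_per_day", "protein_g"),
            ("carbohydrate_g_per_day", "carbohydrate_g"),
            ("fat_g_per_day", "fat_g"),
            ("fiber_g_per_day", "fiber_g"),
        ]:
            grp = pdf.groupby("arm")[col]
            row = {"variable": name}
            for label in ARMS:
                row[label] = _round_half_up(float(grp.mean().get(label, np.nan)), prec)
            nut_rows.append(row)
    nutrients = pd.DataFrame(nut_rows)

    # ---- glycemic control --------------------------------------------
    def summaries(window):
        return {
            label: [
                window_summary(data.glucose[p.patient_id], window, config)
                for p in by_arm[label]
                if p.patient_id in data.glucose
            ]
            for label in ARMS
        }

    full = summaries((1, config.windows[-1][1]))
    gly_rows = []

    def gmean(vals):
        vals = [v for v in vals if v is not None]
        return _round_half_up(float(np.mean(vals)), prec) if vals else None

    gly_rows.append(
        {"variable": "administered_insulin_iu_per_day", **{
            label: gmean([
                np.mean(p.daily_insulin_iu) if p.daily_insulin_iu else None
                for p in by_arm[label]
            ])
            for label in ARMS
        }}
    )
    for name, attr in [
        ("capillary_glucose_mgdl", "glu_m"),
        ("mcg_day1_mgdl", "mcg_day1"),
        ("peak_glucose_mgdl", "peak"),
        ("n_per_patient_day", "n_per_patient_day"),
    ]:
        gly_rows.append(
            {"variable": name, **{
                label: gmean([getattr(s, attr) for s in full[label]])
                for label in ARMS
            }}
        )
    for window in config.windows:
        win = summaries(window)
        tag = f"days_{window[0]}_{window[1]}"
        for name, attr in [
            (f"gli_{tag}", "gli"),
            (f"gv_sd_mgdl_{tag}", "glu_sd"),
            (f"gv_cv_pct_{tag}", "glu_cv"),
        ]:
            gly_rows.append(
                {"variable": name, **{
                    label: gmean([getattr(s, attr) for s in win[label]])
                    for label in ARMS
                }}
            )
    bands = {
        label: classify_readings(
            _concat_series(data, by_arm[label]), config
        )
        for label in ARMS
    }
    for name, attr in [
        ("n_measurements", "n_total"),
        ("pct_80_150", "pct_band_80_150"),
        ("n_hypo_moderate", "moderate_hypo"),
        ("pct_hypo_moderate", "pct_moderate"),
        ("n_hypo_severe", "severe_hypo"),
        ("pct_hypo_severe", "pct_severe"),
    ]:
        gly_rows.append(
            {"variable": name, **{
                label: (
                    _round_half_up(float(getattr(bands[label], attr)), prec)
                    if getattr(bands[label], attr) is not None
                    else None
                )
                for label in ARMS
            }}
        )
    glycemic = pd.DataFrame(gly_rows)

    # ---- infections ---------------------------------------------------
    def exposures(recs):
        return (
            sum(r.ventilator_days for r in recs),
            sum(r.en_days for r in recs),
            sum(r.icu_days for r in recs),
        )

    inf_rows = []
    rates: dict[str, dict[str, RateEstimate]] = {}
    infected = {}
    for label in ARMS:
        recs = by_arm[label]
        vent_d, en_d, icu_d = exposures(recs)
        acq = {
            r.patient_id: acquired_filter(r.infection_events, config.acquired_onset_h)
            for r in recs
        }
        infected[label] = sum(1 for evs in acq.values() if evs)
        all_events = [e for evs in acq.values() for e in evs]
        counts = {
            k: sum(1 for e in all_events if e.kind == k)
            for k in ("tracheobronchitis", "vap")
        }
        rates.setdefault("tracheobronchitis", {})[label] = incidence_rate(
            counts["tracheobronchitis"], vent_d, 1000.0
        )
        rates.setdefault("vap", {})[label] = incidence_rate(
            counts["vap"], vent_d, 1000.0
        )
        rates.setdefault("any_infection", {})[label] = incidence_rate(
            len(all_events), en_d, 100.0
        )
    n_arm = {label: len(by_arm[label]) for label in ARMS}
    inf_rows.append(
        {"variable": "infected_patients_pct", **{
            label: _round_half_up(100.0 * infected[label] / n_arm[label], prec)
            for label in ARMS
        }}
    )
    for kind, scale_name in [
        ("any_infection", "per_100_treatment_days"),
        ("tracheobronchitis", "per_1000_ventilator_days"),
        ("vap", "per_1000_ventilator_days"),
    ]:
        inf_rows.append(
            {"variable": f"{kind}_rate_{scale_name}", **{
                label: _round_half_up(rates[kind][label].rate, prec)
                for label in ARMS
            }}
        )
    infections = pd.DataFrame(inf_rows)

    or_rows = []
    for lab1, lab2 in (("B", "A"), ("C", "A"), ("C", "B")):
        res = odds_ratio(
            infected[lab1], n_arm[lab1] - infected[lab1],
            infected[lab2], n_arm[lab2] - infected[lab2],
            orientation=f"{lab1}/{lab2}",
        )
        or_rows.append(
            {
                "orientation": res.orientation,
                "oddsratio": _round_half_up(res.oddsratio, prec),
                "ci_low": _round_half_up(res.ci_low, prec),
                "ci_high": _round_half_up(res.ci_high, prec),
                "oddsratio_inverse": _round_half_up(res.inverse().oddsratio, prec),
            }
        )
    odds = pd.DataFrame(or_rows)

    # ---- group-level GV vs infection correlations (n = 3 arms) -------
    corr_rows = []
    week1 = summaries(config.windows[0])
    gv_vectors = {
        "mcg_day1": [gmean([s.mcg_day1 for s in full[label]]) for label in ARMS],
        f"gli_days_{config.windows[0][0]}_{config.windows[0][1]}": [
            gmean([s.gli for s in week1[label]]) for label in ARMS
        ],
        f"cv_days_{config.windows[0][0]}_{config.windows[0][1]}": [
            gmean([s.glu_cv for s in week1[label]]) for label in ARMS
        ],
    }
    for kind in ("tracheobronchitis", "vap"):
        yv = [rates[kind][label].rate for label in ARMS]
        for gv_name, xv in gv_vectors.items():
            if any(v is None for v in xv):
                continue
            try:
                r, p = gv_infection_correlation(np.array(xv), np.array(yv))
            except DomainError:
                continue
            corr_rows.append(
                {
                    "gv_index": gv_name,
                    "infection": f"{kind}_per_1000_vd",
                    "pearson_r": _round_half_up(r, 3),
                    "p_value": _round_half_up(p, 3),
                    "note": "group-level, n=3",
                }
            )
    correlations = pd.DataFrame(corr_rows)

    # ---- outcomes -----------------------------------------------------
    out_rows = []
    for name, fn in [
        ("ventilator_days_median", lambda rs: float(np.median([r.ventilator_days for r in rs]))),
        ("icu_days_median", lambda rs: float(np.median([r.icu_days for r in rs]))),
        ("en_days_mean", lambda rs: float(np.mean([r.en_days for r in rs]))),
        ("mortality_28d_pct", lambda rs: 100.0 * sum(r.death_day_28 for r in rs) / len(rs)),
        ("mortality_6mo_pct", lambda rs: 100.0 * sum(r.death_6mo for r in rs) / len(rs)),
        ("closed_early_pct", lambda rs: 100.0 * sum(r.closed_early for r in rs) / len(rs)),
    ]:
        out_rows.append(
            {"variable": name, **{
                label: _round_half_up(fn(by_arm[label]), prec) for label in ARMS
            }}
        )
    outcomes = pd.DataFrame(out_rows)

    return {
        "nutrients": nutrients,
        "glycemic_control": glycemic,
        "infections": infections,
        "odds_ratios": odds,
        "correlations": correlations,
        "outcomes": outcomes,
    }


def _concat_series(data: TrialData, recs) -> "object":
    """Pool an arm's readings into one pseudo-series for band counting."""
    import types

    vals = [
        data.glucose[r.patient_id].value_mgdl
        for r in recs
        if r.patient_id in data.glucose
    ]
    pooled = np.concatenate(vals) if vals else np.empty(0)
    return types.SimpleNamespace(value_mgdl=pooled, n=int(pooled.size))
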