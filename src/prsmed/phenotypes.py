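"""Deterministic phenotype derivation for diabetes and sleep traits.

Diabetes status follows the American Diabetes Association laboratory
criteria combined with anti-diabetes medication records; obstructive sleep
apnea (OSA) severity is categorised from the respiratory event index (REI);
secondary sleep phenotypes (insomnia, short/long sleep, excessive daytime
sleepiness) are derived from questionnaire scores and habitual bed/wake
times.

All classifiers are pure functions of their inputs.  Vectorised wrappers
append derived columns to a cohort table.
"""

from __future__ import annotations

import math
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "DmStatus",
    "OsaCategory",
    "classify_dm_ada",
    "derive_incident_dm",
    "classify_osa_severity",
    "parse_clock_time",
    "sleep_duration_hours",
    "derive_sleep_phenotypes",
    "add_derived_phenotypes",
]


class DmStatus(str, Enum):
    """Glycemic status: normoglycemic, hyperglycemic (pre-diabetic), diabetic."""

    NORMO = "normoglycemic"
    HYPER = "hyperglycemic"
    DIABETIC = "diabetic"
    MISSING = "missing"


class OsaCategory(str, Enum):
    """OSA severity from the respiratory event index (events/hour)."""

    NONE = "none"
    MILD = "mild"
    MODERATE_SEVERE = "moderate_severe"
    MISSING = "missing"


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or x is pd.NA


def classify_dm_ada(
    fasting_time_h=None,
    fasting_glucose=None,
    ogtt_glucose=None,
    a1c=None,
    dm_med=None,
) -> DmStatus:
    """Classify glycemic status from labs and medication per ADA criteria.

    Diabetic if any of: fasting time > 8 h and fasting glucose >= 126 mg/dL;
    fasting time <= 8 h and fasting glucose >= 200 mg/dL; post-OGTT glucose
    >= 200 mg/dL; A1C >= 6.5%; or anti-diabetes medication use (medication
    takes precedence even when labs are normal).  Hyperglycemic if fasting
    glucose 100-125 mg/dL (fasted > 8 h), OGTT 140-199 mg/dL, or
    5.7% <= A1C < 6.5%.  Otherwise normoglycemic when any lab or a negative
    medication record is observed; missing when labs and medication
    information are all absent.

    Parameters
    ----------
    fasting_time_h : float or None
        Hours fasted before the blood draw.
    fasting_glucose, ogtt_glucose : float or None
        Glucose in mg/dL (fasting and post oral glucose tolerance test).
    a1c : float or None
        Glycated hemoglobin, percent.
    dm_med : bool or None
        Anti-diabetes medication use; None when unknown.
    """
    for g in (fasting_glucose, ogtt_glucose):
        if not _isna(g) and g < 0:
            raise ValueError("glucose values must be non-negative")

    med_known = not _isna(dm_med)
    if med_known and bool(dm_med):
        return DmStatus.DIABETIC

    fast_known = not _isna(fasting_glucose) and not _isna(fasting_time_h)
    if fast_known:
        if fasting_time_h > 8 and fasting_glucose >= 126:
            return DmStatus.DIABETIC
        if fasting_time_h <= 8 and fasting_glucose >= 200:
            return DmStatus.DIABETIC
    if not _isna(ogtt_glucose) and ogtt_glucose >= 200:
        return DmStatus.DIABETIC
    if not _isna(a1c) and a1c >= 6.5:
        return DmStatus.DIABETIC

    if fast_known and fasting_time_h > 8 and 100 <= fasting_glucose <= 125:
        return DmStatus.HYPER
    if not _isna(ogtt_glucose) and 140 <= ogtt_glucose <= 199:
        return DmStatus.HYPER
    if not _isna(a1c) and 5.7 <= a1c < 6.5:
        return DmStatus.HYPER

    any_lab = (
        (not _isna(fasting_glucose))
        or (not _isna(ogtt_glucose))
        or (not _isna(a1c))
    )
    if any_lab or med_known:
        return DmStatus.NORMO
    return DmStatus.MISSING


def derive_incident_dm(dm_status_v1, dm_status_v2):
    """Incident diabetes between two visits.

    True iff not diabetic (normo- or hyperglycemic) at visit 1 and diabetic
    at visit 2; None (excluded) when diabetic at visit 1 or either status is
    missing.
    """
    v1 = DmStatus(dm_status_v1) if dm_status_v1 is not None else DmStatus.MISSING
    v2 = DmStatus(dm_status_v2) if dm_status_v2 is not None else DmStatus.MISSING
    if v1 in (DmStatus.MISSING, DmStatus.DIABETIC) or v2 is DmStatus.MISSING:
        return None
    return v2 is DmStatus.DIABETIC


def classify_osa_severity(rei) -> OsaCategory:
    """OSA severity from the respiratory event index.

    REI < 5: none; 5 <= REI < 15: mild; REI >= 15: moderate-to-severe.  The
    boundary REI = 15 is assigned moderate-to-severe so the categories
    partition the half-line.
    """
    if _isna(rei):
        return OsaCategory.MISSING
    if rei < 0:
        raise ValueError("REI must be non-negative")
    if rei < 5:
        return OsaCategory.NONE
    if rei < 15:
        return OsaCategory.MILD
    return OsaCategory.MODERATE_SEVERE


def parse_clock_time(t):
    """Parse a clock time ('HH:MM', 'H:MM', or fractional hours) to hours in [0, 24)."""
    if _isna(t):
        return None
    if isinstance(t, (int, float)):
        h = float(t)
    else:
        s = str(t).strip()
        try:
            if ":" in s:
                hh, mm = s.split(":")[:2]
                h = int(hh) + int(mm) / 60.0
            else:
                h = float(s)
        except (ValueError, TypeError):
            return None
    if not (0 <= h < 24 or h == 24):
        return None
    return h % 24


def sleep_duration_hours(bed, wake, min_hours=3.0, max_hours=20.0):
    """Duration from bed to wake time, modulo 24 h.

    Bedtimes after midnight wrap around; durations outside the plausibility
    window [min_hours, max_hours] are treated as unparsable and return None.
    """
    b, w = parse_clock_time(bed), parse_clock_time(wake)
    if b is None or w is None:
        return None
    dur = (w - b) % 24.0
    if dur < min_hours or dur > max_hours:
        return None
    return dur


def derive_sleep_phenotypes(
    whiirs=None,
    ess=None,
    bed_wd=None,
    wake_wd=None,
    bed_we=None,
    wake_we=None,
) -> dict:
    """Derive insomnia, short/long sleep, and daytime sleepiness flags.

    Average habitual sleep duration weights weekdays 5/7 and weekends 2/7.
    Insomnia: WHIIRS >= 10.  Short sleep: average <= 6 h.  Long sleep:
    average > 9 h.  Excessive daytime sleepiness: ESS > 10 (strict).
    Unavailable inputs yield None flags.
    """
    wd = sleep_duration_hours(bed_wd, wake_wd)
    we = sleep_duration_hours(bed_we, wake_we)
    avg = None if wd is None or we is None else (5.0 / 7.0) * wd + (2.0 / 7.0) * we
    return {
        "insomnia": None if _isna(whiirs) else bool(whiirs >= 10),
        "eds": None if _isna(ess) else bool(ess > 10),
        "avg_sleep_hours": avg,
        "short_sleep": None if avg is None else bool(avg <= 6),
        "long_sleep": None if avg is None else bool(avg > 9),
    }


def add_derived_phenotypes(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append derived phenotype columns to a cohort table.

    Adds ``dm_status_v1``, ``dm_status_v2`` (from visit-specific lab columns
    when present), ``incident_dm``, ``osa_category``, ``osa_mild_severe``,
    and the sleep flags.  Existing ``dm_status_*`` columns are respected.
    """
    out = cohort.copy()

    def _status(row, suffix):
        return classify_dm_ada(
            row.get(f"fasting_time_h{suffix}"),
            row.get(f"fasting_glucose{suffix}"),
            row.get(f"ogtt_glucose{suffix}"),
            row.get(f"a1c{suffix}"),
            row.get(f"dm_med{suffix}"),
        ).value

    for visit, suffix in (("v1", "_v1"), ("v2", "_v2")):
        col = f"dm_status_{visit}"
        if col not in out.columns and f"fasting_glucose{suffix}" in out.columns:
            out[col] = out.apply(_status, axis=1, args=(suffix,))

    if {"dm_status_v1", "dm_status_v2"}.issubset(out.columns):
        out["incident_dm"] = [
            derive_incident_dm(a, b)
            for a, b in zip(out["dm_status_v1"], out["dm_status_v2"])
        ]

    if "rei" in out.columns:
        out["osa_category"] = [classify_osa_severity(r).value for r in out["rei"]]
        out["osa_mild_severe"] = [
            None
            if c == OsaCategory.MISSING.value
            else float(c != OsaCategory.NONE.value)
            for c in out["osa_category"]
        ]

    if "whiirs" in out.columns:
        flags = [
            derive_sleep_phenotypes(
                row.get("whiirs"),
                row.get("ess"),
                row.get("bed_wd"),
                row.get("wake_wd"),
                row.get("bed_we"),
                row.get("wake_we"),
            )
            for _, row in out.iterrows()
        ]
        for key in ("insomnia", "eds", "avg_sleep_hours", "short_sleep", "long_sleep"):
            out[key] = [f[key] for f in flags]
    return out
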