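"""PPI prescriptions → exposure episodes, dose/duration categories, strata.

Exposure to a proton-pump inhibitor begins on the prescription date and
ends after its calculated duration; consecutive prescriptions (gap at most
the configurable grace period, default 0 days) merge into one episode.
Cumulative exposure is the total exposed time during follow-up, not
necessarily continuous.  Months are 30 days everywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PPI_DRUGS = ("omeprazole", "esomeprazole", "lansoprazole", "pantoprazole",
             "rabeprazole")

# upper bound of the standard daily dose (mg); above is high
STANDARD_DOSE_MAX = {
    "omeprazole": 20.0,
    "esomeprazole": 20.0,
    "pantoprazole": 20.0,
    "lansoprazole": 15.0,
    "rabeprazole": 10.0,
}
# printed upper bound of the high range; doses above are still "high"
HIGH_DOSE_MAX = {
    "omeprazole": 40.0,
    "esomeprazole": 40.0,
    "pantoprazole": 40.0,
    "lansoprazole": 30.0,
    "rabeprazole": 20.0,
}

# cumulative-duration bins (days; 30-day months), half-open [lower, upper)
DURATION_EDGES = (30, 90, 180, 360, 720)
DURATION_LABELS = ("<1 month", "1-3 months", "3-6 months", "6-12 months",
                   "12-24 months", ">24 months")
# collapsed scheme used for the dose-duration analysis tables
DURATION_EDGES_COLLAPSED = (30, 90, 180)
DURATION_LABELS_COLLAPSED = ("<1 month", "1-3 months", "3-6 months",
                             ">6 months")


def _missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def prescription_duration(treatment_days=None, quantity=None,
                          daily_units=None) -> int:
    """Duration of one prescription in days.

    The recorded number of treatment days takes precedence; otherwise the
    total dispensed quantity divided by the numeric daily dose, rounded up.
    """
    if not _missing(treatment_days):
        days = int(treatment_days)
        if days <= 0:
            raise ValueError("recorded treatment days must be positive")
        if not _missing(quantity) and not _missing(daily_units) and daily_units:
            derived = math.ceil(quantity / daily_units)
            if derived != days:
                log.warning("treatment days (%d) inconsistent with "
                            "quantity/daily dose (%d); using recorded days",
                            days, derived)
        return days
    if _missing(quantity) or _missing(daily_units):
        raise ValueError("need recorded treatment days or quantity + daily dose")
    if daily_units == 0:
        raise ValueError("numeric daily dose must be non-zero")
    days = math.ceil(quantity / daily_units)
    if days <= 0:
        raise ValueError("derived duration must be positive")
    return days


def dose_category(drug: str, daily_dose_mg: float) -> str:
    """Classify a daily dose as ``standard`` or ``high`` per drug."""
    drug = drug.lower()
    if drug not in STANDARD_DOSE_MAX:
        raise ValueError(f"unknown PPI drug {drug!r}")
    if daily_dose_mg <= 0:
        raise ValueError("daily dose must be positive")
    if daily_dose_mg <= STANDARD_DOSE_MAX[drug]:
        return "standard"
    if daily_dose_mg > HIGH_DOSE_MAX[drug]:
        log.info("%s %.0f mg exceeds the printed high range; classified high",
                 drug, daily_dose_mg)
    return "high"


def duration_category(cumulative_days: float, collapsed: bool = False) -> str:
    """Bin cumulative exposure days into the regulatory duration categories."""
    if cumulative_days < 0:
        raise ValueError("cumulative days must be non-negative")
    edges = DURATION_EDGES_COLLAPSED if collapsed else DURATION_EDGES
    labels = DURATION_LABELS_COLLAPSED if collapsed else DURATION_LABELS
    idx = int(np.searchsorted(edges, cumulative_days, side="right"))
    return labels[idx]


@dataclass
class ExposureEpisode:
    start: float                 # days since study start
    end: float                   # exclusive
    dose: str                    # "standard" or "high"
    prescription_ids: list = field(default_factory=list)

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass
class ExposureTimeline:
    """Ordered, non-overlapping PPI episodes for one participant."""

    participant_id: object
    episodes: list[ExposureEpisode]
    stratum: str                 # "never" / "baseline" / "follow-up"

    @property
    def ever_start(self) -> float | None:
        return self.episodes[0].start if self.episodes else None

    def cumulative_at(self, t: float) -> float:
        """Total exposed days up to time ``t`` (piecewise linear, slope 0/1)."""
        total = 0.0
        for ep in self.episodes:
            total += max(0.0, min(t, ep.end) - ep.start)
            if ep.start >= t:
                break
        return total

    def cumulative_total(self) -> float:
        return sum(ep.length for ep in self.episodes)

    def exposure_change_days(self) -> list[float]:
        """Episode start/end times (current-exposure state changes)."""
        out = []
        for ep in self.episodes:
            out.extend((ep.start, ep.end))
        return out

    def crossing_times(self, thresholds=DURATION_EDGES) -> list[float]:
        """Times at which cumulative exposure crosses the given thresholds."""
        out = []
        cum = 0.0
        for ep in self.episodes:
            for thr in thresholds:
                if cum < thr <= cum + ep.length:
                    out.append(ep.start + (thr - cum))
            cum += ep.length
        return out


def build_timeline(prescriptions: pd.DataFrame, followup_start: float,
                   followup_end: float, *, grace_days: float = 0.0,
                   baseline_window_days: float = 365.0,
                   participant_id=None) -> ExposureTimeline:
    """Merge one participant's prescriptions into exposure episodes.

    ``prescriptions`` needs columns start_day, drug, daily_dose_mg and one
    of treatment_days or (quantity, daily_units).  Prescriptions whose gap
    to the running episode is <= ``grace_days`` are merged; a merged
    episode is high-dose if any constituent is.  Episodes are truncated at
    ``followup_end`` (event or censor date).

    Stratum: ``baseline`` if any episode intersects the first
    ``baseline_window_days`` of the study, ``follow-up`` if exposure exists
    but starts later, ``never`` otherwise.
    """
    rows = []
    for rec in prescriptions.itertuples(index=False):
        days = prescription_duration(getattr(rec, "treatment_days", None),
                                     getattr(rec, "quantity", None),
                                     getattr(rec, "daily_units", None))
        cat = dose_category(rec.drug, rec.daily_dose_mg)
        rows.append((float(rec.start_day), float(rec.start_day) + days, cat,
                     getattr(rec, "prescription_id", None)))
    rows.sort(key=lambda r: (r[0], r[1]))

    episodes: list[ExposureEpisode] = []
    for start, end, cat, rid in rows:
        if episodes and start <= episodes[-1].end + grace_days:
            ep = episodes[-1]
            ep.end = max(ep.end, end)
            ep.dose = "high" if "high" in (ep.dose, cat) else "standard"
            ep.prescription_ids.append(rid)
        else:
            episodes.append(ExposureEpisode(start, end, cat, [rid]))

    stratum = "never"
    if episodes:
        stratum = ("baseline" if episodes[0].start < baseline_window_days
                   else "follow-up")

    # truncate at end of follow-up
    episodes = [ep for ep in episodes if ep.start < followup_end]
    for ep in episodes:
        ep.end = min(ep.end, followup_end)
    episodes = [ep for ep in episodes if ep.length > 0]

    return ExposureTimeline(participant_id=participant_id, episodes=episodes,
                            stratum=stratum)


def build_cohort_timelines(prescriptions: pd.DataFrame,
                           participants: pd.DataFrame, *,
                           end_col: str = "censor_day",
                           grace_days: float = 0.0,
                           baseline_window_days: float = 365.0
                           ) -> dict[object, ExposureTimeline]:
    """Build one timeline per participant (empty timeline when no scripts)."""
    groups = (dict(iter(prescriptions.groupby("participant_id", sort=False)))
              if len(prescriptions) else {})
    empty = prescriptions.iloc[0:0]
    out = {}
    for row in participants.itertuples(index=False):
        pid = row.participant_id
        out[pid] = build_timeline(groups.get(pid, empty),
                                  float(row.entry_day),
                                  float(getattr(row, end_col)),
                                  grace_days=grace_days,
                                  baseline_window_days=baseline_window_days,
                                  participant_id=pid)
    return out
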