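"""Andersen-Gill restructuring: start-stop risk intervals with delayed entry.

Each participant's follow-up (from individual entry to CKD or censoring) is
divided into maximal spans on which all time-varying covariates are
constant.  The resulting start-stop table — one row per at-risk interval
with entry, exit, event status and the covariate values in force — is the
standard counting-process format for survival data with time-varying
covariates, and honours delayed entry by letting the first interval start
at a positive time.

Tie-breaking: a covariate change is applied left-closed (the new value
holds from the change time onward), so an event occurring exactly at a
change time is attributed to the covariate state in force just before it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exposure import DURATION_EDGES, ExposureTimeline

log = logging.getLogger(__name__)


def split_intervals(entry: float, end: float, status: int,
                    changes: list[tuple[float, str, object]],
                    base_covariates: dict) -> list[dict]:
    """Split one participant's follow-up at covariate change points.

    Parameters
    ----------
    entry, end : follow-up window (days since study start), entry < end
    status : 1 if the event occurs at ``end``, else 0
    changes : (day, covariate, new value) triples; days outside
        (entry, end) are ignored with a warning when beyond follow-up
    base_covariates : covariate values in force at entry

    Returns one dict per interval with keys start, stop, status and the
    covariates.  Zero-length intervals are dropped; the number of intervals
    is (number of distinct change days strictly inside follow-up) + 1.
    """
    if not entry < end:
        raise ValueError(f"entry ({entry}) must precede end ({end})")
    cov = dict(base_covariates)
    inside: dict[float, list] = {}
    for day, name, value in sorted(changes, key=lambda c: c[0]):
        if day <= entry:
            cov[name] = value            # already in force at entry
        elif day < end:
            inside.setdefault(day, []).append((name, value))
        else:
            if day > end:
                log.warning("change of %r at day %s is outside follow-up "
                            "(ends %s); ignored", name, day, end)
            # day == end: event attributed to the pre-change state
    rows = []
    cuts = [entry] + sorted(inside) + [end]
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        if hi > lo:
            rows.append({"start": lo, "stop": hi, "status": 0, **cov})
        for name, value in inside.get(hi, []):
            cov[name] = value
    if rows:
        rows[-1]["status"] = int(status)
    return rows


def build_counting_table(participants: pd.DataFrame,
                         timelines: dict[object, ExposureTimeline],
                         ckd: pd.DataFrame, *,
                         entry_col: str = "analysis_entry_day",
                         covariate_cols: tuple[str, ...] = (),
                         age70_col: str = "age70_day",
                         duration_edges=DURATION_EDGES) -> pd.DataFrame:
    """Assemble the cohort-level start-stop table.

    Time-varying covariates constructed here:

    * ``ppi`` — ever-user indicator (1 from first episode start onward);
    * ``ppi_current`` — currently-exposed indicator (episode boundaries);
    * ``ppi_high`` — current episode is high dose;
    * ``ppi_duration_cat`` — cumulative-exposure duration bin index
      (0 = none yet, then 1.. per ``duration_edges`` crossing);
    * ``age70`` — participant is 70 or older (crossing at the birthday).

    Constant covariates are copied from ``covariate_cols`` of
    ``participants``.  Follow-up runs from ``entry_col`` to the CKD event
    or censor day.
    """
    ckd_idx = ckd.set_index("participant_id")
    frames = []
    for row in participants.itertuples(index=False):
        pid = row.participant_id
        entry = float(getattr(row, entry_col))
        st = ckd_idx.loc[pid]
        end = float(st["event_day"]) if st["incident"] else float(st["censor_day"])
        if not entry < end:
            continue  # no at-risk time after exclusion window
        tl = timelines[pid]
        changes: list[tuple[float, str, object]] = []
        if tl.episodes:
            changes.append((tl.ever_start, "ppi", 1))
            for ep in tl.episodes:
                changes.append((ep.start, "ppi_current", 1))
                changes.append((ep.end, "ppi_current", 0))
                changes.append((ep.start, "ppi_high", 1 if ep.dose == "high" else 0))
                changes.append((ep.end, "ppi_high", 0))
            cum0 = tl.cumulative_at(entry)
            base_bin = int(np.searchsorted(duration_edges, cum0, side="right"))
            if cum0 > 0:
                changes.append((entry, "ppi_duration_cat", base_bin))
            for day in tl.crossing_times(duration_edges):
                cum = tl.cumulative_at(day)
                changes.append((day, "ppi_duration_cat",
                                int(np.searchsorted(duration_edges, cum,
                                                    side="right"))))
        age70_day = getattr(row, age70_col, None)
        if age70_day is not None and np.isfinite(age70_day):
            changes.append((float(age70_day), "age70", 1))
        # drop change points at/after end of follow-up (expected: future
        # birthdays, episode ends past the event) before splitting
        changes = [c for c in changes if c[0] < end]
        base = {"ppi": 0, "ppi_current": 0, "ppi_high": 0,
                "ppi_duration_cat": 0, "age70": 0}
        for c in covariate_cols:
            base[c] = getattr(row, c)
        rows = split_intervals(entry, end, int(st["incident"]), changes, base)
        df = pd.DataFrame(rows)
        df.insert(0, "participant_id", pid)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["participant_id", "start", "stop", "status"])
    return pd.concat(frames, ignore_index=True)


@dataclass
class ValidationReport:
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_table(table: pd.DataFrame) -> ValidationReport:
    """Check the counting-process invariants; return all violations found."""
    v: list[str] = []
    if len(table) == 0:
        return ValidationReport(v)
    bad = table["start"] >= table["stop"]
    if bad.any():
        v.append(f"{int(bad.sum())} interval(s) with entry >= exit")
    if not table["status"].isin((0, 1)).all():
        v.append("status outside {0, 1}")
    for pid, g in table.groupby("participant_id", sort=False):
        g = g.sort_values("start")
        starts, stops = g["start"].to_numpy(), g["stop"].to_numpy()
        if np.any(starts[1:] < stops[:-1] - 1e-9):
            v.append(f"participant {pid}: overlapping intervals")
        elif np.any(np.abs(starts[1:] - stops[:-1]) > 1e-9):
            v.append(f"participant {pid}: gap between consecutive intervals")
        stat = g["status"].to_numpy()
        if stat.sum() > 1:
            v.append(f"participant {pid}: more than one event row")
        if stat[:-1].sum() > 0:
            v.append(f"participant {pid}: event on a non-final interval")
    return ValidationReport(v)
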