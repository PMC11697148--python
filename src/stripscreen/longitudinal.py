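"""Longitudinal assembly: compliance, landmark datasets, weekly changes.

Works on two tidy tables:

* ``participants`` — one row per woman: id, enrollment_week, delivery_week,
  boolean outcome columns (pe, pih, iugr) and the matching event_week_*.
* ``features`` — one row per submitted test: participant_id, week, the 72
  color variables and combined_rgb_min.

The discrimination analyses are *landmark* analyses: discrimination is
assessed at a fixed gestational week (default 25) using only women still
event-free at that week, predicting events occurring later. Three outcome
groupings are screened: PE alone, PE∪PIH, and PE∪PIH∪IUGR. Alongside the
week-25 level, the weekly color *changes* over weeks 20–25 (five adjacent
pairs) provide the remaining time points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colorimetry import COMBINED_RGB_COLUMN, FEATURE_SCHEMA

__all__ = [
    "GROUPINGS",
    "ComplianceRecord",
    "LandmarkDataset",
    "compliance_rate",
    "compliance_table",
    "grouping_event_week",
    "build_landmark_dataset",
    "weekly_changes",
    "build_change_dataset",
    "trajectory_table",
]

#: Outcome groupings: name → outcome columns whose union defines an event.
GROUPINGS = {
    "pe": ("pe",),
    "pe_pih": ("pe", "pih"),
    "pe_pih_iugr": ("pe", "pih", "iugr"),
}

#: All feature columns carried through the longitudinal tables.
VALUE_COLUMNS = (*FEATURE_SCHEMA, COMBINED_RGB_COLUMN)


@dataclass
class ComplianceRecord:
    participant_id: str
    n_submitted: int
    n_weeks_total: int

    @property
    def rate(self) -> float:
        """Percentage of weeks (enrollment to delivery, inclusive) with a
        submitted test."""
        return 100.0 * self.n_submitted / self.n_weeks_total


@dataclass
class LandmarkDataset:
    """Included rows (with a case/control label) plus the exclusion log."""

    landmark_week: int
    grouping: str
    data: pd.DataFrame  # participant_id, case (bool), feature columns
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["participant_id", "reason"])
    )

    @property
    def n_cases(self) -> int:
        return int(self.data["case"].sum())

    @property
    def n_controls(self) -> int:
        return int((~self.data["case"]).sum())


def compliance_rate(participant, testlog: pd.DataFrame) -> ComplianceRecord:
    """Compliance for one participant: submitted weeks / total weeks × 100.

    Weeks are counted inclusively from enrollment to delivery. ``participant``
    may be a Participant object or a participants-table row (needs id,
    enrollment_week, delivery_week).
    """
    pid = getattr(participant, "id", None)
    enroll = int(participant.enrollment_week)
    deliver = int(participant.delivery_week)
    total = deliver - enroll + 1
    if total <= 0:
        raise ValueError("empty week range: delivery before enrollment")
    sub = testlog[
        (testlog["participant_id"] == pid)
        & (testlog["week"] >= enroll)
        & (testlog["week"] <= deliver)
        & (testlog["submitted"])
    ]
    return ComplianceRecord(participant_id=pid, n_submitted=len(sub), n_weeks_total=total)


def compliance_table(participants: pd.DataFrame, testlog: pd.DataFrame) -> pd.DataFrame:
    """Per-participant compliance: n_submitted, n_weeks_total, rate (%)."""
    n_sub = (
        testlog[testlog["submitted"]]
        .groupby("participant_id")["week"]
        .size()
        .rename("n_submitted")
    )
    out = participants[["id", "enrollment_week", "delivery_week"]].copy()
    out["n_weeks_total"] = out["delivery_week"] - out["enrollment_week"] + 1
    out = out.merge(n_sub, left_on="id", right_index=True, how="left")
    out["n_submitted"] = out["n_submitted"].fillna(0).astype(int)
    out["rate"] = 100.0 * out["n_submitted"] / out["n_weeks_total"]
    return out[["id", "n_submitted", "n_weeks_total", "rate"]]


def grouping_event_week(participants: pd.DataFrame, grouping: str) -> pd.Series:
    """Earliest in-grouping event week per participant (NaN if event-free)."""
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {list(GROUPINGS)}")
    cols = [f"event_week_{o}" for o in GROUPINGS[grouping]]
    ew = participants[cols].apply(pd.to_numeric, errors="coerce")
    return ew.min(axis=1)


def build_landmark_dataset(
    participants: pd.DataFrame,
    features: pd.DataFrame,
    landmark_week: int = 25,
    grouping: str = "pe_pih_iugr",
) -> LandmarkDataset:
    """Week-``landmark_week`` dataset for one outcome grouping.

    Exclusions (logged with a reason):
    * ``event_on_or_before_landmark`` — the participant's earliest
      in-grouping event is at or before the landmark (not event-free);
    * ``no_test_at_landmark`` — no submitted test in the landmark week.

    Cases are included participants whose in-grouping event occurs after
    the landmark; everyone else included is a control.
    """
    event_week = grouping_event_week(participants, grouping)
    at_landmark = features[features["week"] == landmark_week].set_index("participant_id")
    # one test per participant-week; a duplicate would mean the log was not
    # deduplicated upstream
    at_landmark = at_landmark[~at_landmark.index.duplicated(keep="last")]

    rows, excl = [], []
    for idx, p in participants.reset_index(drop=True).iterrows():
        ew = event_week.iloc[idx] if idx < len(event_week) else np.nan
        if not pd.isna(ew) and ew <= landmark_week:
            excl.append({"participant_id": p["id"], "reason": "event_on_or_before_landmark"})
            continue
        if p["id"] not in at_landmark.index:
            excl.append({"participant_id": p["id"], "reason": "no_test_at_landmark"})
            continue
        row = {"participant_id": p["id"], "case": bool(not pd.isna(ew))}
        feats = at_landmark.loc[p["id"]]
        for c in VALUE_COLUMNS:
            row[c] = feats[c]
        rows.append(row)
    data = pd.DataFrame(rows, columns=["participant_id", "case", *VALUE_COLUMNS])
    exclusions = pd.DataFrame(excl, columns=["participant_id", "reason"])
    return LandmarkDataset(
        landmark_week=landmark_week, grouping=grouping, data=data, exclusions=exclusions
    )


def weekly_changes(
    features: pd.DataFrame, start_week: int = 20, end_week: int = 25
) -> pd.DataFrame:
    """Adjacent-week deltas over [start_week, end_week].

    For each pair (w, w+1) a participant contributes one row iff both weeks
    have a submitted test; the delta is value(w+1) − value(w) for each of
    the 72 variables and the combined RGB value. Output columns:
    participant_id, week_from, week_to, week_pair (e.g. ``d20_21``) and the
    delta-valued feature columns.
    """
    wide = features.set_index(["participant_id", "week"])
    wide = wide[~wide.index.duplicated(keep="last")][list(VALUE_COLUMNS)]
    rows = []
    for w in range(start_week, end_week):
        try:
            a = wide.xs(w, level="week")
            b = wide.xs(w + 1, level="week")
        except KeyError:
            continue
        common = a.index.intersection(b.index)
        if common.empty:
            continue
        delta = b.loc[common] - a.loc[common]
        delta = delta.reset_index().rename(columns={"index": "participant_id"})
        delta.insert(1, "week_from", w)
        delta.insert(2, "week_to", w + 1)
        delta.insert(3, "week_pair", f"d{w}_{w + 1}")
        rows.append(delta)
    cols = ["participant_id", "week_from", "week_to", "week_pair", *VALUE_COLUMNS]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.concat(rows, ignore_index=True)[cols]


def build_change_dataset(
    participants: pd.DataFrame,
    changes: pd.DataFrame,
    week_pair: str,
    grouping: str = "pe_pih_iugr",
) -> LandmarkDataset:
    """Case/control dataset for one weekly-change time point.

    Inclusion requires both weeks of the pair submitted (rows of
    ``changes``), regardless of missing tests in other weeks. Participants
    whose in-grouping event is at or before the later week of the pair are
    excluded; cases are those with a later in-grouping event.
    """
    sub = changes[changes["week_pair"] == week_pair]
    if sub.empty and week_pair not in set(changes.get("week_pair", [])):
        week_to = int(week_pair.split("_")[-1])
    else:
        week_to = int(sub["week_to"].iloc[0]) if len(sub) else int(week_pair.split("_")[-1])
    event_week = grouping_event_week(participants, grouping)
    ew_by_id = pd.Series(event_week.values, index=participants["id"].values)

    rows, excl = [], []
    sub = sub.set_index("participant_id")
    for pid in participants["id"]:
        ew = ew_by_id.get(pid, np.nan)
        if not pd.isna(ew) and ew <= week_to:
            excl.append({"participant_id": pid, "reason": "event_on_or_before_window"})
            continue
        if pid not in sub.index:
            excl.append({"participant_id": pid, "reason": "missing_week_in_pair"})
            continue
        row = {"participant_id": pid, "case": bool(not pd.isna(ew))}
        feats = sub.loc[pid]
        for c in VALUE_COLUMNS:
            row[c] = feats[c]
        rows.append(row)
    data = pd.DataFrame(rows, columns=["participant_id", "case", *VALUE_COLUMNS])
    exclusions = pd.DataFrame(excl, columns=["participant_id", "reason"])
    return LandmarkDataset(
        landmark_week=week_to, grouping=grouping, data=data, exclusions=exclusions
    )


def trajectory_table(
    participants: pd.DataFrame,
    features: pd.DataFrame,
    subset_size: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Long-format combined-minimum-RGB trajectories for plotting.

    Only women with a submitted test in *every* week from enrollment to
    delivery are eligible. The outcome stratum is ``iugr`` > ``pe`` >
    ``pih`` > ``normotensive`` (IUGR takes display precedence). When
    ``subset_size`` is given, each non-IUGR stratum is randomly subsampled
    to at most that many women (seeded); all IUGR women are always kept.
    """
    counts = (
        features.groupby("participant_id")["week"].nunique().rename("n_weeks_with_test")
    )
    merged = participants.merge(counts, left_on="id", right_index=True, how="left")
    merged["n_weeks_with_test"] = merged["n_weeks_with_test"].fillna(0).astype(int)
    total = merged["delivery_week"] - merged["enrollment_week"] + 1
    full = merged[merged["n_weeks_with_test"] >= total]

    def stratum(row):
        if row["iugr"]:
            return "iugr"
        if row["pe"]:
            return "pe"
        if row["pih"]:
            return "pih"
        return "normotensive"

    strata = {pid: stratum(row) for pid, row in full.set_index("id").iterrows()}
    keep = set(strata)
    if subset_size is not None:
        rng = np.random.default_rng(seed)
        keep = set()
        for s in ("normotensive", "pih", "pe", "iugr"):
            ids = sorted(pid for pid, st in strata.items() if st == s)
            if s != "iugr" and len(ids) > subset_size:
                ids = list(rng.choice(ids, size=subset_size, replace=False))
            keep.update(ids)

    rows = features[features["participant_id"].isin(keep)]
    out = rows[["participant_id", "week", COMBINED_RGB_COLUMN]].rename(
        columns={COMBINED_RGB_COLUMN: "value"}
    )
    out = out.copy()
    out["stratum"] = out["participant_id"].map(strata)
    return out.sort_values(["participant_id", "week"]).reset_index(drop=True)
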