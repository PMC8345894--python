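"""Population strata: age/sex/enrollment-window cohorts and their DR series.

Members sharing sex, age group and an exact enrollment window form a "hard"
stratum.  Hard strata with nearby windows are merged into "soft" strata by
weighted K-means on the (start, end) boundary pair, run independently per
(sex, age-group) cell, so that one model instance fits a cohort of
approximately shared observation span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

#: Decade-like age bins; age at mid-enrollment above 65 is excluded because
#: such members typically leave commercial claims data for other coverage.
AGE_BINS = ((0, 10), (11, 20), (21, 30), (31, 40), (41, 50), (51, 65))
AGE_BIN_LABELS = tuple(f"{lo}-{hi}" for lo, hi in AGE_BINS)
MAX_AGE = 65


def assign_age_group(age_mid: float):
    """Age-group index for an age at mid-enrollment, or None if excluded.

    Bins: 0-10, 11-20, 21-30, 31-40, 41-50, 51-65; ages above 65 are
    flagged for exclusion (returns None).  Fractional ages fall in the bin
    whose integer range contains their floor.
    """
    if age_mid < 0:
        raise ValueError(f"age must be non-negative, got {age_mid}")
    if age_mid > MAX_AGE:
        return None
    for idx, (lo, hi) in enumerate(AGE_BINS):
        if age_mid < hi + 1:
            return idx
    return None  # pragma: no cover


@dataclass(frozen=True)
class SoftStratum:
    """A merged cohort of hard strata sharing sex and age group.

    ``window_start``/``window_end`` are member-weighted mean boundaries of
    the constituent hard strata (rounded to the week grid).
    """

    stratum_id: int
    sex: str
    age_group: int
    window_start: int
    window_end: int
    total_members: int
    total_person_weeks: int
    hard_keys: tuple[tuple[int, int], ...] = ()


@dataclass
class DRSeries:
    """Weekly diagnosis-rate series of one stratum.

    ``dr`` is diagnoses/enrollees, defined only where ``enrollees > 0``
    (NaN otherwise).  Weeks outside the stratum's merged span are absent.
    """

    stratum_id: int
    weeks: np.ndarray
    enrollees: np.ndarray
    diagnoses: np.ndarray
    dr: np.ndarray
    condition: str = ""
    sex: str = ""
    age_group: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "stratum_id": self.stratum_id, "week": self.weeks,
            "enrollees": self.enrollees, "diagnoses": self.diagnoses,
            "dr": self.dr})


def build_hard_strata(members: pd.DataFrame) -> pd.DataFrame:
    """One row per distinct (sex, age_group, start, end) among non-excluded
    members, with the member count of each.
    """
    if len(members) == 0:
        raise ValueError("member table is empty")
    m = members.copy()
    m["age_group"] = m["age_mid"].map(
        lambda a: assign_age_group(a) if a >= 0 else None)
    m = m[m["age_group"].notna()]
    m["age_group"] = m["age_group"].astype(int)
    hard = (m.groupby(["sex", "age_group", "enroll_start_week",
                       "enroll_end_week"], as_index=False)
            .agg(member_count=("member_id", "size")))
    return hard.sort_values(list(hard.columns[:4])).reset_index(drop=True)


def merge_strata_kmeans(hard: pd.DataFrame, k_per_age_group: int,
                        seed: int = 0) -> list[SoftStratum]:
    """Merge hard strata into soft strata by K-means on (start, end).

    Clustering runs independently per (sex, age_group) cell in the 2-D
    boundary space, with member counts as sample weights.  If a cell has
    fewer distinct boundary pairs than ``k_per_age_group``, k is reduced
    with a warning.
    """
    out: list[SoftStratum] = []
    sid = 0
    for (sex, age_group), cell in hard.groupby(["sex", "age_group"], sort=True):
        if len(cell) == 0:  # pragma: no cover
            warnings.warn(f"empty stratum cell ({sex}, {age_group}); skipped")
            continue
        X = cell[["enroll_start_week", "enroll_end_week"]].to_numpy(float)
        w = cell["member_count"].to_numpy(float)
        n_distinct = len(np.unique(X, axis=0))
        k = min(k_per_age_group, n_distinct)
        if k < k_per_age_group:
            warnings.warn(
                f"cell ({sex}, {age_group}): only {n_distinct} distinct "
                f"boundary pairs; reducing k to {k}")
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(X, sample_weight=w)
        for lab in range(k):
            sel = labels == lab
            if not sel.any():
                continue
            cw = w[sel]
            starts, ends = X[sel, 0], X[sel, 1]
            ws = int(round(np.average(starts, weights=cw)))
            we = int(round(np.average(ends, weights=cw)))
            pweeks = int(np.sum(cw * (ends - starts + 1)))
            out.append(SoftStratum(
                stratum_id=sid, sex=str(sex), age_group=int(age_group),
                window_start=ws, window_end=we,
                total_members=int(cw.sum()), total_person_weeks=pweeks,
                hard_keys=tuple((int(s), int(e)) for s, e in zip(starts, ends)),
            ))
            sid += 1
    return out


def _member_age_groups(members: pd.DataFrame) -> pd.Series:
    return members["age_mid"].map(
        lambda a: assign_age_group(a) if 0 <= a <= MAX_AGE else -1)


def stratum_members(stratum: SoftStratum, members: pd.DataFrame) -> pd.DataFrame:
    """Member rows belonging to a soft stratum (matching sex, age group and
    one of the constituent hard windows)."""
    ag = _member_age_groups(members)
    keys = set(stratum.hard_keys)
    mask = (members["sex"] == stratum.sex) & (ag == stratum.age_group)
    pairs = list(zip(members["enroll_start_week"], members["enroll_end_week"]))
    mask &= pd.Series([p in keys for p in pairs], index=members.index)
    return members[mask]


def compute_dr_series(stratum: SoftStratum, members: pd.DataFrame,
                      claims: pd.DataFrame, condition: str,
                      dedupe: bool = False) -> DRSeries:
    """Weekly DR series of a soft stratum for one condition.

    For each week in the merged window: enrollees = members active that
    week, diagnoses = matching claims that week, dr = diagnoses/enrollees
    (NaN where no enrollees).  With ``dedupe`` multiple same-member claims
    in a week collapse to one.
    """
    sub = stratum_members(stratum, members)
    if len(sub) == 0:
        raise ValueError(f"stratum {stratum.stratum_id} has no resolvable members")
    weeks = np.arange(stratum.window_start, stratum.window_end + 1)
    starts = sub["enroll_start_week"].to_numpy()[:, None]
    ends = sub["enroll_end_week"].to_numpy()[:, None]
    enrollees = ((starts <= weeks) & (weeks <= ends)).sum(axis=0)

    cl = claims[(claims["condition"] == condition)
                & claims["member_id"].isin(sub["member_id"])]
    if dedupe:
        cl = cl.drop_duplicates(subset=["member_id", "week", "condition"])
    counts = cl.groupby("week").size()
    diagnoses = counts.reindex(weeks, fill_value=0).to_numpy()

    with np.errstate(divide="ignore", invalid="ignore"):
        dr = np.where(enrollees > 0, diagnoses / np.maximum(enrollees, 1), np.nan)
    return DRSeries(stratum_id=stratum.stratum_id, weeks=weeks,
                    enrollees=enrollees, diagnoses=diagnoses, dr=dr,
                    condition=condition, sex=stratum.sex,
                    age_group=stratum.age_group)


def aggregate_dr(series_list: list[DRSeries]) -> pd.DataFrame:
    """Pool diagnoses and enrollees over strata and recompute the ratio.

    Returns a frame indexed by week with summed counts and the pooled DR.
    """
    frames = [s.to_frame() for s in series_list]
    allf = pd.concat(frames, ignore_index=True)
    agg = allf.groupby("week")[["enrollees", "diagnoses"]].sum()
    agg["dr"] = np.where(agg["enrollees"] > 0,
                         agg["diagnoses"] / agg["enrollees"].clip(lower=1), np.nan)
    return agg
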