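"""Biomarker sample selection against treatment-episode DAS time windows.

Serum samples in the biobank are matched to disease-activity (DAS28)
follow-up episodes of treated patients: a sample belongs to the *start*
window of an episode if it was collected at most ``start_before`` days before
the DAS start date or up to ``start_after`` days after (default 30/40,
inclusive at both ends), and to the *end* window analogously with
``end_before``/``end_after`` (default 75/152). The per-treatment summary
mirrors the biobank report layout: total patients, globally eligible serum
samples, and sample/patient counts per window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .store import FusedStore

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowConfig:
    """Day offsets (whole days, all ≥ 0) and sample eligibility predicates."""

    start_before: int = 30
    start_after: int = 40
    end_before: int = 75
    end_after: int = 152
    min_volume: float | None = None
    allowed_statuses: frozenset | None = None  # None = no status filter

    def __post_init__(self):
        for name in ("start_before", "start_after", "end_before", "end_after"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DasEpisode:
    """One treatment episode with its DAS28 anchor dates and scores."""

    coded_id: str
    treatment: str
    start_date: pd.Timestamp
    das_start_date: pd.Timestamp | None
    das_end_date: pd.Timestamp | None
    das28_start: float | None
    das28_end: float | None


def eligible_samples(store: FusedStore, cfg: WindowConfig | None = None) -> pd.DataFrame:
    """Serum samples passing the volume/freezer-status predicates.

    With no predicates configured every serum sample passes; a depleted
    sample is excluded whenever a status whitelist is given.
    """
    cfg = cfg or WindowConfig()
    s = store.samples
    mask = s["sample_type"] == "serum"
    if cfg.min_volume is not None:
        mask &= s["volume"].notna() & (s["volume"] >= cfg.min_volume)
    if cfg.allowed_statuses is not None:
        mask &= s["freezer_status"].isin(list(cfg.allowed_statuses))
    return s.loc[mask].copy()


def build_episodes(store: FusedStore,
                   treatments: Iterable[str] | None = None,
                   strategy: str = "registry") -> list[DasEpisode]:
    """Derive DAS episodes from the treatment and visit tables.

    The default ``registry`` strategy opens one episode per treatment record:
    the episode spans from the treatment start date to the day before the
    patient's next treatment start (or indefinitely for the last treatment);
    ``das_start_date`` is the first visit with a DAS28 in that span and
    ``das_end_date`` the last such visit.
    """
    if strategy != "registry":
        raise ValueError(f"unknown episode-builder strategy {strategy!r}")
    t = store.treatments.sort_values(["coded_id", "start_date"], kind="mergesort")
    if treatments is not None:
        wanted = set(treatments)
    visits = store.visits
    episodes: list[DasEpisode] = []
    for coded_id, group in t.groupby("coded_id", sort=True):
        starts = list(group["start_date"]) + [pd.Timestamp.max]
        pv = visits[(visits["coded_id"] == coded_id) & visits["das28"].notna()]
        pv = pv.sort_values("visit_date", kind="mergesort")
        for i, row in enumerate(group.itertuples(index=False)):
            if treatments is not None and row.treatment not in wanted:
                continue
            span = pv[(pv["visit_date"] >= row.start_date)
                      & (pv["visit_date"] < starts[i + 1])]
            if len(span):
                first, last = span.iloc[0], span.iloc[-1]
                episodes.append(DasEpisode(
                    coded_id=str(coded_id), treatment=row.treatment,
                    start_date=row.start_date,
                    das_start_date=first["visit_date"], das_end_date=last["visit_date"],
                    das28_start=float(first["das28"]), das28_end=float(last["das28"])))
            else:
                episodes.append(DasEpisode(
                    coded_id=str(coded_id), treatment=row.treatment,
                    start_date=row.start_date, das_start_date=None,
                    das_end_date=None, das28_start=None, das28_end=None))
    return episodes


def select_in_window(samples: pd.DataFrame, episode: DasEpisode,
                     which: str, cfg: WindowConfig | None = None) -> pd.DataFrame:
    """Samples of the episode's patient collected inside one DAS window.

    ``which`` is ``"start"`` or ``"end"``; both window edges are inclusive
    ("at most N days before ... up to M days after"). A missing anchor date
    yields an empty selection with a logged warning.
    """
    cfg = cfg or WindowConfig()
    if which == "start":
        anchor, before, after = episode.das_start_date, cfg.start_before, cfg.start_after
    elif which == "end":
        anchor, before, after = episode.das_end_date, cfg.end_before, cfg.end_after
    else:
        raise ValueError(f"window must be 'start' or 'end', got {which!r}")
    if anchor is None or pd.isna(anchor):
        logger.warning("episode %s/%s has no %s DAS date; empty selection",
                       episode.coded_id, episode.treatment, which)
        return samples.iloc[0:0].copy()
    lo = anchor - pd.Timedelta(days=int(before))
    hi = anchor + pd.Timedelta(days=int(after))
    mask = ((samples["coded_id"].astype(str) == episode.coded_id)
            & (samples["sample_date"] >= lo) & (samples["sample_date"] <= hi))
    return samples.loc[mask].copy()


@dataclass
class WindowSelection:
    """Per-treatment summary plus the per-sample assignment records."""

    summary: pd.DataFrame
    assignments: pd.DataFrame
    n_samples_eligible: int


def summarize_selection(store: FusedStore,
                        treatments: Iterable[str],
                        cfg: WindowConfig | None = None,
                        dedupe_overlapping: bool = False) -> WindowSelection:
    """Per-treatment window summary over all derivable DAS episodes.

    Summary columns mirror the biobank report: ``treatment``,
    ``n_patients_total``, ``n_samples_eligible`` (the global eligible serum
    count, echoed on every row), then sample and distinct-patient counts for
    the start and end windows. A sample is counted once per window per
    treatment even if it falls in both windows; with
    ``dedupe_overlapping`` a sample claimed by one episode is not assigned
    again to a later overlapping episode of the same patient and treatment.
    """
    cfg = cfg or WindowConfig()
    treatments = list(treatments)
    eligible = eligible_samples(store, cfg).reset_index().rename(
        columns={"index": "sample_index"})
    episodes = build_episodes(store, treatments)

    records = []
    for which in ("start", "end"):
        seen: set[tuple] = set()
        for ep in episodes:
            sel = select_in_window(eligible, ep, which, cfg)
            for row in sel.itertuples(index=False):
                key = (ep.treatment, which, row.sample_index)
                if dedupe_overlapping and key in seen:
                    continue
                seen.add(key)
                records.append({"treatment": ep.treatment, "window": which,
                                "coded_id": ep.coded_id,
                                "sample_index": row.sample_index,
                                "sample_date": row.sample_date,
                                "episode_start": ep.start_date})
    assignments = pd.DataFrame(
        records, columns=["treatment", "window", "coded_id", "sample_index",
                          "sample_date", "episode_start"])

    t = store.treatments
    rows = []
    for code in treatments:
        n_patients = t.loc[t["treatment"] == code, "coded_id"].nunique()
        sub = assignments[assignments["treatment"] == code]
        start = sub[sub["window"] == "start"]
        end = sub[sub["window"] == "end"]
        rows.append({
            "treatment": code,
            "n_patients_total": int(n_patients),
            "n_samples_eligible": int(len(eligible)),
            "start_window_samples": int(start["sample_index"].nunique()),
            "start_window_patients": int(start["coded_id"].nunique()),
            "end_window_samples": int(end["sample_index"].nunique()),
            "end_window_patients": int(end["coded_id"].nunique()),
        })
    summary = pd.DataFrame(rows)
    return WindowSelection(summary=summary, assignments=assignments,
                           n_samples_eligible=int(len(eligible)))
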