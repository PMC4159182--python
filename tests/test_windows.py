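"""DAS time-window sample selection: inclusive bounds, oracles, summaries."""

import numpy as np
import pandas as pd
import pytest

import cohortfusion as cf
from cohortfusion.windows import DasEpisode, WindowConfig

from .oracles import enumerate_window_offsets


def _episode(start="2012-03-01", end="2012-09-17"):
    return DasEpisode(coded_id="P000001", treatment="A",
                      start_date=pd.Timestamp(start),
                      das_start_date=pd.Timestamp(start),
                      das_end_date=pd.Timestamp(end) if end else None,
                      das28_start=5.1, das28_end=3.0)


def _samples_at_offsets(anchor, offsets, pid="P000001"):
    return pd.DataFrame({
        "coded_id": pid,
        "sample_type": "serum",
        "sample_date": [pd.Timestamp(anchor) + pd.Timedelta(days=d) for d in offsets],
        "n_cells_millions": np.nan,
        "position": [f"01:A{i + 1:02d}" for i in range(len(offsets))],
        "volume": 500.0,
        "freezer_status": "available",
        "offset": offsets,
    })


class TestWindowBounds:
    @pytest.mark.parametrize("offset,selected", [
        (-31, False), (-30, True), (0, True), (40, True), (41, False)])
    def test_start_window_inclusive_bounds(self, offset, selected):
        ep = _episode()
        s = _samples_at_offsets(ep.das_start_date, [offset])
        got = cf.select_in_window(s, ep, "start")
        assert (len(got) == 1) is selected

    @pytest.mark.parametrize("offset,selected", [
        (-76, False), (-75, True), (0, True), (152, True), (153, False)])
    def test_end_window_inclusive_bounds(self, offset, selected):
        ep = _episode()
        s = _samples_at_offsets(ep.das_end_date, [offset])
        got = cf.select_in_window(s, ep, "end")
        assert (len(got) == 1) is selected

    @pytest.mark.parametrize("which,before,after", [
        ("start", 30, 40), ("end", 75, 152)])
    def test_selection_equals_offset_enumeration_oracle(self, which, before, after):
        """Brute-force day enumeration over -200..+200 agrees with the engine."""
        ep = _episode()
        anchor = ep.das_start_date if which == "start" else ep.das_end_date
        offsets = list(range(-200, 201))
        s = _samples_at_offsets(anchor, offsets)
        s["position"] = [f"{(i // 12) + 1:02d}:A{(i % 12) + 1:02d}"
                         for i in range(len(offsets))]
        got = set(cf.select_in_window(s, ep, which)["offset"])
        assert got == enumerate_window_offsets(before, after)

    def test_zero_width_window_selects_same_day_only(self):
        ep = _episode()
        cfg = WindowConfig(start_before=0, start_after=0)
        s = _samples_at_offsets(ep.das_start_date, [-1, 0, 1])
        got = cf.select_in_window(s, ep, "start", cfg)
        assert got["offset"].tolist() == [0]

    def test_missing_anchor_gives_empty_selection(self, caplog):
        ep = DasEpisode("P000001", "A", pd.Timestamp("2012-01-01"),
                        None, None, None, None)
        s = _samples_at_offsets("2012-01-01", [0])
        with caplog.at_level("WARNING"):
            got = cf.select_in_window(s, ep, "start")
        assert len(got) == 0 and any("no start DAS" in r.message for r in caplog.records)

    def test_widening_any_bound_never_shrinks_selection(self):
        ep = _episode()
        s = _samples_at_offsets(ep.das_start_date, list(range(-100, 101, 7)))
        base = len(cf.select_in_window(s, ep, "start", WindowConfig()))
        wider = WindowConfig(start_before=60, start_after=80)
        assert len(cf.select_in_window(s, ep, "start", wider)) >= base

    def test_negative_bounds_rejected(self):
        with pytest.raises(ValueError):
            WindowConfig(start_before=-1)


class TestEligibility:
    def test_depleted_sample_excluded_when_status_filtered(self, small_store):
        cfg = WindowConfig(allowed_statuses=frozenset({"available"}))
        got = cf.eligible_samples(small_store, cfg)
        assert (got["freezer_status"] == "available").all()
        assert (got["sample_type"] == "serum").all()

    def test_no_filters_passes_all_serum(self, small_store):
        got = cf.eligible_samples(small_store)
        expected = (small_store.samples["sample_type"] == "serum").sum()
        assert len(got) == expected

    def test_count_equals_brute_force_predicate_scan(self, medium_store):
        cfg = WindowConfig(min_volume=300.0,
                           allowed_statuses=frozenset({"available", "reserved"}))
        expected = sum(
            1 for r in medium_store.samples.to_dict("records")
            if r["sample_type"] == "serum"
            and pd.notna(r["volume"]) and r["volume"] >= 300.0
            and r["freezer_status"] in ("available", "reserved"))
        assert len(cf.eligible_samples(medium_store, cfg)) == expected


class TestSummary:
    def test_fixture_window_demo_matches_manifest(self):
        store, man = cf.plant_truth(cf.SynthConfig(ra_n=20, psoriasis_n=5, seed=8),
                                    "window_demo")
        eps = [e for e in cf.build_episodes(store, ["A"])
               if e.coded_id == man["coded_id"]]
        assert len(eps) == 1
        ep = eps[0]
        assert str(ep.das_start_date.date()) == man["das_start_date"]
        start = cf.select_in_window(store.samples, ep, "start")
        offs = sorted((start["sample_date"] - ep.das_start_date).dt.days.tolist())
        assert offs == man["expected_start_offsets"]
        end = cf.select_in_window(store.samples, ep, "end")
        offs = sorted((end["sample_date"] - ep.das_end_date).dt.days.tolist())
        assert offs == man["expected_end_offsets"]

    def test_treatment_without_patients_yields_zero_row(self, small_store):
        sel = cf.summarize_selection(small_store, ["Z"])
        row = sel.summary.iloc[0]
        assert row["treatment"] == "Z"
        assert row["n_patients_total"] == 0
        assert row["start_window_samples"] == 0 and row["end_window_samples"] == 0

    def test_sample_in_both_windows_counted_once_per_window(self):
        store, man = cf.plant_truth(cf.SynthConfig(ra_n=20, psoriasis_n=5, seed=8),
                                    "window_demo")
        pid = man["coded_id"]
        # shrink the episode so one sample lies in both windows
        keep = store.visits["coded_id"] != pid
        store.visits = pd.concat([
            store.visits[keep],
            pd.DataFrame([{"coded_id": pid,
                           "visit_date": pd.Timestamp(man["das_start_date"]),
                           "das28": 5.0}]),
        ], ignore_index=True)  # single visit: das start == das end
        sel = cf.summarize_selection(store, ["A"])
        row = sel.summary.set_index("treatment").loc["A"]
        # day-0 sample is inside both windows; each window counts it once
        assert row["start_window_samples"] >= 1
        assert row["end_window_samples"] >= 1
        assert row["start_window_patients"] <= row["n_patients_total"]

    def test_counts_equal_independent_join_recomputation(self, medium_store):
        """Summary counts match a from-scratch join-then-filter recount."""
        cfg = WindowConfig()
        sel = cf.summarize_selection(medium_store, ["A", "B", "C"], cfg)
        eligible = cf.eligible_samples(medium_store, cfg).reset_index() \
            .rename(columns={"index": "sample_index"})
        episodes = cf.build_episodes(medium_store, ["A", "B", "C"])
        for _, row in sel.summary.iterrows():
            code = row["treatment"]
            for which, scol, pcol in (
                    ("start", "start_window_samples", "start_window_patients"),
                    ("end", "end_window_samples", "end_window_patients")):
                samp, pats = set(), set()
                for ep in episodes:
                    if ep.treatment != code:
                        continue
                    anchor = ep.das_start_date if which == "start" else ep.das_end_date
                    if anchor is None or pd.isna(anchor):
                        continue
                    before = cfg.start_before if which == "start" else cfg.end_before
                    after = cfg.start_after if which == "start" else cfg.end_after
                    for r in eligible.to_dict("records"):
                        if str(r["coded_id"]) != ep.coded_id:
                            continue
                        d = (r["sample_date"] - anchor).days
                        if -before <= d <= after:
                            samp.add(r["sample_index"])
                            pats.add(ep.coded_id)
                assert row[scol] == len(samp)
                assert row[pcol] == len(pats)

    def test_eligible_count_echoed_globally_per_row(self, medium_store):
        sel = cf.summarize_selection(medium_store, ["A", "B", "C"])
        assert sel.summary["n_samples_eligible"].nunique() == 1
        assert sel.summary["n_samples_eligible"].iloc[0] == sel.n_samples_eligible

    def test_patients_may_contribute_to_multiple_treatments(self, medium_store):
        """Sequential treatments: per-treatment patient totals can exceed the
        distinct-patient count, mirroring the registry's overlapping groups."""
        sel = cf.summarize_selection(medium_store, ["A", "B", "C"])
        total = sel.summary["n_patients_total"].sum()
        distinct = medium_store.treatments["coded_id"].nunique()
        assert total >= distinct
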