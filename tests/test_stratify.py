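"""Waterfall stratification, metabolic presets, ACPA matrix, PASI change."""

import numpy as np
import pandas as pd
import pytest

import cohortfusion as cf
from cohortfusion.stratify import METABOLIC_PRESETS


class TestWaterfall:
    def test_tautology_step_keeps_full_cohort(self, small_store):
        rep = cf.run_waterfall(small_store, [cf.WaterfallStep.tautology()])
        n_ra = (small_store.patients["cohort"] == "RA").sum()
        assert rep.stages == [("all", n_ra)]
        assert len(rep.final) == n_ra

    def test_constructed_responder_survives_with_expected_delta(self):
        """CCP+, anti-TNF start day 0, DAS28 5.1 at baseline, 3.0 at day 75:
        survives the first four stages with ΔDAS28 = −2.1."""
        ids = ["P000001"]
        d0 = pd.Timestamp("2012-01-01")
        store = cf.FusedStore(
            patients=pd.DataFrame({"coded_id": ids, "cohort": "RA",
                                   "ra_number": "RA 1"}),
            visits=pd.DataFrame([
                {"coded_id": "P000001", "visit_date": d0, "das28": 5.1},
                {"coded_id": "P000001", "visit_date": d0 + pd.Timedelta(days=75),
                 "das28": 3.0}]),
            treatments=pd.DataFrame([{"coded_id": "P000001", "start_date": d0,
                                      "treatment": "A"}]),
            samples=pd.DataFrame(columns=["coded_id", "sample_type", "sample_date",
                                          "n_cells_millions", "position", "volume",
                                          "freezer_status"]),
            genotypes=pd.DataFrame({"coded_id": ids, "hla_dr": "*04/*15"}),
            serology=pd.DataFrame([{"coded_id": "P000001",
                                    "measurement_date": d0, "ccp_serum": 300.0,
                                    "cit_c1_igg": 1.0, "cit_eno_igg": 1.0,
                                    "cit_fib_igg": 1.0, "source": "serum"}]),
            psoriasis=pd.DataFrame(columns=["coded_id", "timepoint", "course",
                                            "pasi", "bmi", "ldl", "hdl", "tg",
                                            "hdl_ldl_ratio"]),
        )
        steps = cf.ra_treatment_response_steps(delta_threshold=-1.2)
        rep = cf.run_waterfall(store, steps)
        assert rep.counts() == [1, 1, 1, 1, 1, 1]
        assert rep.state["delta_das28"].tolist() == pytest.approx([-2.1])

    def test_fixture_manifest_reproduced(self):
        store, man = cf.plant_truth(cf.SynthConfig(ra_n=10, psoriasis_n=2, seed=4),
                                    "waterfall_demo")
        steps = cf.ra_treatment_response_steps(
            delta_threshold=man["delta_threshold"],
            anti_tnf_codes=man["anti_tnf_codes"])
        rep = cf.run_waterfall(store, steps)
        assert rep.counts() == man["expected_stage_counts"]
        assert rep.final.patient_ids == man["expected_final_ids"]

    def test_zero_ccp_positive_cohort_empties_immediately(self):
        store, man = cf.plant_truth(
            cf.SynthConfig(ra_n=10, psoriasis_n=2, seed=4, ccp_positive_fraction=0),
            "waterfall_demo")
        steps = cf.ra_treatment_response_steps(delta_threshold=man["delta_threshold"])
        rep = cf.run_waterfall(store, steps)
        assert rep.counts() == man["expected_stage_counts"] == [0] * 6
        assert rep.final.patient_ids == []

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_stage_counts_non_increasing_for_every_seed(self, seed):
        store = cf.generate(cf.SynthConfig(ra_n=40, psoriasis_n=5, seed=seed))
        steps = cf.ra_treatment_response_steps(delta_threshold=0.0)
        rep = cf.run_waterfall(store, steps)
        counts = rep.counts()
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert len(rep.final) == counts[-1]

    def test_stage_counts_equal_sequential_brute_force(self, medium_store):
        """Each stage count equals filtering the previous stage's survivors
        with an independent per-patient recheck."""
        steps = cf.ra_treatment_response_steps(delta_threshold=0.0)
        rep = cf.run_waterfall(medium_store, steps)
        store = medium_store
        survivors = set(store.patients.loc[store.patients["cohort"] == "RA",
                                           "coded_id"])
        # stage 1: CCP+
        sero = store.serology
        survivors &= set(sero.loc[sero["ccp_serum"] > 25.0, "coded_id"])
        assert rep.stages[0][1] == len(survivors)
        # stage 2: anti-TNF (code A) start exists
        t = store.treatments
        survivors &= set(t.loc[t["treatment"] == "A", "coded_id"])
        assert rep.stages[1][1] == len(survivors)

    def test_duplicate_labels_rejected(self, small_store):
        steps = [cf.WaterfallStep.tautology("s"), cf.WaterfallStep.tautology("s")]
        with pytest.raises(ValueError):
            cf.run_waterfall(small_store, steps)

    def test_expression_step_and_reorder_commutes(self, medium_store):
        a = cf.WaterfallStep.from_expression(
            "serum sample", cf.Criterion("samples", "sample_type", "eq", "serum"))
        b = cf.WaterfallStep.from_expression(
            "das28>3", cf.Criterion("visits", "das28", "gt", 3.0))
        r1 = cf.run_waterfall(medium_store, [a, b])
        r2 = cf.run_waterfall(medium_store, [b, a])
        assert r1.final.patient_ids == r2.final.patient_ids


class TestMetabolic:
    def test_high_risk_preset_row_structure(self, small_store):
        out = cf.metabolic_stratify(small_store, "high_risk")
        assert out["condition"].tolist() == [
            "BMI>29", "BMI>29 & LDL>4.3", "BMI>29 & LDL>4.3 & TG>2.6",
            "LDL>4.3", "LDL>4.3 & TG>2.6", "TG>2.6"]

    def test_low_risk_preset_row_structure(self, small_store):
        out = cf.metabolic_stratify(small_store, "low_risk")
        assert len(out) == 7 and out["condition"].iloc[0] == "BMI<25"

    def test_lean_cohort_gives_all_zero_high_risk_counts(self):
        store = cf.generate(cf.SynthConfig(ra_n=5, psoriasis_n=50, seed=3,
                                           bmi_mean=20.0, bmi_sd=0.1,
                                           ldl_mean=2.0, ldl_sd=0.1,
                                           tg_log_mean=-0.5, tg_log_sd=0.05))
        out = cf.metabolic_stratify(store, "high_risk")
        assert (out["n_patients"] == 0).all()

    def test_conjunction_counts_bounded_by_constituents(self, medium_store):
        for preset in METABOLIC_PRESETS:
            out = cf.metabolic_stratify(medium_store, preset).set_index("condition")
            singles = {c: out.loc[c, "n_patients"]
                       for c in out.index if "&" not in c}
            for cond in out.index:
                if "&" in cond:
                    parts = [p.strip() for p in cond.split("&")]
                    assert out.loc[cond, "n_patients"] <= min(
                        singles[p] for p in parts)

    def test_triple_conjunction_below_pairwise_minimum(self, medium_store):
        out = cf.metabolic_stratify(medium_store, "low_risk").set_index("condition")
        triple = out.loc["BMI<25 & TG<2 & LDL<4", "n_patients"]
        pairs = [out.loc["BMI<25 & TG<2", "n_patients"],
                 out.loc["BMI<25 & LDL<4", "n_patients"],
                 out.loc["TG<2 & LDL<4", "n_patients"]]
        assert triple <= min(pairs)

    def test_unknown_preset_rejected(self, small_store):
        with pytest.raises(ValueError):
            cf.metabolic_stratify(small_store, "medium_risk")


class TestAcpaMatrix:
    def test_column_per_patient_four_fixed_rows(self, small_store):
        mat = cf.extract_acpa_matrix(small_store)
        assert mat.index.tolist() == ["ccp_serum", "cit_c1_igg",
                                      "cit_eno_igg", "cit_fib_igg"]
        assert len(mat.columns) == len(small_store.patients)

    def test_values_equal_direct_store_lookups(self, medium_store):
        mat = cf.extract_acpa_matrix(medium_store)
        sero = medium_store.serology
        sero = sero[sero["source"] == "serum"].sort_values(
            ["coded_id", "measurement_date"], kind="mergesort")
        rng = np.random.default_rng(0)
        cols = rng.choice(mat.columns, size=min(100, len(mat.columns)),
                          replace=False)
        for pid in cols:
            mine = sero[sero["coded_id"] == pid]
            if len(mine):
                last = mine.iloc[-1]
                for spec in mat.index:
                    assert mat.at[spec, pid] == last[spec] or (
                        pd.isna(mat.at[spec, pid]) and pd.isna(last[spec]))
            else:
                assert mat[pid].isna().all()

    def test_patient_without_serology_is_missing_not_zero(self, small_store):
        pso = small_store.patients.loc[
            small_store.patients["cohort"] == "PSORIASIS", "coded_id"].iloc[0]
        mat = cf.extract_acpa_matrix(small_store, [pso])
        assert mat[pso].isna().all()

    def test_empty_cohort_gives_empty_matrix(self, small_store):
        mat = cf.extract_acpa_matrix(small_store, [])
        assert mat.shape == (4, 0)

    def test_longitudinal_layout_keeps_time_axis(self, medium_store):
        mat = cf.extract_acpa_matrix(medium_store, by_time=True)
        assert mat.index.tolist() == cf.ACPA_SPECIFICITIES
        assert mat.columns.names == ["coded_id", "date"]


class TestPasiChange:
    def test_delta_is_followup_minus_onset(self):
        store = cf.generate(cf.SynthConfig(ra_n=5, psoriasis_n=2, seed=1))
        store.psoriasis = pd.DataFrame([
            {"coded_id": "P000006", "timepoint": "onset", "pasi": 12.0},
            {"coded_id": "P000006", "timepoint": "year10", "pasi": 3.5},
            {"coded_id": "P000007", "timepoint": "onset", "pasi": 8.0},
        ])
        out = cf.pasi_change(store).set_index("coded_id")
        assert out.loc["P000006", "delta"] == pytest.approx(-8.5)
        assert pd.isna(out.loc["P000007", "delta"])

    def test_mean_delta_matches_brute_force_over_complete_pairs(self, medium_store):
        out = cf.pasi_change(medium_store)
        complete = out.dropna(subset=["delta"])
        prof = medium_store.psoriasis
        expected = []
        for pid in sorted(set(prof["coded_id"])):
            mine = prof[prof["coded_id"] == pid]
            on = mine[mine["timepoint"] == "onset"]["pasi"]
            yr = mine[mine["timepoint"] == "year10"]["pasi"]
            if len(on) and len(yr):
                expected.append(float(yr.iloc[0]) - float(on.iloc[0]))
        assert complete["delta"].mean() == pytest.approx(np.mean(expected))
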