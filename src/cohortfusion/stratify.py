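"""Cohort stratification: waterfall filtering, metabolic presets, ACPA matrix.

The waterfall model applies inclusion/exclusion criteria sequentially and
reports the number of surviving patients after every stage. The built-in RA
treatment-response preset reproduces the canonical stratification: anti-CCP
positive patients, starting an anti-TNF treatment, with a baseline DAS28 at
treatment start and a follow-up visit in the two-to-three-month window; the
DAS28 change between the two visits is then computed and thresholded.

The metabolic presets reproduce the psoriasis risk-profile breakdowns
(obesity/hyperlipidemia conjunctions over BMI, LDL and triglycerides), and
:func:`extract_acpa_matrix` assembles the four-specificity antibody matrix
(CCP, Cit-C1 IgG, Cit-Eno IgG, Cit-Fib IgG) with one column per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import QuerySchemaError
from .query import Expression, ResultSet, evaluate
from .store import FusedStore

ACPA_SPECIFICITIES = ["ccp_serum", "cit_c1_igg", "cit_eno_igg", "cit_fib_igg"]


# ---------------------------------------------------------------------------
# waterfall

@dataclass
class WaterfallStep:
    """One stage of a waterfall: a label plus a state transformer.

    ``apply`` receives the store and the current cohort state (a DataFrame
    indexed by ``coded_id``, carrying any derived per-patient columns) and
    returns the surviving state. Steps built from query expressions filter;
    derived-computation steps may add columns without filtering.
    """

    label: str
    apply: Callable[[FusedStore, pd.DataFrame], pd.DataFrame]

    @classmethod
    def from_expression(cls, label: str, expr: Expression) -> "WaterfallStep":
        def _apply(store: FusedStore, state: pd.DataFrame) -> pd.DataFrame:
            rs = evaluate(store, expr, granularity="patient")
            return state.loc[state.index.intersection(rs.patient_ids)]
        return cls(label=label, apply=_apply)

    @classmethod
    def tautology(cls, label: str = "all") -> "WaterfallStep":
        return cls(label=label, apply=lambda store, state: state)


@dataclass
class WaterfallReport:
    """Ordered per-stage survivor counts plus the final patient set."""

    stages: list[tuple[str, int]]
    final: ResultSet
    state: pd.DataFrame

    def counts(self) -> list[int]:
        return [n for _, n in self.stages]


def run_waterfall(store: FusedStore, steps: Sequence[WaterfallStep],
                  cohort: str | None = "RA") -> WaterfallReport:
    """Apply the steps sequentially, recording survivors after each stage."""
    if not steps:
        raise ValueError("waterfall needs at least one step")
    labels = [s.label for s in steps]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate step labels: {labels}")
    patients = store.patients
    if cohort is not None:
        patients = patients[patients["cohort"] == cohort]
    state = pd.DataFrame(index=pd.Index(sorted(patients["coded_id"].astype(str)),
                                        name="coded_id"))
    stages = []
    for step in steps:
        try:
            state = step.apply(store, state)
        except QuerySchemaError as exc:
            raise QuerySchemaError(f"step {step.label!r}: {exc}") from exc
        stages.append((step.label, len(state)))
    rows = store.patients[store.patients["coded_id"].isin(set(state.index))]
    rows = rows.sort_values("coded_id", kind="mergesort").reset_index(drop=True)
    final = ResultSet(granularity="patient", rows=rows,
                      provenance={c: "patients" for c in rows.columns})
    return WaterfallReport(stages=stages, final=final, state=state)


def ra_treatment_response_steps(
    delta_threshold: float,
    anti_tnf_codes: Iterable[str] = ("A",),
    ccp_cutoff: float = 25.0,
    window_days: tuple[int, int] = (60, 92),
    baseline_tolerance: int = 30,
    followup: str = "earliest",
    delta_op: str = "le",
) -> list[WaterfallStep]:
    """The built-in RA anti-TNF response waterfall.

    Stages: (1) anti-CCP positive (any serum CCP titre above ``ccp_cutoff``);
    (2) an anti-TNF treatment start exists; (3) a baseline DAS28 measured at
    treatment start (nearest DAS28 visit within ``baseline_tolerance`` days);
    (4) a follow-up DAS28 visit inside the two-to-three-month window
    (``window_days`` days after baseline, inclusive); (5) compute
    ΔDAS28 = follow-up − baseline; (6) keep patients whose ΔDAS28 satisfies
    ``delta_op`` against ``delta_threshold`` (the threshold is study-specific
    and must be supplied). With ``followup="all"`` every in-window visit is
    considered and the patient survives if any satisfies the threshold.
    """
    codes = tuple(anti_tnf_codes)
    if followup not in {"earliest", "nearest_midpoint", "all"}:
        raise ValueError(f"unknown follow-up policy {followup!r}")
    if delta_op not in {"le", "lt", "ge", "gt"}:
        raise ValueError(f"unknown delta comparator {delta_op!r}")

    def ccp_positive(store, state):
        sero = store.serology
        pos = sero.loc[sero["ccp_serum"] > ccp_cutoff, "coded_id"].astype(str)
        return state.loc[state.index.intersection(set(pos))]

    def anti_tnf_start(store, state):
        t = store.treatments
        mine = t[t["treatment"].isin(codes) & t["coded_id"].astype(str).isin(state.index)]
        if not len(mine):
            return state.iloc[0:0]
        first = mine.sort_values("start_date", kind="mergesort") \
                    .groupby("coded_id", sort=True)["start_date"].first()
        out = state.loc[state.index.intersection(first.index.astype(str))].copy()
        out["baseline_date"] = first.reindex(out.index)
        return out

    def baseline_das28(store, state):
        if not len(state):
            return state
        v = store.visits[store.visits["das28"].notna()]
        rows = []
        for coded_id, bdate in state["baseline_date"].items():
            pv = v[v["coded_id"].astype(str) == coded_id]
            if not len(pv):
                continue
            delta = (pv["visit_date"] - bdate).dt.days.abs()
            near = delta.idxmin()
            if delta.loc[near] <= baseline_tolerance:
                rows.append((coded_id, pv.loc[near, "visit_date"],
                             float(pv.loc[near, "das28"])))
        if not rows:
            return state.iloc[0:0]
        idx, dates, scores = zip(*rows)
        out = state.loc[list(idx)].copy()
        out["baseline_visit_date"] = list(dates)
        out["das28_baseline"] = list(scores)
        return out

    def followup_in_window(store, state):
        if not len(state):
            return state
        lo_d, hi_d = window_days
        v = store.visits[store.visits["das28"].notna()]
        rows = []
        for coded_id, r in state.iterrows():
            base = r["baseline_visit_date"]
            lo = base + pd.Timedelta(days=lo_d)
            hi = base + pd.Timedelta(days=hi_d)
            pv = v[(v["coded_id"].astype(str) == coded_id)
                   & (v["visit_date"] >= lo) & (v["visit_date"] <= hi)]
            if not len(pv):
                continue
            pv = pv.sort_values("visit_date", kind="mergesort")
            if followup == "earliest":
                chosen = pv.iloc[[0]]
            elif followup == "nearest_midpoint":
                mid = base + pd.Timedelta(days=(lo_d + hi_d) // 2)
                chosen = pv.loc[[(pv["visit_date"] - mid).abs().idxmin()]]
            else:
                chosen = pv
            for _, cr in chosen.iterrows():
                rows.append((coded_id, cr["visit_date"], float(cr["das28"])))
        if not rows:
            return state.iloc[0:0]
        fu = pd.DataFrame(rows, columns=["coded_id", "followup_date", "das28_followup"]
                          ).set_index("coded_id")
        out = state.loc[state.index.intersection(set(fu.index))].copy()
        out["followup_date"] = fu.groupby(level=0)["followup_date"].first().reindex(out.index)
        out["das28_followup"] = fu.groupby(level=0)["das28_followup"].first().reindex(out.index)
        if followup == "all":
            out.attrs["all_followups"] = fu
        return out

    def compute_delta(store, state):
        if not len(state):
            return state
        out = state.copy()
        out["delta_das28"] = out["das28_followup"] - out["das28_baseline"]
        if "all_followups" in state.attrs:
            fu = state.attrs["all_followups"]
            out.attrs["all_followups"] = fu
        return out

    def _passes(delta: pd.Series) -> pd.Series:
        return {"le": delta <= delta_threshold, "lt": delta < delta_threshold,
                "ge": delta >= delta_threshold, "gt": delta > delta_threshold}[delta_op]

    def delta_filter(store, state):
        if not len(state):
            return state
        if "all_followups" in state.attrs:
            fu = state.attrs["all_followups"].copy()
            fu = fu.join(state["das28_baseline"], how="inner")
            fu["delta"] = fu["das28_followup"] - fu["das28_baseline"]
            keep = set(fu.index[_passes(fu["delta"])])
            return state.loc[state.index.intersection(keep)]
        return state.loc[_passes(state["delta_das28"])]

    return [
        WaterfallStep("ccp_positive", ccp_positive),
        WaterfallStep("anti_tnf_start", anti_tnf_start),
        WaterfallStep("baseline_das28", baseline_das28),
        WaterfallStep("followup_in_window", followup_in_window),
        WaterfallStep("delta_das28", compute_delta),
        WaterfallStep("delta_filter", delta_filter),
    ]


# ---------------------------------------------------------------------------
# metabolic presets

#: (label, [(field, op, value), ...]) rows; single criteria and conjunctions
METABOLIC_PRESETS: dict[str, list[tuple[str, list[tuple[str, str, float]]]]] = {
    "high_risk": [
        ("BMI>29", [("bmi", "gt", 29.0)]),
        ("BMI>29 & LDL>4.3", [("bmi", "gt", 29.0), ("ldl", "gt", 4.3)]),
        ("BMI>29 & LDL>4.3 & TG>2.6",
         [("bmi", "gt", 29.0), ("ldl", "gt", 4.3), ("tg", "gt", 2.6)]),
        ("LDL>4.3", [("ldl", "gt", 4.3)]),
        ("LDL>4.3 & TG>2.6", [("ldl", "gt", 4.3), ("tg", "gt", 2.6)]),
        ("TG>2.6", [("tg", "gt", 2.6)]),
    ],
    "low_risk": [
        ("BMI<25", [("bmi", "lt", 25.0)]),
        ("BMI<25 & TG<2", [("bmi", "lt", 25.0), ("tg", "lt", 2.0)]),
        ("BMI<25 & LDL<4", [("bmi", "lt", 25.0), ("ldl", "lt", 4.0)]),
        ("BMI<25 & TG<2 & LDL<4",
         [("bmi", "lt", 25.0), ("tg", "lt", 2.0), ("ldl", "lt", 4.0)]),
        ("TG<2", [("tg", "lt", 2.0)]),
        ("TG<2 & LDL<4", [("tg", "lt", 2.0), ("ldl", "lt", 4.0)]),
        ("LDL<4", [("ldl", "lt", 4.0)]),
    ],
}

_OPS = {"gt": lambda s, v: s > v, "ge": lambda s, v: s >= v,
        "lt": lambda s, v: s < v, "le": lambda s, v: s <= v}


def metabolic_stratify(store: FusedStore,
                       preset: str | list = "high_risk",
                       timepoint: str = "onset") -> pd.DataFrame:
    """Patient counts per metabolic condition and conjunction.

    ``preset`` is ``"high_risk"`` (obesity/hyperlipidemia: BMI>29, LDL>4.3,
    TG>2.6), ``"low_risk"`` (BMI<25, TG<2, LDL<4), or a custom list of
    ``(label, [(field, op, value), ...])`` rows. One output row per condition,
    counting distinct patients whose profile at ``timepoint`` satisfies every
    clause of the conjunction.
    """
    if isinstance(preset, str):
        if preset not in METABOLIC_PRESETS:
            raise ValueError(f"unknown metabolic preset {preset!r}")
        rows_def = METABOLIC_PRESETS[preset]
    else:
        rows_def = preset
    prof = store.psoriasis
    prof = prof[prof["timepoint"] == timepoint]
    if not len(store.psoriasis):
        raise ValueError("store has no psoriasis profiles")
    out = []
    for label, clauses in rows_def:
        mask = pd.Series(True, index=prof.index)
        for fld, op, val in clauses:
            mask &= _OPS[op](prof[fld], val)
        out.append({"condition": label,
                    "n_patients": int(prof.loc[mask, "coded_id"].nunique()),
                    "criteria": " & ".join(f for f, _, _ in clauses)})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# ACPA matrix & PASI change

def extract_acpa_matrix(store: FusedStore,
                        cohort: ResultSet | Iterable[str] | None = None,
                        source: str | None = "serum",
                        by_time: bool = False) -> pd.DataFrame:
    """Four-specificity antibody titre matrix, one column per patient.

    Rows are the fixed specificities (CCP serum, Cit-C1 IgG, Cit-Eno IgG,
    Cit-Fib IgG); columns are cohort patients. Without ``by_time`` the latest
    measurement per patient is used; with it, columns become
    ``(coded_id, measurement_date)`` pairs so longitudinal antibody patterns
    can be inspected. Patients lacking serology appear as columns of missing
    values (never zero-filled); an empty cohort yields an empty matrix.
    """
    if cohort is None:
        ids = sorted(store.patients["coded_id"].astype(str))
    elif isinstance(cohort, ResultSet):
        ids = cohort.patient_ids
    else:
        ids = sorted({str(i) for i in cohort})
    sero = store.serology
    if source is not None:
        sero = sero[sero["source"] == source]
    sero = sero[sero["coded_id"].astype(str).isin(ids)]
    sero = sero.sort_values(["coded_id", "measurement_date"], kind="mergesort")

    if by_time:
        cols = {}
        for row in sero.itertuples(index=False):
            key = (str(row.coded_id), pd.Timestamp(row.measurement_date))
            cols[key] = [getattr(row, s) for s in ACPA_SPECIFICITIES]
        mat = pd.DataFrame(cols, index=ACPA_SPECIFICITIES)
        if len(mat.columns):
            mat.columns = pd.MultiIndex.from_tuples(mat.columns,
                                                    names=["coded_id", "date"])
        return mat

    latest = sero.groupby(sero["coded_id"].astype(str)).last()
    data = {}
    for pid in ids:
        if pid in latest.index:
            data[pid] = [latest.at[pid, s] for s in ACPA_SPECIFICITIES]
        else:
            data[pid] = [np.nan] * 4
    return pd.DataFrame(data, index=ACPA_SPECIFICITIES, columns=ids)


def pasi_change(store: FusedStore) -> pd.DataFrame:
    """Per-patient PASI at onset vs the 10-year follow-up, with the change.

    ``delta = pasi_year10 − pasi_onset``; patients missing either timepoint
    are listed with a missing delta rather than dropped.
    """
    prof = store.psoriasis
    onset = prof[prof["timepoint"] == "onset"].groupby("coded_id")["pasi"].first()
    year10 = prof[prof["timepoint"] == "year10"].groupby("coded_id")["pasi"].first()
    ids = sorted(set(onset.index.astype(str)) | set(year10.index.astype(str)))
    out = pd.DataFrame({
        "coded_id": ids,
        "pasi_onset": onset.reindex(ids).to_numpy(dtype=float),
        "pasi_year10": year10.reindex(ids).to_numpy(dtype=float),
    })
    out["delta"] = out["pasi_year10"] - out["pasi_onset"]
    return out
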