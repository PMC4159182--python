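"""Seeded synthetic-cohort generator for RA and psoriasis fused stores.

Emulates the structure of the two study cohorts — 2001 rheumatoid-arthritis
patients with registry visits (DAS28 and components), treatment episodes over
the opaque codes A/B/C, biobank specimens, HLA-DR strings, risk-SNP calls and
ACPA serology; and 747 psoriasis patients with clinical/metabolic profiles
(PASI, BMI, LDL, HDL, triglycerides) at onset and a partial 10-year
follow-up. Genotypes are drawn per SNP under Hardy–Weinberg equilibrium
using the packaged major/minor allele identities. Everything derives from a
single seeded generator, so a fixed seed reproduces the store byte for byte.

Distributions the source registries do not pin down (visit counts, titre
distributions, DAS28 trajectories) are simple parametric defaults — Poisson
visit counts, log-normal titres, an AR(1) DAS28 drift — chosen for
testability rather than epidemiological realism.

:func:`plant_truth` builds fixture stores with a known planted answer plus
decoys, together with a manifest stating the exact expected engine result.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .store import (FusedStore, StoreConfig, _empty_table, load_snp_reference,
                    normalize_hla)


def _frame(rows: list[dict], table: str) -> pd.DataFrame:
    return pd.DataFrame(rows) if rows else _empty_table(table)

_EPOCH = pd.Timestamp("2010-01-04")

# registry allele universe: DR2/DR5/DR6 are reported as their split
# families (*15/*16, *11/*12, *13/*14), so *02/*05/*06 never occur
DEFAULT_HLA_FREQS = {
    "*01": 0.10, "*03": 0.12, "*04": 0.25, "*07": 0.08,
    "*08": 0.05, "*09": 0.03, "*10": 0.02, "*11": 0.07, "*12": 0.03,
    "*13": 0.08, "*14": 0.03, "*15": 0.12, "*16": 0.02,
}
#: A/B/C patient proportions of the treated RA cohort (1276/95/251 of 1622)
DEFAULT_TREATMENT_MIX = {"A": 1276 / 1622, "B": 95 / 1622, "C": 251 / 1622}


class SynthConfig(BaseModel):
    """Cohort sizes, mixes and distribution parameters of the generator."""

    seed: int = 42
    ra_n: int = Field(default=2001, gt=0)
    psoriasis_n: int = Field(default=747, gt=0)
    visits_lambda: float = Field(default=3.0, ge=0)
    samples_lambda: float = Field(default=2.5, ge=0)
    treated_fraction: float = Field(default=0.85, ge=0, le=1)
    treatment_mix: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_TREATMENT_MIX))
    hla_allele_freqs: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_HLA_FREQS))
    default_maf: float = Field(default=0.3, ge=0, le=1)
    maf_overrides: dict[str, float] = Field(default_factory=dict)
    ccp_positive_fraction: float = Field(default=0.6, ge=0, le=1)
    ccp_cutoff: float = 25.0
    serology_fraction: float = Field(default=0.9, ge=0, le=1)
    followup_fraction: float = Field(default=225 / 747, ge=0, le=1)
    # metabolic profile distributions (units: kg/m^2 and mmol/L)
    bmi_mean: float = 25.5
    bmi_sd: float = 4.2
    ldl_mean: float = 3.4
    ldl_sd: float = 0.9
    hdl_mean: float = 1.4
    hdl_sd: float = 0.35
    tg_log_mean: float = 0.25
    tg_log_sd: float = 0.45
    # DAS28 AR(1) drift
    das28_baseline_mean: float = 5.0
    das28_baseline_sd: float = 1.2
    das28_target: float = 3.2
    das28_phi: float = 0.8
    das28_noise: float = 0.5
    crp_sentinel_fraction: float = Field(default=0.15, ge=0, le=1)

    @model_validator(mode="after")
    def _check(self):
        if abs(sum(self.treatment_mix.values()) - 1.0) > 1e-6:
            raise ValueError("treatment_mix must sum to 1")
        if abs(sum(self.hla_allele_freqs.values()) - 1.0) > 1e-6:
            raise ValueError("hla_allele_freqs must sum to 1")
        for rs, maf in self.maf_overrides.items():
            if not 0 <= maf <= 1:
                raise ValueError(f"maf override for {rs} outside [0,1]")
        return self


def _ra_ids(n: int) -> list[str]:
    return [f"P{i:06d}" for i in range(1, n + 1)]


def _pso_ids(n: int, offset: int) -> list[str]:
    return [f"P{i:06d}" for i in range(offset + 1, offset + n + 1)]


def _positions(rng: np.random.Generator, n: int) -> list[str]:
    boxes = rng.integers(1, 21, n)
    rows = rng.integers(0, 8, n)
    cells = rng.integers(1, 13, n)
    return [f"{b:02d}:{chr(65 + r)}{c:02d}" for b, r, c in zip(boxes, rows, cells)]


def generate(cfg: SynthConfig | None = None) -> FusedStore:
    """Build a full synthetic fused store from the configuration.

    The output passes store validation and the leakage scan; the genotype
    table carries one column per packaged reference SNP, sampled under
    Hardy–Weinberg from its minor-allele frequency (the one reference entry
    without allele assignments stays unmeasured/missing).
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    snp_ref = load_snp_reference()

    ra_ids = _ra_ids(cfg.ra_n)
    pso_ids = _pso_ids(cfg.psoriasis_n, cfg.ra_n)

    patients = pd.DataFrame({
        "coded_id": ra_ids + pso_ids,
        "cohort": ["RA"] * cfg.ra_n + ["PSORIASIS"] * cfg.psoriasis_n,
        "ra_number": [f"RA {i}" for i in range(1, cfg.ra_n + 1)]
        + [np.nan] * cfg.psoriasis_n,
    })

    # --- registry visits with AR(1) DAS28 trajectories -------------------
    v_rows = []
    first_visit = {}
    visit_dates: dict[str, list[pd.Timestamp]] = {}
    for pid in ra_ids:
        n_vis = 1 + rng.poisson(cfg.visits_lambda)
        start = _EPOCH + pd.Timedelta(days=int(rng.integers(0, 1461)))
        gaps = rng.integers(30, 120, n_vis - 1) if n_vis > 1 else []
        dates = [start]
        for g in gaps:
            dates.append(dates[-1] + pd.Timedelta(days=int(g)))
        first_visit[pid] = start
        visit_dates[pid] = dates
        das = float(np.clip(rng.normal(cfg.das28_baseline_mean, cfg.das28_baseline_sd),
                            0.5, 9.4))
        for d in dates:
            swollen = int(rng.poisson(max(das - 1, 0.2)))
            tender = int(rng.poisson(max(das, 0.2)))
            esr = float(np.round(np.clip(rng.normal(das * 8, 8), 1, 120), 0))
            if rng.random() < cfg.crp_sentinel_fraction:
                crp = 9.99
            else:
                crp = float(np.round(np.clip(rng.lognormal(1.8, 0.8), 0.1, 200), 2))
            v_rows.append({
                "coded_id": pid, "visit_date": d,
                "pain_scale": int(rng.integers(0, 101)),
                "patient_global": int(rng.integers(0, 101)),
                "haq": float(np.round(rng.uniform(0, 3), 2)),
                "swollen_joints": swollen, "tender_joints": tender,
                "esr": esr, "crp": crp,
                "das28": float(np.round(das, 2)),
                "das28_crp": float(np.round(max(das - 0.3, 0.0), 2)),
                "doctor_assessment": int(np.clip(das // 2, 0, 4)),
            })
            das = float(np.clip(cfg.das28_target
                                + cfg.das28_phi * (das - cfg.das28_target)
                                + rng.normal(0, cfg.das28_noise), 0.5, 9.4))
    visits = _frame(v_rows, "visits")

    # --- treatment episodes ----------------------------------------------
    codes = list(cfg.treatment_mix)
    weights = np.array([cfg.treatment_mix[c] for c in codes], dtype=float)
    weights = weights / weights.sum()
    t_rows = []
    for pid in ra_ids:
        if rng.random() >= cfg.treated_fraction:
            continue
        n_epi = 1 + int(rng.random() < 0.25)
        dates = visit_dates[pid]
        for k in range(n_epi):
            code = str(rng.choice(codes, p=weights))
            anchor = dates[min(k * 2, len(dates) - 1)]
            t_rows.append({
                "coded_id": pid, "start_date": anchor, "treatment": code,
                "treatment_dose": f"{int(rng.choice([25, 50, 500]))} mg 1/v",
                "dmard1": "Methotrexate" if rng.random() < 0.6 else np.nan,
                "dmard1_dose": "15 mg 0/" if rng.random() < 0.6 else np.nan,
                "cortisone": "Prednisolone" if rng.random() < 0.4 else np.nan,
                "cortisone_dose": "7.5 mg 1/d" if rng.random() < 0.4 else np.nan,
                "nsaid": "NSAID-COX1" if rng.random() < 0.3 else np.nan,
                "biological_flag": "6" if rng.random() < 0.2 else np.nan,
            })
    treatments = _frame(t_rows, "treatments")

    # --- biobank samples ---------------------------------------------------
    s_rows = []
    stypes = ["serum", "PBMC", "SFMC", "DNA", "EDTA-plasma"]
    sweights = [0.5, 0.25, 0.1, 0.08, 0.07]
    for pid in ra_ids:
        n_s = rng.poisson(cfg.samples_lambda)
        dates = visit_dates[pid]
        for _ in range(n_s):
            st = str(rng.choice(stypes, p=sweights))
            d = dates[int(rng.integers(0, len(dates)))] + pd.Timedelta(
                days=int(rng.integers(-5, 6)))
            cellular = st in ("PBMC", "SFMC")
            s_rows.append({
                "coded_id": pid, "sample_type": st, "sample_date": d,
                "n_cells_millions": float(np.round(rng.lognormal(3.0, 0.6), 1))
                if cellular else np.nan,
                "position": None,
                "volume": float(np.round(rng.uniform(100, 1000), 0))
                if st in ("serum", "EDTA-plasma") else np.nan,
                "freezer_status": str(rng.choice(
                    ["available", "reserved", "depleted"], p=[0.9, 0.05, 0.05])),
            })
    samples = _frame(s_rows, "samples")
    if len(samples):
        samples["position"] = _positions(rng, len(samples))

    # --- genotypes under Hardy-Weinberg ------------------------------------
    geno = {"coded_id": ra_ids}
    alleles = list(cfg.hla_allele_freqs)
    aw = np.array([cfg.hla_allele_freqs[a] for a in alleles])
    aw = aw / aw.sum()
    a1 = rng.choice(alleles, size=cfg.ra_n, p=aw)
    a2 = rng.choice(alleles, size=cfg.ra_n, p=aw)
    geno["hla_dr"] = [normalize_hla(f"{x}/{y}") for x, y in zip(a1, a2)]
    for row in snp_ref.itertuples(index=False):
        if pd.isna(row.major_allele) or pd.isna(row.minor_allele):
            geno[row.rs_number] = [np.nan] * cfg.ra_n
            continue
        maf = cfg.maf_overrides.get(row.rs_number, cfg.default_maf)
        draws = rng.random((cfg.ra_n, 2)) < maf
        calls = []
        for d in draws:
            pair = sorted(row.minor_allele if x else row.major_allele for x in d)
            calls.append("".join(pair))
        geno[row.rs_number] = calls
    genotypes = pd.DataFrame(geno)

    # --- ACPA serology ------------------------------------------------------
    se_rows = []
    for pid in ra_ids:
        if rng.random() >= cfg.serology_fraction:
            continue
        positive = rng.random() < cfg.ccp_positive_fraction
        n_meas = 1 + int(rng.random() < 0.3)
        dates = visit_dates[pid]
        for k in range(n_meas):
            d = dates[min(k, len(dates) - 1)]
            if positive:
                ccp = float(np.round(rng.lognormal(5.5, 0.7), 1))
                cits = np.round(rng.lognormal(4.0, 1.0, 3), 1)
            else:
                ccp = float(np.round(rng.lognormal(1.5, 0.8), 1))
                cits = np.round(rng.lognormal(1.0, 0.8, 3), 1)
            se_rows.append({
                "coded_id": pid, "measurement_date": d,
                "ccp_serum": ccp, "cit_c1_igg": float(cits[0]),
                "cit_eno_igg": float(cits[1]), "cit_fib_igg": float(cits[2]),
                "ccp_iga": float(np.round(rng.lognormal(2.0, 1.0), 1))
                if rng.random() < 0.5 else np.nan,
                "source": "serum" if rng.random() < 0.9 else "synovial_fluid",
            })
    serology = _frame(se_rows, "serology")

    # --- psoriasis metabolic profiles --------------------------------------
    p_rows = []
    courses = ["healed", "guttate", "plaque"]
    for pid in pso_ids:
        course = str(rng.choice(courses, p=[0.2, 0.3, 0.5]))
        followed = rng.random() < cfg.followup_fraction
        for tp in (["onset", "year10"] if followed else ["onset"]):
            bmi = float(np.round(np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd), 15, 55), 1))
            ldl = float(np.round(np.clip(rng.normal(cfg.ldl_mean, cfg.ldl_sd), 0.5, 10), 2))
            hdl = float(np.round(np.clip(rng.normal(cfg.hdl_mean, cfg.hdl_sd), 0.3, 4), 2))
            tg = float(np.round(rng.lognormal(cfg.tg_log_mean, cfg.tg_log_sd), 2))
            pasi = float(np.round(rng.gamma(2.0, 4.0 if tp == "onset" else 2.0), 1))
            p_rows.append({
                "coded_id": pid, "timepoint": tp, "course": course,
                "pasi": pasi, "bmi": bmi, "ldl": ldl, "hdl": hdl, "tg": tg,
                "hdl_ldl_ratio": float(np.round(hdl / ldl, 3)),
            })
    psoriasis = _frame(p_rows, "psoriasis")

    return FusedStore(patients=patients, visits=visits, treatments=treatments,
                      samples=samples, genotypes=genotypes, serology=serology,
                      psoriasis=psoriasis, snp_reference=snp_ref,
                      config=StoreConfig())


# ---------------------------------------------------------------------------
# truth-planting fixtures

#: the worked-example output rows: (cells 10^6, position, CCP serum)
_TABLE2_ROWS = [
    (13.0, "01:F09", 438.9),
    (24.0, "01:E10", 438.9),
    (17.0, "01:H01", 238.9),
    (22.0, "01:G02", 138.9),
    (53.0, "01:B03", 538.9),
    (53.0, "01:G04", 738.9),
    (31.0, "01:H05", 738.9),
]


def plant_truth(cfg: SynthConfig | None = None,
                scenario: str = "table2_like") -> tuple[FusedStore, dict]:
    """Build a fixture store with a planted, exactly-known expected answer.

    Scenarios
    ---------
    ``table2_like``
        Seven planted *04-carrier / rs2064476=AG samples (one per planted
        patient, carrying the worked-example cell counts, freezer positions
        and CCP titres) among at least 50 decoy patients forced to fail the
        carrier or genotype criterion. Manifest: the expected sample rows for
        the C1 ∧ C3 query at sample granularity.
    ``window_demo``
        One patient whose DAS episode has serum samples planted at day
        offsets −31/−30/0/+40/+41 around the DAS start date and
        −76/−75/0/+152/+153 around the DAS end date. Manifest: the inclusive
        window subsets under the default 30/40 and 75/152 bounds.
    ``waterfall_demo``
        Five planted full-pathway responders plus five decoys each failing
        exactly one stage of the RA anti-TNF waterfall. Manifest: expected
        per-stage survivor counts and the final patient set for
        ΔDAS28 threshold −1.2. With ``ccp_positive_fraction = 0`` every
        planted titre is negative and the expected final set is empty.
    """
    cfg = cfg or SynthConfig(ra_n=80, psoriasis_n=20)
    if scenario == "table2_like":
        return _plant_table2(cfg)
    if scenario == "window_demo":
        return _plant_window(cfg)
    if scenario == "waterfall_demo":
        return _plant_waterfall(cfg)
    raise ValueError(f"unknown scenario {scenario!r}")


def _plant_table2(cfg: SynthConfig) -> tuple[FusedStore, dict]:
    from .query import HLA_DR04_SET, And, Criterion

    if cfg.ra_n < 57:
        cfg = cfg.model_copy(update={"ra_n": 57})
    store = generate(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    planted = _ra_ids(cfg.ra_n)[:7]
    decoys = _ra_ids(cfg.ra_n)[7:]

    g = store.genotypes.set_index("coded_id")
    g.loc[planted, "hla_dr"] = "*04/*15"
    g.loc[planted, "rs2064476"] = "AG"
    for pid in decoys:
        mode = rng.integers(0, 3)
        if mode in (0, 2):
            g.at[pid, "hla_dr"] = "*03/*08"
        if mode in (1, 2):
            g.at[pid, "rs2064476"] = "AA"
    store.genotypes = g.reset_index()

    date = _EPOCH + pd.Timedelta(days=700)
    keep = ~store.samples["coded_id"].isin(planted)
    planted_samples = pd.DataFrame([{
        "coded_id": pid, "sample_type": "SFMC", "sample_date": date,
        "n_cells_millions": cells, "position": pos, "volume": np.nan,
        "freezer_status": "available",
    } for pid, (cells, pos, _) in zip(planted, _TABLE2_ROWS)])
    store.samples = pd.concat([store.samples[keep], planted_samples],
                              ignore_index=True)

    keep_s = ~store.serology["coded_id"].isin(planted)
    planted_sero = pd.DataFrame([{
        "coded_id": pid, "measurement_date": date, "ccp_serum": ccp,
        "cit_c1_igg": 100.0, "cit_eno_igg": 50.0, "cit_fib_igg": 75.0,
        "ccp_iga": np.nan, "source": "serum",
    } for pid, (_, _, ccp) in zip(planted, _TABLE2_ROWS)])
    store.serology = pd.concat([store.serology[keep_s], planted_sero],
                               ignore_index=True)

    expr = And(
        Criterion("genotypes", "hla_dr", "in_set", sorted(HLA_DR04_SET)),
        Criterion("genotypes", "rs2064476", "in_set", ["AG", "GG"]),
    )
    manifest = {
        "scenario": "table2_like",
        "granularity": "sample",
        "expression": expr.to_dict(),
        "expected_n": 7,
        "expected_coded_ids": planted,
        "expected_positions": [pos for _, pos, _ in _TABLE2_ROWS],
        "n_decoys": len(decoys),
    }
    return store, manifest


def _plant_window(cfg: SynthConfig) -> tuple[FusedStore, dict]:
    store = generate(cfg)
    pid = _ra_ids(cfg.ra_n)[0]
    d_start = _EPOCH + pd.Timedelta(days=730)
    d_end = d_start + pd.Timedelta(days=200)

    store.treatments = pd.concat([
        store.treatments[store.treatments["coded_id"] != pid],
        pd.DataFrame([{"coded_id": pid, "start_date": d_start, "treatment": "A",
                       "treatment_dose": "50 mg 1/v", "dmard1": np.nan,
                       "dmard1_dose": np.nan, "cortisone": np.nan,
                       "cortisone_dose": np.nan, "nsaid": np.nan,
                       "biological_flag": np.nan}]),
    ], ignore_index=True)

    keep_v = store.visits["coded_id"] != pid
    planted_visits = pd.DataFrame([
        {"coded_id": pid, "visit_date": d_start, "das28": 5.1},
        {"coded_id": pid, "visit_date": d_end, "das28": 3.8},
    ])
    store.visits = pd.concat([store.visits[keep_v], planted_visits],
                             ignore_index=True)

    start_offsets = [-31, -30, 0, 40, 41]
    end_offsets = [-76, -75, 0, 152, 153]
    rows = []
    for off in start_offsets:
        rows.append({"coded_id": pid, "sample_type": "serum",
                     "sample_date": d_start + pd.Timedelta(days=off),
                     "n_cells_millions": np.nan, "position": f"09:A{abs(off) % 12 + 1:02d}",
                     "volume": 500.0, "freezer_status": "available"})
    for off in end_offsets:
        rows.append({"coded_id": pid, "sample_type": "serum",
                     "sample_date": d_end + pd.Timedelta(days=off),
                     "n_cells_millions": np.nan, "position": f"10:B{abs(off) % 12 + 1:02d}",
                     "volume": 500.0, "freezer_status": "available"})
    keep_s = store.samples["coded_id"] != pid
    store.samples = pd.concat([store.samples[keep_s], pd.DataFrame(rows)],
                              ignore_index=True)

    manifest = {
        "scenario": "window_demo",
        "coded_id": pid, "treatment": "A",
        "das_start_date": str(d_start.date()), "das_end_date": str(d_end.date()),
        "planted_start_offsets": start_offsets,
        "planted_end_offsets": end_offsets,
        "expected_start_offsets": [-30, 0, 40],
        "expected_end_offsets": [-75, 0, 152],
    }
    return store, manifest


def _plant_waterfall(cfg: SynthConfig) -> tuple[FusedStore, dict]:
    """Constructed 10-patient RA store: 5 responders + 5 single-failure decoys."""
    delta_threshold = -1.2
    all_ccp_negative = cfg.ccp_positive_fraction == 0
    pos_titre = 5.0 if all_ccp_negative else 300.0

    ids = [f"P{i:06d}" for i in range(1, 11)]
    responders, fail = ids[:5], ids[5:]
    base = _EPOCH + pd.Timedelta(days=365)

    patients = pd.DataFrame({"coded_id": ids, "cohort": "RA",
                             "ra_number": [f"RA {i}" for i in range(1, 11)]})
    t_rows, v_rows, se_rows = [], [], []

    def add_patient(pid, ccp, treatment, visits, offset_days):
        start = base + pd.Timedelta(days=offset_days)
        if treatment is not None:
            t_rows.append({"coded_id": pid, "start_date": start,
                           "treatment": treatment, "treatment_dose": "50 mg 1/v",
                           "dmard1": np.nan, "dmard1_dose": np.nan,
                           "cortisone": np.nan, "cortisone_dose": np.nan,
                           "nsaid": np.nan, "biological_flag": np.nan})
        for day, das in visits:
            v_rows.append({"coded_id": pid, "visit_date": start + pd.Timedelta(days=day),
                           "das28": das})
        se_rows.append({"coded_id": pid, "measurement_date": base,
                        "ccp_serum": ccp, "cit_c1_igg": 10.0, "cit_eno_igg": 10.0,
                        "cit_fib_igg": 10.0, "ccp_iga": np.nan, "source": "serum"})

    for i, pid in enumerate(responders):
        add_patient(pid, pos_titre, "A", [(0, 5.5), (75, 3.0)], offset_days=i * 7)
    # decoys, one failure mode each:
    add_patient(fail[0], 5.0, "A", [(0, 5.5), (75, 3.0)], 0)       # CCP negative
    add_patient(fail[1], pos_titre, "C", [(0, 5.5), (75, 3.0)], 0)  # no anti-TNF
    add_patient(fail[2], pos_titre, "A", [], 0)                     # no DAS visits
    add_patient(fail[3], pos_titre, "A", [(0, 5.5), (120, 3.0)], 0)  # outside window
    add_patient(fail[4], pos_titre, "A", [(0, 5.5), (75, 5.0)], 0)  # delta too small

    store = FusedStore(
        patients=patients,
        visits=pd.DataFrame(v_rows),
        treatments=pd.DataFrame(t_rows),
        samples=pd.DataFrame(columns=["coded_id", "sample_type", "sample_date",
                                      "n_cells_millions", "position", "volume",
                                      "freezer_status"]),
        genotypes=pd.DataFrame({"coded_id": ids, "hla_dr": "*04/*15"}),
        serology=pd.DataFrame(se_rows),
        psoriasis=pd.DataFrame(columns=["coded_id", "timepoint", "course", "pasi",
                                        "bmi", "ldl", "hdl", "tg", "hdl_ldl_ratio"]),
    )
    if all_ccp_negative:
        stage_counts = [0, 0, 0, 0, 0, 0]
        final = []
    else:
        stage_counts = [9, 8, 7, 6, 6, 5]
        final = responders
    manifest = {
        "scenario": "waterfall_demo",
        "delta_threshold": delta_threshold,
        "anti_tnf_codes": ["A"],
        "expected_stage_counts": stage_counts,
        "expected_final_ids": final,
    }
    return store, manifest
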