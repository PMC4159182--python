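"""Fused multi-source cohort store keyed on coded patient identifiers.

The store fuses seven delimited-text sources around one join attribute, the
coded (pseudonymized) patient identifier: a patients roster, clinical-registry
visits with disease-activity measures (DAS28 and its components), treatment
episodes, biobank specimens with freezer coordinates and cell counts,
genotype profiles (HLA-DR string plus SNP calls), ACPA serology panels, and
psoriasis clinical/metabolic profiles. Tables are plain :class:`pandas.DataFrame`
objects with documented column contracts; the store adds referential-integrity
validation and dialect-aware round-trip I/O (Swedish registry exports mix
decimal-comma and decimal-point conventions).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator

import pandas as pd

from .errors import ReferenceError_, StoreError, StoreIntegrityError

logger = logging.getLogger(__name__)

#: file name per source table, in canonical order
TABLE_FILES = {
    "patients": "patients.csv",
    "visits": "visits.csv",
    "treatments": "treatments.csv",
    "samples": "samples.csv",
    "genotypes": "genotypes.csv",
    "serology": "serology.csv",
    "psoriasis": "psoriasis.csv",
}

DATE_COLUMNS = {
    "visits": ["visit_date"],
    "treatments": ["start_date"],
    "samples": ["sample_date"],
    "serology": ["measurement_date"],
}

NUMERIC_COLUMNS = {
    "visits": [
        "pain_scale", "patient_global", "haq", "swollen_joints",
        "tender_joints", "esr", "crp", "das28", "das28_crp",
        "doctor_assessment",
    ],
    "samples": ["n_cells_millions", "volume"],
    "serology": ["ccp_serum", "cit_c1_igg", "cit_eno_igg", "cit_fib_igg", "ccp_iga"],
    "psoriasis": ["pasi", "bmi", "ldl", "hdl", "tg", "hdl_ldl_ratio"],
}

SAMPLE_TYPES = {"PBMC", "SFMC", "serum", "EDTA-plasma", "synovial", "DNA", "RNA"}
FREEZER_STATUSES = {"available", "depleted", "reserved"}

_HLA_RE = re.compile(r"^\*\d{2}(/\*\d{2})?$")
_POSITION_RE = re.compile(r"^\d+:[A-Za-z]\d+$")
_RS_RE = re.compile(r"^(rs)?(\d+)$", re.IGNORECASE)
_BASES = set("ACGT")


# ---------------------------------------------------------------------------
# normalization helpers

def normalize_hla(value: str) -> str:
    """Canonicalize an HLA-DR string: split on "/", strip, sort alleles.

    ``"*15/*04"`` and ``"*04/*15"`` denote the same unordered genotype; the
    canonical form lists alleles lexicographically. Strings that do not match
    the ``*NN`` / ``*NN/*MM`` pattern are returned stripped but otherwise
    untouched so that validation can flag them.
    """
    if not isinstance(value, str):
        return value
    alleles = [a.strip() for a in value.strip().split("/")]
    if all(re.fullmatch(r"\*\d{2}", a) for a in alleles) and 1 <= len(alleles) <= 2:
        return "/".join(sorted(alleles))
    return value.strip()


def normalize_genotype_call(value: str) -> str:
    """Sort the two nucleobases of an unordered genotype call ("GA" -> "AG")."""
    if not isinstance(value, str):
        return value
    v = value.strip().upper()
    if len(v) == 2 and set(v) <= _BASES:
        return "".join(sorted(v))
    return v


def canonical_rs(value) -> str:
    """Canonicalize an rs number: ensure the ``rs`` prefix, lower-case."""
    m = _RS_RE.fullmatch(str(value).strip())
    if not m:
        raise ValueError(f"not an rs number: {value!r}")
    return "rs" + m.group(2)


def is_hla_dr04_carrier(hla_dr: str) -> bool:
    """True iff either HLA-DR allele is *04 (shared-epitope carrier set).

    The enumerated inclusion set {"*01/*04", "*03/*04", "*04", "*04/*04",
    ..., "*04/*16"} is exactly the set of normalized one- or two-allele
    strings containing *04.
    """
    if not isinstance(hla_dr, str) or not _HLA_RE.fullmatch(hla_dr.strip()):
        raise ValueError(f"malformed HLA-DR string: {hla_dr!r}")
    return "*04" in hla_dr.strip().split("/")


# ---------------------------------------------------------------------------
# dialect & config

@dataclass(frozen=True)
class CsvDialect:
    """Delimited-text conventions for one store directory.

    ``point`` is the default (comma-separated, decimal point); ``comma`` is
    the Swedish registry convention (semicolon-separated, decimal comma).
    """

    delimiter: str = ","
    decimal: str = "."
    encoding: str = "utf-8"

    @classmethod
    def point(cls) -> "CsvDialect":
        return cls()

    @classmethod
    def comma(cls) -> "CsvDialect":
        return cls(delimiter=";", decimal=",")


def detect_dialect(path: Path) -> CsvDialect:
    """Sniff the dialect of a store directory from its patients table."""
    sample = Path(path, TABLE_FILES["patients"]).read_text(encoding="utf-8")[:4096]
    first = sample.splitlines()[0] if sample else ""
    if first.count(";") > first.count(","):
        return CsvDialect.comma()
    return CsvDialect.point()


@dataclass(frozen=True)
class StoreConfig:
    """Tunable conventions: dialect, sentinel values, default day windows."""

    dialect: CsvDialect = field(default_factory=CsvDialect)
    #: registry artifact: this exact CRP value means "below detection"
    crp_sentinel: float | None = 9.99
    ccp_positive_cutoff: float = 25.0


# ---------------------------------------------------------------------------
# reference data

@dataclass(frozen=True)
class SnpReferenceEntry:
    """One row of the packaged risk-SNP reference table."""

    rs_number: str
    locus: str
    major_allele: str | None
    minor_allele: str | None
    risk_allele: str | None


def packaged_data_path(name: str) -> Path:
    return Path(resources.files("cohortfusion").joinpath("data", name))


def load_snp_reference(path: str | Path | None = None) -> pd.DataFrame:
    """Load the risk-SNP reference (rs number, locus, major/minor/risk allele).

    The packaged table lists the 65 SNPs predisposing for RA used to genotype
    the cohort; one entry (rs6682654, CD244) carries no allele assignments and
    loads with nulls. Raises on duplicate rs numbers or non-ACGT alleles.
    """
    p = Path(path) if path is not None else packaged_data_path("snp_reference.tsv")
    df = pd.read_csv(p, sep="\t", dtype=str)
    df["rs_number"] = df["rs_number"].map(canonical_rs)
    dupes = df["rs_number"][df["rs_number"].duplicated()]
    if not dupes.empty:
        raise ReferenceError_(f"duplicate rs numbers in reference: {sorted(set(dupes))}")
    for col in ("major_allele", "minor_allele", "risk_allele"):
        bad = df[col].dropna()[~df[col].dropna().isin(list(_BASES))]
        if not bad.empty:
            raise ReferenceError_(f"non-ACGT alleles in {col}: {sorted(set(bad))}")
    return df


def snp_reference_entries(df: pd.DataFrame) -> Iterator[SnpReferenceEntry]:
    for row in df.itertuples(index=False):
        yield SnpReferenceEntry(
            rs_number=row.rs_number,
            locus=row.locus,
            major_allele=None if pd.isna(row.major_allele) else row.major_allele,
            minor_allele=None if pd.isna(row.minor_allele) else row.minor_allele,
            risk_allele=None if pd.isna(row.risk_allele) else row.risk_allele,
        )


# ---------------------------------------------------------------------------
# the fused store

@dataclass
class FusedStore:
    """All source tables of one pseudonymized cohort, joined by ``coded_id``."""

    patients: pd.DataFrame
    visits: pd.DataFrame
    treatments: pd.DataFrame
    samples: pd.DataFrame
    genotypes: pd.DataFrame
    serology: pd.DataFrame
    psoriasis: pd.DataFrame
    snp_reference: pd.DataFrame = field(default_factory=load_snp_reference)
    config: StoreConfig = field(default_factory=StoreConfig)

    def table(self, name: str) -> pd.DataFrame:
        if name not in TABLE_FILES:
            raise KeyError(name)
        return getattr(self, name)

    @property
    def source_names(self) -> list[str]:
        return list(TABLE_FILES)

    def crp_effective(self) -> pd.Series:
        """Visit CRP with the below-detection sentinel masked to missing.

        The raw column is preserved; repeated identical boundary values
        (default 9.99 mg/L) are a registry export artifact, not measurements.
        """
        crp = self.visits["crp"].astype(float)
        if self.config.crp_sentinel is not None:
            crp = crp.mask(crp == self.config.crp_sentinel)
        return crp

    def with_config(self, config: StoreConfig) -> "FusedStore":
        return replace(self, config=config)


def _empty_table(name: str) -> pd.DataFrame:
    cols = {"patients": ["coded_id", "cohort", "ra_number"],
            "visits": ["coded_id", "visit_date"] + NUMERIC_COLUMNS["visits"],
            "treatments": ["coded_id", "start_date", "treatment", "treatment_dose",
                           "dmard1", "dmard1_dose", "cortisone", "cortisone_dose",
                           "nsaid", "biological_flag"],
            "samples": ["coded_id", "sample_type", "sample_date", "n_cells_millions",
                        "position", "volume", "freezer_status"],
            "genotypes": ["coded_id", "hla_dr"],
            "serology": ["coded_id", "measurement_date", "source"] + NUMERIC_COLUMNS["serology"],
            "psoriasis": ["coded_id", "timepoint", "course"] + NUMERIC_COLUMNS["psoriasis"]}[name]
    df = pd.DataFrame(columns=cols)
    for c in DATE_COLUMNS.get(name, []):
        df[c] = pd.to_datetime(df[c])
    for c in NUMERIC_COLUMNS.get(name, []):
        df[c] = df[c].astype(float)
    return df


def _postprocess(name: str, df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "coded_id" in df.columns:
        df["coded_id"] = df["coded_id"].astype(str)
    for c in DATE_COLUMNS.get(name, []):
        if c in df.columns:
            df[c] = pd.to_datetime(df[c], format="ISO8601")
    for c in NUMERIC_COLUMNS.get(name, []):
        if c in df.columns:
            df[c] = pd.to_numeric(df[c])
    if name == "genotypes":
        if "hla_dr" in df.columns:
            df["hla_dr"] = df["hla_dr"].map(normalize_hla, na_action="ignore")
        for c in df.columns:
            if c.startswith("rs"):
                df[c] = df[c].map(normalize_genotype_call, na_action="ignore")
    return df


def load_store(
    directory: str | Path,
    dialect: CsvDialect | str | None = None,
    config: StoreConfig | None = None,
    validate: bool = True,
) -> FusedStore:
    """Read a store directory (one delimited file per source) into a FusedStore.

    Parameters
    ----------
    directory
        Directory holding ``patients.csv`` (mandatory) and any of the other
        source tables; unknown ``*.csv`` files are ignored with a warning.
    dialect
        A :class:`CsvDialect`, the string ``"auto"`` to sniff the convention,
        or None for the default decimal-point dialect.
    validate
        When true (default) referential integrity is enforced: a child-table
        ``coded_id`` absent from the patients roster raises
        :class:`StoreIntegrityError` listing the offending rows.
    """
    directory = Path(directory)
    if dialect == "auto":
        dialect = detect_dialect(directory)
    dialect = dialect or CsvDialect()
    patients_file = directory / TABLE_FILES["patients"]
    if not patients_file.exists():
        raise StoreError(f"missing mandatory patients table: {patients_file}")

    known = set(TABLE_FILES.values())
    for f in sorted(directory.glob("*.csv")):
        if f.name not in known:
            logger.warning("ignoring unknown file in store directory: %s", f.name)

    tables: dict[str, pd.DataFrame] = {}
    for name, fname in TABLE_FILES.items():
        f = directory / fname
        if f.exists():
            # opaque codes must never be inferred as numbers
            raw = pd.read_csv(f, sep=dialect.delimiter, decimal=dialect.decimal,
                              encoding=dialect.encoding,
                              dtype={"coded_id": str, "biological_flag": str,
                                     "treatment": str})
            tables[name] = _postprocess(name, raw)
        else:
            tables[name] = _empty_table(name)

    store = FusedStore(config=config or StoreConfig(dialect=dialect), **tables)
    if validate:
        orphans = [v for v in iter_violations(store) if v.kind == "orphan"]
        if orphans:
            raise StoreIntegrityError(
                f"{len(orphans)} child rows reference unknown patients "
                f"(first: {orphans[0]})", orphans)
    return store


def write_store(store: FusedStore, directory: str | Path,
                dialect: CsvDialect | None = None) -> Path:
    """Write every source table of the store to ``directory`` (round-trippable)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dialect = dialect or store.config.dialect
    for name, fname in TABLE_FILES.items():
        df = store.table(name).copy()
        for c in DATE_COLUMNS.get(name, []):
            if c in df.columns:
                df[c] = df[c].dt.strftime("%Y-%m-%d")
        df.to_csv(directory / fname, sep=dialect.delimiter, decimal=dialect.decimal,
                  index=False, encoding=dialect.encoding)
    return directory


# ---------------------------------------------------------------------------
# validation

@dataclass(frozen=True)
class Violation:
    table: str
    row: int
    column: str
    kind: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation]

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)

    def __iter__(self):
        return iter(self.violations)


def iter_violations(store: FusedStore) -> Iterator[Violation]:
    patients = store.patients
    ids = set(patients["coded_id"].astype(str))
    dup = patients["coded_id"][patients["coded_id"].duplicated()]
    for idx, v in dup.items():
        yield Violation("patients", idx, "coded_id", "duplicate",
                        f"duplicate coded_id {v!r}")

    for name in TABLE_FILES:
        if name == "patients":
            continue
        df = store.table(name)
        if "coded_id" in df.columns and len(df):
            orphan = ~df["coded_id"].astype(str).isin(ids)
            for idx in df.index[orphan]:
                yield Violation(name, idx, "coded_id", "orphan",
                                f"coded_id {df.at[idx, 'coded_id']!r} not in patients")

    def _nonneg(name, cols):
        df = store.table(name)
        for c in cols:
            if c in df.columns:
                bad = df[c].dropna() < 0
                for idx in bad.index[bad]:
                    yield Violation(name, idx, c, "negative",
                                    f"{c} = {df.at[idx, c]} < 0")

    yield from _nonneg("visits", ["swollen_joints", "tender_joints", "haq",
                                  "das28", "das28_crp", "esr"])
    yield from _nonneg("samples", ["n_cells_millions", "volume"])
    yield from _nonneg("serology", NUMERIC_COLUMNS["serology"])
    yield from _nonneg("psoriasis", ["pasi"])

    g = store.genotypes
    if "hla_dr" in g.columns:
        for idx, v in g["hla_dr"].dropna().items():
            if not _HLA_RE.fullmatch(str(v)):
                yield Violation("genotypes", idx, "hla_dr", "format",
                                f"malformed HLA-DR string {v!r}")
    for c in g.columns:
        if c.startswith("rs"):
            for idx, v in g[c].dropna().items():
                sv = str(v)
                if not (len(sv) == 2 and set(sv) <= _BASES):
                    yield Violation("genotypes", idx, c, "format",
                                    f"malformed genotype call {v!r}")

    s = store.samples
    if "position" in s.columns:
        for idx, v in s["position"].dropna().items():
            if not _POSITION_RE.fullmatch(str(v)):
                yield Violation("samples", idx, "position", "format",
                                f"position {v!r} does not match box:cell pattern")
    if "freezer_status" in s.columns:
        for idx, v in s["freezer_status"].dropna().items():
            if str(v) not in FREEZER_STATUSES:
                yield Violation("samples", idx, "freezer_status", "format",
                                f"unknown freezer status {v!r}")


def validate_store(store: FusedStore) -> ValidationReport:
    """Full integrity report: orphan IDs, negative quantities, malformed codes.

    An empty report is equivalent to the store being valid; nothing raises.
    """
    return ValidationReport(list(iter_violations(store)))
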