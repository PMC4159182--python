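"""Cross-source Boolean cohort queries over a :class:`~cohortfusion.store.FusedStore`.

A query is a tree of AND/OR/NOT nodes over :class:`Criterion` leaves, each
leaf naming a source table, a field and a comparison. Evaluation returns
either patients or samples:

* patient granularity uses exists-semantics per source — a patient matches a
  sample-level criterion if at least one of their samples matches;
* sample granularity requires the sample itself to match sample-level
  criteria while its patient must match the patient-level ones.

By default a comparison on a missing value is false (and NOT over missing is
therefore true), matching how sparse registry extracts are usually queried; a
strict three-valued (Kleene) mode is available, in which missing comparisons
propagate as unknown and unknown rows are excluded from the result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Iterable

import pandas as pd
import numpy as np
from lxml import etree

from .errors import QueryEvaluationError, QuerySchemaError
from .store import (DATE_COLUMNS, NUMERIC_COLUMNS, TABLE_FILES, FusedStore,
                    packaged_data_path)

_OPS = {"eq", "ne", "gt", "ge", "lt", "le", "in_set", "between"}

#: the enumerated *04-carrier HLA-DR inclusion set used in the worked example
HLA_DR04_SET = frozenset(
    {"*01/*04", "*03/*04", "*04", "*04/*04", "*04/*07", "*04/*08", "*04/*09",
     "*04/*10", "*04/*11", "*04/*12", "*04/*13", "*04/*14", "*04/*15", "*04/*16"})


# ---------------------------------------------------------------------------
# expression tree

class Expression:
    def to_dict(self) -> dict:
        raise NotImplementedError

    def leaves(self) -> Iterable["Criterion"]:
        raise NotImplementedError

    def __and__(self, other):
        return And(self, other)

    def __or__(self, other):
        return Or(self, other)

    def __invert__(self):
        return Not(self)


@dataclass(frozen=True)
class Criterion(Expression):
    """One declarative filter: ``source.field <op> value``."""

    source: str
    field: str
    op: str
    value: Any = None

    def __post_init__(self):
        if self.op not in _OPS:
            raise ValueError(f"unknown operator {self.op!r}")
        if self.op == "in_set":
            vals = self.value
            if not isinstance(vals, (list, tuple, set, frozenset)) or not len(vals):
                raise ValueError("in_set requires a non-empty collection")
            object.__setattr__(self, "value", tuple(vals))
        if self.op == "between":
            if not isinstance(self.value, (list, tuple)) or len(self.value) != 2:
                raise ValueError("between requires exactly two bounds")
            object.__setattr__(self, "value", tuple(self.value))

    def to_dict(self) -> dict:
        v = list(self.value) if isinstance(self.value, tuple) else self.value
        return {"source": self.source, "field": self.field,
                "op": self.op, "value": v}

    def leaves(self):
        yield self


@dataclass(frozen=True)
class And(Expression):
    children: tuple = ()

    def __init__(self, *children):
        object.__setattr__(self, "children", tuple(children))

    def to_dict(self):
        return {"and": [c.to_dict() for c in self.children]}

    def leaves(self):
        for c in self.children:
            yield from c.leaves()


@dataclass(frozen=True)
class Or(Expression):
    children: tuple = ()

    def __init__(self, *children):
        object.__setattr__(self, "children", tuple(children))

    def to_dict(self):
        return {"or": [c.to_dict() for c in self.children]}

    def leaves(self):
        for c in self.children:
            yield from c.leaves()


@dataclass(frozen=True)
class Not(Expression):
    child: Expression = None

    def to_dict(self):
        return {"not": self.child.to_dict()}

    def leaves(self):
        yield from self.child.leaves()


def expression_from_dict(d: dict) -> Expression:
    """Parse the YAML/JSON query-file encoding of an expression tree."""
    if "and" in d:
        return And(*(expression_from_dict(c) for c in d["and"]))
    if "or" in d:
        return Or(*(expression_from_dict(c) for c in d["or"]))
    if "not" in d:
        return Not(expression_from_dict(d["not"]))
    return Criterion(source=d["source"], field=d["field"],
                     op=d["op"], value=d.get("value"))


# ---------------------------------------------------------------------------
# evaluation

def _check_schema(store: FusedStore, expr: Expression) -> None:
    for leaf in expr.leaves():
        if leaf.source not in TABLE_FILES:
            raise QuerySchemaError(f"unknown source table {leaf.source!r} in leaf {leaf}")
        if leaf.field not in store.table(leaf.source).columns:
            raise QuerySchemaError(
                f"unknown field {leaf.field!r} of source {leaf.source!r} in leaf {leaf}")


def _coerce(series: pd.Series, value):
    if pd.api.types.is_datetime64_any_dtype(series):
        if isinstance(value, (list, tuple)):
            return type(value)(pd.Timestamp(v) for v in value)
        return pd.Timestamp(value)
    return value


def _row_mask(df: pd.DataFrame, crit: Criterion) -> pd.Series:
    s = df[crit.field]
    v = _coerce(s, crit.value)
    try:
        if crit.op == "eq":
            return s == v
        if crit.op == "ne":
            return s.notna() & (s != v)
        if crit.op == "gt":
            return s > v
        if crit.op == "ge":
            return s >= v
        if crit.op == "lt":
            return s < v
        if crit.op == "le":
            return s <= v
        if crit.op == "in_set":
            return s.isin(list(v))
        if crit.op == "between":
            return (s >= v[0]) & (s <= v[1])
    except TypeError as exc:
        raise QueryEvaluationError(f"cannot apply {crit.op!r} to "
                                   f"{crit.source}.{crit.field}: {exc}") from exc
    raise AssertionError(crit.op)


# truth encoding for Kleene logic: 0=False, 1=Unknown, 2=True
_K_NOT = {0: 2, 1: 1, 2: 0}


def _leaf_truth(store, crit, units, granularity, strict):
    """Kleene truth value (0/1/2) of one leaf per result unit."""
    if granularity == "sample" and crit.source == "samples":
        mask = _row_mask(units, crit)
        t = mask.fillna(False).astype(int) * 2
        if strict:
            t = t.where(~units[crit.field].isna(), 1)
        return t

    df = store.table(crit.source)
    mask = _row_mask(df, crit)
    matched = set(df.loc[mask.fillna(False).astype(bool), "coded_id"].astype(str))
    truth = units["coded_id"].isin(matched).astype(int) * 2
    if strict:
        has_missing = df[crit.field].isna()
        unknown_ids = set(df.loc[has_missing, "coded_id"].astype(str))
        # patients with no row at all in the source are unknown too
        present_ids = set(df["coded_id"].astype(str))
        t = truth.copy()
        unk = units["coded_id"].isin(unknown_ids) | ~units["coded_id"].isin(present_ids)
        t = t.where(~(unk & (truth == 0)), 1)
        return t
    return truth


def _eval_tree(store, expr, units, granularity, strict):
    if isinstance(expr, Criterion):
        return _leaf_truth(store, expr, units, granularity, strict)
    if isinstance(expr, And):
        vals = [_eval_tree(store, c, units, granularity, strict) for c in expr.children]
        out = vals[0]
        for v in vals[1:]:
            out = np.minimum(out, v)
        return out
    if isinstance(expr, Or):
        vals = [_eval_tree(store, c, units, granularity, strict) for c in expr.children]
        out = vals[0]
        for v in vals[1:]:
            out = np.maximum(out, v)
        return out
    if isinstance(expr, Not):
        v = _eval_tree(store, expr.child, units, granularity, strict)
        return v.map(_K_NOT)
    raise TypeError(f"not an expression: {expr!r}")


@dataclass
class ResultSet:
    """Joined query result with per-column source provenance."""

    granularity: str
    rows: pd.DataFrame
    provenance: dict[str, str] = dc_field(default_factory=dict)

    @property
    def patient_ids(self) -> list[str]:
        return sorted(set(self.rows["coded_id"].astype(str))) if len(self.rows) else []

    def __len__(self) -> int:
        return len(self.rows)


def evaluate(
    store: FusedStore,
    expr: Expression,
    granularity: str = "patient",
    strict_missing: bool = False,
) -> ResultSet:
    """Evaluate a Boolean expression tree against the fused store.

    Returns one row per matching patient (patient granularity, unique per
    ``coded_id``) or per matching sample. Result rows carry the unit table's
    columns plus any expression-referenced columns from the one-row-per-patient
    sources (patients, genotypes), each annotated with its source table, and
    are sorted by ``coded_id`` then ``sample_date`` for reproducible exports.
    """
    if granularity not in {"patient", "sample"}:
        raise ValueError(f"unknown granularity {granularity!r}")
    _check_schema(store, expr)

    if granularity == "patient":
        units = store.patients[["coded_id"]].copy()
    else:
        units = store.samples.copy()
    units = units.reset_index(drop=True)

    truth = _eval_tree(store, expr, units, granularity, strict_missing)
    keep = truth == 2

    referenced = {}
    for leaf in expr.leaves():
        if leaf.source in ("patients", "genotypes"):
            referenced.setdefault(leaf.source, set()).add(leaf.field)

    if granularity == "patient":
        rows = store.patients[store.patients["coded_id"].isin(
            set(units.loc[keep, "coded_id"]))].copy()
        prov = {c: "patients" for c in rows.columns}
    else:
        rows = units.loc[keep].copy()
        prov = {c: "samples" for c in rows.columns}

    for src, fields in referenced.items():
        extra = [f for f in sorted(fields) if f != "coded_id" and f not in rows.columns]
        if extra:
            right = store.table(src)[["coded_id"] + extra].drop_duplicates("coded_id")
            rows = rows.merge(right, on="coded_id", how="left")
            prov.update({f: src for f in extra})

    sort_cols = ["coded_id"] + (["sample_date"] if "sample_date" in rows.columns else [])
    rows = rows.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    return ResultSet(granularity=granularity, rows=rows, provenance=prov)


# ---------------------------------------------------------------------------
# export

def export_results(rs: ResultSet, format: str, path: str | Path | None = None) -> str:
    """Serialize a result set (csv/tsv/json/xml) with provenance preserved.

    CSV/TSV exports prefix comment lines ``#granularity=`` and one
    ``#column:...=source`` per column; XML validates against the packaged
    query-result schema before being returned.
    """
    df = rs.rows.copy()
    for c in df.columns:
        if pd.api.types.is_datetime64_any_dtype(df[c]):
            df[c] = df[c].dt.strftime("%Y-%m-%d")

    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        header = [f"#granularity={rs.granularity}"]
        header += [f"#column:{c}={rs.provenance.get(c, '?')}" for c in df.columns]
        text = "\n".join(header) + "\n" + df.to_csv(sep=sep, index=False)
    elif format == "json":
        payload = {"granularity": rs.granularity, "provenance": rs.provenance,
                   "rows": json.loads(df.to_json(orient="records"))}
        text = json.dumps(payload, indent=1)
    elif format == "xml":
        ns = "urn:cohortfusion:queryresult:1"
        root = etree.Element(f"{{{ns}}}QueryResult", granularity=rs.granularity)
        for _, row in df.iterrows():
            r = etree.SubElement(root, f"{{{ns}}}Row")
            for col in df.columns:
                val = row[col]
                if pd.isna(val):
                    continue
                cell = etree.SubElement(r, f"{{{ns}}}Cell", column=col,
                                        source=rs.provenance.get(col, "?"))
                cell.text = str(val)
        schema = etree.XMLSchema(etree.parse(str(packaged_data_path("query_result.xsd"))))
        schema.assertValid(etree.ElementTree(root))
        text = etree.tostring(root, pretty_print=True, encoding="unicode")
    else:
        raise ValueError(f"unknown export format {format!r}")

    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def read_results(path: str | Path, format: str = "csv") -> ResultSet:
    """Load a CSV/TSV export back into a ResultSet (round-trip inverse)."""
    sep = "," if format == "csv" else "\t"
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    granularity = "patient"
    provenance = {}
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#granularity="):
            granularity = line.split("=", 1)[1]
        elif line.startswith("#column:"):
            cs, src = line[len("#column:"):].split("=", 1)
            provenance[cs] = src
        else:
            body_start = i
            break
    from io import StringIO
    df = pd.read_csv(StringIO("\n".join(lines[body_start:])), sep=sep,
                     dtype={"coded_id": str})
    for col, src in provenance.items():
        if col in df.columns:
            if col in DATE_COLUMNS.get(src, []):
                df[col] = pd.to_datetime(df[col], format="ISO8601")
            elif col in NUMERIC_COLUMNS.get(src, []):
                df[col] = pd.to_numeric(df[col])
    return ResultSet(granularity=granularity, rows=df, provenance=provenance)
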