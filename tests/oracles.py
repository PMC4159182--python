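"""Independent brute-force oracles the engine implementations are checked against.

These deliberately avoid the package's vectorized evaluation paths: they
interpret criteria row by row over plain Python records, so agreement with
the engines is a genuine cross-check rather than a reimplementation.
"""

from __future__ import annotations

import math

import pandas as pd


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return v is pd.NaT


def row_matches(row: dict, crit) -> bool:
    """Row-level criterion truth; comparisons on missing values are false."""
    v = row.get(crit.field)
    if _is_missing(v):
        return False
    cv = crit.value
    if isinstance(v, pd.Timestamp):
        cv = (tuple(pd.Timestamp(x) for x in cv)
              if isinstance(cv, tuple) else pd.Timestamp(cv))
    if crit.op == "eq":
        return v == cv
    if crit.op == "ne":
        return v != cv
    if crit.op == "gt":
        return v > cv
    if crit.op == "ge":
        return v >= cv
    if crit.op == "lt":
        return v < cv
    if crit.op == "le":
        return v <= cv
    if crit.op == "in_set":
        return v in cv
    if crit.op == "between":
        return cv[0] <= v <= cv[1]
    raise AssertionError(crit.op)


def _rows_by_patient(store) -> dict[str, dict[str, list[dict]]]:
    out: dict[str, dict[str, list[dict]]] = {}
    for name in store.source_names:
        by_pid: dict[str, list[dict]] = {}
        for r in store.table(name).to_dict("records"):
            by_pid.setdefault(str(r.get("coded_id")), []).append(r)
        out[name] = by_pid
    return out


def brute_force_patient_ids(store, expr) -> set[str]:
    """Patient-granularity evaluation by full row scan with exists-semantics."""
    from cohortfusion.query import And, Criterion, Not, Or

    tables = _rows_by_patient(store)

    def leaf_true(pid: str, crit) -> bool:
        return any(row_matches(r, crit) for r in tables[crit.source].get(pid, []))

    def truth(pid: str, node) -> bool:
        if isinstance(node, Criterion):
            return leaf_true(pid, node)
        if isinstance(node, And):
            return all(truth(pid, c) for c in node.children)
        if isinstance(node, Or):
            return any(truth(pid, c) for c in node.children)
        if isinstance(node, Not):
            return not truth(pid, node.child)
        raise TypeError(node)

    return {pid for pid in store.patients["coded_id"].astype(str)
            if truth(pid, expr)}


def brute_force_sample_keys(store, expr) -> list[tuple]:
    """Sample-granularity evaluation; returns sortable per-sample keys."""
    from cohortfusion.query import And, Criterion, Not, Or

    tables = _rows_by_patient(store)

    def truth(sample: dict, node) -> bool:
        if isinstance(node, Criterion):
            if node.source == "samples":
                return row_matches(sample, node)
            pid = str(sample.get("coded_id"))
            return any(row_matches(r, node) for r in tables[node.source].get(pid, []))
        if isinstance(node, And):
            return all(truth(sample, c) for c in node.children)
        if isinstance(node, Or):
            return any(truth(sample, c) for c in node.children)
        if isinstance(node, Not):
            return not truth(sample, node.child)
        raise TypeError(node)

    keys = []
    for rows in tables["samples"].values():
        for r in rows:
            if truth(r, expr):
                keys.append(sample_key(r))
    return sorted(keys)


def sample_key(row: dict) -> tuple:
    return (str(row.get("coded_id")), str(row.get("sample_date")),
            str(row.get("sample_type")), str(row.get("position")))


def result_sample_keys(rs) -> list[tuple]:
    return sorted(sample_key(r) for r in rs.rows.to_dict("records"))


def enumerate_window_offsets(before: int, after: int,
                             lo: int = -200, hi: int = 200) -> set[int]:
    """Day offsets inside an inclusive [-before, +after] window, by enumeration."""
    return {d for d in range(lo, hi + 1) if -before <= d <= after}


def random_expression(rng, store, n_leaves: int):
    """A random 1..4-leaf Boolean tree over a fixed pool of field criteria."""
    from cohortfusion.query import And, Criterion, Not, Or

    pool = [
        lambda: Criterion("visits", "das28", "gt", float(rng.uniform(2, 7))),
        lambda: Criterion("visits", "das28", "between",
                          sorted([float(rng.uniform(1, 8)), float(rng.uniform(1, 8))])),
        lambda: Criterion("samples", "sample_type", "in_set",
                          list(rng.choice(["serum", "PBMC", "SFMC", "DNA"],
                                          size=2, replace=False))),
        lambda: Criterion("samples", "n_cells_millions", "gt",
                          float(rng.uniform(5, 60))),
        lambda: Criterion("samples", "freezer_status", "eq", "available"),
        lambda: Criterion("genotypes", "hla_dr", "in_set",
                          ["*04/*15", "*03/*08", "*01/*03"]),
        lambda: Criterion("genotypes", "rs2064476", "in_set", ["AG", "GG"]),
        lambda: Criterion("serology", "ccp_serum", "ge", float(rng.uniform(5, 300))),
        lambda: Criterion("patients", "cohort", "eq", "RA"),
        lambda: Criterion("treatments", "treatment", "ne", "A"),
        lambda: Criterion("samples", "sample_date", "gt", "2011-06-01"),
    ]

    leaves = [pool[int(rng.integers(0, len(pool)))]() for _ in range(n_leaves)]
    expr = leaves[0]
    for leaf in leaves[1:]:
        kind = int(rng.integers(0, 3))
        if kind == 0:
            expr = And(expr, leaf)
        elif kind == 1:
            expr = Or(expr, leaf)
        else:
            expr = And(expr, Not(leaf))
    if rng.random() < 0.2:
        expr = Not(expr)
    return expr
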