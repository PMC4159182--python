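"""Pseudonymization layer: coding keys, re-identification, leakage scanning.

Direct identifiers (personal numbers, names) are removed from source tables
and replaced by opaque coded identifiers that act as the virtual join
attribute across all sources. The identifier-to-token mapping (the coding
key) is kept apart from any store export, only designated keyholders may
invert it, and every privileged call is written to an append-only audit log.
A brute-force leakage scanner checks that no export ever carries a raw
identifier.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import AuthorizationError, KeyIntegrityError, NotFoundError

PRIVILEGES = {"read", "query", "export", "upload", "delete"}


@dataclass
class CodingKey:
    """Bijection from direct identifiers to coded tokens.

    Tokens look like ``P0482913``: a "P" plus a zero-padded integer drawn
    without replacement from a seeded stream, so they are sortable,
    collision-free and visibly non-identifying.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    created: str = field(default_factory=lambda: _dt.datetime(2020, 1, 1).isoformat())
    keyholder: str = "PI"
    namespace: str = ""

    def __post_init__(self):
        self.check()

    def check(self) -> None:
        tokens = list(self.mapping.values())
        if len(set(tokens)) != len(tokens):
            raise KeyIntegrityError("coding key is not a bijection: duplicate tokens")

    @property
    def inverse(self) -> dict[str, str]:
        return {v: k for k, v in self.mapping.items()}

    def identifiers(self) -> set[str]:
        return set(self.mapping)

    def save(self, path: str | Path) -> None:
        """Persist as a small text file: metadata header + identifier,token rows.

        Encryption at rest is a deployment concern; keep this file outside
        any store directory that is ever exported.
        """
        path = Path(path)
        lines = [f"# created: {self.created}",
                 f"# keyholder: {self.keyholder}",
                 f"# namespace: {self.namespace}",
                 "identifier,coded_id"]
        lines += [f"{k},{v}" for k, v in self.mapping.items()]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CodingKey":
        meta = {}
        mapping = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    k, _, v = line[1:].partition(":")
                    meta[k.strip()] = v.strip()
                elif line and line != "identifier,coded_id":
                    ident, _, tok = line.partition(",")
                    mapping[ident] = tok
        return cls(mapping=mapping, created=meta.get("created", ""),
                   keyholder=meta.get("keyholder", "PI"),
                   namespace=meta.get("namespace", ""))


@dataclass
class AccessPolicy:
    """Flat per-user privilege sets granted by the principal investigator.

    ``upload``/``delete`` must be granted explicitly; keyholders is the very
    limited group allowed to invert the coding key.
    """

    privileges: dict[str, set[str]] = field(default_factory=dict)
    keyholders: set[str] = field(default_factory=set)
    grantor: str = "PI"

    def grant(self, user: str, privs: Iterable[str]) -> None:
        privs = set(privs)
        unknown = privs - PRIVILEGES
        if unknown:
            raise ValueError(f"unknown privileges: {sorted(unknown)}")
        self.privileges.setdefault(user, set()).update(privs)

    def can(self, user: str, priv: str) -> bool:
        return priv in self.privileges.get(user, set())

    def is_keyholder(self, user: str) -> bool:
        return user in self.keyholders


class AuditLog:
    """Append-only JSON-lines record of every privileged operation."""

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path else None
        self.entries: list[dict] = []
        self._counter = 0

    def append(self, user: str, action: str, outcome: str, **detail) -> dict:
        self._counter += 1
        entry = {"seq": self._counter, "user": user, "action": action,
                 "outcome": outcome, **detail}
        self.entries.append(entry)
        if self.path:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(json.dumps(entry) + "\n")
        return entry

    def __len__(self) -> int:
        return len(self.entries)


def _token_stream(rng: np.random.Generator, used: set[str], width: int = 7):
    """Yield fresh "P"+digits tokens, drawn without replacement."""
    hi = 10 ** width
    while True:
        tok = f"P{int(rng.integers(0, hi)):0{width}d}"
        if tok not in used:
            used.add(tok)
            yield tok


def code_records(
    raw_table: pd.DataFrame,
    identifier_columns: list[str],
    key: CodingKey | None = None,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, CodingKey]:
    """Replace direct identifiers with coded tokens; return table and key.

    The identifier columns are dropped from the output and a ``coded_id``
    column is prepended. A given identifier always maps to the same token
    under the same key; identifiers unseen by the key receive fresh tokens
    from the seeded stream (deterministic for a fixed seed and row order).
    Multiple identifier columns are treated as one compound identifier.
    """
    missing = [c for c in identifier_columns if c not in raw_table.columns]
    if missing:
        raise KeyError(f"identifier columns absent from table: {missing}")
    if not identifier_columns:
        raise ValueError("identifier_columns must be non-empty")
    key = key or CodingKey()
    key.check()

    if len(raw_table):
        idents = raw_table[identifier_columns].astype(str).agg("|".join, axis=1)
    else:
        idents = pd.Series([], dtype=str, index=raw_table.index)
    rng = np.random.default_rng(rng_seed)
    used = set(key.mapping.values())
    stream = _token_stream(rng, used)
    for ident in idents:
        if ident not in key.mapping:
            key.mapping[ident] = next(stream)

    coded = raw_table.drop(columns=identifier_columns).copy()
    coded.insert(0, "coded_id", idents.map(key.mapping))
    return coded, key


def reidentify(
    coded_id: str,
    key: CodingKey,
    policy: AccessPolicy,
    user: str,
    audit: AuditLog,
) -> str:
    """Invert the coding key for one token; keyholders only, always audited."""
    if not policy.is_keyholder(user):
        audit.append(user, "reidentify", "denied", coded_id=coded_id)
        raise AuthorizationError(f"user {user!r} is not a keyholder")
    inv = key.inverse
    if coded_id not in inv:
        audit.append(user, "reidentify", "not_found", coded_id=coded_id)
        raise NotFoundError(f"coded_id {coded_id!r} not in key")
    audit.append(user, "reidentify", "ok", coded_id=coded_id)
    return inv[coded_id]


@dataclass(frozen=True)
class LeakageHit:
    table: str
    row: int
    column: str
    identifier: str


def scan_cells(cells: Iterable[tuple[str, int, str, object]],
               identifiers: set[str]) -> list[LeakageHit]:
    """Substring-scan arbitrary (table, row, column, value) cells."""
    hits = []
    for table, row, col, value in cells:
        if pd.isna(value):
            continue
        text = str(value)
        for ident in identifiers:
            if ident and ident in text:
                hits.append(LeakageHit(table, row, col, ident))
    return hits


def scan_for_leakage(store, key: CodingKey) -> list[LeakageHit]:
    """Exhaustive scan of every store cell for raw identifiers from the key.

    Empty result means the store is clean: the de-identification
    postcondition holds. Compound identifiers are scanned part-wise, so a
    single leaked component (e.g. a personal number inside a free-text dose
    field) is caught.
    """
    parts: set[str] = set()
    for ident in key.identifiers():
        parts.update(p for p in ident.split("|") if p)

    def cells():
        for name in store.source_names:
            df = store.table(name)
            for col in df.columns:
                for row, value in df[col].items():
                    yield name, row, col, value

    return scan_cells(cells(), parts)


def scan_text_for_leakage(text: str, key: CodingKey, label: str = "export") -> list[LeakageHit]:
    """Scan one serialized export (CSV/JSON/XML string) for raw identifiers."""
    parts = {p for ident in key.identifiers() for p in ident.split("|") if p}
    return [LeakageHit(label, -1, "-", ident) for ident in sorted(parts) if ident in text]
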