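"""YAML configuration loader for store dialect, sentinels and day windows."""

from __future__ import annotations

from pathlib import Path

import yaml

from .store import CsvDialect, StoreConfig
from .windows import WindowConfig


def load_config(path: str | Path) -> tuple[StoreConfig, WindowConfig]:
    """Read a small YAML file into store and window configurations.

    Recognized keys::

        dialect: {delimiter: ";", decimal: ","}
        crp_sentinel: 9.99          # null disables sentinel masking
        ccp_positive_cutoff: 25
        windows: {start_before: 30, start_after: 40,
                  end_before: 75, end_after: 152, min_volume: 100}
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    d = raw.get("dialect", {})
    dialect = CsvDialect(delimiter=d.get("delimiter", ","),
                         decimal=d.get("decimal", "."))
    store_cfg = StoreConfig(
        dialect=dialect,
        crp_sentinel=raw.get("crp_sentinel", 9.99),
        ccp_positive_cutoff=raw.get("ccp_positive_cutoff", 25.0),
    )
    w = raw.get("windows", {})
    statuses = w.get("allowed_statuses")
    window_cfg = WindowConfig(
        start_before=w.get("start_before", 30),
        start_after=w.get("start_after", 40),
        end_before=w.get("end_before", 75),
        end_after=w.get("end_after", 152),
        min_volume=w.get("min_volume"),
        allowed_statuses=frozenset(statuses) if statuses else None,
    )
    return store_cfg, window_cfg
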