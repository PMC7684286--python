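"""Readers, writers and configuration loading.

The on-disk rendition table is a TSV/CSV with header
``bird_id, group, target_side, day, rendition, pitch_hz, stimulus``; cohort
designs and world configurations are YAML.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import COLUMNS, BirdParams

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = list(COLUMNS)


class RenditionTableError(ValueError):
    pass


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_renditions(path) -> pd.DataFrame:
    """Read and validate a rendition table.

    Raises a descriptive error for missing columns or non-numeric pitches;
    unsorted days within a bird are reported and auto-sorted with a warning.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise RenditionTableError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    pitch = pd.to_numeric(table["pitch_hz"], errors="coerce")
    if pitch.isna().any():
        line = int(np.flatnonzero(pitch.isna())[0]) + 2  # header is line 1
        raise RenditionTableError(f"{path}: non-numeric pitch_hz at line {line}")
    if (pitch <= 0).any():
        line = int(np.flatnonzero((pitch <= 0).to_numpy())[0]) + 2
        raise RenditionTableError(f"{path}: nonpositive pitch_hz at line {line}")
    table["pitch_hz"] = pitch
    table["day"] = pd.to_numeric(table["day"], errors="raise").astype(int)
    if table["stimulus"].dtype != bool:
        table["stimulus"] = (
            table["stimulus"].astype(str).str.lower().isin(("true", "1", "t"))
        )
    for bird, sub in table.groupby("bird_id"):
        if not sub["day"].is_monotonic_increasing:
            logger.warning("%s: days of bird %s not sorted; sorting", path, bird)
            table = table.sort_values(["bird_id", "day", "rendition"]).reset_index(
                drop=True
            )
            break
    return table[REQUIRED_COLUMNS]


def write_renditions(table: pd.DataFrame, path) -> None:
    path = Path(path)
    table.to_csv(path, sep=_sep_for(path), index=False)


def write_summary_csv(summaries: pd.DataFrame, path) -> None:
    summaries.to_csv(path, index=False)


def write_fit_json(fit, path) -> None:
    """Serialize a MixedFit (or any object with to_dict) to JSON."""
    payload = fit.to_dict() if hasattr(fit, "to_dict") else fit
    Path(path).write_text(json.dumps(payload, indent=2))


def load_cohort_design(path) -> list[BirdParams]:
    """YAML cohort design -> list of BirdParams.

    The file is either a mapping with a ``birds:`` list or a bare list; each
    entry holds BirdParams fields.
    """
    raw = yaml.safe_load(Path(path).read_text())
    entries = raw.get("birds", raw) if isinstance(raw, dict) else raw
    if not isinstance(entries, list):
        raise ValueError(f"{path}: expected a list of bird entries")
    return [BirdParams(**entry) for entry in entries]


def load_world_config(path) -> dict:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping")
    return raw


def write_run_log(path, seed: int, config: dict) -> None:
    """Plain-text run log: seed, config hash, library versions."""
    import hashlib
    import statsmodels
    import scipy

    blob = json.dumps(config, sort_keys=True, default=str)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:16]
    lines = [
        f"seed: {seed}",
        f"config_sha256: {digest}",
        f"numpy: {np.__version__}",
        f"pandas: {pd.__version__}",
        f"scipy: {scipy.__version__}",
        f"statsmodels: {statsmodels.__version__}",
        f"config: {blob}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
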