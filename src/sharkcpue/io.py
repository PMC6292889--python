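"""CSV/JSON interchange and run manifests.

Catch tables: columns ``date`` (ISO-8601), ``region``, ``site``, ``gear``,
``group``, ``species`` (may be empty), ``total_length_cm`` (may be empty),
``sex`` (F/M/unknown), ``financial_year``. Effort tables: ``region``,
``site``, ``financial_year``, ``gear``, ``effort`` (gear-years). UTF-8
throughout.
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import DataError
from .records import assign_financial_years
from .synthetic import CATCH_COLUMNS, EFFORT_COLUMNS


def write_catch_csv(catch: pd.DataFrame, path) -> None:
    catch.to_csv(path, index=False, columns=CATCH_COLUMNS)


def read_catch_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"species": "string"},
                     keep_default_na=True)
    missing = set(CATCH_COLUMNS) - {"financial_year"} - set(df.columns)
    if missing:
        raise DataError(f"catch table lacks columns {sorted(missing)}")
    df["species"] = df["species"].fillna("").astype(str)
    if "financial_year" not in df.columns:
        df["financial_year"] = assign_financial_years(df["date"])
    return df


def write_effort_csv(effort: pd.DataFrame, path) -> None:
    effort.to_csv(path, index=False, columns=EFFORT_COLUMNS)


def read_effort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EFFORT_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"effort table lacks columns {sorted(missing)}")
    if (df["effort"] < 0).any():
        raise DataError("negative effort values")
    dup = df.duplicated(subset=["site", "financial_year", "gear"])
    if dup.any():
        raise DataError("duplicate (site, financial_year, gear) effort keys")
    return df


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def build_manifest(config_dict: dict, seed: int, inputs: dict[str, str],
                   extra: dict | None = None) -> dict:
    """Run manifest: config hash, seed, versions, input digests, timestamp."""
    cfg_blob = json.dumps(_jsonable(config_dict), sort_keys=True).encode()
    return {
        "config_sha256": hashlib.sha256(cfg_blob).hexdigest(),
        "seed": seed,
        "package_version": __version__,
        "python": platform.python_version(),
        "inputs": inputs,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        **(extra or {}),
    }


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
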