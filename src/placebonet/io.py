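"""Table I/O with schema validation and provenance.

All tables are plain CSV/TSV. Floats are written at 17 significant digits
(shortest exact double representation), so a write -> read round trip
reproduces values bit-exactly — comfortably inside the 1e-12 contract.
Every output directory gets a ``provenance.json`` recording the config, the
master seed, package version and input checksums, so each numeric output is
a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .parcellation import region_names

__all__ = [
    "read_metadata",
    "read_regional_ct",
    "read_qol",
    "write_table",
    "write_json",
    "write_cohort_tables",
    "provenance_block",
]

FLOAT_FMT = "%.17g"

METADATA_COLUMNS = [
    "subject_id", "group", "age", "sex", "site", "disease_duration",
    "lesion_load", "baseline_edss", "baseline_qol", "total_brain_volume",
]


def _require(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    _require(meta, METADATA_COLUMNS, "metadata table")
    dup = meta["subject_id"][meta["subject_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"metadata table: duplicate subject ids {sorted(set(dup))}")
    return meta


def read_regional_ct(path) -> pd.DataFrame:
    ct = pd.read_csv(path, index_col="subject_id")
    expected = region_names()
    if list(ct.columns) != expected:
        raise ValueError(
            "regional CT table: columns must be the 78 packaged AAL cortical "
            "region names in canonical order"
        )
    if ct.index.duplicated().any():
        raise ValueError("regional CT table: duplicate subject ids")
    if ct.isna().any().any():
        raise ValueError("regional CT table: missing cells are not allowed")
    return ct


def read_qol(path) -> pd.DataFrame:
    qol = pd.read_csv(path)
    _require(qol, ["subject_id", "week", "score"], "QoL table")
    for sid, traj in qol.groupby("subject_id"):
        if traj["week"].duplicated().any():
            raise ValueError(f"QoL table: duplicate weeks for subject {sid!r}")
    return qol


def write_table(df: pd.DataFrame, path, sep: str = ",", index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=index, float_format=FLOAT_FMT)
    return path


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
    return path


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def provenance_block(config: dict, seed: int, inputs: dict[str, str]) -> dict:
    from . import __version__

    return {
        "package": "placebonet",
        "version": __version__,
        "seed": seed,
        "config": _jsonable(config),
        "input_checksums": {k: sha256_of(v) for k, v in inputs.items() if v},
    }


def write_cohort_tables(outdir, cohort, ct, qol, specs: dict, seed: int) -> dict:
    """Write the three synthetic-study CSVs plus a JSON sidecar.

    The sidecar records the generator specs and seed, and flags that the
    visit schedule is a synthetic assumption (the source trial's schedule is
    not published).
    """
    outdir = Path(outdir)
    paths = {
        "metadata": write_table(cohort, outdir / "metadata.csv"),
        "regional_ct": write_table(
            ct.reset_index(), outdir / "regional_ct.csv"
        ),
        "qol": write_table(qol, outdir / "qol.csv"),
    }
    sidecar = {
        "seed": seed,
        "specs": _jsonable(specs),
        "notes": [
            "synthetic cohort: no real imaging or patient data",
            "visit schedule is an assumption (7 visits over 48 weeks)",
        ],
    }
    paths["sidecar"] = write_json(sidecar, outdir / "sidecar.json")
    return {k: str(v) for k, v in paths.items()}
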