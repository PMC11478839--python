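"""File input/output: the PVT CSV dialect and provenance-stamped tables.

PVT tables are comma-delimited UTF-8 text with the exact header columns
``T_K,p_MPa,rho_g_cm3,replicate`` in any order.  Lines starting with ``#``
are comments; output tables carry the run's configuration hash in such a
comment so every artifact is traceable to the configuration that produced
it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .pvtfit import PVT_COLUMNS, PVTDataset

__all__ = ["read_pvt", "write_pvt", "write_table", "write_json"]

#: Format preserving full double precision in text round trips.
_FLOAT_FORMAT = "%.17g"


def read_pvt(path, polymer_id=None, hv_mol_percent=0.0):
    """Read a PVT dataset from a CSV file.

    The header must contain exactly the :data:`~slsorb.pvtfit.PVT_COLUMNS`
    (any order).  Unknown columns, missing columns, non-numeric cells and
    empty files raise :class:`~slsorb.errors.ParseError` naming the
    problem.
    """
    path = Path(path)
    try:
        # round_trip parsing: text written at %.17g reloads bit-exactly
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise ParseError(f"cannot read PVT file {path}: {exc}") from exc
    if len(frame) == 0:
        raise ParseError(f"PVT file {path} contains a header but no rows")
    unknown = [c for c in frame.columns if c not in PVT_COLUMNS]
    if unknown:
        raise ParseError(f"PVT file {path} has unknown columns: {unknown}")
    missing = [c for c in PVT_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"PVT file {path} is missing columns: {missing}")
    for col in ("T_K", "p_MPa", "rho_g_cm3"):
        values = pd.to_numeric(frame[col], errors="coerce")
        if values.isna().any():
            bad = frame.loc[values.isna(), col].iloc[0]
            raise ParseError(
                f"PVT file {path} has a non-numeric value {bad!r} in column {col}"
            )
        frame[col] = values.astype(float)
    frame = frame[list(PVT_COLUMNS)]
    return PVTDataset(
        polymer_id if polymer_id is not None else path.stem,
        float(hv_mol_percent),
        frame,
    )


def write_pvt(dataset, path):
    """Write a PVT dataset in the canonical CSV dialect at full precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dataset.data.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def write_table(frame, path, config_hash=None):
    """Write a result table as CSV, stamped with the configuration hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as handle:
        if config_hash is not None:
            handle.write(f"# config_hash={config_hash}\n")
        frame.to_csv(handle, index=False, float_format=_FLOAT_FORMAT)
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def write_json(payload, path):
    """Write a JSON document (numpy scalars converted transparently)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(_jsonable(payload), handle, indent=2, sort_keys=True)
        handle.write("\n")
    return path
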