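"""Reading and writing the long-format PPT CSV dialect.

One row per measurement, header ``subject,session,side,repetition,ppt_n``:
subject is a string label, session/side/repetition are 1-based integers,
ppt_n is the recorded force in newtons.  This is the single on-disk data
format of the package.
"""

from __future__ import annotations

import os
from typing import Union

import numpy as np
import pandas as pd

__all__ = ["COLUMNS", "read_ppt_csv", "write_ppt_csv", "validate_ppt_frame"]

COLUMNS = ["subject", "session", "side", "repetition", "ppt_n"]
_INDEX_COLS = ["session", "side", "repetition"]


class PPTDataError(ValueError):
    """Malformed PPT data (missing columns, bad indices, non-numeric forces)."""


def validate_ppt_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Check a DataFrame against the dialect and return a normalised copy.

    Raises :class:`PPTDataError` with a row-addressed message on the first
    problem found.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise PPTDataError(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise PPTDataError("no observations: the table is empty")
    out = df.loc[:, COLUMNS].copy()
    out["subject"] = out["subject"].astype(str)
    for col in _INDEX_COLS:
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < 1)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise PPTDataError(
                f"column '{col}', row {row}: expected a 1-based integer index, "
                f"got {df[col].iloc[row]!r}"
            )
        out[col] = vals.astype(int)
    force = pd.to_numeric(out["ppt_n"], errors="coerce")
    bad = ~np.isfinite(force.to_numpy(dtype=float))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise PPTDataError(
            f"column 'ppt_n', row {row}: expected a finite force in newtons, "
            f"got {df['ppt_n'].iloc[row]!r}"
        )
    out["ppt_n"] = force.astype(float)
    dup = out.duplicated(subset=["subject", "session", "side", "repetition"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise PPTDataError(
            f"row {row}: duplicate (subject, session, side, repetition) cell"
        )
    return out


def read_ppt_csv(path: Union[str, os.PathLike]) -> pd.DataFrame:
    """Read and validate a PPT measurement table."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise PPTDataError(f"{path}: empty file") from exc
    return validate_ppt_frame(df)


def write_ppt_csv(df: pd.DataFrame, path: Union[str, os.PathLike]) -> None:
    """Write a PPT measurement table in the package dialect."""
    validate_ppt_frame(df).to_csv(path, index=False)
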