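"""Plain-text I/O for nightly count tables and presence results."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import ClassifiedNight
from .presence import PresenceResult
from .species import CODES


def load_night_counts(path: str | Path) -> pd.DataFrame:
    """Read a night-count CSV (``night_id,EPFU,...,PESU``)."""
    df = pd.read_csv(path)
    if "night_id" not in df.columns:
        raise ValueError(f"{path}: missing 'night_id' column")
    missing = [s for s in CODES if s not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing species columns {missing}")
    counts = df[list(CODES)].to_numpy(float)
    if np.any(counts < 0):
        raise ValueError(f"{path}: negative counts")
    return df[["night_id", *CODES]]


def nights_from_frame(df: pd.DataFrame) -> list[tuple[str, ClassifiedNight]]:
    return [
        (str(row["night_id"]), ClassifiedNight(counts=row[list(CODES)].to_numpy(float)))
        for _, row in df.iterrows()
    ]


def presence_frame(results: dict[str, PresenceResult]) -> pd.DataFrame:
    """Tidy ``night_id,species,pvalue,present`` table."""
    rows = [
        {
            "night_id": night_id,
            "species": s,
            "pvalue": p,
            "present": p <= res.alpha,
        }
        for night_id, res in results.items()
        for s, p in res.pvalues.items()
    ]
    return pd.DataFrame(rows)
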