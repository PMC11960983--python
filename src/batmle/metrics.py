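"""Detection summaries from simulated nights: TP/FN rates, critical
count, and real-world recordings.

The critical count (CC) for a species is the smallest number of
correctly classified files at which the presence test reliably fires
(a chosen percentage of simulated nights with p <= alpha). Real-world
recordings (RWR) converts CC into the number of field recordings a
surveyor would need, accounting for the classifier missing some files:
RWR = CC / sensitivity. RWR assumes no *other* species' files are
misclassified into the examined species, so it can only overstate the
requirement; RWR >= CC always, with equality at sensitivity 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class DetectionSummary:
    species: str
    count: int
    n_obs: int
    pct_tp: float
    pct_fn: float


def tp_fn_by_count(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Percent TP / FN nights grouped by (examined species, its count).

    ``results`` is the tidy frame from ``run_simulation``; every species
    is truly present on every design night, so p <= alpha is a true
    positive and p > alpha a false negative. On the full design each
    (species, count) cell holds 225 nights.
    """
    if results.empty:
        raise ValueError("empty simulation results")
    df = results.copy()
    df["tp"] = df["pvalue"] <= alpha
    out = (
        df.groupby(["examined", "count"], observed=True)
        .agg(n_obs=("tp", "size"), pct_tp=("tp", "mean"))
        .reset_index()
        .rename(columns={"examined": "species"})
    )
    out["count"] = out["count"].astype(int)
    out["pct_tp"] *= 100.0
    out["pct_fn"] = 100.0 - out["pct_tp"]
    return out[["species", "count", "n_obs", "pct_tp", "pct_fn"]]


def empirical_cc(
    summaries: pd.DataFrame, species: str, tp_threshold: float = 90.0
) -> int | None:
    """Smallest count whose TP percentage reaches ``tp_threshold``.

    Survey practice quotes both 75% and 90% reliability criteria; the
    threshold is therefore a parameter (default 90). Returns ``None``
    when no count on the ladder reaches the threshold.
    """
    sub = summaries.loc[summaries["species"] == species].sort_values("count")
    if sub.empty:
        raise KeyError(f"no summaries for species {species!r}")
    hit = sub.loc[sub["pct_tp"] >= tp_threshold, "count"]
    return int(hit.iloc[0]) if len(hit) else None


def rwr(cc: int | None, sensitivity: float) -> float | None:
    """Real-world recordings: CC inflated by imperfect classification."""
    if cc is None:
        return None
    if sensitivity <= 0:
        raise ValueError("sensitivity must be positive to define RWR")
    if sensitivity > 1:
        raise ValueError("sensitivity cannot exceed 1")
    return cc / sensitivity
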