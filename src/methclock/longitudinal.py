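"""Within-individual DNAm-age trajectories.

Repeatedly sampled individuals allow a paired comparison of epigenetic
age across time: only the chronologically first and last samples of each
individual are kept (maximizing temporal separation), pairs separated by
less than a day are dropped as near-duplicates, and the per-individual
change in DNAm age is tested against zero with a one-sample, one-sided
(greater) t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ONE_DAY_YEARS", "LongitudinalPair", "extract_first_last",
           "filter_pairs", "test_delta", "check_interval_consistency"]

ONE_DAY_YEARS = 1.0 / 365.25


@dataclass
class LongitudinalPair:
    individual_id: str
    age_first: float
    age_last: float
    dnam_first: float
    dnam_last: float

    @property
    def interval(self) -> float:
        return self.age_last - self.age_first

    @property
    def delta(self) -> float:
        return self.dnam_last - self.dnam_first


def extract_first_last(predictions: pd.DataFrame) -> pd.DataFrame:
    """One pair per repeatedly sampled individual: first and last samples.

    Samples are ordered by chronological age within individual; singletons
    are skipped.  Duplicate (individual, age) rows with differing
    predictions keep the earliest-listed one, with a warning.  Returns a
    frame with columns ``individual_id, age_first, age_last, dnam_first,
    dnam_last, interval, delta``; the result does not depend on input row
    order beyond that tie rule.
    """
    rows = []
    for ind, grp in predictions.groupby("individual_id", sort=True):
        if grp.duplicated(subset=["age_years"]).any():
            warnings.warn(
                f"individual {ind!r}: duplicate sampling ages; keeping the "
                "earliest-listed prediction for each",
                stacklevel=2,
            )
            grp = grp.drop_duplicates(subset=["age_years"], keep="first")
        if len(grp) < 2:
            continue
        grp = grp.sort_values("age_years", kind="mergesort")
        first, last = grp.iloc[0], grp.iloc[-1]
        rows.append(
            {
                "individual_id": ind,
                "age_first": float(first["age_years"]),
                "age_last": float(last["age_years"]),
                "dnam_first": float(first["dnam_age"]),
                "dnam_last": float(last["dnam_age"]),
            }
        )
    pairs = pd.DataFrame(
        rows, columns=["individual_id", "age_first", "age_last",
                       "dnam_first", "dnam_last"]
    )
    pairs["interval"] = pairs["age_last"] - pairs["age_first"]
    pairs["delta"] = pairs["dnam_last"] - pairs["dnam_first"]
    return pairs


def filter_pairs(
    pairs: pd.DataFrame, min_interval: float = ONE_DAY_YEARS
) -> pd.DataFrame:
    """Drop pairs whose sampling interval is below ``min_interval`` years
    (default: one day), removing same-day or near-duplicate sampling."""
    return pairs.loc[pairs["interval"] >= min_interval].reset_index(drop=True)


def test_delta(pairs: pd.DataFrame) -> dict:
    """One-sample, one-sided (greater) t-test of DNAm-age change vs zero.

    Returns mean delta, t, df (= n - 1), the one-sided p-value, counts of
    increasing/decreasing individuals and the per-pair table.
    """
    deltas = pairs["delta"].to_numpy(float)
    if len(deltas) < 2:
        raise ValueError("need at least 2 pairs")
    if np.std(deltas, ddof=1) == 0:
        raise ValueError("zero variance in deltas: t undefined")
    res = stats.ttest_1samp(deltas, 0.0, alternative="greater")
    return {
        "n": len(deltas),
        "mean_delta": float(deltas.mean()),
        "t": float(res.statistic),
        "df": len(deltas) - 1,
        "p_one_sided": float(res.pvalue),
        "n_increasing": int((deltas > 0).sum()),
        "n_decreasing": int((deltas < 0).sum()),
        "pairs": pairs,
    }


def check_interval_consistency(
    table: pd.DataFrame, tol: float = 0.02
) -> pd.DataFrame:
    """Cross-check a reported interval column against the sampling ages.

    ``table`` needs columns ``individual_id, age_first, age_last,
    interval_reported``.  Returns the table with ``interval_recomputed``
    and ``consistent`` (|difference| <= tol years, about a week).  Used to
    flag transcription errors in published longitudinal tables.
    """
    out = table.copy()
    out["interval_recomputed"] = out["age_last"] - out["age_first"]
    out["consistent"] = (
        (out["interval_reported"] - out["interval_recomputed"]).abs() <= tol
    )
    return out
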