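"""Mean Absolute Activity (MAA): index, expression log-ratio, binning, grouping.

MAA of a sample is the semi-sum of the absolute activities of the two
counterposed regulators: high values mean one program clearly dominates
(intact switch); values near zero mean the two activities balance out
(broken switch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

STRATA = ("very_low", "low", "medium", "high", "very_high")

#: Closed-left / open-right stratum intervals on MAA.
STRATUM_EDGES = {
    "very_low": (0.0, 1.0),
    "low": (1.0, 2.0),
    "medium": (2.0, 3.0),
    "high": (3.0, 4.0),
    "very_high": (4.0, math.inf),
}


class MAAError(ValueError):
    pass


def compute_maa(a1: float, a2: float) -> float:
    """``(|a1| + |a2|) / 2``; symmetric and sign-invariant in both arguments."""
    if not (math.isfinite(a1) and math.isfinite(a2)):
        raise MAAError("activities must be finite")
    return (abs(a1) + abs(a2)) / 2.0


def expression_log_ratio(e1: float, e2: float) -> float:
    """``log2(log2(e1) / log2(e2))`` on linear-scale expression values.

    Undefined (NaN) whenever either value is <= 1, since the inner logs must
    be positive; callers count and report NaNs rather than dropping them
    silently.
    """
    if e1 <= 1.0 or e2 <= 1.0:
        return math.nan
    return math.log2(math.log2(e1) / math.log2(e2))


def bin_maa(maa: float) -> str:
    """Stratum of a MAA value.

    very_low: [0, 1), low: [1, 2), medium: [2, 3), high: [3, 4),
    very_high: [4, inf).  Boundaries are closed on the left.
    """
    if maa < 0 or not math.isfinite(maa):
        raise MAAError(f"MAA must be a finite non-negative value, got {maa}")
    for name, (lo, hi) in STRATUM_EDGES.items():
        if lo <= maa < hi:
            return name
    raise AssertionError("unreachable: strata partition [0, inf)")


def dichotomize(maa_values, threshold: float) -> tuple[np.ndarray, int, int]:
    """Split samples at a threshold: value >= threshold -> ``above``.

    Returns (labels, n_below, n_above).  Ties at the threshold go to
    ``above``.
    """
    vals = np.asarray(maa_values, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise MAAError("non-finite MAA values")
    labels = np.where(vals >= threshold, "above", "below")
    n_above = int(np.sum(vals >= threshold))
    return labels, len(vals) - n_above, n_above


@dataclass
class MAATable:
    """Per-sample MAA records: activities, index, ratio, stratum, group."""

    data: pd.DataFrame  # sample_id, a1, a2, maa, ratio, stratum, group
    threshold: float
    n_ratio_undefined: int
    #: tie rule recorded in output metadata
    tie_rule: str = "ties at threshold assigned to 'above'"


def build_maa_table(
    sample_ids,
    a1,
    a2,
    e1=None,
    e2=None,
    threshold: float | None = None,
) -> MAATable:
    """Assemble the per-sample MAA table.

    ``a1``/``a2`` are the two regulators' NES vectors; ``e1``/``e2`` optional
    linear-scale expression vectors for the log-ratio column.  When
    ``threshold`` is None the group column is omitted.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    maa = np.array([compute_maa(x, y) for x, y in zip(a1, a2)])
    if e1 is not None and e2 is not None:
        ratio = np.array(
            [expression_log_ratio(x, y) for x, y in zip(np.asarray(e1), np.asarray(e2))]
        )
    else:
        ratio = np.full(len(maa), np.nan)
    n_undef = int(np.sum(~np.isfinite(ratio)))
    strata = [bin_maa(v) for v in maa]
    df = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "a1": a1,
            "a2": a2,
            "maa": maa,
            "ratio": ratio,
            "stratum": strata,
        }
    )
    thr = math.nan
    if threshold is not None:
        labels, _, _ = dichotomize(maa, threshold)
        df["group"] = labels
        thr = threshold
    return MAATable(data=df, threshold=thr, n_ratio_undefined=n_undef)


def write_maa_tsv(table: MAATable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_maa_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["sample_id"] = df["sample_id"].astype(str)
    return df
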