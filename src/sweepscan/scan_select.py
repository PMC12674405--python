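"""Empirical-quantile tail selection: turn each statistic's records into
a candidate set with an explicit threshold.

The quantile is the linear-interpolation definition (numpy default);
ties at the threshold are included, so the selection is deterministic and
slightly conservative for candidate discovery. Undefined (NaN) records
are never selected and never enter the quantile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TAILS = ("upper", "lower", "abs_upper")
METHODS = ("fst", "pi", "xpehh", "ihs")


@dataclass
class ScanResult:
    method: str  # fst | pi | xpehh | ihs
    tail: str
    fraction: float
    threshold: float
    selected: pd.DataFrame  # the selected window/site records
    records: pd.DataFrame  # all records with a boolean `selected` column
    gene_set: set[str] = field(default_factory=set)


def select_tail(values, fraction: float = 0.05, tail: str = "upper"
                ) -> tuple[float, np.ndarray]:
    """Threshold and selected indices for one empirical tail.

    ``upper``: values >= the (1 - fraction) quantile; ``lower``: values <=
    the fraction quantile; ``abs_upper``: |values| >= the (1 - fraction)
    quantile of |values|. All-identical values yield an empty selection.
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}, got {tail!r}")
    if not 0 < fraction < 1:
        raise ValueError(f"fraction {fraction} outside (0, 1)")
    values = np.asarray(values, dtype=float)
    defined = np.isfinite(values)
    scored = np.abs(values) if tail == "abs_upper" else values
    v = scored[defined]
    if v.size < 20:
        warnings.warn(f"only {v.size} defined values; {fraction:.0%} tail "
                      "may be empty", stacklevel=2)
    if v.size == 0:
        return float("nan"), np.array([], dtype=np.int64)
    if np.all(v == v[0]):
        warnings.warn("all values identical; empty selection", stacklevel=2)
        return float(v[0]), np.array([], dtype=np.int64)
    if tail == "lower":
        threshold = float(np.quantile(v, fraction))
        sel = defined & (scored <= threshold)
    else:
        threshold = float(np.quantile(v, 1 - fraction))
        sel = defined & (scored >= threshold)
    return threshold, np.flatnonzero(sel)


def make_scan_result(method: str, records: pd.DataFrame, value_col: str,
                     tail: str, fraction: float = 0.05) -> ScanResult:
    """Wrap one statistic's records into a ScanResult via select_tail."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    threshold, idx = select_tail(records[value_col].to_numpy(), fraction, tail)
    records = records.copy()
    records["selected"] = False
    if idx.size:
        records.iloc[idx, records.columns.get_loc("selected")] = True
    selected = records[records["selected"]].drop(columns="selected")
    logger.info("%s: threshold %.6g (%s tail, %.0f%%), %d of %d selected",
                method, threshold, tail, 100 * fraction, len(selected),
                int(np.isfinite(records[value_col]).sum()))
    return ScanResult(method, tail, fraction, threshold, selected, records)
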