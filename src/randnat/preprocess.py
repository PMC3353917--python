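"""Outlier removal by distribution tails, and class-size balancing.

A record is an outlier when *any* of its 11 variables falls strictly
outside the [0.5%, 99.5%] empirical quantile band of that variable's
distribution, estimated within the record's own class.  Flagged records
are removed, then the majority class is randomly subsampled (without
replacement) to the minority class size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_features import LABEL_COLUMN, VARIABLE_NAMES

DEFAULT_LOWER_Q = 0.005
DEFAULT_UPPER_Q = 0.995


@dataclass
class OutlierReport:
    """Cutoffs, per-record flagged variables and per-class totals."""

    cutoffs: pd.DataFrame  # columns: class, variable, lower, upper
    flags: pd.DataFrame  # bool, index = table index, columns = variables
    flagged: pd.Series  # bool per record: any variable out of band
    totals: dict[str, int]  # flagged count per class
    n_records: int

    def flagged_variables(self, index) -> list[str]:
        """Names of the variables that put one record out of band."""
        row = self.flags.loc[index]
        return [v for v in self.flags.columns if row[v]]

    def to_frame(self) -> pd.DataFrame:
        return self.cutoffs.copy()


def flag_outliers(
    table: pd.DataFrame,
    lower_q: float = DEFAULT_LOWER_Q,
    upper_q: float = DEFAULT_UPPER_Q,
) -> OutlierReport:
    """Flag records with any variable in a class-wise distribution tail.

    Quantiles use linear interpolation between order statistics; a value
    is out of band only when *strictly* below the lower or above the
    upper quantile, so a constant variable never flags anything.  Classes
    too small to resolve the requested tail (fewer than ``1/min(tail)``
    records) produce a warning and no flags.
    """
    if not 0 < lower_q < upper_q < 1:
        raise ValueError("need 0 < lower_q < upper_q < 1")
    if LABEL_COLUMN not in table.columns:
        raise ValueError(f"table lacks a {LABEL_COLUMN!r} column")
    classes = table[LABEL_COLUMN].unique()
    for cls in classes:
        if (table[LABEL_COLUMN] == cls).sum() < 10:
            raise ValueError(f"class {cls!r} has fewer than 10 records")

    variables = [v for v in VARIABLE_NAMES if v in table.columns]
    if not variables:
        raise ValueError("table contains none of the canonical variable columns")

    min_n = int(np.ceil(1.0 / min(lower_q, 1.0 - upper_q)))
    flags = pd.DataFrame(False, index=table.index, columns=variables)
    cut_rows = []
    for cls in classes:
        sel = table[LABEL_COLUMN] == cls
        sub = table.loc[sel]
        if len(sub) < min_n:
            warnings.warn(
                f"class {cls!r}: {len(sub)} records cannot resolve the "
                f"{min(lower_q, 1 - upper_q):.3%} tail; no records flagged",
                stacklevel=2,
            )
            for var in variables:
                cut_rows.append((cls, var, np.nan, np.nan))
            continue
        for var in variables:
            x = sub[var].to_numpy(dtype=float)
            lo, hi = np.quantile(x, [lower_q, upper_q])
            cut_rows.append((cls, var, lo, hi))
            flags.loc[sel, var] = (x < lo) | (x > hi)

    flagged = flags.any(axis=1)
    totals = {
        cls: int(flagged[table[LABEL_COLUMN] == cls].sum()) for cls in classes
    }
    cutoffs = pd.DataFrame(cut_rows, columns=["class", "variable", "lower", "upper"])
    return OutlierReport(
        cutoffs=cutoffs,
        flags=flags,
        flagged=flagged,
        totals=totals,
        n_records=len(table),
    )


def remove_outliers(table: pd.DataFrame, report: OutlierReport) -> pd.DataFrame:
    """Drop flagged records, preserving order."""
    if report.n_records != len(table) or not report.flagged.index.equals(table.index):
        raise ValueError("outlier report was not built from this table")
    return table.loc[~report.flagged].copy()


def balance_classes(table: pd.DataFrame, seed: int | np.random.Generator | None = None) -> pd.DataFrame:
    """Subsample every class, without replacement, to the minority size.

    Record order is preserved; with equal class sizes the table is
    returned unchanged (as a copy).
    """
    if LABEL_COLUMN not in table.columns:
        raise ValueError(f"table lacks a {LABEL_COLUMN!r} column")
    sizes = table[LABEL_COLUMN].value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least two classes to balance")
    if (sizes == 0).any():
        raise ValueError("cannot balance with an empty class")
    target = int(sizes.min())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    keep = []
    for cls, n in sizes.items():
        idx = table.index[table[LABEL_COLUMN] == cls].to_numpy()
        if n > target:
            idx = rng.choice(idx, size=target, replace=False)
        keep.append(idx)
    keep = np.concatenate(keep)
    order = np.array([table.index.get_loc(i) for i in keep])
    return table.loc[keep[np.argsort(order)]].copy()
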