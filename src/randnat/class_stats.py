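"""The statistical battery comparing natural and random proteins.

Per variable: Shapiro–Wilk gaussianity within each class, Wilcoxon
rank-sum (Mann–Whitney) for location, Fligner–Killeen for dispersion, plus
descriptive summaries and per-class Pearson correlation matrices.  All
tests are two-sided; the working significance level in the analysis is
0.01 and no multiple-testing correction is applied.

The rank-sum test addresses a location shift between the two class
distributions; under the usual shift model that is a statement about
medians/means, which is how its p-value is read here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .structure_features import LABEL_COLUMN, VARIABLE_NAMES

ALPHA = 0.01


@dataclass(frozen=True)
class VariableComparison:
    variable: str
    mean: dict[str, float]
    sd: dict[str, float]
    location_p: float
    dispersion_p: float
    shapiro_p: dict[str, float]


def _as_sample(x, name: str, min_n: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if len(x) < min_n:
        raise ValueError(f"{name} needs at least {min_n} observations, got {len(x)}")
    if not np.isfinite(x).all():
        raise ValueError(f"{name} contains non-finite values")
    return x


def test_gaussianity(x) -> tuple[float, float]:
    """Shapiro–Wilk test; returns (W, p).  Degenerate samples are an error."""
    x = _as_sample(x, "sample", 3)
    if np.ptp(x) == 0:
        raise ValueError("sample is constant; Shapiro-Wilk W is undefined")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def compare_location(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U); returns (U, p).

    Small tie-free samples get the exact permutation distribution; larger
    or tied samples use the midrank normal approximation with tie
    correction.
    """
    x = _as_sample(x, "x", 2)
    y = _as_sample(y, "y", 2)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def compare_dispersion(x, y) -> tuple[float, float]:
    """Fligner–Killeen test of equal dispersion; returns (chi2, p)."""
    x = _as_sample(x, "x", 2)
    y = _as_sample(y, "y", 2)
    res = stats.fligner(x, y)
    return float(res.statistic), float(res.pvalue)


def summarize_by_class(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-variable class comparison plus per-class correlation matrices.

    Returns a summary frame (one row per variable, canonical order) with
    class means/SDs and the three p-values, and a dict mapping each class
    to the Pearson correlation matrix of the 11 variables.
    """
    missing = [v for v in VARIABLE_NAMES if v not in table.columns]
    if missing:
        raise ValueError(f"feature table missing variable column(s): {missing}")
    classes = sorted(table[LABEL_COLUMN].unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, found {classes}")
    groups = {cls: table[table[LABEL_COLUMN] == cls] for cls in classes}
    for cls, g in groups.items():
        if len(g) < 3:
            raise ValueError(f"class {cls!r} needs at least 3 records")

    rows = []
    for var in VARIABLE_NAMES:
        samples = {cls: g[var].to_numpy(dtype=float) for cls, g in groups.items()}
        a, b = (samples[c] for c in classes)
        row = {"variable": var}
        for cls in classes:
            row[f"mean_{cls}"] = samples[cls].mean()
            row[f"sd_{cls}"] = samples[cls].std(ddof=1)
            try:
                row[f"shapiro_p_{cls}"] = test_gaussianity(samples[cls])[1]
            except ValueError:
                row[f"shapiro_p_{cls}"] = np.nan
        row["location_p"] = compare_location(a, b)[1]
        row["dispersion_p"] = compare_dispersion(a, b)[1]
        rows.append(row)
    summary = pd.DataFrame(rows)
    corr = {cls: g[list(VARIABLE_NAMES)].corr() for cls, g in groups.items()}
    return summary, corr


def summarize_fold_hits(table: pd.DataFrame, z_threshold: float = 2.0) -> pd.DataFrame:
    """Counts and recomputed moments of the fold-similarity results.

    Per set: total rows, rows with a structural hit, hits with Z above
    the spurious-match threshold (2 by convention), and mean/SD of Z and
    RMSD over the non-missing rows.
    """
    rows = []
    for name, g in table.groupby("set"):
        z = g["z_score"].dropna()
        r = g["rmsd"].dropna()
        rows.append(
            {
                "set": name,
                "n": len(g),
                "with_hit": int(g["hit_id"].notna().sum()),
                f"z_gt_{z_threshold:g}": int((z > z_threshold).sum()),
                "z_mean": z.mean(),
                "z_sd": z.std(ddof=1),
                "rmsd_mean": r.mean(),
                "rmsd_sd": r.std(ddof=1),
            }
        )
    return pd.DataFrame(rows).set_index("set")


def write_summary(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, index=False)
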