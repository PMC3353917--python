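"""Synthetic feature tables with the study's per-class statistics.

The original raw data (hundreds of PDB chains and tens of thousands of
ab-initio models of random 70-mers) are not redistributable; this module
stands in for them.  It packages the printed per-class means and standard
deviations of the 11 structural variables and simulates feature tables
whose marginals match them, plus a verbatim fixture of the fold-similarity
search results for the 32 misclassified and 32 correctly classified random
proteins.

Distribution shapes
-------------------
``gaussian``
    Normal(mean, sd) per variable — the default.
``skewed``
    Shifted gamma with shape k=4 (skewness 1), matched mean and sd.
``flat-wide``
    Uniform on mean ± sqrt(3)*sd (matched mean and sd) — the
    qualitative "broad, uniform-like" alternative seen in the natural
    class.

Variables are drawn independently per class; after drawing, physically
impossible values are clipped (percentages to [0, 100], the hydrophobic
surface fraction to [0, 1], counts and areas/volumes to >= 0) and clipping
events are logged.  Net charge is unbounded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .structure_features import ID_COLUMN, LABEL_COLUMN, VARIABLE_NAMES

logger = logging.getLogger(__name__)

CLASSES = ("natural", "random")
SHAPES = ("gaussian", "skewed", "flat-wide")

#: Clipping bounds per variable (lower, upper); None = unbounded.
CLIP_BOUNDS: dict[str, tuple[float | None, float | None]] = {
    "Net charge": (None, None),
    "Volume": (0.0, None),
    "Surface": (0.0, None),
    "Coil": (0.0, None),
    "Beta": (0.0, None),
    "Alpha": (0.0, None),
    "% Alpha": (0.0, 100.0),
    "% Beta": (0.0, 100.0),
    "% Coil": (0.0, 100.0),
    "% Secondary structure": (0.0, 100.0),
    "Surface hydrophobicity": (0.0, 1.0),
}

#: Summary lines printed with the fold-hit table (kept verbatim; they do
#: not exactly equal recomputed column means — report both, never force).
TABLE2_PRINTED_SUMMARY = {
    "misclassified": {"rmsd_mean": 3.2, "rmsd_sd": 0.3, "z_mean": 2.6, "z_sd": 0.9},
    "correct": {"rmsd_mean": 3.4, "rmsd_sd": 0.5, "z_mean": 1.7, "z_sd": 0.7},
}


@dataclass(frozen=True)
class ClassParams:
    """Per-class, per-variable mean and SD for the 11 structural variables."""

    table: pd.DataFrame  # columns: variable, class, mean, sd

    def __post_init__(self):
        got = set(zip(self.table["variable"], self.table["class"]))
        want = {(v, c) for v in VARIABLE_NAMES for c in CLASSES}
        if got != want:
            raise ValueError("params grid must cover 11 variables x 2 classes")
        if (self.table["sd"] <= 0).any():
            raise ValueError("all standard deviations must be positive")

    def _get(self, cls: str, variable: str) -> pd.Series:
        sel = self.table[(self.table["class"] == cls) & (self.table["variable"] == variable)]
        if sel.empty:
            raise KeyError((cls, variable))
        return sel.iloc[0]

    def mean(self, cls: str, variable: str) -> float:
        return float(self._get(cls, variable)["mean"])

    def sd(self, cls: str, variable: str) -> float:
        return float(self._get(cls, variable)["sd"])


def table1_params() -> ClassParams:
    """The packaged printed per-class means/SDs of the 11 variables."""
    with resources.files("randnat.data").joinpath("table1_params.csv").open() as fh:
        return ClassParams(pd.read_csv(fh))


def _draw(shape: str, mean: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if shape == "gaussian":
        return rng.normal(mean, sd, size=n)
    if shape == "skewed":
        k = 4.0  # gamma shape -> skewness 2/sqrt(k) = 1
        theta = sd / np.sqrt(k)
        return rng.gamma(k, theta, size=n) + (mean - k * theta)
    if shape == "flat-wide":
        half = np.sqrt(3.0) * sd
        return rng.uniform(mean - half, mean + half, size=n)
    raise ValueError(f"unknown shape {shape!r}; choose from {SHAPES}")


def simulate_feature_table(
    params: ClassParams | None = None,
    n_per_class: dict[str, int] | None = None,
    shape: str = "gaussian",
    seed: int | np.random.Generator | None = None,
    clip: bool = True,
) -> pd.DataFrame:
    """Simulate a feature table with the given per-class marginals.

    Parameters
    ----------
    params
        Per-class means/SDs; defaults to the packaged printed values.
    n_per_class
        Mapping class -> number of records, e.g. ``{"natural": 762,
        "random": 762}``.  Zero is allowed and yields an empty class.
    shape
        One of :data:`SHAPES`; applied to every variable.
    seed
        Integer seed or a ``numpy.random.Generator``.
    clip
        Apply the physical bounds of :data:`CLIP_BOUNDS` (logged).
    """
    params = table1_params() if params is None else params
    n_per_class = {"natural": 762, "random": 762} if n_per_class is None else n_per_class
    if shape not in SHAPES:
        raise ValueError(f"unknown shape {shape!r}; choose from {SHAPES}")
    for cls, n in n_per_class.items():
        if cls not in CLASSES:
            raise ValueError(f"unknown class {cls!r}")
        if n < 0:
            raise ValueError("class sizes must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    frames = []
    prefix = {"natural": "nat", "random": "rnd"}
    for cls in CLASSES:
        n = int(n_per_class.get(cls, 0))
        block = {
            ID_COLUMN: [f"{prefix[cls]}-{i:06d}" for i in range(n)],
            LABEL_COLUMN: [cls] * n,
        }
        for var in VARIABLE_NAMES:
            x = _draw(shape, params.mean(cls, var), params.sd(cls, var), n, rng)
            if clip:
                lo, hi = CLIP_BOUNDS[var]
                clipped = ((x < lo).sum() if lo is not None else 0) + (
                    (x > hi).sum() if hi is not None else 0
                )
                if clipped:
                    logger.info(
                        "clipped %d/%d draws of %r (%s class) to physical bounds",
                        clipped, n, var, cls,
                    )
                    x = np.clip(x, lo if lo is not None else -np.inf, hi if hi is not None else np.inf)
            block[var] = x
        frames.append(pd.DataFrame(block, columns=[ID_COLUMN, LABEL_COLUMN, *VARIABLE_NAMES]))
    return pd.concat(frames, ignore_index=True)


def table2_fixture() -> pd.DataFrame:
    """The packaged fold-similarity results for the two 32-protein sets.

    Columns: ``set`` (misclassified | correct), ``protein_id``, ``hit_id``
    (missing when no structural hit was found), ``rmsd`` (Å), ``z_score``.
    RMSD and Z are missing exactly when there is no hit.
    """
    with resources.files("randnat.data").joinpath("table2_fold_hits.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"protein_id": str}, na_values=["n.a."])
    df.loc[df["hit_id"] == "no chain", "hit_id"] = pd.NA
    counts = df["set"].value_counts()
    assert counts.get("misclassified") == 32 and counts.get("correct") == 32
    assert (df["hit_id"].isna() == df["rmsd"].isna()).all()
    assert (df["hit_id"].isna() == df["z_score"].isna()).all()
    return df
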