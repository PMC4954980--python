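"""Body-condition indices for bats and dietary-group statistics.

Two scaling indices are supported: the familiar body mass index
(BMI, body mass in kg over squared full body length in m) and the
forearm mass index (FMI), which substitutes forearm length for body
length.  Forearm length is measured far more often than full body
length in bats and, unlike total length, is unaffected by the presence
or absence of a tail, which makes FMI the more comparable index across
chiropteran families.

Species tables are plain pandas DataFrames with the schema

    species, diet, weight_g, body_length_mm, forearm_length_mm,
    blood_glucose_mmol_l

where the last three columns may contain missing values.  Diet labels
come from the closed set in :data:`DIET_LABELS`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DIET_LABELS = frozenset(
    {"frugivore", "insectivore", "carnivore", "omnivore", "sanguivore"}
)

#: index basis -> length column of the species table
BASIS_COLUMNS = {"bmi": "body_length_mm", "fmi": "forearm_length_mm"}

SPECIES_COLUMNS = [
    "species",
    "diet",
    "weight_g",
    "body_length_mm",
    "forearm_length_mm",
    "blood_glucose_mmol_l",
]


def mass_index(weight_g: float, length_mm: float) -> float:
    """Mass index in kg/m**2 from a weight in grams and a length in mm.

    Both BMI and FMI are mass (kg) divided by the square of a length
    (m); which length is used decides which index this is.
    """
    if not weight_g > 0:
        raise ValueError(f"weight must be positive, got {weight_g}")
    if not length_mm > 0:
        raise ValueError(f"length must be positive, got {length_mm}")
    return (weight_g / 1000.0) / (length_mm / 1000.0) ** 2


def _index_column(table: pd.DataFrame, basis: str) -> pd.Series:
    try:
        length_col = BASIS_COLUMNS[basis]
    except KeyError:
        raise ValueError(f"basis must be one of {sorted(BASIS_COLUMNS)}, got {basis!r}")
    length = pd.to_numeric(table[length_col], errors="coerce")
    weight = pd.to_numeric(table["weight_g"], errors="coerce")
    return (weight / 1000.0) / (length / 1000.0) ** 2


@dataclass(frozen=True)
class GroupSummary:
    diet: str
    n: int
    mean: float
    min: float
    max: float


def group_summary(table: pd.DataFrame, basis: str = "fmi") -> list[GroupSummary]:
    """Unweighted per-diet mean/min/max of the chosen index.

    Rows whose basis length is missing are dropped before summarising,
    so a species with only a forearm measurement still contributes to
    FMI summaries.
    """
    if len(table) == 0:
        return []
    index = _index_column(table, basis)
    out = []
    for diet, vals in index.groupby(table["diet"]):
        vals = vals.dropna()
        if len(vals) == 0:
            continue
        out.append(
            GroupSummary(
                diet=str(diet),
                n=int(len(vals)),
                mean=float(vals.mean()),
                min=float(vals.min()),
                max=float(vals.max()),
            )
        )
    return sorted(out, key=lambda s: s.diet)


def filter_small_body(
    table: pd.DataFrame,
    weight_thresh: float = 40.0,
    index_thresh: float = 8.0,
    basis: str = "fmi",
) -> tuple[int, pd.DataFrame]:
    """Species strictly below both a weight and an index threshold.

    Defaults select "small" bats: lighter than 40 g with an index below
    8 kg/m**2.  Both comparisons are strict, so a 40 g species is not
    small.  Returns the survivor count and the surviving rows.
    """
    if not (weight_thresh > 0 and index_thresh > 0):
        raise ValueError("thresholds must be positive")
    if len(table) == 0:
        return 0, table.copy()
    index = _index_column(table, basis)
    weight = pd.to_numeric(table["weight_g"], errors="coerce")
    mask = (weight < weight_thresh) & (index < index_thresh)
    mask = mask.fillna(False)
    survivors = table[mask]
    return int(mask.sum()), survivors


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t statistic, its Satterthwaite df and
    the two-tailed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    if se2 == 0.0:
        # no sampling variance at all: identical means are a perfect null
        return (0.0, float(nx + ny - 2), 1.0) if x.mean() == y.mean() else (
            math.inf,
            float(nx + ny - 2),
            0.0,
        )
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float
    df: float
    p_raw: float
    p_adj: float


@dataclass(frozen=True)
class GroupComparison:
    anova_f: float
    anova_p: float
    pairwise: list[PairwiseComparison]


def compare_groups(table: pd.DataFrame, basis: str = "fmi") -> GroupComparison:
    """One-way ANOVA across diet groups plus Tamhane T2 post hoc tests.

    Tamhane's T2 is realised as all pairwise Welch (unequal-variance)
    t-tests with a Sidak multiplicity adjustment,
    ``p_adj = 1 - (1 - p)**m`` for m pairwise comparisons.
    """
    index = _index_column(table, basis)
    groups: dict[str, np.ndarray] = {}
    for diet, vals in index.groupby(table["diet"]):
        vals = vals.dropna().to_numpy(dtype=float)
        if len(vals) > 0:
            groups[str(diet)] = vals
    if len(groups) < 2:
        raise ValueError("need at least two diet groups with data")
    for diet, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {diet!r} has n < 2")
    if all(v.var(ddof=1) == 0.0 for v in groups.values()):
        raise ValueError("all groups have zero variance; ANOVA undefined")

    f_stat, f_p = stats.f_oneway(*groups.values())
    labels = sorted(groups)
    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    pairwise = []
    for a, b in pairs:
        t, df, p = welch_t(groups[a], groups[b])
        p_adj = min(1.0, 1.0 - (1.0 - p) ** m)
        pairwise.append(PairwiseComparison(a, b, t, df, p, p_adj))
    return GroupComparison(float(f_stat), float(f_p), pairwise)


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    r: float
    r2: float
    n: int


def linfit(x: Iterable[float], y: Iterable[float]) -> FitResult:
    """Least-squares line with Pearson correlation.

    Raises if either variable is constant, since the correlation is
    then undefined.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; fit undefined")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; correlation undefined")
    res = stats.linregress(x, y)
    return FitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r2=float(res.rvalue) ** 2,
        n=len(x),
    )


def read_species_csv(path) -> pd.DataFrame:
    """Read and validate a species morphometric table."""
    table = pd.read_csv(path)
    missing = [c for c in ("species", "diet", "weight_g") if c not in table.columns]
    if missing:
        raise ValueError(f"species table missing columns: {missing}")
    bad = set(table["diet"].dropna()) - DIET_LABELS
    if bad:
        raise ValueError(f"unknown diet labels: {sorted(bad)}")
    for col in SPECIES_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    return table[SPECIES_COLUMNS]
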