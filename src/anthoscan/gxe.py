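"""Genotype × environment partitioning of anthocyanin variation.

Replicate-level measurements from a balanced two-way crossed design
(genotype × environment, here the four treatment combinations of growing
condition and growth stage) are decomposed into genotype, environment, G×E
interaction and residual components, reported as percentages of the total
variation, with Fisher's LSD letter groupings for pairwise comparisons.

Two percentage bases are offered:

``"ss"``
    share of the total sum of squares — the textbook fixed-effects partition.
``"variance_components"``
    shares of the variance components from expected mean squares
    (σ²_G : σ²_E : σ²_G×E : σ²_e, negative estimates clamped to 0) — the
    convention of multi-environment-trial reports, where the question is how
    much of the *population* variance each source contributes.

Likewise two F-test conventions: main effects against the residual mean
square (``test_against="residual"``, the fixed-effects default) or against
the G×E mean square (``"interaction"``, the multi-environment-trial
convention in which environments sampled from a target range make the
interaction the appropriate error for main effects).

The same decomposition is available directly from published cell summaries
(mean ± SD, n per cell): on a balanced design the within-cell sum of squares
is exactly Σ (n−1)·sd², so summary statistics lose nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SOURCES",
    "AnovaRow",
    "AnovaPartition",
    "LsdGrouping",
    "summarize_table",
    "two_way_anova",
    "anova_from_summaries",
    "percent_variation",
    "lsd_groups",
    "lsd_groups_from_stats",
]

SOURCES = ("genotype", "environment", "gxe", "residual")

REQUIRED_COLUMNS = ("genotype", "treatment", "value")


def _stars(p: float) -> str:
    # Convention (documented output metadata): * p<0.05, ** p<0.01, *** p<0.001.
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class AnovaRow:
    source: str
    ss: float
    df: int
    ms: float
    f: float | None
    p: float | None
    percentage: float

    @property
    def stars(self) -> str:
        return "" if self.p is None else _stars(self.p)


@dataclass(frozen=True)
class AnovaPartition:
    """Sum-of-squares decomposition of a balanced two-way crossed design."""

    rows: tuple[AnovaRow, ...]
    n_per_cell: int
    percent_of: str
    test_against: str

    def __getitem__(self, source: str) -> AnovaRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)

    @property
    def total_ss(self) -> float:
        return float(sum(row.ss for row in self.rows))

    @property
    def percentages(self) -> dict[str, float]:
        return {row.source: row.percentage for row in self.rows}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": [r.source for r in self.rows],
                "ss": [r.ss for r in self.rows],
                "df": [r.df for r in self.rows],
                "ms": [r.ms for r in self.rows],
                "F": [r.f for r in self.rows],
                "p": [r.p for r in self.rows],
                "stars": [r.stars for r in self.rows],
                "percentage": [r.percentage for r in self.rows],
            }
        )


def summarize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a replicate-level table to per-cell mean, sd (ddof=1) and n."""
    _validate_table(table)
    out = (
        table.groupby(["genotype", "treatment"], sort=True)["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return out


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"sample table missing columns {missing}")
    if not np.all(np.isfinite(table["value"].to_numpy(dtype=float))):
        raise ValueError("sample values must be finite")


def _cell_arrays(
    summary: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, int, list, list]:
    """Pivot a summary frame to (means, sds) G×E arrays; enforce balance."""
    for col in ("genotype", "treatment", "mean", "sd", "n"):
        if col not in summary.columns:
            raise ValueError(f"summary table missing column {col!r}")
    genotypes = sorted(summary["genotype"].unique())
    treatments = sorted(summary["treatment"].unique())
    ns = summary["n"].unique()
    if len(ns) != 1:
        raise ValueError("unbalanced design: unequal replicate counts per cell; "
                         "only balanced complete layouts are supported")
    n = int(ns[0])
    if n < 2:
        raise ValueError("need at least 2 replicates per cell")
    if len(summary) != len(genotypes) * len(treatments):
        raise ValueError("incomplete design: missing genotype × treatment cells")
    means = summary.pivot(index="genotype", columns="treatment", values="mean")
    sds = summary.pivot(index="genotype", columns="treatment", values="sd")
    if means.isna().any().any() or sds.isna().any().any():
        raise ValueError("incomplete design: missing genotype × treatment cells")
    return (
        means.loc[genotypes, treatments].to_numpy(dtype=float),
        sds.loc[genotypes, treatments].to_numpy(dtype=float),
        n,
        genotypes,
        treatments,
    )


def _variance_component_percentages(
    ss: dict[str, float], dfs: dict[str, int], g: int, e: int, n: int
) -> dict[str, float]:
    ms = {k: ss[k] / dfs[k] for k in SOURCES}
    comp = {
        "genotype": (ms["genotype"] - ms["gxe"]) / (e * n),
        "environment": (ms["environment"] - ms["gxe"]) / (g * n),
        "gxe": (ms["gxe"] - ms["residual"]) / n,
        "residual": ms["residual"],
    }
    comp = {k: max(v, 0.0) for k, v in comp.items()}
    total = sum(comp.values())
    if total == 0:
        raise ValueError("all variance components are zero")
    return {k: 100.0 * v / total for k, v in comp.items()}


def _build_partition(
    means: np.ndarray,
    sds: np.ndarray,
    n: int,
    percent_of: str,
    test_against: str,
) -> AnovaPartition:
    if percent_of not in ("ss", "variance_components"):
        raise ValueError(f"unknown percentage basis {percent_of!r}")
    if test_against not in ("residual", "interaction"):
        raise ValueError(f"unknown error-term convention {test_against!r}")
    g, e = means.shape
    if g < 2 or e < 2:
        raise ValueError("need at least 2 levels per factor")
    grand = means.mean()
    g_means = means.mean(axis=1)
    e_means = means.mean(axis=0)
    ss = {
        "genotype": e * n * float(((g_means - grand) ** 2).sum()),
        "environment": g * n * float(((e_means - grand) ** 2).sum()),
        "gxe": n
        * float(
            ((means - g_means[:, None] - e_means[None, :] + grand) ** 2).sum()
        ),
        "residual": float(((n - 1) * sds**2).sum()),
    }
    dfs = {
        "genotype": g - 1,
        "environment": e - 1,
        "gxe": (g - 1) * (e - 1),
        "residual": g * e * (n - 1),
    }
    ms = {k: ss[k] / dfs[k] for k in SOURCES}

    error_for = {
        "genotype": "gxe" if test_against == "interaction" else "residual",
        "environment": "gxe" if test_against == "interaction" else "residual",
        "gxe": "residual",
    }
    f_p: dict[str, tuple[float | None, float | None]] = {"residual": (None, None)}
    for source, err in error_for.items():
        if ms[err] == 0:
            f_p[source] = (float("inf") if ms[source] > 0 else 0.0,
                           0.0 if ms[source] > 0 else 1.0)
        else:
            f = ms[source] / ms[err]
            p = float(stats.f.sf(f, dfs[source], dfs[err]))
            f_p[source] = (float(f), p)

    total_ss = sum(ss.values())
    if percent_of == "ss":
        if total_ss == 0:
            pct = {k: 0.0 for k in SOURCES}
        else:
            pct = {k: 100.0 * ss[k] / total_ss for k in SOURCES}
    else:
        pct = _variance_component_percentages(ss, dfs, g, e, n)

    rows = tuple(
        AnovaRow(
            source=k, ss=ss[k], df=dfs[k], ms=ms[k],
            f=f_p[k][0], p=f_p[k][1], percentage=pct[k],
        )
        for k in SOURCES
    )
    return AnovaPartition(rows=rows, n_per_cell=n, percent_of=percent_of,
                          test_against=test_against)


def two_way_anova(
    table: pd.DataFrame,
    percent_of: str = "ss",
    test_against: str = "residual",
) -> AnovaPartition:
    """Fixed-effects two-way crossed ANOVA with interaction on raw replicates.

    Requires a balanced complete layout (every genotype × treatment cell with
    the same n ≥ 2).  On balanced data the decomposition through per-cell
    summaries is exact, so this shares its core with
    :func:`anova_from_summaries`.
    """
    summary = summarize_table(table)
    means, sds, n, _, _ = _cell_arrays(summary)
    return _build_partition(means, sds, n, percent_of, test_against)


def anova_from_summaries(
    summary: pd.DataFrame,
    percent_of: str = "ss",
    test_against: str = "residual",
) -> AnovaPartition:
    """Two-way ANOVA reconstructed from per-cell mean ± SD summaries.

    ``summary`` needs columns genotype, treatment, mean, sd, n with equal n
    across a complete grid of cells.  The residual SS is Σ (n−1)·sd²; the
    between-cell SS is decomposed from the cell means exactly as in the
    raw-data case, so the two entry points agree to machine precision on
    balanced designs.
    """
    means, sds, n, _, _ = _cell_arrays(summary)
    return _build_partition(means, sds, n, percent_of, test_against)


def percent_variation(
    partition: AnovaPartition | Mapping[str, float],
) -> AnovaPartition | dict[str, float]:
    """Percentages of total sum of squares per source.

    Accepts either an :class:`AnovaPartition` (returns a copy with SS-based
    percentages) or a plain source → SS mapping (returns source → percent).
    """
    if isinstance(partition, AnovaPartition):
        total = partition.total_ss
        if total == 0:
            raise ValueError("total sum of squares is zero")
        rows = tuple(
            replace(r, percentage=100.0 * r.ss / total) for r in partition.rows
        )
        return AnovaPartition(rows, partition.n_per_cell, "ss", partition.test_against)
    total = float(sum(partition.values()))
    if total == 0:
        raise ValueError("total sum of squares is zero")
    return {k: 100.0 * v / total for k, v in partition.items()}


@dataclass(frozen=True)
class LsdGrouping:
    """Fisher's LSD letter grouping for one factor's level means.

    Levels sharing a letter differ by at most the least significant
    difference; levels sharing no letter differ by more.
    """

    means: dict[str, float]
    letters: dict[str, str]
    lsd: float
    alpha: float
    mse: float
    df_residual: int
    n_per_group: int


def _assign_letters(ordered: list[str], means: dict[str, float], lsd: float) -> dict[str, str]:
    """Insert-and-merge letter assignment on means sorted descending.

    Every maximal run of levels whose extremes differ by ≤ LSD gets one
    letter; a level's string concatenates the letters of all runs covering
    it.  Runs contained in a larger run are dropped.
    """
    k = len(ordered)
    intervals: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and means[ordered[i]] - means[ordered[j + 1]] <= lsd:
            j += 1
        intervals.append((i, j))
    maximal = [
        (a, b)
        for a, b in intervals
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in intervals)
    ]
    maximal = sorted(set(maximal))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {name: "" for name in ordered}
    for letter, (a, b) in zip(alphabet, maximal):
        for idx in range(a, b + 1):
            letters[ordered[idx]] += letter
    return letters


def lsd_groups_from_stats(
    means: Mapping[str, float],
    mse: float,
    df_residual: int,
    n_per_group: int,
    alpha: float = 0.05,
) -> LsdGrouping:
    """LSD letter grouping from group means plus a pooled error estimate."""
    if df_residual <= 0:
        raise ValueError("residual degrees of freedom must be positive")
    if len(means) < 2:
        raise ValueError("need at least 2 groups")
    lsd = float(
        stats.t.ppf(1 - alpha / 2, df_residual) * np.sqrt(2 * mse / n_per_group)
    )
    ordered = sorted(means, key=lambda g: -means[g])
    letters = _assign_letters(ordered, dict(means), lsd)
    return LsdGrouping(
        means=dict(means), letters=letters, lsd=lsd, alpha=alpha,
        mse=float(mse), df_residual=int(df_residual), n_per_group=int(n_per_group),
    )


def lsd_groups(
    table: pd.DataFrame, factor: str = "genotype", alpha: float = 0.05
) -> LsdGrouping:
    """Fisher's LSD grouping of ``factor`` level means at level ``alpha``.

    The pooled error is the within-cell (genotype × treatment) residual when
    both factors are present, else the one-way within-group residual.
    LSD = t(1−α/2, df_res) · √(2·MSE / n), n the per-level observation count
    (equal counts required).
    """
    _validate_table(table)
    if factor not in table.columns:
        raise ValueError(f"factor column {factor!r} not in table")
    counts = table.groupby(factor)["value"].count()
    if counts.nunique() != 1:
        raise ValueError("unequal group sizes; LSD requires equal n per level")
    n_per_group = int(counts.iloc[0])
    group_means = table.groupby(factor)["value"].mean().to_dict()

    cell_cols = [c for c in ("genotype", "treatment") if c in table.columns]
    resid = table["value"] - table.groupby(cell_cols)["value"].transform("mean")
    n_cells = table.groupby(cell_cols).ngroups
    df_residual = len(table) - n_cells
    if df_residual <= 0:
        raise ValueError("no residual degrees of freedom (need replicates per cell)")
    mse = float((resid**2).sum() / df_residual)
    return lsd_groups_from_stats(group_means, mse, df_residual, n_per_group, alpha)
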