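"""Concordance and known-groups statistics.

Ordinal cross-tabulation, tie-corrected (midrank) Spearman correlation
computed directly from a contingency table, and one-way ANOVA with
Bonferroni post-hoc comparisons reconstructed from per-group summary
statistics (n, mean, SD) — algebraically identical to the raw-data
computation when the summaries are exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "GroupSummary",
    "AnovaResult",
    "PairwiseComparison",
    "crosstab",
    "spearman_from_table",
    "anova_from_summaries",
    "bonferroni_posthoc",
    "load_contingency_csv",
    "load_group_summaries",
    "table2_counts",
    "table3_summaries",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts cross-classifying two ordered ordinal variables."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-d matrix")
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError(
                f"counts shape {counts.shape} does not match labels "
                f"({len(self.row_labels)}, {len(self.col_labels)})"
            )
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def expand_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Unroll into n paired ordinal codes (row index, col index)."""
        rows, cols = [], []
        for i, j in np.ndindex(*self.counts.shape):
            c = self.counts[i, j]
            rows.extend([i] * c)
            cols.extend([j] * c)
        return np.asarray(rows), np.asarray(cols)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics (n, mean, sd) for one group."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta_squared: float
    ms_within: float
    ss_between: float
    ss_within: float


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    mean_difference: float
    se: float
    ci_low: float
    ci_high: float
    p_adjusted: float
    t: float


def crosstab(
    levels_a: Sequence,
    levels_b: Sequence,
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate paired ordinal levels (ints or ImpactLevel-likes)."""
    a = np.asarray([int(x) for x in levels_a])
    b = np.asarray([int(x) for x in levels_b])
    if a.shape != b.shape:
        raise ValueError(f"paired vectors differ in length: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("no records to tabulate")
    n_rows = (max(a.max() + 1, len(row_labels)) if row_labels else a.max() + 1)
    n_cols = (max(b.max() + 1, len(col_labels)) if col_labels else b.max() + 1)
    counts = np.zeros((n_rows, n_cols), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    rl = tuple(row_labels) if row_labels else tuple(str(i) for i in range(n_rows))
    cl = tuple(col_labels) if col_labels else tuple(str(i) for i in range(n_cols))
    return ContingencyTable(row_labels=rl, col_labels=cl, counts=counts)


def _midranks(totals: np.ndarray) -> np.ndarray:
    """Midrank of each ordered category given its marginal counts."""
    cum = np.concatenate([[0], np.cumsum(totals)])
    return cum[:-1] + (totals + 1) / 2.0


def spearman_from_table(t: ContingencyTable) -> float:
    """Tie-corrected Spearman correlation computed directly from counts.

    Assigns each ordinal category its midrank and computes the
    count-weighted Pearson correlation of the midranks — identical to
    expanding the table into n unit records and correlating their midranks.
    """
    if t.n < 2:
        raise ValueError("need at least 2 records")
    row_tot = t.row_totals.astype(float)
    col_tot = t.col_totals.astype(float)
    if np.count_nonzero(row_tot) < 2 or np.count_nonzero(col_tot) < 2:
        raise ValueError("degenerate margin: all mass in a single row or column")
    r = _midranks(row_tot)
    c = _midranks(col_tot)
    w = t.counts.astype(float)
    n = t.n
    r_mean = (row_tot @ r) / n
    c_mean = (col_tot @ c) / n
    cov = float((r - r_mean) @ w @ (c - c_mean)) / n
    var_r = float(row_tot @ (r - r_mean) ** 2) / n
    var_c = float(col_tot @ (c - c_mean) ** 2) / n
    return cov / np.sqrt(var_r * var_c)


def spearman_pvalue(rho: float, n: int) -> float:
    """Large-sample t approximation for the Spearman correlation p-value."""
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return float(2 * sps.t.sf(abs(t), df=n - 2))


def anova_from_summaries(groups: Sequence[GroupSummary]) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group (n, mean, sd).

    SSB from group sizes and means about the grand mean; SSW from
    (n-1)*sd^2.  Exact when the summaries are exact.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups], dtype=float)
    sd = np.array([g.sd for g in groups], dtype=float)
    big_n = n.sum()
    k = len(groups)
    grand_mean = float((n * m).sum() / big_n)
    ssb = float((n * (m - grand_mean) ** 2).sum())
    ssw = float(((n - 1) * sd**2).sum())
    df_b = k - 1
    df_w = int(big_n) - k
    msw = ssw / df_w
    if msw == 0:
        raise ZeroDivisionError("within-group variance is zero: F is infinite")
    f = (ssb / df_b) / msw
    p = float(sps.f.sf(f, df_b, df_w))
    eta2 = ssb / (ssb + ssw)
    return AnovaResult(F=f, df_between=df_b, df_within=df_w, p=p, eta_squared=eta2,
                       ms_within=msw, ss_between=ssb, ss_within=ssw)


def bonferroni_posthoc(
    groups: Sequence[GroupSummary],
    alpha: float = 0.05,
    m: int | None = None,
) -> list[PairwiseComparison]:
    """All pairwise comparisons with Bonferroni-adjusted p-values and CIs.

    Uses the pooled within-group variance (ANOVA MSW) with df = N - g.
    p_adjusted = min(1, m * p_raw); the CI uses the adjusted critical value
    t_{df, alpha/(2m)}, so CI width grows with the comparison count.
    """
    res = anova_from_summaries(groups)
    if m is None:
        m = len(groups) * (len(groups) - 1) // 2
    df = res.df_within
    t_crit = float(sps.t.ppf(1.0 - alpha / (2.0 * m), df))
    out = []
    for gi, gj in itertools.combinations(groups, 2):
        diff = gi.mean - gj.mean
        se = float(np.sqrt(res.ms_within * (1.0 / gi.n + 1.0 / gj.n)))
        t = diff / se
        p_adj = min(1.0, m * float(2 * sps.t.sf(abs(t), df)))
        out.append(PairwiseComparison(
            pair=(gi.label, gj.label),
            mean_difference=diff,
            se=se,
            ci_low=diff - t_crit * se,
            ci_high=diff + t_crit * se,
            p_adjusted=p_adj,
            t=t,
        ))
    return out


# ---------------------------------------------------------------------------
# Fixtures and I/O


def load_contingency_csv(path: str | Path) -> ContingencyTable:
    """Read a counts CSV whose first column holds row labels."""
    df = pd.read_csv(path, index_col=0)
    return ContingencyTable(
        row_labels=tuple(str(i) for i in df.index),
        col_labels=tuple(str(c) for c in df.columns),
        counts=df.to_numpy(dtype=np.int64),
    )


def load_group_summaries(path: str | Path) -> list[GroupSummary]:
    """Read a summaries CSV with columns label, n, mean, sd."""
    df = pd.read_csv(path)
    return [
        GroupSummary(label=str(r["label"]), n=int(r["n"]), mean=float(r["mean"]),
                     sd=float(r["sd"]))
        for _, r in df.iterrows()
    ]


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("impactlevels").joinpath("data", name)))


def table2_counts() -> ContingencyTable:
    """Bundled 4x4 cross-classification fixture (bookmark rubric x GCPS-R)."""
    return load_contingency_csv(_fixture_path("table2_counts.csv"))


def table3_summaries() -> list[GroupSummary]:
    """Bundled per-group T-score summaries (n, mean, sd) for known-groups ANOVA."""
    return load_group_summaries(_fixture_path("table3_summaries.csv"))
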