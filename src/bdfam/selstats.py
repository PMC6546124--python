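"""Selection-test post-processing and group comparisons.

Branch-site tests for positive selection compare a null codon model
(foreground ω fixed to 1) against an alternative allowing ω > 1 on
specified branches.  This module consumes the resulting per-hypothesis
log-likelihood pairs: it forms the likelihood-ratio statistic
−2Δln L = 2(lnL_alt − lnL_null), converts it to an upper-tail χ²
probability, and applies the step-down Holm–Bonferroni correction across
hypotheses.  Branch-site parameter estimates (p0, p1, p2a, p2b, ω0, ω1,
ω2) are carried through as metadata, validated for range but never used
in computation.

It also provides the two-sample t-test used to compare branch-length
statistics (CBL, normalized CBL, cumulative patristic distance) between
stable and unstable clades.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .family_events import StabilityCall
from .treestats import CladeBranchStats

__all__ = [
    "LRTRecord",
    "GroupComparison",
    "lrt",
    "chi2_sf",
    "holm_bonferroni",
    "two_sample_t",
    "compare_groups",
    "process_lrt_table",
    "read_lrt_table",
]

# branch-site metadata: (column, lower bound, upper bound); proportions sum
# is not checked because printed values are rounded
_METADATA_RANGES = {
    "p0": (0.0, 1.0),
    "p1": (0.0, 1.0),
    "p2a": (0.0, 1.0),
    "p2b": (0.0, 1.0),
    "w0": (0.0, math.inf),
    "w1": (0.0, math.inf),
    "w2": (0.0, math.inf),
}


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail probability of the χ² distribution with ``df`` degrees."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("chi-squared statistic must be nonnegative")
    return sps.chi2.sf(x, df)[()]


def lrt(lnl_null: float, lnl_alt: float, df: int = 1) -> tuple[float, float]:
    """Likelihood-ratio statistic and raw χ² P value.

    The statistic is 2(lnL_alt − lnL_null).  A negative value (the
    alternative converged below the null, which happens with real
    optimizer output) is clamped to 0 with a warning rather than raised.
    """
    if not (math.isfinite(lnl_null) and math.isfinite(lnl_alt)):
        raise ValueError("log-likelihoods must be finite")
    stat = 2.0 * (lnl_alt - lnl_null)
    if stat < 0:
        warnings.warn(
            f"alternative lnL ({lnl_alt}) below null ({lnl_null}); "
            "clamping LRT statistic to 0",
            stacklevel=2,
        )
        stat = 0.0
    return stat, float(chi2_sf(stat, df))


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Step-down Holm–Bonferroni corrected P values, in input order.

    The i-th smallest raw P is multiplied by (m − i + 1) and a running
    maximum enforces monotonicity in the sorted order (so the largest raw
    value can be lifted above m×p itself); results are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("need a one-dimensional, nonempty list of P values")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("P values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass(frozen=True)
class LRTRecord:
    """One processed branch-site likelihood-ratio test."""

    label: str
    lnl_null: float
    lnl_alt: float
    df: int
    stat: float
    p_raw: float
    p_holm: float
    clamped: bool = False
    metadata: Mapping[str, float] = field(default_factory=dict, hash=False)

    def __post_init__(self):
        if self.stat < 0:
            raise ValueError("LRT statistic must be nonnegative")
        if not 0 <= self.p_raw <= 1 or not 0 <= self.p_holm <= 1:
            raise ValueError("P values must lie in [0, 1]")
        if self.p_holm < self.p_raw - 1e-15:
            raise ValueError("corrected P cannot be below raw P")


def _validate_metadata(df: pd.DataFrame) -> None:
    for col, (lo, hi) in _METADATA_RANGES.items():
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="raise")
            ok = vals.isna() | ((vals >= lo) & (vals <= hi))
            if not ok.all():
                bad = df.loc[~ok, "label"].tolist()
                raise ValueError(f"column {col!r} out of range for rows {bad}")


def read_lrt_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("label", "lnL_null", "lnL_alt"):
        if col not in df.columns:
            raise ValueError(f"LRT table lacks column {col!r}")
    if "df" not in df.columns:
        df["df"] = 1
    return df


def process_lrt_table(table: pd.DataFrame) -> tuple[pd.DataFrame, list[LRTRecord]]:
    """Add ``stat``, ``p_raw`` and ``p_holm`` columns to an LRT table.

    The Holm correction is applied across all rows of the table — the
    family of hypotheses is the table.
    """
    _validate_metadata(table)
    out = table.copy()
    stats_, praw, clamped = [], [], []
    for _, row in out.iterrows():
        raw_stat = 2.0 * (float(row["lnL_alt"]) - float(row["lnL_null"]))
        s, p = lrt(float(row["lnL_null"]), float(row["lnL_alt"]), int(row["df"]))
        stats_.append(s)
        praw.append(p)
        clamped.append(raw_stat < 0)
    out["stat"] = stats_
    out["p_raw"] = praw
    out["p_holm"] = holm_bonferroni(praw)
    meta_cols = [c for c in _METADATA_RANGES if c in table.columns]
    records = [
        LRTRecord(
            label=str(row["label"]),
            lnl_null=float(row["lnL_null"]),
            lnl_alt=float(row["lnL_alt"]),
            df=int(row["df"]),
            stat=float(row["stat"]),
            p_raw=float(row["p_raw"]),
            p_holm=float(row["p_holm"]),
            clamped=bool(cl),
            metadata={c: row[c] for c in meta_cols},
        )
        for (_, row), cl in zip(out.iterrows(), clamped)
    ]
    return out, records


# -- group comparison -----------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample t-test summary for one branch-length metric."""

    metric: str
    group_labels: tuple[str, str]
    group_sizes: tuple[int, int]
    group_means: tuple[float, float]
    t: float
    df: float
    p: float
    flavor: str

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "flavor": self.flavor,
            "groups": {
                label: {"n": n, "mean": m}
                for label, n, m in zip(
                    self.group_labels, self.group_sizes, self.group_means
                )
            },
            "t": self.t,
            "df": self.df,
            "p": self.p,
        }


def two_sample_t(
    a: Sequence[float],
    b: Sequence[float],
    flavor: str = "student_pooled",
    metric: str = "value",
    labels: tuple[str, str] = ("a", "b"),
) -> GroupComparison:
    """Two-sided two-sample t-test (pooled-variance Student or Welch)."""
    if flavor not in ("student_pooled", "welch"):
        raise ValueError(f"unknown t-test flavor {flavor!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if flavor == "student_pooled" and np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        raise ValueError("pooled variance is zero; t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=(flavor == "student_pooled"))
    return GroupComparison(
        metric=metric,
        group_labels=labels,
        group_sizes=(int(a.size), int(b.size)),
        group_means=(float(a.mean()), float(b.mean())),
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        flavor=flavor,
    )


def compare_groups(
    stats: Sequence[CladeBranchStats],
    calls: Sequence[StabilityCall],
    metric: str = "cbl",
    flavor: str = "student_pooled",
) -> GroupComparison:
    """Compare a branch-length metric between stable and unstable clades."""
    if metric not in ("cbl", "normalized_cbl", "cpd"):
        raise ValueError(f"unknown metric {metric!r}")
    status = {c.clade_id: c.status for c in calls}
    missing = sorted({s.clade_id for s in stats} - set(status))
    if missing:
        raise ValueError(f"clades without a stability call: {missing}")
    groups: dict[str, list[float]] = {"stable": [], "unstable": []}
    for s in stats:
        groups[status[s.clade_id]].append(getattr(s, metric))
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(
                f"group {name!r} has {len(vals)} clade(s); need at least 2"
            )
    return two_sample_t(
        groups["stable"],
        groups["unstable"],
        flavor=flavor,
        metric=metric,
        labels=("stable", "unstable"),
    )
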