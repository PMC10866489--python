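"""Distribution summaries and nonparametric two-sample comparisons.

Completeness distributions are summarized with the statistics a violin plot
displays (median, interquartile range, central 95% data interval) and
compared pairwise with the Mann-Whitney U test (location) and the two-sample
Kolmogorov-Smirnov test (distribution shape).  Because each results panel
runs many pairwise comparisons, significance is assessed against a
Bonferroni-adjusted α = 0.05/m within the panel's comparison family; the
family is one panel and is never pooled across panels.

Test computations are delegated to scipy.stats; method tags record whether
the Mann-Whitney p-value came from exact enumeration or the tie-corrected
normal approximation, so small discrepancies against other software are
auditable.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

BASE_ALPHA = 0.05

#: Largest n_x·n_y for which the exact Mann-Whitney null is enumerated.
EXACT_MW_LIMIT = 400


class ComparisonError(ValueError):
    pass


@dataclass(frozen=True)
class DistributionSummary:
    """Violin-plot statistics for one group of CCM2 percentages.

    The "95% interval" is the central 95% data interval (2.5th–97.5th
    percentiles) of the sample, not a standard-error-based interval.
    """

    label: str
    n: int
    median: float
    q1: float
    q3: float
    lo95: float
    hi95: float
    sample: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.q1 <= self.median <= self.q3:
            raise ComparisonError("quartiles out of order")


def summarize_distribution(
    scores: Sequence[float], label: str
) -> DistributionSummary:
    """Summary statistics with linear-interpolation quantiles."""
    if len(scores) == 0:
        raise ComparisonError(f"group {label!r} is empty")
    arr = np.sort(np.asarray(scores, dtype=float))
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    lo, hi = np.percentile(arr, [2.5, 97.5])
    return DistributionSummary(
        label=label,
        n=len(arr),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        lo95=float(lo),
        hi95=float(hi),
        sample=tuple(arr),
    )


@dataclass(frozen=True)
class ComparisonResult:
    """One pairwise two-sample comparison (Mann-Whitney U + KS D)."""

    label_x: str
    label_y: str
    n_x: int
    n_y: int
    u_stat: float
    p_mw: float
    d_stat: float
    p_ks: float
    mw_method: str  # "exact" | "approximate"
    ks_method: str = "approximate"
    p_mw_exact: float | None = None
    p_mw_approx: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.u_stat <= self.n_x * self.n_y:
            raise ComparisonError("U outside [0, n_x·n_y]")
        if not 0 <= self.d_stat <= 1:
            raise ComparisonError("D outside [0, 1]")

    def swapped(self) -> "ComparisonResult":
        return ComparisonResult(
            label_x=self.label_y,
            label_y=self.label_x,
            n_x=self.n_y,
            n_y=self.n_x,
            u_stat=self.n_x * self.n_y - self.u_stat,
            p_mw=self.p_mw,
            d_stat=self.d_stat,
            p_ks=self.p_ks,
            mw_method=self.mw_method,
            ks_method=self.ks_method,
            p_mw_exact=self.p_mw_exact,
            p_mw_approx=self.p_mw_approx,
        )


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    label_x: str = "x",
    label_y: str = "y",
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    The p-value is exact (full enumeration of the null permutation
    distribution of U) when n_x·n_y ≤ 400 and the pooled sample is tie-free;
    otherwise the tie-corrected normal approximation with continuity
    correction is used.  Both p-values are retained when both are
    computable; KS fields are zeroed (use :func:`ks_two_sample` or
    :func:`compare_pair`).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) == 0 or len(ya) == 0:
        raise ComparisonError("both samples must be nonempty")
    ties = _has_ties(xa, ya)
    exact_ok = (len(xa) * len(ya) <= EXACT_MW_LIMIT) and not ties
    p_exact = None
    if exact_ok:
        res_exact = stats.mannwhitneyu(
            xa, ya, alternative="two-sided", method="exact"
        )
        p_exact = float(res_exact.pvalue)
    res_approx = stats.mannwhitneyu(
        xa, ya, alternative="two-sided", method="asymptotic",
        use_continuity=True,
    )
    p_approx = float(res_approx.pvalue)
    u = float(res_approx.statistic)
    method = "exact" if exact_ok else "approximate"
    return ComparisonResult(
        label_x=label_x,
        label_y=label_y,
        n_x=len(xa),
        n_y=len(ya),
        u_stat=u,
        p_mw=p_exact if exact_ok else p_approx,
        d_stat=0.0,
        p_ks=1.0,
        mw_method=method,
        p_mw_exact=p_exact,
        p_mw_approx=p_approx,
    )


def ks_two_sample(
    x: Sequence[float],
    y: Sequence[float],
    label_x: str = "x",
    label_y: str = "y",
) -> ComparisonResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D is the supremum over observed points of |ECDF_x − ECDF_y|; the
    p-value uses the asymptotic Kolmogorov distribution at effective
    sample size n_x·n_y/(n_x+n_y).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) == 0 or len(ya) == 0:
        raise ComparisonError("both samples must be nonempty")
    res = stats.ks_2samp(xa, ya, alternative="two-sided", method="asymp")
    return ComparisonResult(
        label_x=label_x,
        label_y=label_y,
        n_x=len(xa),
        n_y=len(ya),
        u_stat=0.0,
        p_mw=1.0,
        d_stat=float(res.statistic),
        p_ks=float(res.pvalue),
        mw_method="approximate",
        ks_method="approximate",
    )


def compare_pair(
    x: Sequence[float],
    y: Sequence[float],
    label_x: str = "x",
    label_y: str = "y",
) -> ComparisonResult:
    """Both tests on one pair, merged into a single result row."""
    mw = mann_whitney(x, y, label_x, label_y)
    ks = ks_two_sample(x, y, label_x, label_y)
    return ComparisonResult(
        label_x=label_x,
        label_y=label_y,
        n_x=mw.n_x,
        n_y=mw.n_y,
        u_stat=mw.u_stat,
        p_mw=mw.p_mw,
        d_stat=ks.d_stat,
        p_ks=ks.p_ks,
        mw_method=mw.mw_method,
        ks_method=ks.ks_method,
        p_mw_exact=mw.p_mw_exact,
        p_mw_approx=mw.p_mw_approx,
    )


@dataclass
class ComparisonFamily:
    """All pairwise comparisons of one results panel, Bonferroni-corrected."""

    comparisons: list[ComparisonResult]
    alpha: float = BASE_ALPHA

    @property
    def m(self) -> int:
        return len(self.comparisons)

    @property
    def adjusted_alpha(self) -> float:
        return self.alpha / self.m if self.m else self.alpha

    def significant_mw(self) -> list[bool]:
        return [c.p_mw < self.adjusted_alpha for c in self.comparisons]

    def significant_ks(self) -> list[bool]:
        return [c.p_ks < self.adjusted_alpha for c in self.comparisons]

    def any_significant(self) -> bool:
        return any(self.significant_mw()) or any(self.significant_ks())

    def to_rows(self) -> list[dict]:
        rows = []
        for c, sig_mw, sig_ks in zip(
            self.comparisons, self.significant_mw(), self.significant_ks()
        ):
            rows.append(
                {
                    "group_x": c.label_x,
                    "group_y": c.label_y,
                    "n_x": c.n_x,
                    "n_y": c.n_y,
                    "U": c.u_stat,
                    "p_mw": c.p_mw,
                    "mw_method": c.mw_method,
                    "D": c.d_stat,
                    "p_ks": c.p_ks,
                    "ks_method": c.ks_method,
                    "m": self.m,
                    "adjusted_alpha": self.adjusted_alpha,
                    "significant_mw": sig_mw,
                    "significant_ks": sig_ks,
                }
            )
        return rows


def run_family(
    groups: Sequence[tuple[str, Sequence[float]]],
    alpha: float = BASE_ALPHA,
) -> ComparisonFamily:
    """All C(k, 2) pairwise comparisons among k groups as one family."""
    if len(groups) < 2:
        raise ComparisonError("a comparison family needs at least two groups")
    for label, scores in groups:
        if len(scores) == 0:
            raise ComparisonError(f"group {label!r} is empty")
    comparisons = [
        compare_pair(sx, sy, lx, ly)
        for (lx, sx), (ly, sy) in itertools.combinations(groups, 2)
    ]
    return ComparisonFamily(comparisons=comparisons, alpha=alpha)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def summaries_to_rows(
    summaries: Iterable[DistributionSummary],
) -> list[dict]:
    return [
        {
            "group": s.label,
            "n": s.n,
            "median": s.median,
            "q1": s.q1,
            "q3": s.q3,
            "lo95": s.lo95,
            "hi95": s.hi95,
            "interval_kind": "central 95% data interval (2.5–97.5 pct)",
        }
        for s in summaries
    ]


def export_family(
    family: ComparisonFamily,
    summaries: Sequence[DistributionSummary],
    csv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Write one panel's comparisons + summaries as CSV (and JSON mirror)."""
    import pandas as pd

    rows = family.to_rows()
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            "comparisons": rows,
            "summaries": summaries_to_rows(summaries),
            "alpha": family.alpha,
            "m": family.m,
            "adjusted_alpha": family.adjusted_alpha,
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))
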