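"""Group comparisons relating niche metrics to invasiveness and range traits.

Thin wrappers around the standard non-parametric tests (Kruskal–Wallis,
Pearson chi-squared on counts, Dunn post-hoc with Benjamini–Hochberg
correction, Kendall tau-b) that return a uniform :class:`TestReport`, plus
the occurrence-count sensitivity check used to confirm that sample size
does not drive the niche metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .niche_metrics import bh_adjust


@dataclass
class TestReport:
    method: str
    statistic: float | None
    df: float | None
    p: float | None
    group_sizes: dict[str, int] = field(default_factory=dict)
    pairwise: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "group_sizes": self.group_sizes,
        }
        if self.pairwise is not None:
            d["pairwise"] = self.pairwise.to_dict(orient="records")
        if self.extra:
            d["extra"] = self.extra
        return d


def _split_groups(values, groups) -> dict:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        out[g] = values[groups == g]
        if len(out[g]) == 0:
            raise ValueError(f"group {g!r} has no observations")
    return out


def kruskal_wallis(values, groups) -> TestReport:
    """Tie-corrected Kruskal–Wallis H with a chi-squared reference."""
    by = _split_groups(values, groups)
    if len(by) < 2:
        raise ValueError("need at least 2 groups")
    samples = list(by.values())
    if len(np.unique(np.concatenate(samples))) == 1:
        # all observations tied: no evidence against equality
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*samples)
    return TestReport(
        method="kruskal_wallis",
        statistic=float(h),
        df=len(by) - 1,
        p=float(p),
        group_sizes={str(g): len(v) for g, v in by.items()},
    )


def chi_squared_counts(table) -> TestReport:
    """Pearson chi-squared on an r x c count table (no continuity correction)."""
    T = np.asarray(table, dtype=float)
    if (T < 0).any() or T.sum() == 0:
        raise ValueError("counts must be non-negative with a positive total")
    if (T.sum(axis=0) == 0).any() or (T.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    res = stats.chi2_contingency(T, correction=False)
    return TestReport(
        method="chi_squared",
        statistic=float(res.statistic),
        df=float(res.dof),
        p=float(res.pvalue),
        group_sizes={"total": int(T.sum())},
    )


def dunn_posthoc(values, groups) -> TestReport:
    """Dunn's post-hoc test on pooled ranks, BH-adjusted across pairs.

    z_ij = (rbar_i - rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with
    the tie term T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p.
    """
    by = _split_groups(values, groups)
    if len(by) < 3:
        raise ValueError("Dunn post-hoc needs >= 3 groups; use kruskal_wallis")
    pooled = np.concatenate(list(by.values()))
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12.0 * (N - 1))
    mean_rank, sizes = {}, {}
    start = 0
    for g, v in by.items():
        mean_rank[g] = ranks[start : start + len(v)].mean()
        sizes[g] = len(v)
        start += len(v)
    rows = []
    for a, b in combinations(by.keys(), 2):
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": str(a), "group_b": str(b), "z": float(z), "p": float(p)})
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(np.clip(table["p"].to_numpy(), np.finfo(float).tiny, 1.0))
    return TestReport(
        method="dunn",
        statistic=None,
        df=None,
        p=None,
        group_sizes={str(g): n for g, n in sizes.items()},
        pairwise=table,
    )


def kendall_tau(x, y) -> TestReport:
    """Kendall tau-b with two-sided p (exact enumeration for small n, no ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 pairs")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        raise ValueError("constant vector: tau undefined")
    has_ties = len(np.unique(x)) < len(x) or len(np.unique(y)) < len(y)
    method = "exact" if (len(x) <= 8 and not has_ties) else "asymptotic"
    res = stats.kendalltau(x, y, method=method)
    return TestReport(
        method="kendall_tau_b",
        statistic=float(res.statistic),
        df=None,
        p=float(res.pvalue),
        group_sizes={"n": len(x)},
    )


def occurrence_sensitivity(table: pd.DataFrame) -> dict:
    """QC block: does the number of native occurrences drive the results?

    Returns the Kendall correlation of D with n_native and the
    Kruskal–Wallis comparison of n_native across expansion classes; marked
    not computable for degenerate inputs (fewer than 3 species, constant
    metrics, or a single expansion class).
    """
    out: dict = {"computable": True}
    try:
        out["d_vs_n_native"] = kendall_tau(
            table["n_native"].to_numpy(), table["D"].to_numpy()
        ).to_dict()
    except ValueError as exc:
        out["computable"] = False
        out["d_vs_n_native"] = {"error": str(exc)}
    try:
        if table["expansion_class"].nunique() < 2:
            raise ValueError("only one expansion class present")
        out["n_native_by_expansion_class"] = kruskal_wallis(
            table["n_native"].to_numpy(), table["expansion_class"].to_numpy()
        ).to_dict()
    except ValueError as exc:
        out["computable"] = False
        out["n_native_by_expansion_class"] = {"error": str(exc)}
    return out
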