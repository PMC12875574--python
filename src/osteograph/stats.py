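"""Two-group comparison of per-image network metrics.

Groups (e.g. young vs aged fields of view) are compared per metric with a
two-sided Mann-Whitney U test at alpha = 0.05: the exact permutation null
is used for small samples without ties (combined n <= 20), the normal
approximation with tie correction and continuity correction otherwise.
The U statistic is reported as min(U_x, U_y).  Group-level percentage
changes are reported descriptively (they are single values, so no test is
attached to them), with the convention that a positive percentage is a
decrease relative to the reference group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectomics import ConnectomicsMetrics
from .errors import UndefinedValueError, ValidationError

__all__ = [
    "GroupComparison",
    "mann_whitney_u",
    "percent_change",
    "compare_cohorts",
    "comparisons_to_frame",
    "significance_stars",
]

ALPHA = 0.05
EXACT_LIMIT = 20  # combined sample size up to which the exact null is used


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p) with U = min(U_x, U_y).

    The exact permutation distribution is used when the combined sample
    size is <= 20 and there are no ties; otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    exact = (x.size + y.size) <= EXACT_LIMIT and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=not exact,
    )
    u_x = float(res.statistic)
    u = min(u_x, x.size * y.size - u_x)
    return u, float(min(res.pvalue, 1.0))


def percent_change(mean_reference: float, mean_other: float) -> float:
    """100 x (reference - other) / reference: positive means a decrease
    relative to the reference group."""
    if mean_reference == 0:
        raise UndefinedValueError("percent change is undefined for a zero reference mean")
    return 100.0 * (mean_reference - mean_other) / mean_reference


def significance_stars(p: float, alpha: float = ALPHA) -> str:
    """Figure-style star notation: **** (p<1e-4), * (p<alpha), n.s."""
    if p < 1e-4:
        return "****"
    if p < alpha:
        return "*"
    return "n.s."


@dataclass
class GroupComparison:
    metric_name: str
    group_a_values: np.ndarray
    group_b_values: np.ndarray
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    u_statistic: float
    p_value: float
    significant: bool
    percent_change: Optional[float]  # None when the reference mean is zero
    stars: str


def _extract(metrics: Sequence[ConnectomicsMetrics], name: str) -> np.ndarray:
    try:
        return np.array([getattr(m, name) for m in metrics], dtype=float)
    except AttributeError as exc:
        raise ValidationError(f"unknown metric {name!r}") from exc


def compare_cohorts(
    metrics_a: Sequence[ConnectomicsMetrics],
    metrics_b: Sequence[ConnectomicsMetrics],
    metric_names: Sequence[str] | None = None,
    alpha: float = ALPHA,
    holm: bool = False,
) -> list[GroupComparison]:
    """One GroupComparison per metric (default: all six network metrics).

    Group a is the reference for the percentage change.  ``holm=True``
    applies a Holm step-down correction across the requested metrics
    (off by default: each metric is reported at its own alpha).
    """
    if len(metrics_a) < 2 or len(metrics_b) < 2:
        raise ValidationError("need at least 2 images per group")
    names = list(metric_names) if metric_names is not None else list(ConnectomicsMetrics._FIELDS)
    raw = []
    for name in names:
        a = _extract(metrics_a, name)
        b = _extract(metrics_b, name)
        u, p = mann_whitney_u(a, b)
        raw.append((name, a, b, u, p))
    pvals = np.array([r[4] for r in raw])
    if holm:
        order = np.argsort(pvals)
        adj = np.empty_like(pvals)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (len(pvals) - rank) * pvals[idx])
            adj[idx] = min(running, 1.0)
        pvals = adj
    out = []
    for (name, a, b, u, _), p in zip(raw, pvals):
        mean_a = float(a.mean())
        pc = percent_change(mean_a, float(b.mean())) if mean_a != 0 else None
        out.append(
            GroupComparison(
                metric_name=name,
                group_a_values=a,
                group_b_values=b,
                mean_a=mean_a,
                sd_a=float(a.std(ddof=1)),
                mean_b=float(b.mean()),
                sd_b=float(b.std(ddof=1)),
                u_statistic=u,
                p_value=float(p),
                significant=bool(p < alpha),
                percent_change=pc,
                stars=significance_stars(p, alpha),
            )
        )
    return out


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """CSV-ready summary: mean +/- SD per group, U, p, stars, % change."""
    return pd.DataFrame(
        [
            {
                "metric": c.metric_name,
                "mean_a": c.mean_a,
                "sd_a": c.sd_a,
                "mean_b": c.mean_b,
                "sd_b": c.sd_b,
                "u_statistic": c.u_statistic,
                "p_value": c.p_value,
                "significant": c.significant,
                "stars": c.stars,
                "percent_change": c.percent_change,
            }
            for c in comparisons
        ]
    )
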