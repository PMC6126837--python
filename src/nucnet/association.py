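"""Correlation-based validation of inferred inter-nucleosome interactions.

For an inferred edge Mark-A -> Mark-B, nucleosome pairs are ranked by the
Mark-A signal at the "before" nucleosome (descending), grouped into
consecutive bins of 100 pairs, and the Pearson coefficient is computed
across the bin means of Mark-A(before) and Mark-B(after). Pairs with both
values zero are excluded beforehand; nonlinear couplings are probed by
log-transforming Mark-A (log10(x+1)) before ranking and averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass(frozen=True)
class BinnedCorrelationResult:
    mark_a: str
    mark_b: str
    bin_means_a: tuple[float, ...]
    bin_means_b: tuple[float, ...]
    coefficient: float  # NaN when undefined (e.g. constant bin means)
    transform: str  # linear | logA
    n_pairs_used: int


@dataclass(frozen=True)
class GroupRegressionResult:
    groups: int
    x_means: tuple[float, ...]
    y_means: tuple[float, ...]
    slope: float
    adjusted_r2: float
    p_value: float


def _pair_values(
    pairs, matrix: pd.DataFrame, mark_a: str, mark_b: str, b_at: str
) -> tuple[np.ndarray, np.ndarray]:
    a = np.array(
        [matrix.at[p.before.nucleosome.id, mark_a] for p in pairs], dtype=float
    )
    which = {"after": lambda p: p.after, "before": lambda p: p.before}[b_at]
    b = np.array(
        [matrix.at[which(p).nucleosome.id, mark_b] for p in pairs], dtype=float
    )
    return a, b


def _binned(
    a: np.ndarray,
    b: np.ndarray,
    mark_a: str,
    mark_b: str,
    bin_size: int,
    log_a: bool,
) -> BinnedCorrelationResult:
    keep = (a != 0) | (b != 0)
    a, b = a[keep], b[keep]
    if log_a:
        a = np.log10(a + 1.0)
    n_bins = len(a) // bin_size
    if n_bins < 2:
        raise ValueError(
            f"only {len(a)} usable pairs -> {n_bins} full bin(s); need >= 2"
        )
    # stable descending rank by Mark-A at the before nucleosome
    order = np.argsort(-a, kind="stable")
    a, b = a[order], b[order]
    used = n_bins * bin_size
    ma = a[:used].reshape(n_bins, bin_size).mean(axis=1)
    mb = b[:used].reshape(n_bins, bin_size).mean(axis=1)
    if np.ptp(ma) == 0 or np.ptp(mb) == 0:
        coef = float("nan")  # correlation undefined on constant bin means
    else:
        coef = float(stats.pearsonr(ma, mb)[0])
    return BinnedCorrelationResult(
        mark_a=mark_a,
        mark_b=mark_b,
        bin_means_a=tuple(map(float, ma)),
        bin_means_b=tuple(map(float, mb)),
        coefficient=coef,
        transform="logA" if log_a else "linear",
        n_pairs_used=used,
    )


def binned_correlation(
    pairs,
    matrix: pd.DataFrame,
    mark_a: str,
    mark_b: str,
    bin_size: int = 100,
    log_a: bool = False,
) -> BinnedCorrelationResult:
    """Binned Pearson correlation of Mark-A at "before" vs Mark-B at "after"
    nucleosomes.

    A pair enters the analysis iff Mark-A(before) or Mark-B(after) is
    nonzero. The final partial bin is dropped. With ``bin_size=1`` the result
    equals the plain pairwise Pearson coefficient on the filtered pairs.
    """
    a, b = _pair_values(pairs, matrix, mark_a, mark_b, b_at="after")
    return _binned(a, b, mark_a, mark_b, bin_size, log_a)


def onsite_correlation(
    pairs,
    matrix: pd.DataFrame,
    mark_a: str,
    mark_b: str,
    bin_size: int = 100,
    log_a: bool = False,
) -> BinnedCorrelationResult:
    """As :func:`binned_correlation` but with Mark-B read at the same
    "before" nucleosome — the on-site baseline an inter-nucleosomal coupling
    is compared against."""
    a, b = _pair_values(pairs, matrix, mark_a, mark_b, b_at="before")
    return _binned(a, b, mark_a, mark_b, bin_size, log_a)


def cross_group_regression(
    ranking_value, x, y, groups: int = 10
) -> GroupRegressionResult:
    """Regress a per-group y metric on a per-group x metric across
    rank-defined groups.

    Anchors are ranked by ``ranking_value`` (descending, e.g. expression
    level) and divided into ``groups`` equal parts (remainder spread over
    the leading groups); per-group means of x and y are fit by ordinary
    least squares y ~ x. Reports the slope, the adjusted R² =
    1 - (1-R²)(g-1)/(g-2), and the two-sided slope p-value.
    """
    if groups < 3:
        raise ValueError("need at least 3 groups")
    r = np.asarray(ranking_value, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(r) == len(x) == len(y)):
        raise ValueError("ranking_value, x, y must have equal length")
    if len(r) < groups:
        raise ValueError("fewer anchors than groups")
    order = np.argsort(-r, kind="stable")
    idx_groups = np.array_split(order, groups)
    xm = np.array([x[g].mean() for g in idx_groups])
    ym = np.array([y[g].mean() for g in idx_groups])
    model = sm.OLS(ym, sm.add_constant(xm)).fit()
    r2 = float(model.rsquared)
    adj = 1.0 - (1.0 - r2) * (groups - 1) / (groups - 2)
    return GroupRegressionResult(
        groups=groups,
        x_means=tuple(map(float, xm)),
        y_means=tuple(map(float, ym)),
        slope=float(model.params[1]),
        adjusted_r2=float(adj),
        p_value=float(model.pvalues[1]),
    )
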