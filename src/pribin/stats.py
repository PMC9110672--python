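"""Two-group comparison of engineered features.

The comparison is the non-parametric Mann-Whitney U test: exact two-sided
p-values for small, tie-free samples (total n <= 20) and a normal
approximation with tie and continuity corrections otherwise.  Significance is
star-coded at the conventional thresholds (* p<=0.05, ** p<=0.01,
*** p<=0.001, **** p<=0.0001).  P-values are reported unadjusted — matching
standard practice for small cytometry cohorts — with a Benjamini-Hochberg
column added as a clearly labelled extension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError

__all__ = ["GroupComparison", "mann_whitney", "star_code", "compare_groups"]

EXACT_MAX_TOTAL_N = 20


@dataclass(frozen=True)
class GroupComparison:
    """Result of one feature's two-group Mann-Whitney comparison."""

    feature: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    u_statistic: float
    p_value: float
    stars: str
    n_missing: int = 0


def _clean(values, label: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if not finite.all():
        warnings.warn(
            f"dropping {int((~finite).sum())} missing value(s) from group {label}",
            stacklevel=3,
        )
    arr = arr[finite]
    if arr.size == 0:
        raise ConfigError(f"group {label} is empty after missing-value removal")
    return arr


def mann_whitney(a, b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` with U the statistic of the first sample (so that
    swapping groups maps U to ``n_a*n_b - U``).  ``mode='exact'`` forces the
    exact null distribution; ``'auto'`` uses it when there are no ties and
    ``n_a + n_b <= 20``, falling back to the tie-corrected normal
    approximation with continuity correction.
    """
    if mode not in ("auto", "exact", "asymptotic"):
        raise ConfigError(f"unknown mode {mode!r}")
    a = _clean(a, "a")
    b = _clean(b, "b")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        # all observations identical: no evidence either way
        return (a.size * b.size / 2.0, 1.0)
    if mode == "exact" or (mode == "auto" and not has_ties and pooled.size <= EXACT_MAX_TOTAL_N):
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return (float(res.statistic), float(min(res.pvalue, 1.0)))


_STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_code(p: float) -> str:
    """Significance stars: smallest threshold with ``p <= threshold``; 'ns'
    above 0.05."""
    if not (0.0 < p <= 1.0):
        raise ConfigError(f"p-value must be in (0, 1], got {p}")
    for threshold, stars in _STAR_THRESHOLDS:
        if p <= threshold:
            return stars
    return "ns"


def compare_groups(
    features: pd.DataFrame,
    grouping: dict[str, str] | None = None,
    mode: str = "auto",
) -> pd.DataFrame:
    """Mann-Whitney comparison of every feature column between two groups.

    ``features`` is the matrix from :func:`pribin.features.build_feature_matrix`
    (rows = samples, a ``group`` column plus feature columns); ``grouping``
    optionally overrides the group labels by sample id.  Exactly two groups
    must remain after mapping.  Output columns: group medians, U, unadjusted
    p, stars, and ``p_adj_bh`` (Benjamini-Hochberg, an extension — the
    headline p-values are the unadjusted ones).
    """
    if grouping is not None:
        labels = pd.Series({s: grouping[s] for s in features.index})
    elif "group" in features.columns:
        labels = features["group"]
    else:
        raise ConfigError("no 'group' column and no grouping map given")
    group_names = sorted(labels.unique())
    if len(group_names) != 2:
        raise ConfigError(f"need exactly 2 groups, got {group_names}")
    ga, gb = group_names
    feature_cols = [c for c in features.columns if c != "group"]

    rows = []
    for col in feature_cols:
        va = features.loc[labels == ga, col].to_numpy(dtype=float)
        vb = features.loc[labels == gb, col].to_numpy(dtype=float)
        n_missing = int(np.isnan(va).sum() + np.isnan(vb).sum())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                u, p = mann_whitney(va, vb, mode=mode)
        except ConfigError:
            rows.append(
                GroupComparison(col, 0, 0, np.nan, np.nan, np.nan, np.nan, "ns", n_missing)
            )
            continue
        va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
        rows.append(
            GroupComparison(
                feature=col,
                n_a=va.size,
                n_b=vb.size,
                median_a=float(np.median(va)),
                median_b=float(np.median(vb)),
                u_statistic=u,
                p_value=p,
                stars=star_code(p),
                n_missing=n_missing,
            )
        )
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("feature")
    out.attrs["group_a"], out.attrs["group_b"] = ga, gb
    valid = out["p_value"].notna()
    out["p_adj_bh"] = np.nan
    if valid.any():
        out.loc[valid, "p_adj_bh"] = multipletests(
            out.loc[valid, "p_value"], method="fdr_bh"
        )[1]
    return out
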