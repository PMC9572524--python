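"""Descriptive statistics over a pRRx feature table.

Covers the comparison toolkit used to contrast members of the pRRx family
with each other and between rhythms: percentile/histogram distribution
summaries, Spearman rank-correlation matrices, nonparametric
Bland–Altman-style difference analysis (bias, SD of differences and
percentile limits of agreement), and hypothesis tests (Shapiro–Wilk
normality, paired Wilcoxon within rhythm, Mann–Whitney between rhythms).

All tests are two-sided and reported raw, without multiplicity
correction.  Percentiles use linear interpolation between order
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import META_COLUMNS

__all__ = [
    "DistributionSummary",
    "summarize_distributions",
    "correlation_heatmap",
    "difference_analysis",
    "run_tests",
]

PERCENTILES = (10, 25, 50, 75, 90)
HIST_BINS = np.linspace(0.0, 100.0, 26)  # 25 equal bins over percent scale
_SHAPIRO_MAX_N = 5000


def _feature_cols(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


@dataclass
class DistributionSummary:
    """Percentiles and histogram counts per threshold for one label."""

    label: str
    percentiles: pd.DataFrame  # rows: p10..p90; columns: thresholds
    hist_counts: pd.DataFrame  # rows: 25 bins; columns: thresholds
    bin_edges: np.ndarray


def summarize_distributions(table: pd.DataFrame) -> dict[str, DistributionSummary]:
    """Empirical percentiles {10,25,50,75,90} and histogram counts of every
    pRRx column, separately per label."""
    out = {}
    for label, grp in table.groupby("label", sort=True):
        cols = _feature_cols(table)
        if grp.empty:
            raise ValueError(f"no rows for label {label!r}")
        vals = grp[cols].to_numpy(float)
        pct = np.percentile(vals, PERCENTILES, axis=0)
        hist = np.stack(
            [np.histogram(vals[:, j], bins=HIST_BINS)[0] for j in range(vals.shape[1])],
            axis=1,
        )
        out[label] = DistributionSummary(
            label=label,
            percentiles=pd.DataFrame(
                pct, index=[f"p{p}" for p in PERCENTILES], columns=cols
            ),
            hist_counts=pd.DataFrame(hist, columns=cols),
            bin_edges=HIST_BINS.copy(),
        )
    return out


def correlation_heatmap(table: pd.DataFrame, label: str) -> pd.DataFrame:
    """Spearman rho matrix over all threshold pairs for one label.

    Ties get average ranks.  A constant column has no defined rank
    correlation; its entries are reported as NaN (missing), except the
    diagonal which is 1 by convention.
    """
    grp = table[table["label"] == label]
    cols = _feature_cols(table)
    if len(grp) < 3:
        raise ValueError(
            f"need >= 3 rows for label {label!r}, got {len(grp)}"
        )
    vals = grp[cols].to_numpy(float)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # constant columns are deliberately reported as missing
        warnings.simplefilter("ignore", sps.ConstantInputWarning)
        rho = sps.spearmanr(vals, axis=0).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly 2 columns
        rho = np.array([[1.0, rho], [rho, 1.0]])
    else:
        rho = np.array(rho, copy=True)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=cols, columns=cols)


def difference_analysis(table: pd.DataFrame, label: str) -> pd.DataFrame:
    """Bias and limits of agreement for every ordered threshold pair.

    For each pair x_a < x_b: bias = mean(pRRx_a − pRRx_b) (non-negative by
    pRRx monotonicity), the SD of the differences, and the nonparametric
    limits of agreement, defined as the 2.5th and 97.5th percentiles of the
    difference distribution.
    """
    grp = table[table["label"] == label]
    cols = _feature_cols(table)
    if len(grp) < 2:
        raise ValueError(f"need >= 2 rows for label {label!r}, got {len(grp)}")
    vals = grp[cols].to_numpy(float)
    rows = []
    for ia in range(len(cols)):
        for ib in range(ia + 1, len(cols)):
            d = vals[:, ia] - vals[:, ib]
            lo, hi = np.percentile(d, [2.5, 97.5])
            rows.append(
                (cols[ia], cols[ib], float(d.mean()), float(d.std(ddof=1)),
                 float(lo), float(hi))
            )
    return pd.DataFrame(
        rows, columns=["x_a", "x_b", "bias", "sd", "loa_low", "loa_high"]
    )


def _shapiro(values: np.ndarray, rng: np.random.Generator):
    """Shapiro–Wilk on at most 5000 values (deterministic subsample above)."""
    v = np.asarray(values, float)
    if len(v) > _SHAPIRO_MAX_N:
        v = rng.choice(v, size=_SHAPIRO_MAX_N, replace=False)
    if len(v) < 3:
        return np.nan, np.nan, "inapplicable_too_few"
    if np.ptp(v) == 0:
        return np.nan, np.nan, "inapplicable_constant"
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue), ""


def run_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Hypothesis-test battery over the feature table.

    * Shapiro–Wilk normality per (label, threshold);
    * Wilcoxon signed-rank for every within-label threshold pair (paired
      across segments);
    * Mann–Whitney per threshold between AF and SR.

    All two-sided.  Degenerate inputs (all ties / constant) are reported
    with an ``inapplicable`` note and NaN p-value rather than raising.
    """
    cols = _feature_cols(table)
    rng = np.random.default_rng(0)  # only for Shapiro subsampling
    rows = []
    for label, grp in table.groupby("label", sort=True):
        vals = grp[cols].to_numpy(float)
        for j, c in enumerate(cols):
            stat, p, note = _shapiro(vals[:, j], rng)
            rows.append(("shapiro_wilk", label, c, "", stat, p, note))
        for ia in range(len(cols)):
            for ib in range(ia + 1, len(cols)):
                d = vals[:, ia] - vals[:, ib]
                if np.all(d == 0):
                    rows.append(("wilcoxon_paired", label, cols[ia], cols[ib],
                                 np.nan, np.nan, "inapplicable_all_zero"))
                    continue
                res = sps.wilcoxon(d, alternative="two-sided")
                rows.append(("wilcoxon_paired", label, cols[ia], cols[ib],
                             float(res.statistic), float(res.pvalue), ""))
    labels = sorted(table["label"].unique())
    if len(labels) == 2:
        a = table[table["label"] == labels[0]]
        b = table[table["label"] == labels[1]]
        for c in cols:
            x, y = a[c].to_numpy(float), b[c].to_numpy(float)
            if np.ptp(np.concatenate([x, y])) == 0:
                rows.append(("mann_whitney", f"{labels[0]}|{labels[1]}", c, "",
                             np.nan, np.nan, "inapplicable_constant"))
                continue
            res = sps.mannwhitneyu(x, y, alternative="two-sided")
            rows.append(("mann_whitney", f"{labels[0]}|{labels[1]}", c, "",
                         float(res.statistic), float(res.pvalue), ""))
    return pd.DataFrame(
        rows,
        columns=["test", "group", "x_a", "x_b", "statistic", "p_value", "note"],
    )
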