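"""Diagnostic evaluation of pRRx thresholds: ROC, Youden cutoffs,
classification metrics with bootstrap confidence intervals, and the
diagnostic odds ratio.

Conventions
-----------
* AF is the positive class; a segment is called AF when its pRRx value is
  **greater than or equal to** the cutoff.
* Candidate cutoffs are the observed score values; among ties on Youden's
  J = sensitivity + specificity − 1, the largest (most specific) cutoff
  wins.
* Confidence intervals are percentile bootstrap (2.5th/97.5th percentile
  of the replicate distribution at 95%); segments are resampled with
  replacement as whole rows, unstratified by default.
* DOR = (TP·TN)/(FP·FN); when any cell is zero, 0.5 is added to every
  cell (Haldane–Anscombe) so the ratio stays finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "POSITIVE_LABEL",
    "METRIC_NAMES",
    "ConfusionCounts",
    "MetricSummary",
    "DiagnosticResult",
    "ComparisonReport",
    "roc_auc",
    "youden_cutoff",
    "classify_metrics",
    "bootstrap_metrics",
    "sweep",
    "SweepResult",
    "compare_thresholds",
    "cross_validate",
]

POSITIVE_LABEL = "AF"
METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "ppv", "npv",
                "f1", "dor")
_SHAPIRO_MAX_N = 5000


def _positive_mask(labels) -> np.ndarray:
    y = np.asarray(labels) == POSITIVE_LABEL
    if y.all() or not y.any():
        raise ValueError("both classes (AF and SR) must be present")
    return y


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricSummary:
    """Point value on the full sample plus bootstrap median and CI."""

    point: float
    median: float
    ci_low: float
    ci_high: float


@dataclass
class DiagnosticResult:
    """Evaluation of one pRRx threshold at one cutoff."""

    x_ms: float
    name: str
    auc: float
    cutoff: float
    youden_j: float
    counts: ConfusionCounts
    metrics: dict[str, MetricSummary]
    n_boot: int
    seed: int | None = None
    source_x_ms: float | None = None  # set by cross_validate

    def to_row(self) -> dict:
        row = {"x_ms": self.x_ms, "name": self.name, "auc": self.auc,
               "cutoff": self.cutoff, "youden_j": self.youden_j}
        if self.source_x_ms is not None:
            row["source_x_ms"] = self.source_x_ms
        for m, s in self.metrics.items():
            row[m] = s.point
            row[f"{m}_median"] = s.median
            row[f"{m}_ci_low"] = s.ci_low
            row[f"{m}_ci_high"] = s.ci_high
        return row


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve, AF positive, higher score => AF.

    Equals the Mann–Whitney U statistic divided by n_AF·n_SR, with tied
    score pairs contributing 1/2.
    """
    y = _positive_mask(labels)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def youden_cutoff(scores, labels) -> tuple[float, float]:
    """Cutoff among observed scores maximizing Youden's J.

    Decision rule: score >= cutoff => AF.  Ties on J resolve to the
    largest cutoff.  Returns ``(cutoff, J)``.
    """
    scores = np.asarray(scores, dtype=float)
    y = _positive_mask(labels)
    af = np.sort(scores[y])
    sr = np.sort(scores[~y])
    n_af, n_sr = len(af), len(sr)
    candidates = np.unique(scores)
    # integer counts: af >= c and sr < c at each candidate
    ge_af = n_af - np.searchsorted(af, candidates, side="left")
    lt_sr = np.searchsorted(sr, candidates, side="left")
    # maximize J = ge_af/n_af + lt_sr/n_sr - 1 in exact integer arithmetic
    # so exactly tied candidates cannot be misordered by float rounding
    score = ge_af * n_sr + lt_sr * n_af
    best = np.flatnonzero(score == score.max())[-1]
    j = score[best] / (n_af * n_sr) - 1.0
    return float(candidates[best]), float(j)


def _metric_arrays(tp, fp, fn, tn) -> dict[str, np.ndarray]:
    """Vectorized metric definitions over (arrays of) confusion counts."""
    tp = np.asarray(tp, dtype=float)
    fp = np.asarray(fp, dtype=float)
    fn = np.asarray(fn, dtype=float)
    tn = np.asarray(tn, dtype=float)
    n = tp + fp + fn + tn
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        acc = (tp + tn) / n
        ppv = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        npv = np.where(tn + fn > 0, tn / (tn + fn), np.nan)
        f1 = np.where(2 * tp + fp + fn > 0, 2 * tp / (2 * tp + fp + fn), 0.0)
        zero_cell = (tp == 0) | (fp == 0) | (fn == 0) | (tn == 0)
        h = np.where(zero_cell, 0.5, 0.0)  # Haldane–Anscombe correction
        dor = ((tp + h) * (tn + h)) / ((fp + h) * (fn + h))
    return {"sensitivity": sens, "specificity": spec, "accuracy": acc,
            "ppv": ppv, "npv": npv, "f1": f1, "dor": dor}


def classify_metrics(scores, labels, cutoff: float
                     ) -> tuple[ConfusionCounts, dict[str, float]]:
    """Confusion counts and metrics at a fixed cutoff (score >= cutoff => AF)."""
    if not np.isfinite(cutoff):
        raise ValueError(f"cutoff must be finite, got {cutoff}")
    scores = np.asarray(scores, dtype=float)
    y = _positive_mask(labels)
    pred = scores >= cutoff
    counts = ConfusionCounts(
        tp=int((pred & y).sum()),
        fp=int((pred & ~y).sum()),
        fn=int((~pred & y).sum()),
        tn=int((~pred & ~y).sum()),
    )
    arrays = _metric_arrays(counts.tp, counts.fp, counts.fn, counts.tn)
    return counts, {k: float(v) for k, v in arrays.items()}


def _resample_indices(rng: np.random.Generator, y: np.ndarray, n_boot: int,
                      stratified: bool) -> np.ndarray:
    """Bootstrap row indices, (n_boot, n).  Unstratified replicates that
    lose a class are redrawn (logged); stratified resampling draws within
    each class so both are always present."""
    n = len(y)
    if stratified:
        pos = np.flatnonzero(y)
        neg = np.flatnonzero(~y)
        ip = pos[rng.integers(0, len(pos), size=(n_boot, len(pos)))]
        ineg = neg[rng.integers(0, len(neg), size=(n_boot, len(neg)))]
        return np.concatenate([ip, ineg], axis=1)
    idx = rng.integers(0, n, size=(n_boot, n))
    n_redrawn = 0
    while True:
        npos = y[idx].sum(axis=1)
        bad = (npos == 0) | (npos == n)
        if not bad.any():
            break
        n_redrawn += int(bad.sum())
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
    if n_redrawn:
        logger.info("bootstrap: redrew %d replicate(s) with an empty class",
                    n_redrawn)
    return idx


def _replicate_metrics(scores: np.ndarray, y: np.ndarray, cutoff: float,
                       idx: np.ndarray) -> dict[str, np.ndarray]:
    """Per-replicate metric arrays at a fixed cutoff, chunked to bound
    memory."""
    pred = scores >= cutoff
    out = {m: np.empty(len(idx)) for m in METRIC_NAMES}
    chunk = max(1, int(5_000_000 // max(1, idx.shape[1])))
    for lo in range(0, len(idx), chunk):
        sl = idx[lo:lo + chunk]
        py = y[sl]
        pp = pred[sl]
        tp = (pp & py).sum(axis=1)
        fp = (pp & ~py).sum(axis=1)
        fn = (~pp & py).sum(axis=1)
        tn = (~pp & ~py).sum(axis=1)
        arrays = _metric_arrays(tp, fp, fn, tn)
        for m in METRIC_NAMES:
            out[m][lo:lo + len(sl)] = arrays[m]
    return out


def _summaries(point: dict[str, float], reps: dict[str, np.ndarray],
               ci_level: float) -> dict[str, MetricSummary]:
    alpha = 100.0 * (1.0 - ci_level) / 2.0
    out = {}
    for m in METRIC_NAMES:
        r = reps[m]
        med = float(np.nanmedian(r))
        lo, hi = np.nanpercentile(r, [alpha, 100.0 - alpha])
        out[m] = MetricSummary(point=point[m], median=med,
                               ci_low=float(lo), ci_high=float(hi))
    return out


def bootstrap_metrics(scores, labels, cutoff: float, n_boot: int = 5000,
                      seed=0, stratified: bool = False,
                      ci_level: float = 0.95) -> dict[str, MetricSummary]:
    """Percentile-bootstrap summaries of all metrics at a fixed cutoff.

    Segments (rows) are resampled with replacement ``n_boot`` times; every
    metric is recomputed per replicate at the *fixed* cutoff.  Returns a
    mapping metric -> :class:`MetricSummary`.  Identical seed gives
    bit-identical output.
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    scores = np.asarray(scores, dtype=float)
    y = _positive_mask(labels)
    _, point = classify_metrics(scores, labels, cutoff)
    rng = np.random.default_rng(seed)
    idx = _resample_indices(rng, y, n_boot, stratified)
    reps = _replicate_metrics(scores, y, cutoff, idx)
    return _summaries(point, reps, ci_level)


@dataclass
class SweepResult:
    """Per-threshold diagnostic results over a grid."""

    results: list[DiagnosticResult]
    best_auc_name: str = ""
    best_dor_name: str = ""

    def __post_init__(self) -> None:
        if self.results and not self.best_auc_name:
            aucs = [r.auc for r in self.results]
            self.best_auc_name = self.results[int(np.argmax(aucs))].name
            dors = [r.metrics["dor"].median for r in self.results]
            self.best_dor_name = self.results[int(np.argmax(dors))].name

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def __getitem__(self, name: str) -> DiagnosticResult:
        for r in self.results:
            if r.name == name:
                return r
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.results])


def sweep(table: pd.DataFrame, grid, n_boot: int = 5000, seed=0,
          stratified: bool = False, ci_level: float = 0.95) -> SweepResult:
    """Evaluate every grid threshold: AUC, Youden cutoff on the full data,
    then bootstrap CIs for all metrics at that cutoff.

    Per-threshold random streams are spawned deterministically from
    *seed*, so results do not depend on evaluation order.
    """
    labels = table["label"].to_numpy()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(grid.names))
    results = []
    for name, x, child in zip(grid.names, grid.x_ms, children):
        scores = table[name].to_numpy(float)
        auc = roc_auc(scores, labels)
        cutoff, j = youden_cutoff(scores, labels)
        counts, _ = classify_metrics(scores, labels, cutoff)
        metrics = bootstrap_metrics(scores, labels, cutoff, n_boot=n_boot,
                                    seed=child, stratified=stratified,
                                    ci_level=ci_level)
        results.append(DiagnosticResult(
            x_ms=float(x), name=name, auc=auc, cutoff=cutoff, youden_j=j,
            counts=counts, metrics=metrics, n_boot=n_boot,
            seed=seed if isinstance(seed, int) else None,
        ))
    return SweepResult(results)


@dataclass
class ComparisonReport:
    """Paired-bootstrap comparison of two thresholds' metrics."""

    name_a: str
    name_b: str
    x_a: float
    x_b: float
    cutoff_a: float
    cutoff_b: float
    n_boot: int
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __str__(self) -> str:
        lines = [
            f"Comparison {self.name_a} (cutoff {self.cutoff_a:.2f}%) vs "
            f"{self.name_b} (cutoff {self.cutoff_b:.2f}%), "
            f"{self.n_boot} paired bootstrap replicates",
        ]
        for _, r in self.table.iterrows():
            lines.append(
                f"  {r['metric']:>12}: {self.name_a}={r['median_a']:.4f} "
                f"{self.name_b}={r['median_b']:.4f}  {r['test']}"
                f" p={r['p_value']:.3g} {r['note']}".rstrip()
            )
        return "\n".join(lines)


def _normal_verdict(x: np.ndarray, rng: np.random.Generator) -> bool:
    v = x[np.isfinite(x)]
    if len(v) > _SHAPIRO_MAX_N:
        v = rng.choice(v, size=_SHAPIRO_MAX_N, replace=False)
    if len(v) < 3 or np.ptp(v) == 0:
        return False
    return bool(sps.shapiro(v).pvalue > 0.05)


def compare_thresholds(table: pd.DataFrame, grid, x_a: float, x_b: float,
                       n_boot: int = 5000, seed=0,
                       metrics: tuple = ("accuracy", "sensitivity",
                                         "specificity", "dor"),
                       stratified: bool = False) -> ComparisonReport:
    """Compare the classification metrics of two grid thresholds with a
    paired bootstrap.

    Both thresholds get their own Youden cutoff on the full data; every
    bootstrap replicate uses the *same* resampled rows for both.  Each
    metric's two replicate distributions get a Shapiro–Wilk normality
    verdict; a paired t-test is used when both look normal, a Wilcoxon
    signed-rank test otherwise (two-sided).
    """
    name_a = grid.name_of(x_a)
    name_b = grid.name_of(x_b)
    labels = table["label"].to_numpy()
    y = _positive_mask(labels)
    sa = table[name_a].to_numpy(float)
    sb = table[name_b].to_numpy(float)
    cut_a, _ = youden_cutoff(sa, labels)
    cut_b, _ = youden_cutoff(sb, labels)
    rng = np.random.default_rng(seed)
    idx = _resample_indices(rng, y, n_boot, stratified)
    reps_a = _replicate_metrics(sa, y, cut_a, idx)
    reps_b = _replicate_metrics(sb, y, cut_b, idx)
    rows = []
    for m in metrics:
        ra, rb = reps_a[m], reps_b[m]
        d = ra - rb
        norm_a = _normal_verdict(ra, rng)
        norm_b = _normal_verdict(rb, rng)
        note = ""
        if np.all(d[np.isfinite(d)] == 0):
            test, stat, p, note = "none", np.nan, 1.0, "identical_distributions"
        elif norm_a and norm_b:
            res = sps.ttest_rel(ra, rb, nan_policy="omit")
            test, stat, p = "paired_t", float(res.statistic), float(res.pvalue)
        else:
            fin = np.isfinite(d)
            res = sps.wilcoxon(d[fin], alternative="two-sided")
            test, stat, p = "wilcoxon", float(res.statistic), float(res.pvalue)
        rows.append({
            "metric": m,
            "median_a": float(np.nanmedian(ra)),
            "median_b": float(np.nanmedian(rb)),
            "ci_low_a": float(np.nanpercentile(ra, 2.5)),
            "ci_high_a": float(np.nanpercentile(ra, 97.5)),
            "ci_low_b": float(np.nanpercentile(rb, 2.5)),
            "ci_high_b": float(np.nanpercentile(rb, 97.5)),
            "normal_a": norm_a, "normal_b": norm_b,
            "test": test, "statistic": stat, "p_value": p, "note": note,
        })
    return ComparisonReport(
        name_a=name_a, name_b=name_b, x_a=float(x_a), x_b=float(x_b),
        cutoff_a=cut_a, cutoff_b=cut_b, n_boot=n_boot,
        table=pd.DataFrame(rows),
    )


def cross_validate(cutoffs: dict[float, float], table_b: pd.DataFrame,
                   grid_b, n_boot: int = 5000, seed=0,
                   stratified: bool = False) -> list[DiagnosticResult]:
    """Apply cutoffs learned on dataset A to dataset B without
    re-optimization.

    *cutoffs* maps source threshold x (ms) to the cutoff (percent) learned
    on A.  Each source threshold is mapped to the nearest representable
    threshold of B's grid (exact midpoints resolve toward the smaller x),
    then all metrics and bootstrap CIs are computed on B at the fixed
    cutoff.
    """
    if table_b.empty:
        raise ValueError("validation table is empty")
    labels = table_b["label"].to_numpy()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(cutoffs))
    results = []
    for (x_src, cutoff), child in zip(sorted(cutoffs.items()), children):
        x_tgt = grid_b.nearest_x(x_src)
        name = grid_b.name_of(x_tgt)
        scores = table_b[name].to_numpy(float)
        auc = roc_auc(scores, labels)
        counts, point = classify_metrics(scores, labels, cutoff)
        metrics = bootstrap_metrics(scores, labels, cutoff, n_boot=n_boot,
                                    seed=child, stratified=stratified)
        results.append(DiagnosticResult(
            x_ms=float(x_tgt), name=name, auc=auc, cutoff=float(cutoff),
            youden_j=point["sensitivity"] + point["specificity"] - 1.0,
            counts=counts, metrics=metrics, n_boot=n_boot,
            source_x_ms=float(x_src),
        ))
    return results
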