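"""End-to-end orchestration: simulate / segment / featurize / describe /
evaluate / compare / validate, with a run manifest and deterministic
seeding.

Every stage reads and writes plain CSV so runs can be resumed, inspected
or diffed; a rerun with the same config produces byte-identical CSV
bodies.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import compare_thresholds, cross_validate, sweep
from .features import META_COLUMNS, build_grid, feature_matrix
from .io import RRSeries, read_rr_table
from .segmentation import Segment, SegmentationConfig, segment_series
from .stats import (difference_analysis, correlation_heatmap, run_tests,
                    summarize_distributions)
from .synthetic import generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "simulate_command",
           "write_segments", "read_segments"]


class PipelineError(RuntimeError):
    """Configuration or input error surfaced to the CLI as exit != 0."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    inputs: list[str] = field(default_factory=list)
    out_dir: str = "prrx-out"
    seed: int = 0
    n_boot: int = 5000
    fs: float | None = None  # override the fs declared in the input files
    k_max: int = 25
    window_s: float = 60.0
    min_rr_ms: float = 240.0
    max_rr_ms: float = 3000.0
    max_excluded_ms: float = 6000.0
    strict_purity: bool = False
    stratified_bootstrap: bool = False
    ci_level: float = 0.95
    compare_x: list[float] | None = None  # default: pRR31 vs pRR50-equivalent
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(
            window_s=self.window_s,
            min_duration_s=self.window_s,
            min_rr_ms=self.min_rr_ms,
            max_rr_ms=self.max_rr_ms,
            max_excluded_ms=self.max_excluded_ms,
            strict_purity=self.strict_purity,
        )


def write_segments(segments: list[Segment], summary_path, rr_path) -> None:
    """Persist a segment set: one summary row per segment plus the
    retained RR rows (with gap flags)."""
    summary = pd.DataFrame(
        [(s.record_id, s.start_time_ms, s.label, s.fs, len(s),
          s.excluded_ms, s.n_removed) for s in segments],
        columns=["record_id", "start_time_ms", "label", "fs", "n_intervals",
                 "excluded_ms", "n_removed"],
    )
    summary.to_csv(summary_path, index=False)
    rows = []
    for s in segments:
        for i, (rr, gap) in enumerate(zip(s.rr_ms, s.gap_after)):
            rows.append((s.record_id, s.start_time_ms, i, rr, int(gap)))
    pd.DataFrame(
        rows, columns=["record_id", "start_time_ms", "i", "rr_ms", "gap_after"]
    ).to_csv(rr_path, index=False)


def read_segments(summary_path, rr_path) -> list[Segment]:
    """Inverse of :func:`write_segments`."""
    summary = pd.read_csv(summary_path)
    rr = pd.read_csv(rr_path)
    grouped = rr.groupby(["record_id", "start_time_ms"], sort=False)
    out = []
    for _, row in summary.iterrows():
        g = grouped.get_group((row["record_id"], row["start_time_ms"]))
        g = g.sort_values("i")
        out.append(Segment(
            record_id=row["record_id"],
            start_time_ms=float(row["start_time_ms"]),
            label=row["label"],
            fs=float(row["fs"]),
            rr_ms=g["rr_ms"].to_numpy(float),
            gap_after=g["gap_after"].to_numpy(bool),
            excluded_ms=float(row["excluded_ms"]),
            n_removed=int(row["n_removed"]),
        ))
    return out


def _load_inputs(config: RunConfig) -> list[RRSeries]:
    if not config.inputs:
        raise PipelineError("no input files given")
    paths = []
    for pattern in config.inputs:
        p = Path(pattern)
        if p.is_dir():
            paths.extend(sorted(p.glob("*.csv")))
        elif any(ch in pattern for ch in "*?["):
            hits = sorted(Path(".").glob(pattern))
            if not hits:
                raise PipelineError(f"pattern matched no files: {pattern}")
            paths.extend(hits)
        else:
            if not p.exists():
                raise PipelineError(f"input not found: {pattern}")
            paths.append(p)
    series = [read_rr_table(p) for p in paths]
    if config.fs is not None:
        for s in series:
            s.fs = config.fs
    return series


def run_pipeline(config: RunConfig) -> Path:
    """Run segment -> featurize -> describe -> evaluate -> compare and
    write all artifacts plus a manifest to ``config.out_dir``.

    Inputs are validated before anything is written, so a failing run
    leaves no partial artifact directory behind.
    """
    series = _load_inputs(config)
    fs = series[0].fs
    if any(abs(s.fs - fs) > 1e-9 for s in series):
        raise PipelineError("input series have differing sampling rates; "
                            "use the fs override to resample thresholds")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    segments, tally = segment_series(series, config.segmentation())
    if not segments:
        raise PipelineError("no segment survived segmentation/filtering")
    write_segments(segments, out / "segments.csv", out / "segment_rr.csv")

    grid = build_grid(fs, config.k_max)
    table = feature_matrix(segments, grid)
    table.to_csv(out / "prrx.csv", index=False)

    labels = sorted(table["label"].unique())
    summaries = summarize_distributions(table)
    for label, summ in summaries.items():
        summ.percentiles.to_csv(out / f"percentiles_{label}.csv")
        summ.hist_counts.to_csv(out / f"histograms_{label}.csv", index=False)
    for label in labels:
        grp = table[table["label"] == label]
        if len(grp) >= 3:
            correlation_heatmap(table, label).to_csv(
                out / f"correlation_{label}.csv")
        if len(grp) >= 2:
            difference_analysis(table, label).to_csv(
                out / f"differences_{label}.csv", index=False)
    run_tests(table).to_csv(out / "tests.csv", index=False)

    results = None
    comparison = None
    if len(labels) == 2:
        results = sweep(table, grid, n_boot=config.n_boot, seed=config.seed,
                        stratified=config.stratified_bootstrap,
                        ci_level=config.ci_level)
        results.to_frame().to_csv(out / "sweep.csv", index=False)
        x_a, x_b = config.compare_x or (grid.nearest_x(31.25),
                                        grid.equivalent_x(50.0))
        comparison = compare_thresholds(
            table, grid, x_a, x_b, n_boot=config.n_boot, seed=config.seed,
            stratified=config.stratified_bootstrap)
        comparison.table.to_csv(out / "comparison.csv", index=False)
        (out / "comparison.txt").write_text(str(comparison) + "\n",
                                            encoding="utf-8")
    else:
        logger.warning("only one label present; skipping diagnostic stages")

    if config.plots:
        from . import plotting
        plotting.save_standard_plots(out / "plots", table, summaries,
                                     results.to_frame() if results else None)

    cfg_dict = asdict(config)
    manifest = {
        "prrx_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "n_boot": config.n_boot,
        "fs": fs,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "n_series": len(series),
        "n_segments": len(segments),
        "rejections": {k: v for k, v in tally.items() if k != "accepted"},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %d series -> %d segments -> %s",
                len(series), len(segments), out)
    return out


def simulate_command(out_dir, n_sr: int, n_af: int, duration_s: float = 60.0,
                     fs: float = 128.0, seed: int = 0,
                     p_ventricular: float = 0.0,
                     p_supraventricular: float = 0.0,
                     p_artifact: float = 0.0) -> list[Path]:
    """Generate a synthetic cohort and write one RR table per series."""
    from .io import write_rr_table
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(
        n_sr=n_sr, n_af=n_af, duration_s=duration_s, fs=fs, seed=seed,
        p_ventricular=p_ventricular, p_supraventricular=p_supraventricular,
        p_artifact=p_artifact)
    paths = []
    for series in cohort:
        path = out / f"{series.record_id}.csv"
        write_rr_table(series, path)
        paths.append(path)
    logger.info("simulate: wrote %d series to %s", len(paths), out)
    return paths
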