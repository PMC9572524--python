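"""Synthetic beat-annotated RR tachograms for sinus rhythm and AF.

The generator emulates the statistical structure the downstream analysis
relies on, not the electrophysiology:

* **Sinus rhythm (SR)** — a bounded random walk: each RR interval equals the
  previous one plus Gaussian noise of scale ``sd_diff``, reflected so that
  it stays within ``ratio_bounds`` (default 80–120%) of its predecessor.
  This reproduces the tight coupling of successive sinus intervals.
* **Atrial fibrillation (AF)** — independent draws from a right-skewed
  gamma law with the configured mean and SD: successive intervals are
  nearly uncorrelated and highly variable, with no ratio constraint.
* **Ectopy / artifact** — an ectopic beat (ventricular or supraventricular)
  is simulated as a shortened RR interval followed by a compensatory
  lengthened one; artifact intervals get implausible durations.  All three
  are flagged in ``beat_type`` so the exclusion filters can be exercised.

Every emitted RR duration is rounded to the nearest multiple of the
sampling period ``Δ = 1000/fs`` ms, mirroring the quantization of R-wave
locations to ECG samples.

Single series share one set of parameters; :func:`generate_cohort` adds
log-normal between-series dispersion around the class defaults, emulating
the between-patient heterogeneity of a Holter cohort (without it, synthetic
SR and AF would be perfectly separable at almost every pRRx threshold,
which no real cohort is).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import RRSeries

__all__ = [
    "SyntheticConfig",
    "CohortDispersion",
    "SR_DEFAULTS",
    "AF_DEFAULTS",
    "generate_series",
    "generate_cohort",
]

# Absolute physiological corridor for SR interval durations (ms).  The walk
# is clamped here at every step; without the clamp the multiplicative
# ratio constraint lets the walk drift toward zero and the duration target
# is never reached.
_RR_FLOOR_MS = 300.0
_RR_CEIL_MS = 2000.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic RR series.

    Parameters
    ----------
    rhythm : {"SR", "AF"}
        Rhythm of the whole series (constant; no transitions).
    duration_s : float
        Minimum cumulative RR duration to generate, in seconds.
    fs : float
        ECG sampling rate in Hz; RR durations are quantized to 1000/fs ms.
    mean_rr, sd_rr : float
        Mean and SD of the RR distribution in ms (AF: the gamma law;
        SR: the initial interval draw).
    sd_diff : float
        SR only — scale (ms) of the Gaussian successive-difference noise.
    ratio_bounds : (float, float)
        SR only — each interval is kept within this fraction band of its
        predecessor (default 0.8–1.2).
    p_ventricular, p_supraventricular, p_artifact : float
        Per-beat probabilities of the corresponding disturbance.
    seed : int
        Seed of the single pseudo-random stream used for the series.
    """

    rhythm: str = "SR"
    duration_s: float = 60.0
    fs: float = 128.0
    mean_rr: float = 900.0
    sd_rr: float = 50.0
    sd_diff: float = 25.0
    ratio_bounds: tuple[float, float] = (0.8, 1.2)
    p_ventricular: float = 0.0
    p_supraventricular: float = 0.0
    p_artifact: float = 0.0
    seed: int = 0
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.rhythm not in ("SR", "AF"):
            raise ValueError(f"rhythm must be 'SR' or 'AF', got {self.rhythm!r}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        for name in ("p_ventricular", "p_supraventricular", "p_artifact"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        lo, hi = self.ratio_bounds
        if not lo < 1.0 < hi:
            raise ValueError(
                f"ratio_bounds must straddle 1, got ({lo}, {hi})"
            )
        if self.mean_rr <= 0 or self.sd_rr < 0 or self.sd_diff < 0:
            raise ValueError("mean_rr must be > 0 and scales must be >= 0")


#: Per-series class defaults (ms): typical resting sinus rhythm and a
#: moderately rate-controlled AF.
SR_DEFAULTS = SyntheticConfig(rhythm="SR", mean_rr=900.0, sd_rr=50.0, sd_diff=25.0)
AF_DEFAULTS = SyntheticConfig(rhythm="AF", mean_rr=650.0, sd_rr=150.0)


@dataclass(frozen=True)
class CohortDispersion:
    """Log-normal between-series dispersion of the class parameters.

    Each generated series draws its own ``mean_rr`` (and ``sd_rr``,
    ``sd_diff``) as ``default * exp(N(0, sigma))``.  Defaults reflect
    population spread of resting heart rate, of short-term sinus
    variability (RMSSD spans roughly 10–60 ms in adults) and of AF
    ventricular-rate irregularity.
    """

    sigma_mean_rr: float = 0.12
    sigma_sd_rr: float = 0.3
    sigma_sd_diff: float = 0.5


SR_DISPERSION = CohortDispersion(0.12, 0.3, 0.5)
AF_DISPERSION = CohortDispersion(0.15, 0.5, 0.0)


def generate_series(config: SyntheticConfig) -> RRSeries:
    """Generate one beat-annotated RR series.

    Returns an :class:`~prrx.io.RRSeries` whose cumulative duration is at
    least ``config.duration_s`` seconds, with every RR an exact multiple of
    ``1000/fs`` ms, a constant rhythm annotation, and ectopic/artifact
    intervals flagged per the configured probabilities.  The same config
    (including seed) always produces bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    target_ms = config.duration_s * 1000.0
    delta = 1000.0 / config.fs

    if config.rhythm == "AF":
        rr = _af_intervals(rng, config, target_ms, delta)
    else:
        rr = _sr_intervals(rng, config, target_ms, delta)

    rr, beat_type = _inject_disturbances(rng, rr, config)

    # quantize to the sampling grid, keeping durations positive
    rr = np.maximum(np.rint(rr / delta), 1.0) * delta

    # artifacts shorten intervals, so the quantized sum can dip below the
    # target; extend by continuing the walk/draws from the last interval
    while rr.sum() < target_ms:
        deficit = target_ms - rr.sum()
        if config.rhythm == "AF":
            extra = _af_intervals(rng, config, deficit, delta)
        else:
            extra = _sr_continue(rng, config, deficit, float(rr[-1]))
        extra = np.maximum(np.rint(extra / delta), 1.0) * delta
        rr = np.concatenate([rr, extra])
        beat_type = np.concatenate([beat_type, np.full(len(extra), "N")])

    record_id = config.record_id or f"synthetic-{config.rhythm}-{config.seed}"
    return RRSeries(
        record_id=record_id,
        fs=config.fs,
        rr_ms=rr,
        beat_type=beat_type,
        rhythm=np.full(len(rr), config.rhythm, dtype="U2"),
        meta={"seed": config.seed, "generator": "prrx.synthetic"},
    )


def _af_intervals(rng, config, target_ms, delta):
    """I.i.d. gamma draws with the configured mean and SD; the quantized
    cumulative sum reaches *target_ms*."""
    if config.sd_rr == 0:
        q = np.rint(config.mean_rr / delta) * delta
        n = int(np.ceil(target_ms / q))
        return np.full(n, config.mean_rr)
    shape = (config.mean_rr / config.sd_rr) ** 2
    scale = config.sd_rr**2 / config.mean_rr
    chunks = []
    qtotal = 0.0
    while qtotal < target_ms:
        n = max(16, int((target_ms - qtotal) / config.mean_rr) + 4)
        block = np.clip(rng.gamma(shape, scale, size=n), _RR_FLOOR_MS, _RR_CEIL_MS)
        chunks.append(block)
        qtotal += (np.maximum(np.rint(block / delta), 1.0) * delta).sum()
    rr = np.concatenate(chunks)
    qcum = np.cumsum(np.maximum(np.rint(rr / delta), 1.0) * delta)
    stop = int(np.searchsorted(qcum, target_ms)) + 1
    return rr[:stop]


def _sr_intervals(rng, config, target_ms, delta):
    """Bounded Gaussian random walk with reflection at the ratio bounds;
    the quantized cumulative sum reaches *target_ms*."""
    rr0 = float(np.clip(rng.normal(config.mean_rr, config.sd_rr),
                        _RR_FLOOR_MS, _RR_CEIL_MS))
    out = [rr0]
    qtotal = max(np.rint(rr0 / delta), 1.0) * delta
    lo_f, hi_f = config.ratio_bounds
    while qtotal < target_ms:
        nxt = _sr_step(rng, out[-1], config.sd_diff, lo_f, hi_f)
        out.append(nxt)
        qtotal += max(np.rint(nxt / delta), 1.0) * delta
    return np.array(out)


def _sr_continue(rng, config, target_ms, last_rr):
    """Continue an SR walk from *last_rr* until *target_ms* more is filled."""
    lo_f, hi_f = config.ratio_bounds
    out = []
    total = 0.0
    prev = last_rr
    while total < target_ms:
        prev = _sr_step(rng, prev, config.sd_diff, lo_f, hi_f)
        out.append(prev)
        total += prev
    return np.array(out)


def _sr_step(rng, prev, sd_diff, lo_f, hi_f):
    nxt = prev + rng.normal(0.0, sd_diff)
    lo, hi = lo_f * prev, hi_f * prev
    # reflect into the band; converges since each bounce sheds one width
    while nxt < lo or nxt > hi:
        if nxt < lo:
            nxt = 2.0 * lo - nxt
        if nxt > hi:
            nxt = 2.0 * hi - nxt
    return min(max(nxt, _RR_FLOOR_MS), _RR_CEIL_MS)


def _inject_disturbances(rng, rr, config):
    """Flag per-beat disturbances; ectopy shortens one RR and lengthens the
    next (compensatory pause), artifacts get implausible durations."""
    n = len(rr)
    beat_type = np.full(n, "N", dtype="U1")
    p_total = config.p_ventricular + config.p_supraventricular + config.p_artifact
    if p_total == 0 or n < 3:
        return rr, beat_type
    u = rng.random(n)
    rr = rr.copy()
    i = 1
    while i < n - 1:
        if u[i] < config.p_ventricular:
            code = "V"
        elif u[i] < config.p_ventricular + config.p_supraventricular:
            code = "S"
        elif u[i] < p_total:
            code = "A"
        else:
            i += 1
            continue
        if code == "A":
            # technical artifact: a spuriously short detection
            rr[i] = rng.uniform(80.0, 200.0)
            beat_type[i] = "A"
            i += 1
        else:
            # premature beat: early interval + compensatory pause, the
            # coupled pair preserving total time
            pair = rr[i] + rr[i + 1]
            frac = rng.uniform(0.45, 0.7)
            rr[i] = frac * pair / 2.0
            rr[i + 1] = pair - rr[i]
            beat_type[i] = code
            i += 2  # compensatory interval stays 'N'; skip it
    return rr, beat_type


def generate_cohort(
    n_sr: int,
    n_af: int,
    duration_s: float = 60.0,
    fs: float = 128.0,
    seed: int = 0,
    sr_base: SyntheticConfig = SR_DEFAULTS,
    af_base: SyntheticConfig = AF_DEFAULTS,
    sr_dispersion: CohortDispersion = SR_DISPERSION,
    af_dispersion: CohortDispersion = AF_DISPERSION,
    p_ventricular: float = 0.0,
    p_supraventricular: float = 0.0,
    p_artifact: float = 0.0,
) -> list[RRSeries]:
    """Generate a heterogeneous cohort of SR and AF series.

    Each series draws its own parameters log-normally around the class
    defaults (see :class:`CohortDispersion`), then calls
    :func:`generate_series` with a seed derived deterministically from
    *seed*.  Returns the SR series followed by the AF series.
    """
    rng = np.random.default_rng(seed)
    out: list[RRSeries] = []
    for rhythm, n, base, disp in (
        ("SR", n_sr, sr_base, sr_dispersion),
        ("AF", n_af, af_base, af_dispersion),
    ):
        for i in range(n):
            cfg = replace(
                base,
                rhythm=rhythm,
                duration_s=duration_s,
                fs=fs,
                mean_rr=base.mean_rr * np.exp(rng.normal(0, disp.sigma_mean_rr)),
                sd_rr=base.sd_rr * np.exp(rng.normal(0, disp.sigma_sd_rr)),
                sd_diff=base.sd_diff * np.exp(rng.normal(0, disp.sigma_sd_diff)),
                p_ventricular=p_ventricular,
                p_supraventricular=p_supraventricular,
                p_artifact=p_artifact,
                seed=int(rng.integers(0, 2**31 - 1)),
                record_id=f"syn-{rhythm.lower()}-{i:04d}",
            )
            out.append(generate_series(cfg))
    return out
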