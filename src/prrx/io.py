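"""Reading and writing beat-annotated RR-interval series.

Two sources are supported:

* a plain tabular dialect (UTF-8 text, ``# record_id=`` / ``# fs=`` header
  comments, then CSV columns ``rr_ms,beat_type,rhythm``), convenient for
  synthetic data and for exchanging tachograms between tools;
* WFDB-style beat annotations (R-wave sample indices, beat symbols and
  rhythm aux strings), converted to RR intervals by :func:`from_annotations`.

An RR interval is attributed to its *terminating* beat for both its beat
type and the rhythm in force: a premature beat shortens the interval that
ends on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RRSeries",
    "BEAT_CODES",
    "RHYTHM_CODES",
    "RRParseError",
    "read_rr_table",
    "write_rr_table",
    "from_annotations",
    "read_wfdb",
]

#: Per-interval beat codes: normal, supraventricular premature, ventricular
#: premature, technical artifact, other.
BEAT_CODES = ("N", "S", "V", "A", "O")

#: Per-interval rhythm codes: sinus rhythm, atrial fibrillation, other.
RHYTHM_CODES = ("SR", "AF", "O")

# WFDB beat symbol -> dialect beat code (MIT annotation conventions).
WFDB_BEAT_MAP = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N", ".": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "|": "A", "~": "A", "!": "A", '"': "A", "x": "A", "Q": "A",
}

# WFDB rhythm aux string -> dialect rhythm code.
WFDB_RHYTHM_MAP = {
    "(N": "SR", "(NSR": "SR", "(SR": "SR",
    "(AFIB": "AF", "(AF": "AF",
}


class RRParseError(ValueError):
    """Raised when an RR table file does not conform to the dialect."""


@dataclass
class RRSeries:
    """One record's RR-interval tachogram with per-interval annotations.

    Parameters
    ----------
    record_id : str
        Identifier of the source record.
    fs : float
        Sampling frequency of the underlying ECG in Hz; RR durations from
        annotations are integer multiples of the sampling period
        ``1000 / fs`` ms.
    rr_ms : ndarray of float
        Ordered RR durations in milliseconds, all positive.
    beat_type : ndarray of str
        Code of the beat *terminating* each interval (see :data:`BEAT_CODES`).
    rhythm : ndarray of str
        Rhythm annotation in force at each interval's terminating beat
        (see :data:`RHYTHM_CODES`).
    meta : dict
        Free-form provenance (e.g. generator seed).
    """

    record_id: str
    fs: float
    rr_ms: np.ndarray
    beat_type: np.ndarray
    rhythm: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.beat_type = np.asarray(self.beat_type, dtype="U1")
        self.rhythm = np.asarray(self.rhythm, dtype="U2")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        n = len(self.rr_ms)
        if len(self.beat_type) != n or len(self.rhythm) != n:
            raise ValueError(
                "rr_ms, beat_type and rhythm must have equal length "
                f"({n}, {len(self.beat_type)}, {len(self.rhythm)})"
            )
        if n and not np.all(self.rr_ms > 0):
            raise ValueError("all RR durations must be positive")
        bad = set(np.unique(self.beat_type)) - set(BEAT_CODES)
        if bad:
            raise ValueError(f"unknown beat codes: {sorted(bad)}")
        bad = set(np.unique(self.rhythm)) - set(RHYTHM_CODES)
        if bad:
            raise ValueError(f"unknown rhythm codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.rr_ms)

    @property
    def delta_ms(self) -> float:
        """Sampling period 1000/fs in ms (the RR quantization step)."""
        return 1000.0 / self.fs

    @property
    def duration_ms(self) -> float:
        return float(self.rr_ms.sum())


def read_rr_table(path: str | Path) -> RRSeries:
    """Read an RR series from the plain tabular dialect.

    The dialect is UTF-8 text: comment header lines ``# record_id=<id>``
    and ``# fs=<Hz>``, then CSV rows ``rr_ms,beat_type,rhythm``.

    Raises
    ------
    RRParseError
        On missing header keys or columns, non-numeric RR values or
        unknown codes; the message names the offending line number.
    """
    path = Path(path)
    record_id = None
    fs = None
    rr, bt, rh = [], [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key = key.strip()
                    if key == "record_id":
                        record_id = val.strip()
                    elif key == "fs":
                        try:
                            fs = float(val)
                        except ValueError:
                            raise RRParseError(
                                f"{path}:{lineno}: non-numeric fs {val!r}"
                            ) from None
                continue
            parts = [p.strip() for p in line.split(",")]
            if parts[0] == "rr_ms":  # optional column header row
                continue
            if len(parts) != 3:
                raise RRParseError(
                    f"{path}:{lineno}: expected 3 columns "
                    f"(rr_ms,beat_type,rhythm), got {len(parts)}"
                )
            try:
                rr.append(float(parts[0]))
            except ValueError:
                raise RRParseError(
                    f"{path}:{lineno}: non-numeric rr_ms {parts[0]!r}"
                ) from None
            if parts[1] not in BEAT_CODES:
                raise RRParseError(
                    f"{path}:{lineno}: unknown beat code {parts[1]!r}"
                )
            if parts[2] not in RHYTHM_CODES:
                raise RRParseError(
                    f"{path}:{lineno}: unknown rhythm code {parts[2]!r}"
                )
            bt.append(parts[1])
            rh.append(parts[2])
    if fs is None:
        raise RRParseError(f"{path}: missing '# fs=' header line")
    if record_id is None:
        record_id = path.stem
    try:
        return RRSeries(record_id, fs, np.array(rr), np.array(bt), np.array(rh))
    except ValueError as exc:
        raise RRParseError(f"{path}: {exc}") from exc


def write_rr_table(series: RRSeries, path: str | Path) -> None:
    """Write *series* in the plain tabular dialect (inverse of
    :func:`read_rr_table`)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# record_id={series.record_id}\n")
        fh.write(f"# fs={series.fs:g}\n")
        fh.write("rr_ms,beat_type,rhythm\n")
        for rr, bt, rh in zip(series.rr_ms, series.beat_type, series.rhythm):
            fh.write(f"{rr:g},{bt},{rh}\n")


def from_annotations(
    beat_samples,
    beat_codes,
    rhythm_labels,
    fs: float,
    record_id: str = "",
) -> RRSeries:
    """Build an :class:`RRSeries` from beat-level annotations.

    Parameters
    ----------
    beat_samples : sequence of int
        Strictly increasing 0-based R-wave sample indices.
    beat_codes : sequence of str
        One beat symbol per beat; WFDB symbols are mapped to the dialect
        codes, already-valid dialect codes pass through.
    rhythm_labels : sequence of str
        Per-beat rhythm aux strings (``"(AFIB"``, ``"(N"``, or ``""``);
        a non-empty label changes the rhythm in force from that beat on.
    fs : float
        Sampling frequency in Hz.

    Returns
    -------
    RRSeries
        ``rr_ms[i] = (beat_samples[i+1] - beat_samples[i]) * 1000 / fs``;
        each interval inherits the beat type and rhythm of its terminating
        beat.
    """
    samples = np.asarray(beat_samples, dtype=np.int64)
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if len(samples) and np.any(np.diff(samples) <= 0):
        bad = int(np.argmax(np.diff(samples) <= 0))
        raise ValueError(
            f"beat samples must be strictly increasing "
            f"(violation at beat {bad + 1})"
        )
    beat_codes = list(beat_codes)
    rhythm_labels = list(rhythm_labels)
    if not (len(beat_codes) == len(rhythm_labels) == len(samples)):
        raise ValueError("beat_samples, beat_codes, rhythm_labels lengths differ")

    # rhythm in force at each beat: carry the last non-empty aux forward
    rhythm_at = []
    current = "O"
    for aux in rhythm_labels:
        if aux:
            current = WFDB_RHYTHM_MAP.get(aux, aux if aux in RHYTHM_CODES else "O")
        rhythm_at.append(current)

    rr_ms = np.diff(samples) * (1000.0 / fs)
    bt = [
        c if c in BEAT_CODES else WFDB_BEAT_MAP.get(c, "O")
        for c in beat_codes[1:]
    ]
    return RRSeries(
        record_id=record_id,
        fs=fs,
        rr_ms=rr_ms,
        beat_type=np.array(bt, dtype="U1"),
        rhythm=np.array(rhythm_at[1:], dtype="U2"),
    )


def read_wfdb(record: str, annotator: str = "atr") -> RRSeries:
    """Read a PhysioNet WFDB annotation record through the ``wfdb`` package.

    Thin adapter over :func:`from_annotations`; requires the optional
    ``wfdb`` dependency (``pip install prrx[wfdb]``) and a locally
    downloaded record.
    """
    try:
        import wfdb  # noqa: PLC0415 - optional dependency
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package"
        ) from exc
    ann = wfdb.rdann(record, annotator)  # pragma: no cover - optional path
    aux = [a.rstrip("\x00") for a in ann.aux_note]  # pragma: no cover
    return from_annotations(  # pragma: no cover
        ann.sample, ann.symbol, aux, float(ann.fs), record_id=Path(record).name
    )
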