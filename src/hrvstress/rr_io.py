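"""Input/output for RR-interval series, beat annotations, and tabular results.

The central container is :class:`RRSeries`: an ordered sequence of RR
(beat-to-beat) intervals in milliseconds together with cumulative beat times
in seconds and a per-beat quality flag.  Beat ``i``'s time is the *end* of
interval ``i`` (the cumulative sum including ``rr[i]``); this convention fixes
the uneven-sampling abscissa used by the Lomb-Scargle periodogram and is used
everywhere in the package.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FLAG_OK",
    "FLAG_OUTLIER",
    "FLAG_ECTOPIC",
    "FLAG_INTERPOLATED",
    "RRSeries",
    "LabeledSegment",
    "ParseError",
    "EmptyInputError",
    "ValidationError",
    "read_rr_text",
    "write_rr_text",
    "read_wfdb_annotation",
    "read_segments",
    "write_segments",
    "write_table",
    "read_table",
]

# Per-beat quality flags.  A corrected beat keeps its original classification
# and additionally carries FLAG_INTERPOLATED (flags are a bit mask).
FLAG_OK = 0
FLAG_OUTLIER = 1
FLAG_ECTOPIC = 2
FLAG_INTERPOLATED = 4

_FLAG_NAMES = {
    FLAG_OK: "ok",
    FLAG_OUTLIER: "outlier",
    FLAG_ECTOPIC: "ectopic",
    FLAG_INTERPOLATED: "interpolated",
}


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class EmptyInputError(ValueError):
    """An input file contained no usable data."""


class ValidationError(ValueError):
    """Structured input violated a contract (overlap, unknown label, ...)."""


@dataclass
class RRSeries:
    """Beat-indexed RR durations with cumulative beat times and flags.

    Parameters
    ----------
    record_id:
        Identifier of the recording.
    rr:
        RR intervals in milliseconds, strictly positive.
    beat_time:
        Elapsed time in seconds at each beat, ``beat_time[i] ==
        cumsum(rr[: i + 1]) / 1000``.  Rebuilt automatically when omitted.
    flags:
        Per-beat quality bit mask (``FLAG_OK`` / ``FLAG_OUTLIER`` /
        ``FLAG_ECTOPIC`` optionally combined with ``FLAG_INTERPOLATED``).
    """

    record_id: str
    rr: np.ndarray
    beat_time: np.ndarray = None  # type: ignore[assignment]
    flags: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        if self.rr.ndim != 1:
            raise ValidationError("rr must be one-dimensional")
        if self.rr.size == 0:
            raise EmptyInputError(f"record {self.record_id!r}: no RR intervals")
        if np.any(self.rr <= 0):
            raise ValidationError(f"record {self.record_id!r}: non-positive RR interval")
        if self.beat_time is None:
            self.beat_time = np.cumsum(self.rr) / 1000.0
        else:
            self.beat_time = np.asarray(self.beat_time, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(self.rr.size, dtype=np.int8)
        else:
            self.flags = np.asarray(self.flags, dtype=np.int8)
        if not (self.rr.size == self.beat_time.size == self.flags.size):
            raise ValidationError("rr, beat_time and flags must have equal length")
        if np.any(np.diff(self.beat_time) <= 0):
            raise ValidationError("beat_time must be strictly increasing")

    def __len__(self) -> int:
        return int(self.rr.size)

    def flag_names(self) -> list[str]:
        """Human-readable flag labels, e.g. ``'outlier+interpolated'``."""
        out = []
        for f in self.flags:
            f = int(f)
            if f == FLAG_OK:
                out.append("ok")
                continue
            parts = [name for bit, name in _FLAG_NAMES.items() if bit and f & bit]
            out.append("+".join(parts))
        return out


@dataclass(frozen=True)
class LabeledSegment:
    """A time interval of a recording carrying one stress-condition label."""

    start: float
    end: float
    label: str

    VALID_LABELS = ("low", "high", "excluded")

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"segment start {self.start} must precede end {self.end}")
        if self.label not in self.VALID_LABELS:
            raise ValidationError(
                f"unknown segment label {self.label!r}; expected one of {self.VALID_LABELS}"
            )

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


# ---------------------------------------------------------------------------
# RR text dialect: one value per line, '#' comments, blank lines ignored.
# A CSV variant with a 'rr_ms' header column is accepted transparently.
# ---------------------------------------------------------------------------

def read_rr_text(path: str | Path, unit: str = "ms", record_id: str | None = None) -> RRSeries:
    """Read an RR series from plain text (one interval per line) or rr_ms CSV.

    Parameters
    ----------
    path:
        Input file.  Lines that are blank or start with ``#`` are ignored.
        A file whose first data line is the header ``rr_ms`` is read as the
        one-column CSV dialect.
    unit:
        ``'ms'`` or ``'s'``; values are converted to milliseconds internally.
    """
    if unit not in ("ms", "s"):
        raise ValueError(f"unit must be 'ms' or 's', got {unit!r}")
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = [
        (i + 1, ln.strip()) for i, ln in enumerate(lines)
        if ln.strip() and not ln.strip().startswith("#")
    ]
    if data_lines and data_lines[0][1].lower() == "rr_ms":
        data_lines = data_lines[1:]
    for lineno, text in data_lines:
        try:
            values.append(float(text))
        except ValueError:
            raise ParseError(f"{path}: non-numeric RR value {text!r} at line {lineno}") from None
    if not values:
        raise EmptyInputError(f"{path}: no RR values found")
    rr = np.asarray(values, dtype=float)
    if unit == "s":
        rr = rr * 1000.0
    return RRSeries(record_id=record_id or path.stem, rr=rr)


def write_rr_text(series: RRSeries, path: str | Path) -> None:
    """Write an RR series in the plain-text dialect (ms, one value per line)."""
    with open(path, "w") as fh:
        fh.write(f"# record {series.record_id}\n")
        for v in series.rr:
            fh.write(f"{v:.12g}\n")


# ---------------------------------------------------------------------------
# Minimal WFDB (MIT-format) beat-annotation reader.
# ---------------------------------------------------------------------------

# Annotation codes regarded as beats (QRS complexes) in the MIT code table:
# NORMAL..BBB, plus paced/fusion/ectopic beat codes.  Non-beat event codes
# (rhythm changes, signal quality, comments) are excluded.
_BEAT_CODES = frozenset(
    [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 30, 31, 34, 35, 38, 41]
)


def _read_header_fs(header_path: Path) -> float:
    """Sampling frequency from a WFDB .hea file (3rd token of the record line)."""
    with open(header_path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            # record-name n_sig [fs [...]]
            if len(tokens) >= 3:
                try:
                    return float(tokens[2].split("/")[0])
                except ValueError as exc:
                    raise ParseError(f"{header_path}: bad sampling frequency {tokens[2]!r}") from exc
            return 250.0  # WFDB default when fs is absent
    raise ParseError(f"{header_path}: no record line found")


def _read_annotation_samples(ann_path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Beat sample indices and annotation codes from a MIT-format file.

    The format is a stream of little-endian 16-bit words: the high 6 bits are
    the annotation code, the low 10 bits the sample-interval increment.  Codes
    59-63 are pseudo-annotations (SKIP carries a 4-byte interval; NUM, SUB,
    CHN modify state; AUX is followed by a padded byte string); code 0 with
    increment 0 is end-of-file.
    """
    data = ann_path.read_bytes()
    samples: list[int] = []
    codes: list[int] = []
    t = 0
    i = 0
    n = len(data)
    while i + 1 < n:
        word = struct.unpack_from("<H", data, i)[0]
        i += 2
        code = word >> 10
        incr = word & 0x3FF
        if code == 0 and incr == 0:  # EOF
            break
        if code == 59:  # SKIP: next two words hold a 32-bit interval
            if i + 3 >= n:
                raise ParseError(f"{ann_path}: truncated SKIP pseudo-annotation")
            high = struct.unpack_from("<H", data, i)[0]
            low = struct.unpack_from("<H", data, i + 2)[0]
            i += 4
            t += (high << 16) | low
            continue
        if code in (60, 61, 62):  # NUM / SUB / CHN: state only
            continue
        if code == 63:  # AUX: incr = byte count, padded to even
            i += incr + (incr & 1)
            continue
        t += incr
        if code in _BEAT_CODES:
            samples.append(t)
            codes.append(code)
    return np.asarray(samples, dtype=np.int64), np.asarray(codes, dtype=np.int16)


def read_wfdb_annotation(
    record_path: str | Path, annotator: str = "atr", record_id: str | None = None
) -> RRSeries:
    """Read beat annotations of a WFDB record and return the RR series.

    ``record_path`` is the record path without extension; ``<record>.hea``
    supplies the sampling frequency and ``<record>.<annotator>`` the beat
    annotations.  RR intervals are successive differences of beat sample
    indices divided by the sampling frequency, in milliseconds.
    """
    record_path = Path(record_path)
    header = record_path.with_suffix(".hea")
    ann = record_path.with_suffix(f".{annotator}")
    if not header.exists():
        raise IOError(f"missing WFDB header {header}")
    if not ann.exists():
        raise IOError(f"missing WFDB annotation file {ann}")
    fs = _read_header_fs(header)
    samples, _codes = _read_annotation_samples(ann)
    if samples.size < 2:
        raise EmptyInputError(f"{ann}: fewer than 2 beat annotations")
    rr_ms = np.diff(samples) / fs * 1000.0
    return RRSeries(record_id=record_id or record_path.name, rr=rr_ms)


# ---------------------------------------------------------------------------
# Segment-label files.
# ---------------------------------------------------------------------------

def read_segments(path: str | Path) -> list[LabeledSegment]:
    """Read, validate and time-sort a segment-label CSV (start_s,end_s,label)."""
    df = pd.read_csv(path)
    required = {"start_s", "end_s", "label"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    segments = [
        LabeledSegment(float(r.start_s), float(r.end_s), str(r.label).strip())
        for r in df.itertuples()
    ]
    return validate_segments(segments)


def validate_segments(segments: Iterable[LabeledSegment]) -> list[LabeledSegment]:
    """Sort segments by start time and reject overlaps."""
    segs = sorted(segments, key=lambda s: s.start)
    for a, b in zip(segs, segs[1:]):
        if b.start < a.end:
            raise ValidationError(
                f"segments ({a.start},{a.end},{a.label}) and "
                f"({b.start},{b.end},{b.label}) overlap"
            )
    return segs


def write_segments(segments: Sequence[LabeledSegment], path: str | Path) -> None:
    pd.DataFrame(
        {"start_s": [s.start for s in segments],
         "end_s": [s.end for s in segments],
         "label": [s.label for s in segments]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Tabular outputs.  CSV with a stable column order; floats carry 12
# significant digits so a write/read round trip is value-identical at that
# textual precision.
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature/report table as CSV (12 significant digits)."""
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty table")
    table.to_csv(path, index=False, float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
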