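"""RR-series cleaning and multi-scale, center-aligned epoching.

Cleaning applies two rules in one forward pass over the beats:

* **outlier** — an interval outside ``[rr_min, rr_max]`` (defaults 280 and
  1500 ms);
* **ectopic** — an interval differing from the reference interval by more
  than ``ectopic_frac`` (default 20%).  The reference is the last *accepted*
  interval: a flagged beat never becomes the reference, so a single artifact
  cannot cascade flags down the series.

Flagged beats are replaced by linear interpolation over beat index between
the nearest non-flagged neighbours (nearest non-flagged value at either end),
and beat times are rebuilt from the corrected intervals.  Exactly one pass is
made; an interpolated value is never re-examined.

Epoching divides the retained span (everything after a head discard,
default 300 s) into consecutive non-overlapping 5-minute parent epochs.
Each shorter scale (30 s, 1, 2, 3 min) contributes one sub-epoch per parent
sharing the parent's midpoint, so every ultra-short epoch is nested inside
— and pairs with — its own 5-minute epoch.  An epoch inherits the label of
the segment containing its parent midpoint; midpoints falling in no segment
or in an ``excluded`` segment drop the epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .rr_io import (
    FLAG_ECTOPIC,
    FLAG_INTERPOLATED,
    FLAG_OK,
    FLAG_OUTLIER,
    LabeledSegment,
    RRSeries,
)

__all__ = [
    "SCALE_SECONDS",
    "SCALES",
    "CleanConfig",
    "Epoch",
    "EpochSet",
    "DegenerateSeriesError",
    "clean_rr",
    "segment_epochs",
    "epoch_manifest",
]

#: Nominal duration in seconds of each analysis scale.  5 min is the
#: reference (short-term) scale; the others are the ultra-short scales.
SCALE_SECONDS: dict[str, int] = {
    "30s": 30,
    "1min": 60,
    "2min": 120,
    "3min": 180,
    "5min": 300,
}
SCALES: tuple[str, ...] = tuple(SCALE_SECONDS)
REFERENCE_SCALE = "5min"


class DegenerateSeriesError(ValueError):
    """Every beat of a series was flagged; nothing to interpolate from."""


@dataclass(frozen=True)
class CleanConfig:
    """Cleaning and epoching parameters.

    Attributes
    ----------
    rr_min, rr_max:
        Physiological plausibility bounds in ms; intervals outside are
        outliers.
    ectopic_frac:
        Maximum tolerated relative change versus the reference interval.
    discard_head:
        Seconds discarded from the start of every recording (poor signal
        quality at hook-up).
    min_beats:
        Minimum intervals for an epoch to be analyzable (sample entropy and
        spectral estimates are meaningless on near-empty windows).
    """

    rr_min: float = 280.0
    rr_max: float = 1500.0
    ectopic_frac: float = 0.20
    discard_head: float = 300.0
    min_beats: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.rr_min < self.rr_max:
            raise ValueError("require 0 < rr_min < rr_max")
        if not 0 < self.ectopic_frac < 1:
            raise ValueError("ectopic_frac must be in (0, 1)")
        if self.discard_head < 0:
            raise ValueError("discard_head must be >= 0")


def clean_rr(series: RRSeries, cfg: CleanConfig = CleanConfig()) -> RRSeries:
    """Flag outlier/ectopic beats and replace them by linear interpolation.

    Returns a new :class:`RRSeries` of the same length whose ``flags`` record
    the original classification plus ``interpolated`` for every corrected
    beat, and whose ``beat_time`` is rebuilt from the corrected intervals.
    """
    rr = series.rr.copy()
    n = rr.size
    flags = np.zeros(n, dtype=np.int8)

    ref: float | None = None  # last accepted interval
    for i in range(n):
        if not (cfg.rr_min <= rr[i] <= cfg.rr_max):
            flags[i] = FLAG_OUTLIER
        elif ref is not None and abs(rr[i] - ref) / ref > cfg.ectopic_frac:
            flags[i] = FLAG_ECTOPIC
        else:
            ref = rr[i]

    bad = flags != FLAG_OK
    if bad.all():
        raise DegenerateSeriesError(
            f"record {series.record_id!r}: every beat flagged; cannot interpolate"
        )
    if bad.any():
        good_idx = np.flatnonzero(~bad)
        rr[bad] = np.interp(np.flatnonzero(bad), good_idx, rr[good_idx])
        flags[bad] |= FLAG_INTERPOLATED

    return RRSeries(record_id=series.record_id, rr=rr, flags=flags)


@dataclass(frozen=True)
class Epoch:
    """One labeled analysis window; sub-epochs share their parent's midpoint."""

    record_id: str
    scale: str
    parent_index: int
    start: float
    end: float
    label: str
    rr_view: np.ndarray = field(repr=False)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def n_beats(self) -> int:
        return int(self.rr_view.size)


@dataclass
class EpochSet:
    """All epochs of one or more records plus the validity threshold."""

    epochs: list[Epoch]
    min_beats: int = 10

    def valid(self) -> list[Epoch]:
        return [e for e in self.epochs if e.n_beats >= self.min_beats]

    def at_scale(self, scale: str) -> list[Epoch]:
        return [e for e in self.valid() if e.scale == scale]

    def __len__(self) -> int:
        return len(self.epochs)

    def extend(self, other: "EpochSet") -> None:
        self.epochs.extend(other.epochs)


def _label_at(segments: Sequence[LabeledSegment], t: float) -> str | None:
    for seg in segments:
        if seg.contains(t):
            return seg.label
    return None


def segment_epochs(
    series: RRSeries,
    segments: Sequence[LabeledSegment],
    cfg: CleanConfig = CleanConfig(),
    scales: Iterable[str] = SCALES,
) -> EpochSet:
    """Cut labeled epochs at the requested scales from a cleaned series.

    Consecutive 300-s parent windows start at ``cfg.discard_head``; a
    trailing partial window is dropped.  Parents whose midpoint lies in no
    segment or in an ``excluded`` segment are dropped together with their
    sub-epochs.  Windows are half-open ``[start, end)`` on beat time.
    """
    scales = list(scales)
    unknown = set(scales) - set(SCALE_SECONDS)
    if unknown:
        raise ValueError(f"unknown scales {sorted(unknown)}")

    t = series.beat_time
    rr = series.rr
    t_end = t[-1]
    parent_len = SCALE_SECONDS[REFERENCE_SCALE]

    epochs: list[Epoch] = []
    parent_index = 0
    start = cfg.discard_head
    while start + parent_len <= t_end:
        end = start + parent_len
        mid = (start + end) / 2.0
        label = _label_at(segments, mid)
        if label in ("low", "high"):
            for scale in scales:
                dur = SCALE_SECONDS[scale]
                s = mid - dur / 2.0
                e = mid + dur / 2.0
                view = rr[(t >= s) & (t < e)]
                epochs.append(
                    Epoch(
                        record_id=series.record_id,
                        scale=scale,
                        parent_index=parent_index,
                        start=s,
                        end=e,
                        label=label,
                        rr_view=view,
                    )
                )
        parent_index += 1
        start = end

    return EpochSet(epochs=epochs, min_beats=cfg.min_beats)


def epoch_manifest(epoch_set: EpochSet) -> pd.DataFrame:
    """Tabular epoch summary (record, scale, parent, window, label, beats)."""
    rows = [
        {
            "record_id": e.record_id,
            "scale": e.scale,
            "parent_index": e.parent_index,
            "start_s": e.start,
            "end_s": e.end,
            "label": e.label,
            "n_beats": e.n_beats,
        }
        for e in epoch_set.epochs
    ]
    return pd.DataFrame(rows)
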