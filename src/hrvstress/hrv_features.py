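"""The 22-feature HRV suite: time-domain, spectral, and non-linear measures.

Computed per epoch on its RR view (milliseconds):

* 10 time-domain features — MeanNN, SDNN, SDSD, NN50, pNN50, NN20, pNN20,
  RMSSD, MeanHR, SDHR.  Every feature standard deviation uses the population
  (1/n) normalization: one convention everywhere, under which both dispersion
  identities hold exactly — SD1 = SDSD/sqrt(2) and RMSSD^2 = SDSD^2 +
  mean(diff)^2 (hence RMSSD >= SDSD).
  pNN50/pNN20 are the threshold counts divided by the total number of RR
  intervals in the epoch (not the number of successive pairs).  MeanHR and
  SDHR are the mean and SD of the instantaneous per-beat heart rate
  60000/RR_i in bpm.
* 7 frequency-domain features — band powers of the RR tachogram estimated
  with the Lomb-Scargle periodogram, which handles the unevenly sampled beat
  times directly without resampling.  VLF is (f_min, 0.04] Hz, LF
  (0.04, 0.15] Hz, HF (0.15, 0.4] Hz; TP = VLF + LF + HF by construction
  (the trapezoid quadrature segments partition exactly); LFnu = LF/(LF+HF),
  HFnu = HF/(LF+HF), LF/HF their ratio.
* 5 non-linear features — Poincaré descriptors SD1/SD2 (dispersion of the
  lagged scatter perpendicular/parallel to the identity line), the Toichi
  indices CSI = SD2/SD1 and CVI = log10(16*SD1*SD2), and sample entropy
  (m = 2, r = 0.2*SDNN, Chebyshev distance, self-matches excluded).

Undefined values (e.g. LF/HF with zero HF power, SampEn with no template
matches) propagate as NaN — an explicit not-available marker that downstream
statistics drop, never absorb as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lombscargle
from scipy.spatial.distance import pdist

from .preprocess import Epoch, EpochSet

__all__ = [
    "FEATURE_NAMES",
    "TIME_DOMAIN_FEATURES",
    "FREQUENCY_FEATURES",
    "NONLINEAR_FEATURES",
    "FrequencyGrid",
    "grid_for_duration",
    "time_domain",
    "lomb_scargle_psd",
    "frequency_features",
    "sample_entropy",
    "nonlinear_features",
    "extract_features",
    "extract_all",
    "InsufficientDataError",
]

TIME_DOMAIN_FEATURES = (
    "MeanNN", "SDNN", "SDSD", "NN50", "pNN50", "NN20", "pNN20",
    "RMSSD", "MeanHR", "SDHR",
)
FREQUENCY_FEATURES = ("LF", "HF", "LF_HF", "TP", "VLF", "LFnu", "HFnu")
NONLINEAR_FEATURES = ("CSI", "CVI", "SD1", "SD2", "SampEn")

#: Canonical column order of the feature table.
FEATURE_NAMES: tuple[str, ...] = TIME_DOMAIN_FEATURES + FREQUENCY_FEATURES + NONLINEAR_FEATURES

VLF_EDGE = 0.04
LF_EDGE = 0.15
HF_EDGE = 0.40


class InsufficientDataError(ValueError):
    """Too few intervals for the requested feature."""


# ---------------------------------------------------------------------------
# Time domain
# ---------------------------------------------------------------------------

def time_domain(rr: np.ndarray) -> dict[str, float]:
    """The ten time-domain features of an epoch's RR view (ms)."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise InsufficientDataError("time-domain features need >= 2 intervals")
    d = np.diff(rr)
    hr = 60000.0 / rr
    nn50 = int(np.sum(np.abs(d) > 50.0))
    nn20 = int(np.sum(np.abs(d) > 20.0))
    return {
        "MeanNN": float(np.mean(rr)),
        "SDNN": float(np.std(rr)),
        "SDSD": float(np.std(d)),
        "NN50": float(nn50),
        "pNN50": nn50 / rr.size,
        "NN20": float(nn20),
        "pNN20": nn20 / rr.size,
        "RMSSD": float(np.sqrt(np.mean(d**2))),
        "MeanHR": float(np.mean(hr)),
        "SDHR": float(np.std(hr)),
    }


# ---------------------------------------------------------------------------
# Frequency domain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyGrid:
    """Evaluation frequencies (Hz) for the periodogram, strictly increasing."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 1 or f.size < 2 or np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be 1-D, strictly increasing, length >= 2")
        object.__setattr__(self, "freqs", f)


def grid_for_duration(duration_s: float, f_max: float = HF_EDGE,
                      oversample: int = 4, f_floor: float = 0.003) -> FrequencyGrid:
    """Frequency grid tied to the epoch length.

    The lowest frequency is ``max(1/T, f_floor)`` — one full cycle must fit in
    the window — and the spacing is ``1/(oversample*T)``, so short epochs get
    proportionally coarser grids and stay computable (with VLF/LF necessarily
    unreliable below the window's resolution).
    """
    f_min = max(1.0 / duration_s, f_floor)
    df = 1.0 / (oversample * duration_s)
    n = int(np.floor((f_max - f_min) / df + 1e-9))
    return FrequencyGrid(f_min + df * np.arange(n + 1))


def lomb_scargle_psd(rr: np.ndarray, beat_time: np.ndarray,
                     grid: FrequencyGrid) -> np.ndarray:
    """Lomb-Scargle power spectral density of the RR tachogram (ms^2/Hz).

    The mean-subtracted periodogram is rescaled so that trapezoidal
    integration over the full grid equals the sample variance of the series
    (ms^2); band powers in physical units then follow directly from
    quadrature, and total power matches SDNN^2 (population variance).
    """
    rr = np.asarray(rr, dtype=float)
    t = np.asarray(beat_time, dtype=float)
    if rr.size < 4:
        raise InsufficientDataError("spectral features need >= 4 intervals")
    var = float(np.var(rr))
    if var == 0.0:
        return np.zeros_like(grid.freqs)
    y = rr - rr.mean()
    power = lombscargle(t, y, 2.0 * np.pi * grid.freqs)
    total = float(np.trapezoid(power, grid.freqs))
    if total <= 0.0:
        return np.zeros_like(grid.freqs)
    return power * (var / total)


def frequency_features(psd: np.ndarray, grid: FrequencyGrid) -> dict[str, float]:
    """Band powers by trapezoidal quadrature; the bands partition the grid.

    Each trapezoid segment is assigned to the band containing its midpoint,
    so VLF + LF + HF equals TP exactly (identical quadrature).
    """
    f = grid.freqs
    psd = np.asarray(psd, dtype=float)
    if psd.shape != f.shape:
        raise ValueError("psd and grid shapes differ")
    seg_area = 0.5 * (psd[:-1] + psd[1:]) * np.diff(f)
    mid = 0.5 * (f[:-1] + f[1:])
    vlf = float(seg_area[mid <= VLF_EDGE].sum())
    lf = float(seg_area[(mid > VLF_EDGE) & (mid <= LF_EDGE)].sum())
    hf = float(seg_area[mid > LF_EDGE].sum())
    tp = vlf + lf + hf
    lf_hf = lf / hf if hf > 0 else np.nan
    denom = lf + hf
    lfnu = lf / denom if denom > 0 else np.nan
    hfnu = hf / denom if denom > 0 else np.nan
    return {"LF": lf, "HF": hf, "LF_HF": lf_hf, "TP": tp,
            "VLF": vlf, "LFnu": lfnu, "HFnu": hfnu}


# ---------------------------------------------------------------------------
# Non-linear
# ---------------------------------------------------------------------------

def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy: -ln(A/B) with Chebyshev distance, no self-matches.

    ``B`` counts pairs of length-``m`` templates within tolerance ``r`` among
    the ``n - m`` templates that admit an (m+1)-extension; ``A`` counts the
    matching (m+1)-extensions.  ``r`` defaults to 0.2 times the sample SD of
    ``x`` (1 ms fallback for a constant series).  Returns NaN when either
    count is zero.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise InsufficientDataError(f"sample entropy needs >= {m + 2} points")
    if r is None:
        sd = float(np.std(x))
        r = 0.2 * sd if sd > 0 else 1.0

    # Templates restricted to the n-m positions that extend to length m+1,
    # per the standard counting convention.
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[: n - m]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    b = int(np.sum(pdist(tm, metric="chebyshev") <= r))
    a = int(np.sum(pdist(tm1, metric="chebyshev") <= r))
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


def nonlinear_features(rr: np.ndarray) -> dict[str, float]:
    """Poincaré descriptors (SD1/SD2, CSI, CVI) and sample entropy."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 3:
        raise InsufficientDataError("Poincaré features need >= 3 intervals")
    d = np.diff(rr)
    s = rr[1:] + rr[:-1]
    sd1 = float(np.std(d / np.sqrt(2.0)))
    sd2 = float(np.std(s / np.sqrt(2.0)))
    csi = sd2 / sd1 if sd1 > 0 else np.nan
    cvi = float(np.log10(16.0 * sd1 * sd2)) if sd1 > 0 and sd2 > 0 else np.nan
    try:
        sampen = sample_entropy(rr)
    except InsufficientDataError:
        sampen = np.nan
    return {"CSI": csi, "CVI": cvi, "SD1": sd1, "SD2": sd2, "SampEn": sampen}


# ---------------------------------------------------------------------------
# Per-epoch assembly
# ---------------------------------------------------------------------------

def extract_features(epoch: Epoch) -> dict[str, float]:
    """All 22 features of one epoch, NaN where undefined."""
    rr = epoch.rr_view
    row: dict[str, float] = {}
    row.update(time_domain(rr))
    duration = epoch.end - epoch.start
    try:
        grid = grid_for_duration(duration)
        t0 = np.cumsum(rr) / 1000.0  # epoch-local beat times
        psd = lomb_scargle_psd(rr, t0, grid)
        row.update(frequency_features(psd, grid))
    except InsufficientDataError:
        row.update({k: np.nan for k in FREQUENCY_FEATURES})
    try:
        row.update(nonlinear_features(rr))
    except InsufficientDataError:
        row.update({k: np.nan for k in NONLINEAR_FEATURES})
    return row


def extract_all(epoch_set: EpochSet) -> pd.DataFrame:
    """Feature table: one row per valid epoch, 22 feature columns.

    Rows are keyed by (record_id, parent_index, scale, label); the feature
    columns follow the canonical order of :data:`FEATURE_NAMES`.
    """
    rows = []
    for epoch in epoch_set.valid():
        row = {
            "record_id": epoch.record_id,
            "parent_index": epoch.parent_index,
            "scale": epoch.scale,
            "label": epoch.label,
        }
        row.update(extract_features(epoch))
        rows.append(row)
    columns = ["record_id", "parent_index", "scale", "label", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=columns)
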