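"""Synthetic labeled RR recordings with controllable stress structure.

The generator emulates the statistical contrasts the analysis pipeline
assumes between a low-stress and a high-stress state: mean RR level,
overall variability, oscillatory power in the LF (~0.1 Hz) and HF
(~0.25 Hz) bands, and beat-to-beat regularity.  Beat-by-beat synthesis:

    rr_i = mean_rr + lf_amp * sin(2*pi*f_LF*t_i + phi_LF)
                   + hf_amp * sin(2*pi*f_HF*t_i + phi_HF) + e_i

with AR(1) noise e_i = knob * e_{i-1} + N(0, noise_sd) and beat times t_i
accumulated from the generated intervals themselves, so the series is
unevenly sampled exactly like a real tachogram.  Oscillator frequencies are
drawn once per record from narrow bands around 0.1 and 0.25 Hz rather than
fixed, to avoid grid-aligned spectral-leakage artifacts in tests.

Artifacts are injected post hoc with per-beat probabilities: an *outlier*
replaces the interval by a draw outside the physiological 280-1500 ms
range; an *ectopic* scales it by a factor outside [0.8, 1.25], guaranteeing
violation of the 20% successive-change rule relative to an undisturbed
neighbour.  Ground truth (injected positions, drawn frequencies, per-state
design parameters) is returned alongside.

The default study configuration mirrors a rest/city-drive protocol: two
low-stress blocks flanking a high-stress block, with the high-stress state
having shorter intervals, larger overall variability, a larger LF/HF
amplitude ratio, and a more oscillation-dominated (hence more regular,
lower-entropy) signal.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np

from .rr_io import LabeledSegment, RRSeries, write_rr_text, write_segments

__all__ = [
    "StressStateParams",
    "SimConfig",
    "default_sim_config",
    "generate",
    "make_stress_study",
]

OUTLIER_RANGE = (280.0, 1500.0)
ECTOPIC_FACTOR_RANGE = (0.8, 1.25)


@dataclass(frozen=True)
class StressStateParams:
    """Design parameters of one stress state.

    Attributes
    ----------
    mean_rr:
        Mean RR interval in ms (high stress -> shorter intervals).
    lf_amp, hf_amp:
        Amplitudes (ms) of the ~0.1 Hz and ~0.25 Hz oscillations; their
        squared ratio sets the LF/HF band-power ratio.
    noise_sd:
        Innovation SD (ms) of the AR(1) jitter.
    sampen_knob:
        AR(1) coefficient in [0, 1) shaping the noise autocorrelation.
    sdnn_target:
        Optional overall SD (ms).  When set, the innovation SD is rescaled
        so the stationary series SD equals it (the oscillations contribute
        amp^2/2 each); must exceed the oscillatory contribution.
    """

    mean_rr: float
    lf_amp: float = 0.0
    hf_amp: float = 0.0
    noise_sd: float = 0.0
    sampen_knob: float = 0.0
    sdnn_target: float | None = None

    def __post_init__(self) -> None:
        if not 400.0 <= self.mean_rr <= 1400.0:
            raise ValueError(f"mean_rr {self.mean_rr} outside [400, 1400] ms")
        if self.lf_amp < 0 or self.hf_amp < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise_sd must be >= 0")
        if not 0.0 <= self.sampen_knob < 1.0:
            raise ValueError("sampen_knob must be in [0, 1)")
        if self.sdnn_target is not None:
            osc_var = self.lf_amp**2 / 2 + self.hf_amp**2 / 2
            if self.sdnn_target**2 <= osc_var:
                raise ValueError(
                    "sdnn_target^2 must exceed the oscillatory variance "
                    f"({osc_var:.1f} ms^2)"
                )

    @property
    def innovation_sd(self) -> float:
        """Innovation SD actually used (derived from sdnn_target when set)."""
        if self.sdnn_target is None:
            return self.noise_sd
        noise_var = self.sdnn_target**2 - self.lf_amp**2 / 2 - self.hf_amp**2 / 2
        return float(np.sqrt(noise_var * (1.0 - self.sampen_knob**2)))

    @property
    def stationary_sd(self) -> float:
        """Design SD of the generated series (oscillations + AR(1) noise)."""
        inn = self.innovation_sd
        noise_var = inn**2 / (1.0 - self.sampen_knob**2)
        return float(np.sqrt(self.lf_amp**2 / 2 + self.hf_amp**2 / 2 + noise_var))


@dataclass(frozen=True)
class SimConfig:
    """A full simulated recording: labeled blocks, state parameters, artifacts."""

    segments: tuple[tuple[float, str], ...]
    params: dict[str, StressStateParams]
    outlier_rate: float = 0.0
    ectopic_rate: float = 0.0
    seed: int = 0
    record_id: str = "synthetic"
    #: Seconds over which state parameters blend linearly after a segment
    #: transition; heart rate shifts over tens of seconds, not one beat, and
    #: an instantaneous mean-RR step would itself trip the 20% ectopic rule.
    ramp_s: float = 30.0

    def __post_init__(self) -> None:
        for dur, state in self.segments:
            if dur < 600.0:
                raise ValueError(f"segment duration {dur} s < 600 s (need >= 2 parent epochs)")
            if state not in self.params:
                raise ValueError(f"segment state {state!r} has no parameters")
        for rate in (self.outlier_rate, self.ectopic_rate):
            if not 0.0 <= rate <= 0.1:
                raise ValueError("artifact rates must be in [0, 0.1]")
        for state, p in self.params.items():
            # 5-sigma excursion below the floor means the config cannot
            # guarantee positive intervals.
            if p.mean_rr - p.lf_amp - p.hf_amp - 5.0 * p.stationary_sd <= 0:
                raise ValueError(f"state {state!r}: parameters imply non-positive RR")


def default_sim_config(seed: int = 0, outlier_rate: float = 0.0,
                       ectopic_rate: float = 0.0) -> SimConfig:
    """The default two-state stress study.

    The high-stress state has a lower mean RR (tachycardia), a higher overall
    variability, a much larger LF/HF amplitude ratio (sympathetic Mayer-wave
    dominance), and a signal dominated by its deterministic oscillatory
    component — hence lower sample entropy, visibly so even in 30-s windows
    where the entropy estimator is at its noisiest.  The low-stress state is
    jitter-dominated: weak oscillations over near-white beat-to-beat noise.

    The single record emulates the *pooled* epoch corpus of a multi-subject
    stress study: two long low-stress blocks flanking a high-stress block,
    59 five-minute epochs in total after the 300-s head discard (38 low,
    21 high).
    """
    low = StressStateParams(mean_rr=850.0, lf_amp=12.0, hf_amp=10.0,
                            noise_sd=28.0, sampen_knob=0.35)
    high = StressStateParams(mean_rr=700.0, lf_amp=60.0, hf_amp=5.0,
                             noise_sd=4.0, sampen_knob=0.20)
    return SimConfig(
        segments=((6000.0, "low"), (6300.0, "high"), (5700.0, "low")),
        params={"low": low, "high": high},
        outlier_rate=outlier_rate,
        ectopic_rate=ectopic_rate,
        seed=seed,
    )


def generate(config: SimConfig) -> tuple[RRSeries, list[LabeledSegment], dict]:
    """Synthesize one labeled RR recording plus its ground-truth record."""
    rng = np.random.default_rng(config.seed)
    f_lf = rng.uniform(0.095, 0.105)
    f_hf = rng.uniform(0.24, 0.26)
    phi_lf = rng.uniform(0.0, 2.0 * np.pi)
    phi_hf = rng.uniform(0.0, 2.0 * np.pi)

    rr: list[float] = []
    states: list[str] = []
    t = 0.0
    e = 0.0
    seg_start = 0.0
    segments: list[LabeledSegment] = []
    prev: StressStateParams | None = None
    for duration, state in config.segments:
        p = config.params[state]
        seg_end = seg_start + duration
        segments.append(LabeledSegment(seg_start, seg_end, state))
        while t < seg_end:
            if prev is not None and config.ramp_s > 0 and t < seg_start + config.ramp_s:
                w = (t - seg_start) / config.ramp_s
            else:
                w = 1.0
            mean_rr = (1 - w) * (prev.mean_rr if prev else p.mean_rr) + w * p.mean_rr
            lf_amp = (1 - w) * (prev.lf_amp if prev else p.lf_amp) + w * p.lf_amp
            hf_amp = (1 - w) * (prev.hf_amp if prev else p.hf_amp) + w * p.hf_amp
            inn = (1 - w) * (prev.innovation_sd if prev else p.innovation_sd) + w * p.innovation_sd
            knob = (1 - w) * (prev.sampen_knob if prev else p.sampen_knob) + w * p.sampen_knob
            e = knob * e + rng.normal(0.0, inn)
            val = (
                mean_rr
                + lf_amp * np.sin(2.0 * np.pi * f_lf * t + phi_lf)
                + hf_amp * np.sin(2.0 * np.pi * f_hf * t + phi_hf)
                + e
            )
            if val <= 0:  # unreachable under config validation; hard guard
                raise RuntimeError("generated a non-positive RR interval")
            rr.append(val)
            states.append(state)
            t += val / 1000.0
        prev = p
        seg_start = seg_end

    rr_arr = np.asarray(rr, dtype=float)

    # Post-hoc artifact injection; outliers take precedence over ectopics
    # when both fire on the same beat.
    n = rr_arr.size
    out_mask = rng.random(n) < config.outlier_rate
    ect_mask = (rng.random(n) < config.ectopic_rate) & ~out_mask
    out_idx = np.flatnonzero(out_mask)
    ect_idx = np.flatnonzero(ect_mask)
    for i in out_idx:
        if rng.random() < 0.5:
            rr_arr[i] = rng.uniform(100.0, OUTLIER_RANGE[0] - 20.0)
        else:
            rr_arr[i] = rng.uniform(OUTLIER_RANGE[1] + 100.0, 2200.0)
    for i in ect_idx:
        if rng.random() < 0.5:
            rr_arr[i] *= rng.uniform(0.50, 0.75)
        else:
            rr_arr[i] *= rng.uniform(1.35, 1.60)

    series = RRSeries(record_id=config.record_id, rr=rr_arr)
    truth = {
        "seed": config.seed,
        "f_lf": f_lf,
        "f_hf": f_hf,
        "outlier_indices": out_idx.tolist(),
        "ectopic_indices": ect_idx.tolist(),
        "beat_states": states,
        "params": {k: asdict(v) for k, v in config.params.items()},
        "segments": [(s.start, s.end, s.label) for s in segments],
    }
    return series, segments, truth


def make_stress_study(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Emit rr text, segment CSV, and truth JSON consumable by the pipeline."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series, segments, truth = generate(config)
    paths = {
        "rr": out_dir / "rr.txt",
        "segments": out_dir / "segments.csv",
        "truth": out_dir / "truth.json",
    }
    write_rr_text(series, paths["rr"])
    write_segments(segments, paths["segments"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2)
    return paths
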