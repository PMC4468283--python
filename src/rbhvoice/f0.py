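"""Frame-level voicing decision and fundamental-frequency estimation.

The speech signal (16 kHz) is cut into 16 ms frames with a 10 ms shift.  Each
frame gets an RMS energy; a frame is voiced when the normalized
autocorrelation within the F0 search range shows a clear peak AND its energy
is not negligible relative to the recording.  F0 on voiced frames comes from
the best lag of the normalized cross-correlation, refined by parabolic
interpolation, then median-smoothed with an octave-jump correction that folds
isolated doubling/tripling/halving errors back to the neighbour consensus.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import FramingConfig, VoicingConfig
from .errors import EmptyTrackError
from .io import Recording


@dataclass
class FrameTrack:
    """Per-frame analysis results over a recording."""

    frame_length: float
    frame_shift: float
    sample_rate: int
    energy: np.ndarray                      # RMS per frame
    voiced: np.ndarray | None = None        # bool per frame
    f0: np.ndarray | None = None            # Hz, NaN where unvoiced

    @property
    def n_frames(self) -> int:
        return len(self.energy)

    @property
    def times(self) -> np.ndarray:
        """Frame-center times in seconds."""
        return np.arange(self.n_frames) * self.frame_shift + self.frame_length / 2

    def frames_in(self, start: float, end: float) -> np.ndarray:
        """Indices of frames whose center lies in [start, end)."""
        t = self.times
        return np.nonzero((t >= start) & (t < end))[0]


@dataclass
class VoicedSection:
    start_frame: int
    end_frame: int  # exclusive
    voiced: bool

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class VoicedSectionList:
    """Maximal runs of equal voicing covering the track exactly once."""

    sections: list[VoicedSection]
    frame_shift: float

    def subset(self, voiced: bool) -> list[VoicedSection]:
        return [s for s in self.sections if s.voiced == voiced]

    def count(self, voiced: bool) -> int:
        return len(self.subset(voiced))

    def lengths(self, voiced: bool) -> np.ndarray:
        """Section lengths in seconds (frames x shift)."""
        return np.array([s.n_frames * self.frame_shift for s in self.subset(voiced)])


def frame_signal(recording: Recording, config: FramingConfig | None = None) -> FrameTrack:
    """Cut the speech channel into frames and compute per-frame RMS energy."""
    cfg = config or FramingConfig()
    sr = recording.sample_rate
    flen = int(round(cfg.frame_length * sr))
    shift = int(round(cfg.frame_shift * sr))
    x = recording.speech
    if len(x) < flen:
        raise EmptyTrackError(
            f"signal of {len(x)} samples is shorter than one {flen}-sample frame")
    n_frames = (len(x) - flen) // shift + 1
    idx = np.arange(flen)[None, :] + shift * np.arange(n_frames)[:, None]
    frames = x[idx]
    energy = np.sqrt(np.mean(frames * frames, axis=1))
    return FrameTrack(cfg.frame_length, cfg.frame_shift, sr, energy)


def _frame_correlation(x: np.ndarray, center: int, min_lag: int, max_lag: int
                       ) -> np.ndarray:
    """Normalized cross-correlation over lags [min_lag, max_lag] around a frame.

    The correlation window spans ``max_lag`` samples on each side of the frame
    center (zero-padded at the signal edges), so that even the lowest F0 in the
    search range contributes a full period.
    """
    n = max_lag
    lo, hi = center - n, center + n
    w = np.zeros(2 * n)
    s0, s1 = max(lo, 0), min(hi, len(x))
    w[s0 - lo:s1 - lo] = x[s0:s1]
    num = np.correlate(w, w[:n], mode="valid")  # lags 0 .. n
    csum = np.concatenate(([0.0], np.cumsum(w * w)))
    e0 = csum[n] - csum[0]
    lags = np.arange(min_lag, max_lag + 1)
    e_lag = csum[lags + n] - csum[lags]
    den = np.sqrt(e0 * e_lag)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num[min_lag:max_lag + 1] / den, 0.0)
    return r


def _best_lag(r: np.ndarray, min_lag: int, subharmonic_ratio: float = 0.0
              ) -> tuple[float, float]:
    """Peak lag (parabolic-refined) and the maximal correlation value.

    A periodic signal correlates at the period T and at 2T, 3T, ..., and
    under jitter a multiple can even edge out T itself, so the raw argmax is
    prone to subharmonic (octave-down) errors.  When ``subharmonic_ratio`` is
    set, the chosen lag is the *shortest* local maximum whose correlation
    reaches that fraction of the best peak; exact score ties break toward the
    longer lag (lower F0) to bias against octave-up errors.
    """
    best = len(r) - 1 - int(np.argmax(r[::-1]))
    peak = float(r[best])
    chosen = best
    if subharmonic_ratio > 0.0 and peak > 0.0:
        floor = subharmonic_ratio * peak
        interior = np.arange(1, len(r) - 1)
        local_max = interior[(r[interior] >= r[interior - 1])
                             & (r[interior] >= r[interior + 1])
                             & (r[interior] >= floor)]
        if len(local_max):
            chosen = min(int(local_max[0]), best)
    lag = float(chosen + min_lag)
    if 0 < chosen < len(r) - 1:
        y0, y1, y2 = r[chosen - 1], r[chosen], r[chosen + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            lag += float(np.clip(delta, -0.5, 0.5))
    return lag, peak


def detect_voicing(track: FrameTrack, recording: Recording,
                   config: VoicingConfig | None = None) -> FrameTrack:
    """Flag voiced frames (autocorrelation peak AND relative-energy gates)."""
    cfg = config or VoicingConfig()
    sr = recording.sample_rate
    min_lag = int(np.floor(sr / cfg.f0_max))
    max_lag = int(np.ceil(sr / cfg.f0_min))
    flen = int(round(track.frame_length * sr))
    shift = int(round(track.frame_shift * sr))
    # level reference over non-silent frames only, so that padding a recording
    # with digital silence does not move the gate
    nonzero = track.energy[track.energy > 0]
    e_gate = cfg.e_thresh * (float(np.median(nonzero)) if len(nonzero) else 0.0)
    voiced = np.zeros(track.n_frames, dtype=bool)
    peaks = np.zeros(track.n_frames)
    x = recording.speech
    for i in range(track.n_frames):
        if track.energy[i] < e_gate or track.energy[i] == 0.0:
            continue
        center = i * shift + flen // 2
        r = _frame_correlation(x, center, min_lag, max_lag)
        _, peak = _best_lag(r, min_lag)
        peaks[i] = peak
        voiced[i] = peak >= cfg.v_thresh
    track.voiced = voiced
    return track


def _median_smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(values) == 0:
        return values
    half = window // 2
    out = np.empty_like(values)
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        out[i] = np.median(values[lo:hi])
    return out


_OCTAVE_FACTORS = (2.0, 3.0, 0.5, 1.0 / 3.0)


def _fold_octave_jumps(f0: np.ndarray, tol: float) -> np.ndarray:
    """Fold frames sitting at 2x/3x/(1/2)x/(1/3)x of both neighbours back down.

    The consensus of the two neighbours is their mean when they agree within
    ``tol``; a folded frame is divided by the offending factor, so corrections
    only ever apply a factor from {1/3, 1/2, 2, 3}.
    """
    out = f0.copy()
    for i in range(1, len(f0) - 1):
        a, b = out[i - 1], out[i + 1]
        if abs(a - b) > tol * max(a, b):
            continue
        consensus = 0.5 * (a + b)
        for k in _OCTAVE_FACTORS:
            if abs(out[i] - k * consensus) <= tol * k * consensus:
                if k != 1.0:
                    out[i] = out[i] / k
                break
    return out


def estimate_f0(track: FrameTrack, recording: Recording,
                config: VoicingConfig | None = None) -> FrameTrack:
    """Estimate F0 (Hz) on every voiced frame; NaN elsewhere."""
    cfg = config or VoicingConfig()
    if track.voiced is None:
        detect_voicing(track, recording, cfg)
    sr = recording.sample_rate
    min_lag = int(np.floor(sr / cfg.f0_max))
    max_lag = int(np.ceil(sr / cfg.f0_min))
    flen = int(round(track.frame_length * sr))
    shift = int(round(track.frame_shift * sr))
    f0 = np.full(track.n_frames, np.nan)
    x = recording.speech
    voiced_idx = np.nonzero(track.voiced)[0]
    for i in voiced_idx:
        center = i * shift + flen // 2
        r = _frame_correlation(x, center, min_lag, max_lag)
        lag, _ = _best_lag(r, min_lag, cfg.subharmonic_ratio)
        f0[i] = sr / lag
    # smooth and correct within each voiced run independently
    run_start = None
    for i in range(track.n_frames + 1):
        in_run = i < track.n_frames and track.voiced[i]
        if in_run and run_start is None:
            run_start = i
        elif not in_run and run_start is not None:
            seg = f0[run_start:i]
            seg = _median_smooth(seg, cfg.median_window)
            seg = _fold_octave_jumps(seg, cfg.octave_tolerance)
            f0[run_start:i] = seg
            run_start = None
    f0 = np.clip(f0, cfg.f0_min, cfg.f0_max)
    track.f0 = f0
    return track


def segment_sections(track: FrameTrack) -> VoicedSectionList:
    """Run-length encode the voicing flags into maximal sections."""
    flags = track.voiced
    if flags is None:
        raise ValueError("voicing flags not computed yet")
    sections: list[VoicedSection] = []
    start = 0
    for i in range(1, len(flags) + 1):
        if i == len(flags) or flags[i] != flags[start]:
            sections.append(VoicedSection(start, i, bool(flags[start])))
            start = i
    if len(flags) == 0:
        sections = []
    return VoicedSectionList(sections, track.frame_shift)


def analyze_track(recording: Recording, framing: FramingConfig | None = None,
                  voicing: VoicingConfig | None = None) -> FrameTrack:
    """Convenience: frame, detect voicing, estimate F0 in one call."""
    track = frame_signal(recording, framing)
    detect_voicing(track, recording, voicing)
    estimate_f0(track, recording, voicing)
    return track


def track_to_tsv(track: FrameTrack) -> str:
    """Debug dump: frame_index, time, energy, voiced, f0."""
    lines = ["frame\ttime\tenergy\tvoiced\tf0"]
    f0 = track.f0 if track.f0 is not None else np.full(track.n_frames, np.nan)
    voiced = track.voiced if track.voiced is not None else np.zeros(track.n_frames, bool)
    for i, t in enumerate(track.times):
        f0s = "" if np.isnan(f0[i]) else f"{f0[i]:.6g}"
        lines.append(f"{i}\t{t:.4f}\t{track.energy[i]:.6g}\t{int(voiced[i])}\t{f0s}")
    return "\n".join(lines) + "\n"
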