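"""Word-level and window-level prosodic features.

For every word, 33 features describe pauses, the energy contour, duration and
the F0 contour, each in up to two contexts: the word itself (``W``) and the
word-pause-word interval spanning the two preceding words (``WPW``).  Fifteen
"global" features are computed on consecutive 15-word windows from jitter,
shimmer, and voiced/unvoiced section statistics.  Averaging the per-word and
per-window vectors over the recording yields one feature vector per speaker.

Normalisations (the exact conventions are package choices, see
docs/methods.md): F0 is expressed in semitones relative to the recording
median of voiced frames; energy is normalised by the recording mean frame
energy; duration by the expected duration of the word's character count at
the recording's mean duration per character.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ProsodyConfig
from .errors import UndefinedValueError, ValidationError
from .f0 import FrameTrack, VoicedSectionList, segment_sections
from .features import GLOBAL_FEATURES, LOCAL_FEATURES
from .io import Recording, WordAlignment, WordInterval

_WPW_FEATURES = tuple(f for f in LOCAL_FEATURES if f.endswith("WPW"))


# ---------------------------------------------------------------------------
# irregularity primitives


def jitter(periods) -> float:
    """Local relative jitter: mean |T_{i+1} - T_i| / mean T (dimensionless)."""
    t = np.asarray(periods, dtype=float)
    if len(t) < 2:
        raise UndefinedValueError("jitter needs at least 2 periods")
    return float(np.mean(np.abs(np.diff(t))) / np.mean(t))


def shimmer(amplitudes) -> float:
    """Local relative shimmer: mean |A_{i+1} - A_i| / mean A (dimensionless)."""
    a = np.asarray(amplitudes, dtype=float)
    if len(a) < 2:
        raise UndefinedValueError("shimmer needs at least 2 amplitudes")
    return float(np.mean(np.abs(np.diff(a))) / np.mean(a))


# ---------------------------------------------------------------------------
# helpers


def _regression(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and mean squared residual of y over t."""
    if len(y) < 2 or np.ptp(t) == 0:
        return 0.0, 0.0
    coeffs = np.polyfit(t, y, 1)
    resid = y - np.polyval(coeffs, t)
    return float(coeffs[0]), float(np.mean(resid * resid))


def _semitones(f0: np.ndarray, ref: float) -> np.ndarray:
    return 12.0 * np.log2(f0 / ref)


def _rel_pos(t: float, t0: float, t1: float) -> float:
    return float(np.clip((t - t0) / (t1 - t0), 0.0, 1.0))


class _RecordingContext:
    """Recording-level reference values shared by all word computations."""

    def __init__(self, recording: Recording, alignment: WordAlignment,
                 track: FrameTrack, config: ProsodyConfig):
        self.track = track
        self.config = config
        self.words = alignment.words(config.filler_labels)
        if not self.words:
            raise ValidationError("alignment contains no non-filler words")
        self.fills = alignment.fills(config.filler_labels)
        nonzero = track.energy[track.energy > 0]
        self.mean_energy = float(np.mean(nonzero)) if len(nonzero) else np.nan
        if track.f0 is not None and np.any(~np.isnan(track.f0)):
            self.median_f0 = float(np.nanmedian(track.f0))
        else:
            self.median_f0 = np.nan
        total_dur = sum(w.end - w.start for w in self.words)
        total_chars = sum(max(len(w.label), 1) for w in self.words)
        self.dur_per_char = total_dur / total_chars


def _energy_features(ctx: _RecordingContext, t0: float, t1: float,
                     suffix: str, with_max: bool) -> dict[str, float]:
    track = ctx.track
    idx = track.frames_in(t0, t1)
    out: dict[str, float] = {}
    if len(idx) == 0:
        keys = ["EnRegCoeff", "EnMseReg", "EnAbs", "EnNorm", "EnMean"]
        out = {k + suffix: np.nan for k in keys}
        if with_max:
            out["EnMax" + suffix] = np.nan
            out["EnMaxPos" + suffix] = np.nan
        return out
    en = track.energy[idx]
    t = track.times[idx]
    slope, mse = _regression(t - t0, en)
    out["EnRegCoeff" + suffix] = slope
    out["EnMseReg" + suffix] = mse
    out["EnAbs" + suffix] = float(np.sum(en))
    out["EnMean" + suffix] = float(np.mean(en))
    out["EnNorm" + suffix] = float(np.mean(en)) / ctx.mean_energy
    if with_max:
        k = int(np.argmax(en))
        out["EnMax" + suffix] = float(en[k])
        out["EnMaxPos" + suffix] = _rel_pos(t[k], t0, t1)
    return out


def _f0_features(ctx: _RecordingContext, t0: float, t1: float,
                 suffix: str, full: bool) -> dict[str, float]:
    track = ctx.track
    idx = track.frames_in(t0, t1)
    if track.f0 is None:
        raise ValidationError("track has no F0 estimates")
    voiced = idx[~np.isnan(track.f0[idx])]
    if len(voiced) == 0 or np.isnan(ctx.median_f0):
        out = {"F0RegCoeff" + suffix: np.nan, "F0MseReg" + suffix: np.nan}
        if full:
            for n in ("F0Mean", "F0Max", "F0MaxPos", "F0Min", "F0MinPos",
                      "F0Off", "F0OffPos", "F0On", "F0OnPos"):
                out[n + "W"] = np.nan
        return out
    st = _semitones(track.f0[voiced], ctx.median_f0)
    t = track.times[voiced]
    slope, mse = _regression(t - t0, st)
    out = {"F0RegCoeff" + suffix: slope, "F0MseReg" + suffix: mse}
    if full:
        kmax, kmin = int(np.argmax(st)), int(np.argmin(st))
        out.update({
            "F0MeanW": float(np.mean(st)),
            "F0MaxW": float(st[kmax]), "F0MaxPosW": _rel_pos(t[kmax], t0, t1),
            "F0MinW": float(st[kmin]), "F0MinPosW": _rel_pos(t[kmin], t0, t1),
            "F0OnW": float(st[0]), "F0OnPosW": _rel_pos(t[0], t0, t1),
            "F0OffW": float(st[-1]), "F0OffPosW": _rel_pos(t[-1], t0, t1),
        })
    return out


def _pauses(ctx: _RecordingContext, i: int) -> dict[str, float]:
    """Silent and filled pause durations before and after word i."""
    words = ctx.words
    out = {"PauseBefore": 0.0, "PauseFillBefore": 0.0,
           "PauseAfter": 0.0, "PauseFillAfter": 0.0}

    def fill_in(lo: float, hi: float) -> float:
        return sum(min(f.end, hi) - max(f.start, lo)
                   for f in ctx.fills if f.start < hi and f.end > lo)

    if i > 0:
        gap_lo, gap_hi = words[i - 1].end, words[i].start
        filled = fill_in(gap_lo, gap_hi)
        out["PauseFillBefore"] = filled
        out["PauseBefore"] = max(gap_hi - gap_lo - filled, 0.0)
    if i < len(words) - 1:
        gap_lo, gap_hi = words[i].end, words[i + 1].start
        filled = fill_in(gap_lo, gap_hi)
        out["PauseFillAfter"] = filled
        out["PauseAfter"] = max(gap_hi - gap_lo - filled, 0.0)
    return out


# ---------------------------------------------------------------------------
# local (per-word) extraction


def extract_local(recording: Recording, alignment: WordAlignment,
                  track: FrameTrack, config: ProsodyConfig | None = None
                  ) -> pd.DataFrame:
    """One 33-feature vector per word (rows: word index, columns: features).

    Word-pause-word (WPW) features of the first two words, which have no such
    context, are imputed with the recording mean of the feature; F0 features
    of words without any voiced frame stay NaN and are skipped on
    aggregation.
    """
    cfg = config or ProsodyConfig()
    ctx = _RecordingContext(recording, alignment, track, cfg)
    words = ctx.words
    rows = []
    for i, w in enumerate(words):
        feats: dict[str, float] = {}
        feats.update(_pauses(ctx, i))
        # current-word context
        feats.update(_energy_features(ctx, w.start, w.end, "W", with_max=True))
        feats.update(_f0_features(ctx, w.start, w.end, "W", full=True))
        feats["DurAbsW"] = w.end - w.start
        feats["DurNormW"] = feats["DurAbsW"] / (
            max(len(w.label), 1) * ctx.dur_per_char)
        # word-pause-word context: the two words preceding the current one
        if i >= 2:
            a, b = words[i - 2], words[i - 1]
            feats.update(_energy_features(ctx, a.start, b.end, "WPW", with_max=False))
            feats.update(_f0_features(ctx, a.start, b.end, "WPW", full=False))
            feats["DurAbsWPW"] = b.end - a.start
            nchar = max(len(a.label), 1) + max(len(b.label), 1)
            feats["DurNormWPW"] = feats["DurAbsWPW"] / (nchar * ctx.dur_per_char)
        else:
            for name in _WPW_FEATURES:
                feats[name] = np.nan
        rows.append(feats)
    table = pd.DataFrame(rows, columns=list(LOCAL_FEATURES))
    assert table.shape[1] == 33
    # impute missing WPW context (first two words) with the recording mean
    for name in _WPW_FEATURES:
        col = table[name]
        if col.iloc[:2].isna().any() and col.iloc[2:].notna().any():
            table.loc[col.isna(), name] = float(col.iloc[2:].mean())
    return table


# ---------------------------------------------------------------------------
# pitch-synchronous cycle peaks (for jitter/shimmer on running speech)


def _dominant_sign(x: np.ndarray) -> float:
    return 1.0 if abs(float(x.max())) >= abs(float(x.min())) else -1.0


def _refine(x: np.ndarray, p: int) -> tuple[float, float]:
    """Parabolic sub-sample refinement of a local maximum: (position, value)."""
    if 0 < p < len(x) - 1:
        y0, y1, y2 = x[p - 1], x[p], x[p + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            d = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
            return p + d, float(y1 - 0.25 * (y0 - y2) * d)
    return float(p), float(x[p])


def cycle_peaks(signal: np.ndarray, sample_rate: float, t0: float, t1: float,
                f0_hint: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-cycle waveform peaks in [t0, t1), seeded by an F0 hint.

    Starting from the strongest peak, successive cycle peaks are located by
    stepping one expected period and searching +-30 % around the predicted
    position.  Returns sub-sample peak times (s) and amplitudes; the first and
    last cycle are dropped to avoid onset/offset transients.
    """
    n0, n1 = int(round(t0 * sample_rate)), int(round(t1 * sample_rate))
    seg = np.asarray(signal[max(n0, 0):min(n1, len(signal))], dtype=float)
    period = sample_rate / f0_hint
    if len(seg) < 2 * period or not np.any(seg):
        return np.array([]), np.array([])
    seg = seg * _dominant_sign(seg)
    anchor = int(np.argmax(seg))
    half = max(int(round(0.3 * period)), 1)

    def walk(start: int, step: float) -> list[int]:
        found = []
        expected = start + step
        while 0 <= expected < len(seg):
            lo = max(int(round(expected)) - half, 0)
            hi = min(int(round(expected)) + half + 1, len(seg))
            if hi - lo < 2:
                break
            p = lo + int(np.argmax(seg[lo:hi]))
            found.append(p)
            expected = p + step
        return found

    peaks = sorted(walk(anchor, -period) + [anchor] + walk(anchor, period))
    if len(peaks) < 4:
        return np.array([]), np.array([])
    refined = [_refine(seg, p) for p in peaks]
    pos = np.array([r[0] for r in refined])
    amp = np.array([r[1] for r in refined])
    # trim weak edge peaks (onset buildup / offset decay spill-over), then one
    # more full cycle on each side against residual transients
    strong = amp >= 0.5 * np.median(amp)
    lo, hi = 0, len(amp)
    while lo < hi and not strong[lo]:
        lo += 1
    while hi > lo and not strong[hi - 1]:
        hi -= 1
    pos, amp = pos[lo + 1:hi - 1], amp[lo + 1:hi - 1]
    if len(pos) < 2:
        return np.array([]), np.array([])
    return (pos + n0) / sample_rate, amp


# ---------------------------------------------------------------------------
# global (per-window) extraction


def _word_windows(n_words: int, config: ProsodyConfig) -> list[tuple[int, int]]:
    """Consecutive non-overlapping index ranges of ~window_words words.

    A final remainder of at least ``min_tail_words`` becomes its own window;
    a shorter one is merged into the previous window.
    """
    w = config.window_words
    if n_words <= w:
        return [(0, n_words)]
    bounds = list(range(0, n_words, w))
    windows = [(b, min(b + w, n_words)) for b in bounds]
    last = windows[-1]
    if last[1] - last[0] < config.min_tail_words and len(windows) > 1:
        windows[-2] = (windows[-2][0], last[1])
        windows.pop()
    return windows


def _section_stats(sections: VoicedSectionList, t0: float, t1: float
                   ) -> dict[str, float]:
    shift = sections.frame_shift
    clipped: dict[bool, list[float]] = {True: [], False: []}
    for s in sections.sections:
        s_t0, s_t1 = s.start_frame * shift, s.end_frame * shift
        lo, hi = max(s_t0, t0), min(s_t1, t1)
        if hi - lo > 1e-12:
            clipped[s.voiced].append(hi - lo)
    span = t1 - t0
    v, u = clipped[True], clipped[False]
    len_v, len_u = sum(v), sum(u)
    return {
        "NumVoiced": float(len(v)),
        "MaxLenVoiced": max(v) if v else 0.0,
        "NumUnvoiced": float(len(u)),
        "MaxLenUnvoiced": max(u) if u else 0.0,
        "RelNumVoicedUnvoiced": len(v) / len(u) if u else np.nan,
        "RelLenVoicedSignal": len_v / span,
        "RelLenUnvoicedSignal": len_u / span,
        "MeanLenVoiced": len_v / len(v) if v else 0.0,
        "MeanLenUnvoiced": len_u / len(u) if u else 0.0,
        "RelLenVoicedUnvoiced": len_v / len_u if len_u > 0 else np.nan,
    }


def extract_global(recording: Recording, alignment: WordAlignment,
                   track: FrameTrack, config: ProsodyConfig | None = None
                   ) -> pd.DataFrame:
    """One 15-feature vector per 15-word window.

    Jitter and shimmer (percent) are computed per voiced section from
    pitch-synchronous waveform peaks seeded by the frame F0, then averaged
    over the sections inside the window; section counts and lengths are
    restricted to the window's time span; StandDevF0 is the standard
    deviation of the semitone-scale F0 over voiced frames.
    """
    cfg = config or ProsodyConfig()
    ctx = _RecordingContext(recording, alignment, track, cfg)
    sections = segment_sections(track)
    shift = track.frame_shift
    min_period, max_period = 1.0 / 500.0, 1.0 / 50.0

    windows = _word_windows(len(ctx.words), cfg)
    rows = []
    for a, b in windows:
        t0, t1 = ctx.words[a].start, ctx.words[b - 1].end
        feats = _section_stats(sections, t0, t1)
        # jitter/shimmer per voiced section inside the window
        jits, shims = [], []
        for s in sections.subset(True):
            s_t0 = max(s.start_frame * shift, t0)
            s_t1 = min(s.end_frame * shift + track.frame_length, t1)
            if s_t1 - s_t0 <= 0:
                continue
            f0_vals = track.f0[s.start_frame:s.end_frame]
            f0_vals = f0_vals[~np.isnan(f0_vals)]
            if len(f0_vals) == 0:
                continue
            times, amps = cycle_peaks(recording.speech, recording.sample_rate,
                                      s_t0, s_t1, float(np.median(f0_vals)))
            if len(times) < cfg.min_cycles_per_section:
                continue
            periods = np.diff(times)
            med = np.median(periods)
            ok = ((periods >= min_period) & (periods <= max_period)
                  & (np.abs(periods - med) <= 0.2 * med))
            if ok.sum() < cfg.min_cycles_per_section - 1:
                continue
            jits.append(100.0 * jitter(periods[ok]))
            shims.append(100.0 * shimmer(amps))
        feats["MeanJitter"] = float(np.mean(jits)) if jits else np.nan
        feats["StandDevJitter"] = float(np.std(jits)) if jits else np.nan
        feats["MeanShimmer"] = float(np.mean(shims)) if shims else np.nan
        feats["StandDevShimmer"] = float(np.std(shims)) if shims else np.nan
        # F0 spread over the window, semitone scale
        idx = track.frames_in(t0, t1)
        voiced = idx[~np.isnan(track.f0[idx])]
        if len(voiced) >= 2 and not np.isnan(ctx.median_f0):
            feats["StandDevF0"] = float(np.std(
                _semitones(track.f0[voiced], ctx.median_f0), ddof=1))
        else:
            feats["StandDevF0"] = np.nan
        rows.append(feats)
    table = pd.DataFrame(rows, columns=list(GLOBAL_FEATURES))
    assert table.shape[1] == 15
    return table


# ---------------------------------------------------------------------------
# recording-level aggregation


def aggregate(local_table: pd.DataFrame, global_table: pd.DataFrame,
              egg_summary=None) -> pd.Series:
    """Mean over words and windows -> one named vector per recording.

    Missing-coded (NaN) entries are skipped; a feature missing everywhere is
    dropped from the output.  CFx/CQx are appended when an EGG summary is
    given (48 + 2 values).
    """
    if len(local_table) == 0:
        raise ValidationError("no words to aggregate")
    values = {}
    for name in LOCAL_FEATURES:
        values[name] = float(local_table[name].mean())
    for name in GLOBAL_FEATURES:
        values[name] = float(global_table[name].mean())
    if egg_summary is not None:
        values["CFx"] = float(egg_summary.cfx)
        values["CQx"] = float(egg_summary.cqx)
    out = pd.Series(values)
    return out.dropna()
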