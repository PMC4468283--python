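"""Electroglottographic cycle analysis: Fx, Qx and the irregularity summaries.

The electroglottogram (EGG) tracks vocal-fold contact area; each closure
produces a steep rise, so closure instants are located as positive peaks of
the differentiated EGG (dEGG) above an adaptive threshold.  Per full cycle
between successive closures we compute the period frequency Fx = 1/T and the
contact quotient Qx (closed-phase time over period, percent).  The summaries
are mean absolute cycle-to-cycle changes: CFx in percent of the mean Fx, CQx
in percentage points of Qx.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .config import EggConfig
from .errors import UndefinedValueError


@dataclass
class EggCycleSeries:
    """Per-cycle results: one entry per full closure-to-closure cycle.

    ``contiguous[i]`` is True when cycle ``i+1`` starts exactly where cycle
    ``i`` ends; only contiguous pairs enter the cycle-to-cycle statistics, so
    unvoiced gaps never produce spurious irregularity.
    """

    closure_instants: np.ndarray     # s, start of each cycle
    period: np.ndarray               # s
    fx: np.ndarray                   # Hz
    qx: np.ndarray | None = None     # percent, NaN where undefined
    contiguous: np.ndarray | None = None  # bool, len n_cycles - 1

    @property
    def n_cycles(self) -> int:
        return len(self.period)

    def pairs(self) -> np.ndarray:
        """Indices i where cycles i and i+1 are contiguous."""
        if self.n_cycles < 2:
            return np.array([], dtype=int)
        if self.contiguous is None:
            return np.arange(self.n_cycles - 1)
        return np.nonzero(self.contiguous)[0]


@dataclass
class EggSummary:
    cfx: float      # percent
    cqx: float      # percentage points
    n_cycles: int


def _rolling_percentile(x: np.ndarray, window: int, q: float) -> np.ndarray:
    """Piecewise 95th-percentile envelope, linearly interpolated between hops."""
    if len(x) <= window:
        return np.full(len(x), np.percentile(x, q))
    hop = max(window // 2, 1)
    centers = np.arange(0, len(x), hop)
    values = np.array([
        np.percentile(x[max(0, c - window // 2):c + window // 2 + 1], q)
        for c in centers
    ])
    return np.interp(np.arange(len(x)), centers, values)


def _refine_peak(d: np.ndarray, p: int) -> float:
    """Sub-sample peak position by parabolic interpolation."""
    if 0 < p < len(d) - 1:
        y0, y1, y2 = d[p - 1], d[p], d[p + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            return p + float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
    return float(p)


def detect_cycles(egg: np.ndarray, sample_rate: float,
                  config: EggConfig | None = None) -> EggCycleSeries:
    """Locate closure instants and form full vocal-fold cycles.

    Peaks of dEGG must exceed ``peak_rel_threshold`` times the rolling 95th
    percentile of dEGG (floored at a tenth of the global maximum, so silence
    yields no peaks) and be at least ``1/fx_max`` apart.  Cycles implying an
    Fx outside [fx_min, fx_max] are discarded; partial cycles at the signal
    edges never form (only closure-to-closure spans count).
    """
    cfg = config or EggConfig()
    x = np.asarray(egg, dtype=float)
    if cfg.invert:
        x = -x
    d = np.diff(x) * sample_rate
    pos = np.clip(d, 0.0, None)
    if not np.any(pos > 0):
        raise UndefinedValueError("no positive dEGG excursion: no cycles")
    window = max(int(cfg.rolling_window * sample_rate), 3)
    envelope = _rolling_percentile(pos, window, 95.0)
    floor = 0.1 * float(pos.max())
    height = cfg.peak_rel_threshold * np.maximum(envelope, floor)
    min_sep = max(int(sample_rate / cfg.fx_max), 1)
    peaks, _ = find_peaks(d, height=height, distance=min_sep)
    if len(peaks) < 3:
        raise UndefinedValueError(f"only {len(peaks)} closure candidates found")
    instants = np.array([_refine_peak(d, p) for p in peaks]) / sample_rate
    periods = np.diff(instants)
    fx = 1.0 / periods
    valid = (fx >= cfg.fx_min) & (fx <= cfg.fx_max)
    if valid.sum() < 2:
        raise UndefinedValueError("fewer than 2 cycles in the admissible Fx range")
    idx = np.nonzero(valid)[0]
    contiguous = np.diff(idx) == 1
    return EggCycleSeries(
        closure_instants=instants[idx],
        period=periods[idx],
        fx=fx[idx],
        contiguous=contiguous,
    )


def contact_quotient(egg: np.ndarray, sample_rate: float, series: EggCycleSeries,
                     config: EggConfig | None = None) -> EggCycleSeries:
    """Per-cycle contact quotient Qx (percent of the period spent closed).

    Within each cycle the EGG is normalized to [0, 1] between its minimum and
    maximum; the closed phase is the total time above ``contact_level``, with
    threshold crossings placed by linear interpolation for sub-sample
    accuracy.  Flat cycles are skipped (Qx = NaN).
    """
    cfg = config or EggConfig()
    x = np.asarray(egg, dtype=float)
    if cfg.invert:
        x = -x
    qx = np.full(series.n_cycles, np.nan)
    for i in range(series.n_cycles):
        s0 = series.closure_instants[i] * sample_rate
        s1 = s0 + series.period[i] * sample_rate
        a, b = int(np.floor(s0)), int(np.ceil(s1))
        seg = x[max(a, 0):min(b + 1, len(x))]
        if len(seg) < 3:
            continue
        lo, hi = float(seg.min()), float(seg.max())
        if hi - lo <= 0:
            continue  # flat cycle
        level = lo + cfg.contact_level * (hi - lo)
        above = seg >= level
        t_closed = 0.0
        j = 0
        while j < len(seg) - 1:
            if above[j] and above[j + 1]:
                t_closed += 1.0
            elif above[j] != above[j + 1]:
                frac = (level - seg[j]) / (seg[j + 1] - seg[j])
                t_closed += (1.0 - frac) if above[j + 1] else frac
            j += 1
        qx[i] = 100.0 * (t_closed / sample_rate) / series.period[i]
    series.qx = qx
    return series


def cfx(series: EggCycleSeries) -> float:
    """Irregularity of Fx: 100 x mean |Fx_{i+1} - Fx_i| / mean Fx, percent."""
    pairs = series.pairs()
    if len(pairs) < 1 or series.n_cycles < 2:
        raise UndefinedValueError("CFx needs at least 2 contiguous cycles")
    diffs = np.abs(series.fx[pairs + 1] - series.fx[pairs])
    return 100.0 * float(np.mean(diffs)) / float(np.mean(series.fx))


def cqx(series: EggCycleSeries) -> float:
    """Irregularity of Qx: mean |Qx_{i+1} - Qx_i| in percentage points."""
    if series.qx is None:
        raise UndefinedValueError("contact quotient not computed")
    pairs = series.pairs()
    ok = [i for i in pairs
          if not (np.isnan(series.qx[i]) or np.isnan(series.qx[i + 1]))]
    if len(ok) < 1:
        raise UndefinedValueError("CQx needs at least 2 contiguous cycles with Qx")
    diffs = [abs(series.qx[i + 1] - series.qx[i]) for i in ok]
    return float(np.mean(diffs))


def analyze_egg(egg: np.ndarray, sample_rate: float,
                config: EggConfig | None = None
                ) -> tuple[EggCycleSeries, EggSummary]:
    """Full EGG chain: cycles, contact quotient, CFx/CQx summary."""
    cfg = config or EggConfig()
    series = detect_cycles(egg, sample_rate, cfg)
    contact_quotient(egg, sample_rate, series, cfg)
    return series, EggSummary(cfx=cfx(series), cqx=cqx(series),
                              n_cycles=series.n_cycles)


def series_to_tsv(series: EggCycleSeries) -> str:
    lines = ["cycle\tclosure_time\tperiod\tfx\tqx"]
    qx = series.qx if series.qx is not None else np.full(series.n_cycles, np.nan)
    for i in range(series.n_cycles):
        q = "" if np.isnan(qx[i]) else f"{qx[i]:.6g}"
        lines.append(f"{i}\t{series.closure_instants[i]:.6f}\t"
                     f"{series.period[i]:.6g}\t{series.fx[i]:.6g}\t{q}")
    return "\n".join(lines) + "\n"
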