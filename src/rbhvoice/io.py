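"""External formats and the shared data model.

Conventions used throughout the package:

* amplitudes are floating point in [-1, 1] regardless of the source bit depth;
* times are seconds, 0-based, in half-open intervals ``[start, end)``;
* the speech channel is analysed at exactly 16 kHz (anti-aliased resampling on
  read), while an electroglottographic (EGG) channel keeps its native rate;
* missing values are NaN, never silently zero.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import ConfigError, FormatError, ValidationError
from .features import CANONICAL_FEATURES

ANALYSIS_RATE = 16000
CRITERIA = ("R", "B", "H")


# ---------------------------------------------------------------------------
# recordings


@dataclass
class Recording:
    """A speech waveform (16 kHz) with an optional parallel EGG channel."""

    id: str
    speech: np.ndarray
    sample_rate: int = ANALYSIS_RATE
    egg: np.ndarray | None = None
    egg_sample_rate: float | None = None

    @property
    def duration(self) -> float:
        return len(self.speech) / self.sample_rate

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        self.speech = np.asarray(self.speech, dtype=float)
        if self.egg is not None:
            self.egg = np.asarray(self.egg, dtype=float)
            if not self.egg_sample_rate or self.egg_sample_rate <= 0:
                raise ValidationError("egg_sample_rate must be positive when egg is set")


def _to_float(x: np.ndarray) -> np.ndarray:
    """Scale integer PCM to [-1, 1]; pass floats through."""
    if x.dtype == np.int16:
        return x / 32768.0
    if x.dtype == np.int32:
        return x / 2147483648.0
    if x.dtype == np.uint8:
        return (x.astype(float) - 128.0) / 128.0
    return x.astype(float)


def _read_wav(path: str | Path) -> tuple[int, np.ndarray]:
    try:
        rate, data = wavfile.read(str(path))
    except (ValueError, EOFError) as exc:
        raise FormatError(f"{path}: not a readable PCM WAV file ({exc})") from exc
    return rate, _to_float(np.asarray(data))


def resample_to(x: np.ndarray, rate_in: int, rate_out: int) -> np.ndarray:
    if rate_in == rate_out:
        return np.asarray(x, dtype=float)
    g = math.gcd(int(rate_in), int(rate_out))
    return resample_poly(x, rate_out // g, rate_in // g)


def read_recording(
    audio_path: str | Path,
    egg_path: str | Path | None = None,
    channel_map: dict[str, int] | None = None,
    rec_id: str | None = None,
) -> Recording:
    """Read a recording from one or two WAV files.

    A two-channel ``audio_path`` is split according to ``channel_map``
    (e.g. ``{"speech": 0, "egg": 1}``); otherwise the optional ``egg_path``
    supplies the EGG channel.  Speech is resampled to 16 kHz.
    """
    rate, data = _read_wav(audio_path)
    egg = None
    egg_rate: float | None = None
    if data.ndim == 2:
        n_channels = data.shape[1]
        cmap = channel_map or {"speech": 0}
        for role, idx in cmap.items():
            if idx >= n_channels:
                raise ConfigError(
                    f"channel_map assigns {role!r} to channel {idx}, "
                    f"but the file has {n_channels} channels"
                )
        data_t = data.T
        speech = data_t[cmap.get("speech", 0)]
        if "egg" in cmap:
            egg = data_t[cmap["egg"]]
            egg_rate = float(rate)
    else:
        speech = data
    if egg_path is not None:
        egg_rate_f, egg_data = _read_wav(egg_path)
        if egg_data.ndim == 2:
            egg_data = egg_data[:, 0]
        egg, egg_rate = egg_data, float(egg_rate_f)
    speech = resample_to(speech, rate, ANALYSIS_RATE)
    return Recording(
        id=rec_id or Path(audio_path).stem,
        speech=speech,
        sample_rate=ANALYSIS_RATE,
        egg=egg,
        egg_sample_rate=egg_rate,
    )


def write_recording(recording: Recording, audio_path: str | Path,
                    egg_path: str | Path | None = None) -> None:
    """Write the speech (and optionally EGG) channels as float32 WAV."""
    wavfile.write(str(audio_path), recording.sample_rate,
                  recording.speech.astype(np.float32))
    if egg_path is not None and recording.egg is not None:
        wavfile.write(str(egg_path), int(recording.egg_sample_rate),
                      recording.egg.astype(np.float32))


# ---------------------------------------------------------------------------
# word alignments


@dataclass(frozen=True)
class WordInterval:
    label: str
    start: float
    end: float


@dataclass
class WordAlignment:
    """Ordered, non-overlapping labeled word intervals in seconds.

    Silent/empty intervals are dropped on read; pauses are recovered as gaps
    between consecutive entries.  Filled-pause labels stay in ``entries`` and
    are classified downstream against the configured filler set.
    """

    entries: list[WordInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("alignment contains no words")
        for e in self.entries:
            if not e.start < e.end:
                raise ValidationError(f"interval {e.label!r}: start {e.start} >= end {e.end}")
            if e.start < 0:
                raise ValidationError(f"interval {e.label!r} starts before 0")
        starts = [e.start for e in self.entries]
        if starts != sorted(starts):
            raise ValidationError("alignment entries are not sorted by start time")
        for a, b in zip(self.entries, self.entries[1:]):
            if b.start < a.end - 1e-9:
                raise ValidationError(
                    f"overlapping intervals: {a.label!r} [{a.start},{a.end}) and "
                    f"{b.label!r} [{b.start},{b.end})"
                )

    def words(self, filler_labels: tuple[str, ...] = ()) -> list[WordInterval]:
        fillers = {f.lower() for f in filler_labels}
        return [e for e in self.entries if e.label.lower() not in fillers]

    def fills(self, filler_labels: tuple[str, ...]) -> list[WordInterval]:
        fillers = {f.lower() for f in filler_labels}
        return [e for e in self.entries if e.label.lower() in fillers]


def _unquote(s: str) -> str:
    return s[1:-1].replace('""', '"')


def _textgrid_tokens(text: str) -> list[str | float]:
    """Reduce either TextGrid text form to a uniform value stream.

    The stream is: class, name, xmin, xmax, n, then n interval triples
    (xmin, xmax, text) or n point pairs, repeated per tier.  Header values
    (global xmin/xmax and the tier count) come first.
    """
    lines = text.splitlines()
    long_form = any(re.match(r"\s*xmin\s*=", ln) for ln in lines)
    tokens: list[str | float] = []
    if long_form:
        pat = re.compile(
            r'\s*(?:class|name|text|mark)\s*=\s*("(?:[^"]|"")*")\s*$'
            r"|\s*(?:xmin|xmax|number|time)\s*=\s*(-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?)\s*$"
            r"|\s*(?:size\s*=|intervals:\s*size\s*=|points:\s*size\s*=)\s*(\d+)\s*$"
        )
        for ln in lines:
            m = pat.match(ln)
            if not m:
                continue
            if m.group(1) is not None:
                tokens.append(_unquote(m.group(1)))
            elif m.group(2) is not None:
                tokens.append(float(m.group(2)))
            else:
                tokens.append(float(m.group(3)))
    else:
        for ln in lines[2:]:  # skip the two header lines
            ln = ln.strip()
            if not ln or ln == "<exists>":
                continue
            if ln.startswith('"'):
                tokens.append(_unquote(ln))
            else:
                m = re.match(r"-?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?$", ln)
                if m:
                    tokens.append(float(ln))
    return tokens


def _parse_textgrid(text: str, tier: str | None) -> list[tuple[str, float, float]]:
    """Parse a Praat TextGrid (long or short text form) into interval triples."""
    if "ooTextFile" not in text[:200] or "TextGrid" not in text[:200]:
        raise FormatError("not a Praat TextGrid (missing ooTextFile header)")
    tokens = _textgrid_tokens(text)
    pos = 0

    def take() -> str | float:
        nonlocal pos
        if pos >= len(tokens):
            raise FormatError("truncated TextGrid")
        tok = tokens[pos]
        pos += 1
        return tok

    take()  # global xmin
    take()  # global xmax
    size = take()
    if not isinstance(size, float):
        raise FormatError("could not locate tier count")
    tiers: list[tuple[str, list[tuple[str, float, float]]]] = []
    for _ in range(int(size)):
        klass = take()
        name = take()
        take()  # tier xmin
        take()  # tier xmax
        n = int(take())
        if klass == "IntervalTier":
            intervals = []
            for _ in range(n):
                x0, x1, label = take(), take(), take()
                intervals.append((str(label), float(x0), float(x1)))
            tiers.append((str(name), intervals))
        else:  # point tier: consume and ignore
            for _ in range(n):
                take(), take()
    if not tiers:
        raise FormatError("TextGrid contains no interval tier")
    if tier is not None:
        for name, intervals in tiers:
            if name == tier:
                return intervals
        raise FormatError(f"TextGrid has no interval tier named {tier!r}")
    return tiers[0][1]


def read_alignment(path: str | Path, dialect: str = "textgrid",
                   tier: str | None = None) -> WordAlignment:
    """Read a word alignment from a Praat TextGrid or a CTM file.

    ``dialect`` selects the parser; for TextGrids, ``tier`` names the interval
    tier to use (default: the first one).  Empty-label intervals are dropped.
    """
    text = Path(path).read_text(encoding="utf-8")
    if dialect == "textgrid":
        triples = _parse_textgrid(text, tier)
        entries = [WordInterval(label.strip(), s, e)
                   for label, s, e in triples if label.strip()]
    elif dialect == "ctm":
        entries = []
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith(";;"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: CTM line needs >= 5 fields")
            start, dur, word = float(parts[2]), float(parts[3]), parts[4]
            entries.append(WordInterval(word, start, start + dur))
        entries.sort(key=lambda e: e.start)
    else:
        raise ConfigError(f"unknown alignment dialect {dialect!r}")
    return WordAlignment(entries)


def write_alignment_ctm(alignment: WordAlignment, path: str | Path,
                        rec_id: str = "rec") -> None:
    lines = [f"{rec_id} 1 {e.start:.12g} {e.end - e.start:.12g} {e.label}"
             for e in alignment.entries]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# rating panels


@dataclass
class RatingPanel:
    """Items x raters x {R, B, H} integer ratings on the 0-3 scale.

    ``scores`` is a float array with NaN for missing ratings; a rating of 0
    means the criterion is absent, 3 a high degree.
    """

    items: list[str]
    raters: list[str]
    scores: np.ndarray  # (n_items, n_raters, 3)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.items), len(self.raters), 3):
            raise ValidationError(
                f"scores shape {self.scores.shape} does not match "
                f"({len(self.items)}, {len(self.raters)}, 3)"
            )
        present = self.scores[~np.isnan(self.scores)]
        if present.size and not np.isin(present, [0.0, 1.0, 2.0, 3.0]).all():
            raise ValidationError("ratings must be integers in {0, 1, 2, 3}")

    def criterion_index(self, criterion: str) -> int:
        try:
            return CRITERIA.index(criterion)
        except ValueError:
            raise ValidationError(f"unknown criterion {criterion!r}") from None

    def criterion_matrix(self, criterion: str) -> np.ndarray:
        """Items x raters matrix for one criterion (NaN = missing)."""
        return self.scores[:, :, self.criterion_index(criterion)]

    def item_means(self, criterion: str) -> np.ndarray:
        """Per-item mean over the available raters — the human reference."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.criterion_matrix(criterion), axis=1)


def read_ratings(path: str | Path) -> RatingPanel:
    """Read a delimited ratings table with columns item, rater, R, B, H."""
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype={0: str, 1: str})
    except Exception as exc:  # pandas raises a zoo of parser errors
        raise FormatError(f"{path}: not a readable delimited table ({exc})") from exc
    required = ["item", "rater", *CRITERIA]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    items = list(dict.fromkeys(df["item"].astype(str)))
    raters = list(dict.fromkeys(df["rater"].astype(str)))
    scores = np.full((len(items), len(raters), 3), np.nan)
    item_pos = {v: i for i, v in enumerate(items)}
    rater_pos = {v: i for i, v in enumerate(raters)}
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        item, rater = str(row.item), str(row.rater)
        if (item, rater) in seen:
            raise ValidationError(f"duplicate rating for item {item!r}, rater {rater!r}")
        seen.add((item, rater))
        for k, crit in enumerate(CRITERIA):
            value = getattr(row, crit)
            if pd.isna(value):
                continue
            v = float(value)
            if v not in (0.0, 1.0, 2.0, 3.0):
                raise ValidationError(
                    f"item {item!r}, rater {rater!r}: {crit} = {value!r} "
                    "outside {0, 1, 2, 3}"
                )
            scores[item_pos[item], rater_pos[rater], k] = v
    return RatingPanel(items, raters, scores)


def write_ratings(panel: RatingPanel, path: str | Path) -> None:
    rows = []
    for i, item in enumerate(panel.items):
        for j, rater in enumerate(panel.raters):
            triple = panel.scores[i, j]
            rows.append({
                "item": item, "rater": rater,
                **{c: ("" if np.isnan(triple[k]) else int(triple[k]))
                   for k, c in enumerate(CRITERIA)},
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# feature tables


_CANON_ORDER = {name: i for i, name in enumerate(CANONICAL_FEATURES)}


def canonical_column_order(columns: list[str]) -> list[str]:
    """Known features in registry order first, unknown columns after, as given."""
    known = sorted([c for c in columns if c in _CANON_ORDER], key=_CANON_ORDER.get)
    unknown = [c for c in columns if c not in _CANON_ORDER]
    return known + unknown


class FeatureTable:
    """Recording-by-feature matrix with a deterministic column order."""

    def __init__(self, data: pd.DataFrame):
        if data.columns.duplicated().any():
            raise ValidationError("duplicate feature columns")
        all_missing = [c for c in data.columns if data[c].isna().all()]
        if all_missing:
            raise ValidationError(f"columns entirely missing: {all_missing}")
        self.data = data.loc[:, canonical_column_order(list(data.columns))].astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.index.name = "id"

    @property
    def rows(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def matrix(self, columns: list[str] | None = None) -> np.ndarray:
        return self.data.loc[:, columns or self.columns].to_numpy(dtype=float)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, FeatureTable)
                and self.data.equals(other.data))


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write as TSV ('.' decimal separator, 12 significant digits, NaN empty)."""
    table.data.to_csv(path, sep="\t", float_format="%.12g", na_rep="")


def read_feature_table(path: str | Path) -> FeatureTable:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.index.name != "id":
        raise FormatError(f"{path}: first column must be 'id', got {df.index.name!r}")
    return FeatureTable(df)
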