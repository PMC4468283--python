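"""Canonical feature-name registry.

The word-level (local) features combine a base measure (pause, energy,
duration, F0) with a context suffix: ``W`` for the current word, ``WPW`` for
the interval spanning the two preceding words and the pause between them.
The 15 global features are computed on 15-word windows.  The canonical column
order of a feature table is: the 33 local names, the 15 global names, then the
electroglottographic summaries CFx and CQx.
"""
from __future__ import annotations

import json

LOCAL_FEATURES: tuple[str, ...] = (
    # pauses around the current word (silent and filled)
    "PauseBefore", "PauseFillBefore", "PauseAfter", "PauseFillAfter",
    # energy contour
    "EnRegCoeffWPW", "EnRegCoeffW",
    "EnMseRegWPW", "EnMseRegW",
    "EnAbsWPW", "EnAbsW",
    "EnNormWPW", "EnNormW",
    "EnMeanWPW", "EnMeanW",
    "EnMaxW", "EnMaxPosW",
    # duration
    "DurAbsWPW", "DurAbsW",
    "DurNormWPW", "DurNormW",
    # F0 contour (semitone-normalized)
    "F0RegCoeffWPW", "F0RegCoeffW",
    "F0MseRegWPW", "F0MseRegW",
    "F0MeanW", "F0MaxW", "F0MaxPosW", "F0MinW", "F0MinPosW",
    "F0OffW", "F0OffPosW", "F0OnW", "F0OnPosW",
)

GLOBAL_FEATURES: tuple[str, ...] = (
    "MeanJitter", "StandDevJitter", "MeanShimmer", "StandDevShimmer",
    "NumVoiced", "MaxLenVoiced", "NumUnvoiced", "MaxLenUnvoiced",
    "RelNumVoicedUnvoiced",
    "RelLenVoicedSignal", "RelLenUnvoicedSignal",
    "StandDevF0",
    "MeanLenVoiced", "MeanLenUnvoiced", "RelLenVoicedUnvoiced",
)

EGG_FEATURES: tuple[str, ...] = ("CFx", "CQx")

CANONICAL_FEATURES: tuple[str, ...] = LOCAL_FEATURES + GLOBAL_FEATURES + EGG_FEATURES

assert len(LOCAL_FEATURES) == 33
assert len(GLOBAL_FEATURES) == 15


def registry_json() -> str:
    """The canonical registry as a JSON document (for export/debugging)."""
    return json.dumps(
        {
            "local": list(LOCAL_FEATURES),
            "global": list(GLOBAL_FEATURES),
            "egg": list(EGG_FEATURES),
        },
        indent=2,
        ensure_ascii=False,
    )
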