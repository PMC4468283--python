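# rbhvoice

Automatic evaluation of voice quality from **connected speech**, for clinical
voice researchers and speech scientists who want an objective counterpart to
perceptual ratings on the German **RBH** scheme (Roughness, Breathiness,
Hoarseness, each scored 0–3 by listeners).

Sustained-vowel measures miss much of what listeners hear in running speech:
onsets, pauses, F0 movement, and the irregular patches where phonation breaks
down. `rbhvoice` therefore analyses whole read texts. From a recording with
word-level time alignments it extracts:

* **33 word-level prosodic features** — silent/filled pause durations, energy
  contour statistics (regression slope and MSE, mean, max and its position,
  absolute and normalised energy), absolute and normalised durations, and F0
  contour statistics (mean, extrema and their positions, onset/offset values
  and positions, slope, MSE), each computed on the word itself (`W`) and/or on
  the word-pause-word interval of the two preceding words (`WPW`);
* **15 window-level ("global") features** on consecutive 15-word windows —
  mean and SD of jitter and shimmer, counts, maximal/mean lengths and length
  ratios of voiced and unvoiced sections, and the SD of F0;
* **electroglottographic irregularity measures** from an optional EGG channel:
  per-cycle period frequency Fx and contact quotient Qx, summarised as

      CFx = 100 · mean|Fx_{i+1} − Fx_i| / mean(Fx)     [percent]
      CQx = mean|Qx_{i+1} − Qx_i|                      [percentage points]

Per-feature averages over the recording give one 48-dimensional vector
(50 with EGG) per speaker. Perceptual ratings are modelled per criterion by
**correlation-based feature selection** (best-first search over the merit
`M_S = k·r̄_cf / √(k + k(k−1)·r̄_ff)` in 10-fold cross-validation) followed by
**linear ε-support-vector regression trained with sequential minimal
optimization (SMO)**. An agreement module supplies Krippendorff's α
(coincidence-matrix form, interval or ordinal metric, missing-safe), Pearson r
and Spearman ρ with significance, and rater-versus-rest statistics.

Published weight sets for the three criteria (e.g. the best roughness model:
six prosodic features plus CFx) ship as presets; their intercepts were never
published, so preset predictions are relative scores for correlation-based use.

## Worked example

The package includes seeded generators for speech-like audio and EGG signals
with known ground truth, so the whole chain can be exercised without clinical
data:

```python
from rbhvoice import (VoiceSpec, EggSpec, synth_voice, synth_egg,
                      analyze_recording)

plan = [(f"wort{k}", 0.3, 0.12) for k in range(17)]   # 17 words + pauses
rec, alignment = synth_voice(VoiceSpec(
    word_plan=plan, f0_contour=110.0, jitter_pct=2.0, shimmer_pct=6.0,
    noise_snr_db=30.0, seed=7))
rec.egg = synth_egg(EggSpec(duration=rec.duration - 0.1, f0_contour=110.0,
                            contact_quotient_pct=48.0, cycle_perturb_pct=2.0,
                            qx_perturb_pct=1.0, seed=8))
rec.egg_sample_rate = 16000.0

vector, egg_summary, counts = analyze_recording(rec, alignment)
print(counts)
for name in ("MeanJitter", "MeanShimmer", "NumVoiced", "F0MeanW",
             "StandDevF0", "CFx", "CQx"):
    print(f"{name:12s} {vector[name]:8.3f}")
```

prints

```
{'words': 17, 'windows': 1, 'voiced_sections': 17, 'cycles': 775}
MeanJitter      2.216
MeanShimmer     7.854
NumVoiced      17.000
F0MeanW        -0.907
StandDevF0      3.081
CFx             2.129
CQx             1.202
```

The injected 2 % jitter comes back as `MeanJitter ≈ 2.2 %` and the 2 % EGG
cycle perturbation as `CFx ≈ 2.1 %` (mean absolute cycle-to-cycle statistics
of a Gaussian perturbation with sd *s* concentrate near `2s/√π ≈ 1.13 s`, so
slight overshoot is expected). `F0MeanW` and `StandDevF0` are in semitones
relative to the recording median F0; the negative mean reflects a few
octave-down frames on this deliberately noisy voice — the same tracking
behaviour whose side effects make the F0 extremum features clinically
informative. `NumVoiced` counts voiced sections in the 15-word window, one
per word here.

A full study — many recordings, a rating panel, one fitted model per
criterion — runs from a JSON manifest:

```sh
rbhvoice study manifest.json --seed 1 --out report/
rbhvoice agreement ratings.tsv
rbhvoice analyze rec.wav --alignment rec.ctm --egg rec_egg.wav
```

`report/` then contains the feature table, the agreement tables, the fitted
weights and human-machine correlations per criterion, and a feature
correlation matrix (Pearson upper triangle, Spearman lower). Reports are
byte-identical across reruns with the same inputs, config and seed.

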