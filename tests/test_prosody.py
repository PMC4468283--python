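import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbhvoice.config import ProsodyConfig
from rbhvoice.errors import UndefinedValueError
from rbhvoice.f0 import analyze_track
from rbhvoice.features import GLOBAL_FEATURES, LOCAL_FEATURES
from rbhvoice.io import Recording, WordAlignment, WordInterval
from rbhvoice.prosody import (_word_windows, aggregate, extract_global,
                              extract_local, jitter, shimmer)
from tests.conftest import make_voice


class TestJitterShimmer:
    def test_constant_periods_zero(self):
        assert jitter([0.01] * 5) == 0.0

    def test_alternating_periods(self):
        assert jitter([0.0099, 0.0101] * 4) == pytest.approx(0.02, rel=1e-9)

    def test_hand_computed_jitter(self):
        # diffs (0, 3) ms -> mean 1.5 ms; mean T = 11 ms
        assert jitter([0.010, 0.010, 0.013]) == pytest.approx(1.5 / 11.0, rel=1e-9)

    def test_constant_amplitudes_zero(self):
        assert shimmer([0.7] * 4) == 0.0

    def test_alternating_amplitudes(self):
        assert shimmer([0.9, 1.1] * 4) == pytest.approx(0.2, rel=1e-9)

    def test_hand_computed_shimmer(self):
        # diffs (0, 0.5) -> mean 0.25; mean A = 2.5/3
        assert shimmer([1.0, 1.0, 0.5]) == pytest.approx(0.25 / (2.5 / 3), rel=1e-9)

    @pytest.mark.parametrize("fn", [jitter, shimmer])
    def test_too_few_values(self, fn):
        with pytest.raises(UndefinedValueError):
            fn([0.01])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.002, 0.02), min_size=2, max_size=20),
           st.floats(0.1, 100))
    def test_scale_invariance(self, periods, c):
        """Jitter (and shimmer) are invariant under positive scaling."""
        assert jitter(periods) == pytest.approx(
            jitter([c * p for p in periods]), rel=1e-9, abs=1e-12)


class TestLocalFeatures:
    def test_emits_exactly_33(self, perturbed_voice):
        rec, ali, track = perturbed_voice
        table = extract_local(rec, ali, track)
        assert table.shape == (len(ali.entries), 33)
        assert list(table.columns) == list(LOCAL_FEATURES)

    def test_no_missing_after_imputation(self, perturbed_voice):
        rec, ali, track = perturbed_voice
        table = extract_local(rec, ali, track)
        assert not table.isna().any().any()

    def test_constant_energy_flat_regression(self):
        """A word with a constant-amplitude contour has zero energy slope."""
        x = np.where(np.arange(16000) % 160 < 80, 0.8, -0.8)  # constant RMS
        rec = Recording("sq", x)
        ali = WordAlignment([WordInterval("wort", 0.0, 1.0)])
        track = analyze_track(rec)
        table = extract_local(rec, ali, track)
        assert table.EnRegCoeffW[0] == pytest.approx(0.0, abs=1e-9)
        assert table.EnMseRegW[0] == pytest.approx(0.0, abs=1e-12)

    def test_pause_gap_shared_between_words(self, clean_voice):
        rec, ali, track = clean_voice
        table = extract_local(rec, ali, track)
        gap = ali.entries[1].start - ali.entries[0].end
        assert table.PauseAfter[0] == pytest.approx(gap)
        assert table.PauseBefore[1] == pytest.approx(gap)
        assert table.PauseFillBefore[1] == 0.0

    def test_position_features_in_unit_interval(self, perturbed_voice):
        rec, ali, track = perturbed_voice
        table = extract_local(rec, ali, track)
        for col in [c for c in table.columns if c.endswith("Pos" + "W")]:
            assert ((table[col] >= 0) & (table[col] <= 1)).all()

    def test_time_shift_invariance(self):
        """Delaying signal and alignment by whole frames changes nothing.

        Invariance is exact up to boundary effects: the silence edge creates
        one partial frame that can nudge the median-based level and F0
        references, so features agree to 0.1 % rather than bit-exactly.
        """
        rec, ali = make_voice(n_words=5, jitter=1.0, shimmer=3.0, seed=4)
        shift = 0.1  # a multiple of the frame shift
        rec2 = Recording("s", np.concatenate(
            [np.zeros(int(shift * rec.sample_rate)), rec.speech]))
        ali2 = WordAlignment([WordInterval(e.label, e.start + shift,
                                           e.end + shift)
                              for e in ali.entries])
        t1 = extract_local(rec, ali, analyze_track(rec))
        t2 = extract_local(rec2, ali2, analyze_track(rec2))
        for col in ("DurAbsW", "F0MeanW", "EnNormW", "PauseBefore",
                    "EnMaxPosW", "DurNormWPW"):
            np.testing.assert_allclose(t1[col], t2[col], rtol=1e-3, atol=1e-6,
                                       err_msg=col)


class TestGlobalFeatures:
    def test_emits_exactly_15(self, perturbed_voice):
        rec, ali, track = perturbed_voice
        table = extract_global(rec, ali, track)
        assert table.shape[1] == 15
        assert list(table.columns) == list(GLOBAL_FEATURES)

    def test_zero_injection_zero_jitter(self, clean_voice):
        rec, ali, track = clean_voice
        table = extract_global(rec, ali, track)
        assert table.MeanJitter[0] / 100.0 == pytest.approx(0.0, abs=1e-6)

    def test_injected_jitter_recovered(self):
        rec, ali = make_voice(jitter=3.0, snr=30.0, seed=1)
        table = extract_global(rec, ali, analyze_track(rec))
        assert 2.4 <= table.MeanJitter[0] <= 3.6

    @pytest.mark.parametrize("grid,param,feature", [
        ((0.0, 1.0, 2.0, 4.0), "jitter", "MeanJitter"),
        ((0.0, 5.0, 10.0), "shimmer", "MeanShimmer"),
    ])
    def test_recovery_monotone_in_injection(self, grid, param, feature):
        """Estimated jitter/shimmer increase with the injected level."""
        values = []
        for level in grid:
            rec, ali = make_voice(**{param: level}, seed=1)
            table = extract_global(rec, ali, analyze_track(rec))
            values.append(table[feature][0])
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_voiced_unvoiced_ratios_bounded(self, perturbed_voice):
        rec, ali, track = perturbed_voice
        table = extract_global(rec, ali, track)
        total = table.RelLenVoicedSignal + table.RelLenUnvoicedSignal
        assert (total <= 1.0 + 1e-9).all()
        assert (table.MeanJitter >= 0).all() and (table.MeanShimmer >= 0).all()

    @pytest.mark.parametrize("n_words,expected", [
        (10, [(0, 10)]),
        (15, [(0, 15)]),
        (23, [(0, 15), (15, 23)]),           # 8-word tail keeps its window
        (20, [(0, 20)]),                     # 5-word tail merges back
        (33, [(0, 15), (15, 33)]),           # 3-word tail merges into window 2
        (45, [(0, 15), (15, 30), (30, 45)]),
    ])
    def test_window_partition(self, n_words, expected):
        assert _word_windows(n_words, ProsodyConfig()) == expected


class TestAggregate:
    def test_single_word_recording(self):
        rec, ali = make_voice(n_words=1, seed=2)
        track = analyze_track(rec)
        local = extract_local(rec, ali, track)
        global_ = extract_global(rec, ali, track)
        vec = aggregate(local, global_)
        for name in vec.index:
            if name in local.columns:
                assert vec[name] == pytest.approx(local[name][0])

    def test_mean_of_two_durations(self, perturbed_voice):
        rec, ali, track = perturbed_voice
        local = extract_local(rec, ali, track)
        vec = aggregate(local, extract_global(rec, ali, track))
        assert vec["DurAbsW"] == pytest.approx(local.DurAbsW.mean())

    def test_length_48_without_egg(self, perturbed_voice):
        rec, ali, track = perturbed_voice
        vec = aggregate(extract_local(rec, ali, track),
                        extract_global(rec, ali, track))
        assert len(vec) == 48
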