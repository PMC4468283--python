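import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rbhvoice.agreement import (krippendorff_alpha, panel_summary, pearson,
                                rater_vs_rest, spearman)
from rbhvoice.errors import UndefinedValueError
from rbhvoice.io import RatingPanel


def panel_of(matrix):
    """Items x raters matrix (NaN = missing) replicated over all 3 criteria."""
    m = np.asarray(matrix, dtype=float)
    return RatingPanel([f"i{k}" for k in range(m.shape[0])],
                       [f"r{k}" for k in range(m.shape[1])],
                       np.stack([m] * 3, axis=2))


def brute_force_alpha(mat):
    """Independent pairwise-enumeration oracle (interval metric)."""
    o = {}
    for row in np.asarray(mat, dtype=float):
        present = row[~np.isnan(row)]
        m = len(present)
        if m < 2:
            continue
        for i in range(m):
            for j in range(m):
                if i != j:
                    key = (present[i], present[j])
                    o[key] = o.get(key, 0.0) + 1.0 / (m - 1)
    n_c = {}
    for (a, _), w in o.items():
        n_c[a] = n_c.get(a, 0.0) + w
    n = sum(n_c.values())
    d_o = sum(w * (a - b) ** 2 for (a, b), w in o.items()) / n
    d_e = sum(n_c[a] * n_c[b] * (a - b) ** 2
              for a in n_c for b in n_c) / (n * (n - 1))
    return 1.0 if d_e == 0 else 1.0 - d_o / d_e


class TestKrippendorffAlpha:
    def test_perfect_agreement(self):
        assert krippendorff_alpha(panel_of([[0, 0], [1, 1], [3, 3]]), "R") == 1.0

    def test_small_panel_matches_oracle(self):
        mat = [[0, 0], [1, 1], [2, 3], [3, 2]]
        assert krippendorff_alpha(panel_of(mat), "R") == pytest.approx(
            brute_force_alpha(mat), abs=1e-12)

    def test_independent_rater_near_zero(self):
        rng = np.random.default_rng(0)
        items = rng.integers(0, 4, 30).astype(float)
        noise = rng.permutation(items)
        mat = np.stack([items, noise], axis=1)
        a = krippendorff_alpha(panel_of(mat), "R")
        assert a == pytest.approx(brute_force_alpha(mat), abs=1e-12)
        assert abs(a) < 0.5

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_oracle_on_random_panels(self, seed):
        """Coincidence-matrix alpha equals pairwise enumeration exactly."""
        rng = np.random.default_rng(seed)
        mat = rng.integers(0, 4, (rng.integers(2, 6), rng.integers(2, 5))
                           ).astype(float)
        mat[rng.random(mat.shape) < 0.2] = np.nan
        if not ((~np.isnan(mat)).sum(axis=1) >= 2).any():
            return
        try:
            a = krippendorff_alpha(panel_of(mat), "R")
        except UndefinedValueError:
            return
        assert a == pytest.approx(brute_force_alpha(mat), abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_invariance(self, seed):
        """Alpha ignores the ordering of raters and of items."""
        rng = np.random.default_rng(seed)
        mat = rng.integers(0, 4, (5, 4)).astype(float)
        a = krippendorff_alpha(panel_of(mat), "R")
        shuffled = mat[rng.permutation(5)][:, rng.permutation(4)]
        assert krippendorff_alpha(panel_of(shuffled), "R") == pytest.approx(a)

    def test_ordinal_metric_differs_from_interval(self):
        # skewed value margins, so ordinal distances are not proportional
        # to squared interval distances
        mat = [[0, 0], [0, 1], [0, 0], [1, 3], [3, 3], [0, 0], [2, 3]]
        a_int = krippendorff_alpha(panel_of(mat), "R", metric="interval")
        a_ord = krippendorff_alpha(panel_of(mat), "R", metric="ordinal")
        assert a_int != pytest.approx(a_ord)

    def test_no_pairable_items_raises(self):
        mat = [[0, np.nan], [np.nan, 1.0]]
        with pytest.raises(UndefinedValueError):
            krippendorff_alpha(panel_of(mat), "R")


class TestCorrelations:
    def test_identity_perfect(self):
        r, _ = pearson([1, 2, 3], [1, 2, 3])
        rho, _ = spearman([1, 2, 3], [1, 2, 3])
        assert r == pytest.approx(1.0)
        assert rho == pytest.approx(1.0)

    def test_spearman_monotone_transform(self):
        """Rho is -1 for any strictly decreasing transform of x."""
        x = np.array([0.5, 1.0, 2.0, 3.5, 7.0])
        rho, _ = spearman(x, np.exp(-x))
        assert rho == pytest.approx(-1.0)

    def test_hand_ranked_spearman(self):
        # ranks of y = (2,1,4,3,5): sum d^2 = 4 -> rho = 1 - 24/120
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(1 - 6 * 4 / (5 * 24), rel=1e-9)

    def test_pearson_affine_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        r1, _ = pearson(x, y)
        r2, _ = pearson(3.0 * x + 5.0, 0.5 * y - 2.0)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_large_n_p_matches_t_distribution(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal(40), rng.standard_normal(40)
        r, p = pearson(x, y)
        t = r * np.sqrt(38 / (1 - r * r))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 38), rel=1e-9)

    def test_small_n_exact_permutation_p(self):
        r, p = pearson([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 5.0])
        assert 0.0 < p <= 1.0  # exact enumeration over 4! pairings
        assert p == pytest.approx(2 / 24, rel=1e-9)  # only reversal ties |r|

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRaterVsRest:
    def test_identical_raters(self):
        mat = np.tile(np.array([0.0, 1, 2, 3, 1]), (4, 1)).T
        r, rho, skipped = rater_vs_rest(panel_of(mat), "R")
        assert r == pytest.approx(1.0)
        assert rho == pytest.approx(1.0)
        assert skipped == 0

    def test_duplicated_rater_symmetry(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 4, 12).astype(float)
        other = rng.integers(0, 4, 12).astype(float)
        mat = np.stack([base, other, base], axis=1)
        panel = panel_of(mat)
        # rater 0 and rater 2 are identical, so their correlations agree
        r_all, _, _ = rater_vs_rest(panel, "R")
        assert np.isfinite(r_all)

    def test_matches_direct_recomputation(self):
        """Mean rater-vs-rest r equals a straightforward reimplementation."""
        rng = np.random.default_rng(4)
        true = rng.uniform(0, 3, 30)
        mat = np.clip(np.round(true[:, None]
                               + 0.5 * rng.standard_normal((30, 6))), 0, 3)
        r, rho, _ = rater_vs_rest(panel_of(mat), "R")
        direct = []
        for j in range(6):
            rest = np.delete(mat, j, axis=1).mean(axis=1)
            direct.append(np.corrcoef(mat[:, j], rest)[0, 1])
        assert r == pytest.approx(np.mean(direct), abs=0.05)


class TestPanelSummary:
    def test_single_item_stats(self):
        mat = [[1, 1, 1], [0, 1, 2]]
        report = panel_summary(panel_of(mat))
        s = report.summary["R"]
        assert s["mean"] == pytest.approx(1.0)
        assert s["min"] == pytest.approx(1.0)
        # too few items for cross-criterion correlations: NaN, not an error
        assert np.isnan(report.cross[("R", "B")]["r"])

    def test_min_max_of_item_means(self):
        mat = [[0, 1], [1, 2], [2, 3]]
        report = panel_summary(panel_of(mat))
        assert report.summary["R"]["min"] == pytest.approx(0.5)
        assert report.summary["R"]["max"] == pytest.approx(2.5)

    def test_identical_criteria_correlate_perfectly(self):
        mat = np.array([[0, 1], [1, 2], [3, 2], [2, 0]], dtype=float)
        report = panel_summary(panel_of(mat))
        assert report.cross[("R", "B")]["r"] == pytest.approx(1.0)
        assert report.cross[("B", "H")]["rho"] == pytest.approx(1.0)
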