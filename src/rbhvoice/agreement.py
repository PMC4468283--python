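"""Interrater-agreement statistics for perceptual rating panels.

Krippendorff's alpha is computed from the coincidence-matrix formulation,
which handles missing ratings naturally: every item contributes all ordered
pairs of its available ratings, weighted by 1/(m_u - 1).  The difference
metric is interval on the numeric 0-3 scale by default; the ordinal metric is
available by flag.  Pearson's r and Spearman's rho come with two-sided
p-values: a t-approximation for n >= 10 and an exact permutation distribution
below that.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import UndefinedValueError, ValidationError
from .io import CRITERIA, RatingPanel


# ---------------------------------------------------------------------------
# Krippendorff's alpha


def _coincidence_matrix(ratings: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Observed coincidences o_ck over the value domain.

    ``ratings`` is items x raters with NaN for missing.  Each item (unit)
    with m >= 2 ratings adds, for every ordered pair of its ratings (c, k),
    a weight of 1/(m-1) to o_ck.
    """
    v_index = {v: i for i, v in enumerate(values)}
    o = np.zeros((len(values), len(values)))
    for row in ratings:
        present = row[~np.isnan(row)]
        m = len(present)
        if m < 2:
            continue
        idx = np.array([v_index[v] for v in present])
        counts = np.bincount(idx, minlength=len(values)).astype(float)
        pair = np.outer(counts, counts) - np.diag(counts)
        o += pair / (m - 1)
    return o


def _delta_matrix(values: np.ndarray, metric: str,
                  n_c: np.ndarray | None = None) -> np.ndarray:
    if metric == "interval":
        return (values[:, None] - values[None, :]) ** 2
    if metric == "ordinal":
        # cumulative-margin formulation: delta_ck = (sum_{g=c}^{k} n_g - (n_c+n_k)/2)^2
        assert n_c is not None
        csum = np.concatenate(([0.0], np.cumsum(n_c)))
        d = np.zeros((len(values), len(values)))
        for i in range(len(values)):
            for j in range(len(values)):
                lo, hi = min(i, j), max(i, j)
                between = csum[hi + 1] - csum[lo]
                d[i, j] = (between - (n_c[i] + n_c[j]) / 2.0) ** 2
        return d
    raise ValidationError(f"unknown alpha metric {metric!r}")


def krippendorff_alpha(panel: RatingPanel, criterion: str,
                       metric: str = "interval") -> float:
    """Chance-corrected agreement alpha = 1 - D_o / D_e for one criterion."""
    ratings = panel.criterion_matrix(criterion)
    if ratings.shape[1] < 2:
        raise UndefinedValueError("alpha needs at least 2 raters")
    usable = (~np.isnan(ratings)).sum(axis=1) >= 2
    if not usable.any():
        raise UndefinedValueError("no item carries 2 or more ratings")
    present = ratings[~np.isnan(ratings)]
    values = np.unique(present)
    o = _coincidence_matrix(ratings, values)
    n_c = o.sum(axis=1)
    n = n_c.sum()
    delta = _delta_matrix(values, metric, n_c)
    d_o = float((o * delta).sum()) / n
    d_e = float((np.outer(n_c, n_c) * delta).sum()) / (n * (n - 1))
    if d_e == 0:
        # every pairable rating identical: perfect agreement by convention
        return 1.0
    return 1.0 - d_o / d_e


# ---------------------------------------------------------------------------
# correlations


def _check_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("inputs must be equal-length 1-D with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedValueError("zero variance in an input")
    return x, y


def _p_value(stat_fn, x: np.ndarray, y: np.ndarray, observed: float) -> float:
    if len(x) >= 10:
        # two-sided t-approximation
        n = len(x)
        r = min(max(observed, -1.0), 1.0)
        if abs(r) == 1.0:
            return 0.0
        t = r * np.sqrt((n - 2) / (1 - r * r))
        return float(2 * stats.t.sf(abs(t), n - 2))
    res = stats.permutation_test(
        (x, y), lambda a, b: stat_fn(a, b),
        permutation_type="pairings", alternative="two-sided",
        n_resamples=np.inf,
    )
    return float(res.pvalue)


def pearson(x, y) -> tuple[float, float]:
    """Pearson's product-moment r with a two-sided p-value."""
    x, y = _check_xy(x, y)
    r = float(np.corrcoef(x, y)[0, 1])
    p = _p_value(lambda a, b: np.corrcoef(a, b)[0, 1], x, y, r)
    return r, p


def spearman(x, y) -> tuple[float, float]:
    """Spearman's rank-order rho (mid-ranked ties) with a two-sided p-value."""
    x, y = _check_xy(x, y)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    p = _p_value(
        lambda a, b: np.corrcoef(stats.rankdata(a), stats.rankdata(b))[0, 1],
        x, y, rho)
    return rho, p


# ---------------------------------------------------------------------------
# panel-level reports


def rater_vs_rest(panel: RatingPanel, criterion: str
                  ) -> tuple[float, float, int]:
    """Mean correlation of each rater with the average of all others.

    Returns (mean r, mean rho, number of raters skipped for zero variance).
    """
    ratings = panel.criterion_matrix(criterion)
    n_raters = ratings.shape[1]
    if n_raters < 3:
        raise UndefinedValueError("rater-vs-rest needs at least 3 raters")
    rs, rhos, skipped = [], [], 0
    for j in range(n_raters):
        own = ratings[:, j]
        rest = np.delete(ratings, j, axis=1)
        with np.errstate(invalid="ignore"):
            rest_mean = np.nanmean(rest, axis=1)
        ok = ~np.isnan(own) & ~np.isnan(rest_mean)
        if ok.sum() < 3 or np.ptp(own[ok]) == 0 or np.ptp(rest_mean[ok]) == 0:
            skipped += 1
            continue
        r, _ = pearson(own[ok], rest_mean[ok])
        rho, _ = spearman(own[ok], rest_mean[ok])
        rs.append(r)
        rhos.append(rho)
    if not rs:
        raise UndefinedValueError("no rater with usable variance")
    return float(np.mean(rs)), float(np.mean(rhos)), skipped


@dataclass
class AgreementReport:
    """Per-criterion agreement statistics and criterion cross-correlations."""

    summary: dict[str, dict[str, float]]          # mean/sd/min/max/alpha/r/rho
    cross: dict[tuple[str, str], dict[str, float]]  # r, rho, p_r, p_rho

    def summary_table(self) -> str:
        header = f"{'':4s}{'Average':>9s}{'Std.dev.':>10s}{'Min':>7s}{'Max':>7s}" \
                 f"{'alpha':>8s}{'r':>7s}{'rho':>7s}"
        lines = [header]
        for c in CRITERIA:
            s = self.summary[c]
            lines.append(
                f"{c:4s}{s['mean']:9.2f}{s['sd']:10.2f}{s['min']:7.2f}"
                f"{s['max']:7.2f}{s['alpha']:8.2f}{s['rater_vs_rest_r']:7.2f}"
                f"{s['rater_vs_rest_rho']:7.2f}")
        return "\n".join(lines)

    def cross_table(self) -> str:
        lines = ["pair  r (rho)        significance"]
        for (a, b), v in self.cross.items():
            star = "**" if v["p_r"] < 0.01 else ("*" if v["p_r"] < 0.05 else "")
            lines.append(f"{a}-{b}   {v['r']:5.2f} ({v['rho']:5.2f}){star}")
        return "\n".join(lines)


def panel_summary(panel: RatingPanel, metric: str = "interval") -> AgreementReport:
    """Item-averaged statistics, alpha, rater-vs-rest and cross-correlations."""
    summary: dict[str, dict[str, float]] = {}
    means = {}
    for c in CRITERIA:
        m = panel.item_means(c)
        means[c] = m
        entry = {
            "mean": float(np.nanmean(m)),
            "sd": float(np.nanstd(m, ddof=1)),
            "min": float(np.nanmin(m)),
            "max": float(np.nanmax(m)),
            "alpha": krippendorff_alpha(panel, c, metric),
        }
        try:
            r, rho, _ = rater_vs_rest(panel, c)
        except UndefinedValueError:
            r = rho = float("nan")
        entry["rater_vs_rest_r"] = r
        entry["rater_vs_rest_rho"] = rho
        summary[c] = entry
    cross: dict[tuple[str, str], dict[str, float]] = {}
    nan = float("nan")
    for i, a in enumerate(CRITERIA):
        for b in CRITERIA[i + 1:]:
            ok = ~np.isnan(means[a]) & ~np.isnan(means[b])
            try:
                r, p_r = pearson(means[a][ok], means[b][ok])
                rho, p_rho = spearman(means[a][ok], means[b][ok])
            except (ValidationError, UndefinedValueError):
                r = rho = p_r = p_rho = nan  # too few items or no variance
            cross[(a, b)] = {"r": r, "rho": rho, "p_r": p_r, "p_rho": p_rho}
    return AgreementReport(summary, cross)
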