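"""Rating-prediction models: SMO-trained linear epsilon-SVR and
correlation-based feature selection (CFS) in 10-fold cross-validation.

``SMORegressor`` solves the linear epsilon-insensitive support-vector
regression dual with sequential minimal optimization (maximal-violating-pair
working-set selection, analytic two-variable updates) on standardized
features.  ``CFSSelector`` runs a best-first subset search maximizing the CFS
merit

    M_S = k * mean|r_cf| / sqrt(k + k (k - 1) * mean|r_ff|)

inside each cross-validation fold and ranks features by how often the folds
select them.  Published weight sets for the roughness/breathiness/hoarseness
models ship as presets; their intercepts are unknown, so preset predictions
are relative scores suitable for correlation-based evaluation only.
"""
from __future__ import annotations

import heapq
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import agreement
from .errors import ValidationError
from .io import FeatureTable


# ---------------------------------------------------------------------------
# SMO epsilon-SVR


class SMORegressor(BaseEstimator, RegressorMixin):
    """Linear epsilon-SVR trained by sequential minimal optimization.

    Parameters
    ----------
    C : float
        Regularization (penalty on residuals outside the epsilon tube).
    epsilon : float
        Half-width of the insensitive tube, in target units.
    tol : float
        Maximal KKT violation allowed at convergence.
    max_iter : int
        Cap on pairwise updates; exceeding it raises with the remaining gap.
    standardize : bool
        Standardize features to zero mean / unit variance before solving
        (weights are reported both in standardized and original units).
    """

    def __init__(self, C: float = 1.0, epsilon: float = 0.001,
                 tol: float = 1e-3, max_iter: int = 2_000_000,
                 standardize: bool = True):
        self.C = C
        self.epsilon = epsilon
        self.tol = tol
        self.max_iter = max_iter
        self.standardize = standardize

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValidationError("X must be 2-D with one target per row")
        if len(y) < 3:
            raise ValidationError("need at least 3 training items")
        n, p = X.shape
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            self.scale_ = np.where(scale > 0, scale, 1.0)
        else:
            self.mean_ = np.zeros(p)
            self.scale_ = np.ones(p)
        Z = (X - self.mean_) / self.scale_

        K = Z @ Z.T
        beta, b, n_iter, gap = _smo_solve(K, y, self.C, self.epsilon,
                                          self.tol, self.max_iter)
        if gap > self.tol:
            raise ValidationError(
                f"SMO did not converge in {self.max_iter} iterations "
                f"(remaining KKT violation {gap:.3g})")
        self.dual_coef_ = beta
        self.coef_std_ = Z.T @ beta           # weights on standardized features
        self.coef_ = self.coef_std_ / self.scale_
        self.intercept_ = float(b - self.coef_ @ self.mean_)
        self.n_iter_ = n_iter
        self.n_features_in_ = p
        f = Z @ self.coef_std_ + b
        slack = np.maximum(np.abs(y - f) - self.epsilon, 0.0)
        self.objective_ = float(0.5 * self.coef_std_ @ self.coef_std_
                                + self.C * slack.sum())
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_


def _smo_solve(K: np.ndarray, y: np.ndarray, C: float, epsilon: float,
               tol: float, max_iter: int
               ) -> tuple[np.ndarray, float, int, float]:
    """Solve the SVR dual by maximal-violating-pair SMO.

    The 2n-variable form uses a_t with sign z_t (+1 for the alpha of sample
    i, -1 for alpha*), linear term p_t = epsilon -+ y_i, the equality
    constraint sum z_t a_t = 0 and box 0 <= a_t <= C.  Returns the net
    coefficients beta = alpha - alpha*, the intercept, the iteration count
    and the final violation m - M.
    """
    n = len(y)
    sample = np.concatenate([np.arange(n), np.arange(n)])
    z = np.concatenate([np.ones(n), -np.ones(n)])
    p = np.concatenate([epsilon - y, epsilon + y])
    a = np.zeros(2 * n)
    G = p.copy()
    it = 0
    gap = np.inf
    while it < max_iter:
        up = ((z > 0) & (a < C)) | ((z < 0) & (a > 0))
        low = ((z < 0) & (a < C)) | ((z > 0) & (a > 0))
        score = -z * G
        m_val = score[up].max()
        M_val = score[low].min()
        gap = m_val - M_val
        if gap < tol:
            break
        i = int(np.flatnonzero(up)[np.argmax(score[up])])
        j = int(np.flatnonzero(low)[np.argmin(score[low])])
        si, sj = sample[i], sample[j]
        kii, kjj, kij = K[si, si], K[sj, sj], K[si, sj]
        old_ai, old_aj = a[i], a[j]
        if z[i] != z[j]:
            quad = max(kii + kjj - 2 * kij, 1e-12)
            delta = (-G[i] - G[j]) / quad
            diff = a[i] - a[j]
            a[i] += delta
            a[j] += delta
            if diff > 0:
                if a[j] < 0:
                    a[j] = 0.0
                    a[i] = diff
            else:
                if a[i] < 0:
                    a[i] = 0.0
                    a[j] = -diff
            if diff > 0:
                if a[i] > C:
                    a[i] = C
                    a[j] = C - diff
            else:
                if a[j] > C:
                    a[j] = C
                    a[i] = C + diff
        else:
            quad = max(kii + kjj - 2 * kij, 1e-12)
            delta = (G[i] - G[j]) / quad
            tot = a[i] + a[j]
            a[i] -= delta
            a[j] += delta
            if tot > C:
                if a[i] > C:
                    a[i] = C
                    a[j] = tot - C
                elif a[j] > C:
                    a[j] = C
                    a[i] = tot - C
            else:
                if a[j] < 0:
                    a[j] = 0.0
                    a[i] = tot
                elif a[i] < 0:
                    a[i] = 0.0
                    a[j] = tot
        d_i, d_j = a[i] - old_ai, a[j] - old_aj
        kcol = z[i] * d_i * K[:, si] + z[j] * d_j * K[:, sj]
        G += z * kcol[sample]
        it += 1
    b = 0.5 * (m_val + M_val) if np.isfinite(gap) else 0.0
    beta = a[:n] - a[n:]
    return beta, float(b), it, float(gap)


# ---------------------------------------------------------------------------
# CFS merit and best-first search


def cfs_merit(subset: tuple[int, ...], r_cf: np.ndarray, r_ff: np.ndarray) -> float:
    """CFS merit of a feature subset from absolute correlations.

    ``r_cf``: |correlation| of each feature with the target; ``r_ff``:
    |correlation| matrix between features.  For k = 1 the merit reduces to
    |r_cf| of the single feature.
    """
    k = len(subset)
    if k == 0:
        return 0.0
    idx = np.asarray(subset)
    mean_cf = float(r_cf[idx].mean())
    if k == 1:
        return mean_cf
    sub = r_ff[np.ix_(idx, idx)]
    mean_ff = float((sub.sum() - np.trace(sub)) / (k * (k - 1)))
    return k * mean_cf / np.sqrt(k + k * (k - 1) * mean_ff)


def cfs_best_first(r_cf: np.ndarray, r_ff: np.ndarray,
                   stall_limit: int = 5) -> tuple[tuple[int, ...], float]:
    """Best-first forward search over feature subsets maximizing CFS merit.

    Keeps an open list of evaluated subsets ordered by merit, always expands
    the best open node by single-feature additions, and stops after
    ``stall_limit`` consecutive expansions without improving the best merit.
    """
    n = len(r_cf)
    start: tuple[int, ...] = ()
    evaluated: dict[tuple[int, ...], float] = {start: 0.0}
    heap: list[tuple[float, tuple[int, ...]]] = [(0.0, start)]
    best_subset, best_merit = start, 0.0
    stalls = 0
    while heap and stalls < stall_limit:
        _, node = heapq.heappop(heap)
        improved = False
        for f in range(n):
            if f in node:
                continue
            child = tuple(sorted(node + (f,)))
            if child in evaluated:
                continue
            merit = cfs_merit(child, r_cf, r_ff)
            evaluated[child] = merit
            heapq.heappush(heap, (-merit, child))
            if merit > best_merit + 1e-12:
                best_subset, best_merit = child, merit
                improved = True
        stalls = 0 if improved else stalls + 1
    return best_subset, best_merit


def _abs_correlations(X: np.ndarray, y: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    xn = np.sqrt((Xc * Xc).sum(axis=0))
    yn = np.sqrt((yc * yc).sum())
    # a feature constant within this training part correlates with nothing
    with np.errstate(invalid="ignore", divide="ignore"):
        r_cf = np.abs(Xc.T @ yc / (xn * yn))
        r_ff = np.abs((Xc.T @ Xc) / np.outer(xn, xn))
    r_cf = np.nan_to_num(r_cf)
    r_ff = np.nan_to_num(r_ff)
    np.fill_diagonal(r_ff, 1.0)
    return r_cf, r_ff


@dataclass
class SelectionResult:
    """Cross-fold CFS outcome: features ranked by selection frequency."""

    ranked_features: list[str]
    frequencies: dict[str, float]
    fold_subsets: list[list[str]]
    merits: list[float]          # best merit per fold
    mean_merit: dict[str, float]

    def selected(self, min_frequency: float = 0.5) -> list[str]:
        names = [f for f in self.ranked_features
                 if self.frequencies[f] >= min_frequency]
        return names or self.ranked_features[:1]


class CFSSelector(BaseEstimator):
    """Correlation-based feature selection in seeded k-fold cross-validation.

    Within each fold's training part, a best-first search maximizes the CFS
    merit; features are then ranked by the fraction of folds selecting them,
    with ties broken by the mean merit of the selecting folds, then by name.
    """

    def __init__(self, n_folds: int = 10, stall_limit: int = 5,
                 random_state: int | None = 0):
        self.n_folds = n_folds
        self.stall_limit = stall_limit
        self.random_state = random_state

    def fit(self, X, y, feature_names: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n < self.n_folds:
            raise ValidationError(
                f"{n} items cannot fill {self.n_folds} folds; reduce n_folds")
        if np.ptp(y) == 0:
            raise ValidationError("constant target")
        names = list(feature_names) if feature_names is not None \
            else [f"x{i}" for i in range(p)]
        keep = np.ptp(X, axis=0) > 0
        if not keep.all():
            dropped = [names[i] for i in range(p) if not keep[i]]
            warnings.warn(f"dropping constant feature columns: {dropped}")
        active = [i for i in range(p) if keep[i]]
        Xa = X[:, active]
        # seeded shuffle, contiguous blocks as folds
        rng = np.random.default_rng(self.random_state)
        perm = rng.permutation(n)
        blocks = np.array_split(perm, self.n_folds)
        counts = np.zeros(len(active))
        merit_sums = np.zeros(len(active))
        fold_subsets, merits = [], []
        for held_out in blocks:
            train = np.setdiff1d(np.arange(n), held_out)
            r_cf, r_ff = _abs_correlations(Xa[train], y[train])
            subset, merit = cfs_best_first(r_cf, r_ff, self.stall_limit)
            fold_subsets.append(sorted(names[active[i]] for i in subset))
            merits.append(merit)
            for i in subset:
                counts[i] += 1
                merit_sums[i] += merit
        n_folds = len(blocks)
        freq = counts / n_folds
        mean_merit = np.where(counts > 0, merit_sums / np.maximum(counts, 1), 0.0)
        order = sorted(
            range(len(active)),
            key=lambda i: (-freq[i], -mean_merit[i], names[active[i]]))
        self.ranked_features_ = [names[active[i]] for i in order]
        self.frequencies_ = {names[active[i]]: float(freq[i]) for i in order}
        self.mean_merit_ = {names[active[i]]: float(mean_merit[i]) for i in order}
        self.fold_subsets_ = fold_subsets
        self.merits_ = merits
        self.feature_names_in_ = names
        return self

    def result(self) -> SelectionResult:
        return SelectionResult(self.ranked_features_, self.frequencies_,
                               self.fold_subsets_, self.merits_,
                               self.mean_merit_)


def cfs_select(table: FeatureTable, target, folds: int = 10,
               seed: int | None = 0, stall_limit: int = 5) -> SelectionResult:
    """Functional wrapper over :class:`CFSSelector` for feature tables."""
    sel = CFSSelector(n_folds=folds, stall_limit=stall_limit, random_state=seed)
    sel.fit(table.matrix(), np.asarray(target, dtype=float),
            feature_names=table.columns)
    return sel.result()


# ---------------------------------------------------------------------------
# named regression models and presets


@dataclass
class RegressionModel:
    """A linear rating model: named weights on standardized features.

    ``intercept`` may be None (as for the published presets, which print
    weights only); predictions are then relative scores — meaningful up to an
    affine transform, which suffices for correlation-based evaluation.
    """

    feature_names: list[str]
    weights: np.ndarray
    intercept: float | None = None
    C: float = 1.0
    epsilon: float = 0.001
    means: np.ndarray | None = None   # training standardization
    scales: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.feature_names):
            raise ValidationError("one weight per feature required")

    @property
    def relative(self) -> bool:
        return self.intercept is None

    def predict(self, table: FeatureTable) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in table.columns]
        if missing:
            raise ValidationError(f"feature table lacks model features: {missing}")
        X = table.matrix(self.feature_names)
        if self.means is not None:
            Z = (X - self.means) / self.scales
        else:
            # no stored standardization (preset): z-score within the table
            sd = X.std(axis=0)
            Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        score = Z @ self.weights
        return score + (self.intercept or 0.0)

    def to_json(self) -> str:
        return json.dumps({
            "feature_names": self.feature_names,
            "weights": list(self.weights),
            "intercept": self.intercept,
            "C": self.C,
            "epsilon": self.epsilon,
            "means": None if self.means is None else list(self.means),
            "scales": None if self.scales is None else list(self.scales),
            "meta": self.meta,
        }, indent=2)

    @classmethod
    def from_json(cls, doc: str) -> "RegressionModel":
        d = json.loads(doc)
        return cls(
            feature_names=d["feature_names"], weights=np.asarray(d["weights"]),
            intercept=d["intercept"], C=d["C"], epsilon=d["epsilon"],
            means=None if d["means"] is None else np.asarray(d["means"]),
            scales=None if d["scales"] is None else np.asarray(d["scales"]),
            meta=d.get("meta", {}),
        )


def train_svr(table: FeatureTable, target, selected: list[str],
              C: float = 1.0, epsilon: float = 0.001,
              tol: float = 1e-3) -> RegressionModel:
    """Fit a linear SMO-SVR on the selected columns of a feature table."""
    if not selected:
        raise ValidationError("empty feature selection")
    reg = SMORegressor(C=C, epsilon=epsilon, tol=tol)
    reg.fit(table.matrix(selected), np.asarray(target, dtype=float))
    return RegressionModel(
        feature_names=list(selected),
        weights=reg.coef_std_,
        intercept=float(reg.intercept_ + reg.coef_ @ reg.mean_),
        C=C, epsilon=epsilon,
        means=reg.mean_, scales=reg.scale_,
        meta={"n_iter": reg.n_iter_, "objective": reg.objective_},
    )


def evaluate(predictions, reference) -> tuple[float, float, float]:
    """Pearson r, Spearman rho and the (Pearson) p-value vs the reference."""
    r, p = agreement.pearson(predictions, reference)
    rho, _ = agreement.spearman(predictions, reference)
    return r, rho, p


def load_presets() -> dict[str, RegressionModel]:
    """The published weight sets as relative (intercept-free) models."""
    doc = json.loads(
        resources.files("rbhvoice").joinpath("presets.json").read_text())
    registry = {}
    for name, entry in doc.items():
        feats = list(entry["weights"])
        registry[name] = RegressionModel(
            feature_names=feats,
            weights=np.array([entry["weights"][f] for f in feats]),
            intercept=None,
            meta={k: v for k, v in entry.items() if k != "weights"},
        )
    return registry
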