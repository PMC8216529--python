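"""Neighbourhood component analysis (NCA) feature weighting and selection.

This is the feature-weighting NCA variant used for EMG feature selection
(the analogue of MATLAB's ``fscnca``): each feature r carries a nonnegative
relevance weight w_r entering a quadratic distance metric

    d_w(x_i, x_j) = sum_r w_r^2 |x_ir - x_jr|

and the weights maximise the regularised expected leave-one-out
nearest-neighbour accuracy

    F(w) = sum_i p_i - lambda * sum_r w_r^2,
    p_i  = sum_{j != i, y_j = y_i} p_ij,
    p_ij = exp(-d_w(x_i, x_j)/sigma) / sum_{l != i} exp(-d_w(x_i, x_l)/sigma)

by monotone gradient ascent from the all-ones weight vector.  Irrelevant
features are driven towards zero weight; ranking the features by weight and
sweeping top-k subsets against cross-validated classifier accuracy selects
the operating feature set.

Not implemented here (by design): the Mahalanobis-matrix NCA that learns a
full linear subspace.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted

from musclenet.features import parse_feature_name

META_COLUMNS = ("group", "task")


def feature_columns(df: pd.DataFrame) -> list[str]:
    """Feature columns of a table (everything but the metadata columns)."""
    return [c for c in df.columns if c not in META_COLUMNS]


def standardize(df: pd.DataFrame):
    """Z-score the feature columns; drop zero-variance columns with a warning.

    Returns the standardized table and the scaler parameters
    ``{column: (mean, sd)}`` for held-out application via :func:`apply_scaler`.
    """
    if len(df) < 2:
        raise ValueError("need at least 2 rows to standardize")
    cols = feature_columns(df)
    out = df.copy()
    scaler: dict[str, tuple[float, float]] = {}
    dropped = []
    for c in cols:
        mu = float(df[c].mean())
        sd = float(df[c].std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            dropped.append(c)
            out = out.drop(columns=c)
            continue
        scaler[c] = (mu, sd)
        out[c] = (df[c] - mu) / sd
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} zero-variance feature column(s): {dropped}",
            UserWarning,
            stacklevel=2,
        )
    return out, scaler


def apply_scaler(df: pd.DataFrame, scaler: dict[str, tuple[float, float]]):
    """Apply stored standardization parameters to a (held-out) table."""
    keep = [c for c in df.columns if c in scaler or c in META_COLUMNS]
    out = df[keep].copy()
    for c, (mu, sd) in scaler.items():
        out[c] = (df[c] - mu) / sd
    return out


class NCAFeatureSelector(BaseEstimator, TransformerMixin):
    """Scikit-learn-compatible NCA feature weighter/selector.

    Parameters
    ----------
    lambda_reg : float or "auto"
        Ridge penalty on the weights; "auto" uses 1/n_samples.
    sigma : float
        Kernel width of the softmax neighbour probabilities; 1.0 is
        appropriate on standardized features.
    max_iter, tol, patience
        Ascent stops when the objective improves by less than ``tol`` for
        ``patience`` consecutive iterations, or at ``max_iter``.
    n_features_to_select : int or None
        If set, :meth:`transform` keeps the top-k ranked features; otherwise
        it returns the feature-weighted inputs ``X * weights_``.

    Attributes
    ----------
    weights_ : (n_features,) nonnegative relevance weights.
    ranking_ : feature indices sorted by descending weight (stable ties).
    objective_trace_ : objective value per accepted iteration (non-decreasing).
    """

    def __init__(
        self,
        lambda_reg="auto",
        sigma: float = 1.0,
        max_iter: int = 300,
        tol: float = 1e-6,
        patience: int = 5,
        initial_step: float = 0.1,
        n_features_to_select: int | None = None,
        random_state: int | None = None,
    ):
        self.lambda_reg = lambda_reg
        self.sigma = sigma
        self.max_iter = max_iter
        self.tol = tol
        self.patience = patience
        self.initial_step = initial_step
        self.n_features_to_select = n_features_to_select
        self.random_state = random_state

    @staticmethod
    def _objective(w, D, same, sigma, lam):
        d_ij = np.einsum("ijr,r->ij", D, w**2)
        logits = -d_ij / sigma
        np.fill_diagonal(logits, -np.inf)
        logits = logits - logits.max(axis=1, keepdims=True)
        K = np.exp(logits)
        Z = K.sum(axis=1)
        P = K / Z[:, None]
        p_i = (P * same).sum(axis=1)
        F = float(p_i.sum() - lam * np.sum(w**2))
        M = P * p_i[:, None] - P * same
        grad = (2.0 * w / sigma) * np.einsum("ij,ijr->r", M, D) - 2.0 * lam * w
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite NCA gradient")
        return F, grad

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes, counts = np.unique(y, return_counts=True)
        if np.any(counts < 2):
            raise ValueError("every class needs at least 2 samples")
        n, d = X.shape
        lam = 1.0 / n if self.lambda_reg == "auto" else float(self.lambda_reg)
        D = np.abs(X[:, None, :] - X[None, :, :])
        same = (y[:, None] == y[None, :]) & ~np.eye(n, dtype=bool)
        w = np.ones(d)
        try:
            F, grad = self._objective(w, D, same, self.sigma, lam)
        except FloatingPointError as exc:  # pragma: no cover - defensive
            raise FloatingPointError(f"iteration 0: {exc}") from exc
        trace = [F]
        step = float(self.initial_step)
        stall = 0
        for it in range(1, self.max_iter + 1):
            accepted = False
            for _ in range(40):
                w_new = w + step * grad
                try:
                    F_new, grad_new = self._objective(w_new, D, same, self.sigma, lam)
                except FloatingPointError as exc:
                    raise FloatingPointError(f"iteration {it}: {exc}") from exc
                if F_new >= F:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                break
            improvement = F_new - F
            w, F, grad = w_new, F_new, grad_new
            trace.append(F)
            step *= 1.2
            if improvement < self.tol:
                stall += 1
                if stall >= self.patience:
                    break
            else:
                stall = 0
        self.weights_ = np.abs(w)
        self.ranking_ = np.argsort(-self.weights_, kind="stable")
        self.objective_trace_ = np.array(trace)
        self.n_iter_ = len(trace) - 1
        self.n_features_in_ = d
        return self

    def transform(self, X):
        check_is_fitted(self, "weights_")
        X = check_array(X, dtype=float)
        if self.n_features_to_select is not None:
            k = min(self.n_features_to_select, len(self.weights_))
            return X[:, self.ranking_[:k]]
        return X * self.weights_

    def relevant_features(self, threshold_frac: float = 0.02) -> np.ndarray:
        """Indices of features whose weight exceeds ``threshold_frac * max``."""
        check_is_fitted(self, "weights_")
        wmax = self.weights_.max()
        if wmax == 0:
            return np.array([], dtype=int)
        return np.flatnonzero(self.weights_ >= threshold_frac * wmax)


def nca_fit(
    X: np.ndarray, y: np.ndarray, seed: int | None = None, **hyperparams
) -> NCAFeatureSelector:
    """Convenience wrapper: fit an :class:`NCAFeatureSelector` on arrays."""
    return NCAFeatureSelector(random_state=seed, **hyperparams).fit(X, y)


def rank_and_select(weights: np.ndarray, names: list[str], k: int) -> list[str]:
    """Top-k feature names by weight; ties broken by original column order."""
    if not 1 <= k <= len(names):
        raise ValueError("k must lie in [1, number of features]")
    order = np.argsort(-np.asarray(weights, dtype=float), kind="stable")
    return [names[i] for i in order[:k]]


def weight_table(selector: NCAFeatureSelector, names: list[str]) -> pd.DataFrame:
    """Weights and ranks as a tidy (feature, weight, rank) table."""
    ranks = np.empty(len(names), dtype=int)
    ranks[selector.ranking_] = np.arange(1, len(names) + 1)
    return pd.DataFrame(
        {"feature": names, "weight": selector.weights_, "rank": ranks}
    ).sort_values("rank", ignore_index=True)


def muscle_weight_summary(
    weights: np.ndarray, names: list[str]
) -> pd.DataFrame:
    """Per-muscle weight distributions, sides pooled.

    Coherence (pair) features are attributed to the first-named muscle of
    the pair.  Returns median and quartiles per muscle.
    """
    by_muscle: dict[str, list[float]] = {}
    for w, name in zip(weights, names):
        muscle = parse_feature_name(name)["muscle"]
        by_muscle.setdefault(muscle, []).append(float(w))
    rows = []
    for muscle in sorted(by_muscle):
        vals = np.array(by_muscle[muscle])
        rows.append(
            {
                "muscle": muscle,
                "n_features": len(vals),
                "median": float(np.median(vals)),
                "q1": float(np.percentile(vals, 25)),
                "q3": float(np.percentile(vals, 75)),
                "mean": float(np.mean(vals)),
            }
        )
    return pd.DataFrame(rows)


def accuracy_vs_k(
    table: pd.DataFrame,
    classifier_name: str,
    k_grid,
    cv_cfg=None,
    nca_params: dict | None = None,
    refit_per_fold: bool = True,
) -> pd.DataFrame:
    """Cross-validated accuracy as a function of the number of NCA features.

    By default the NCA ranking is refit inside each training fold (no
    selection leakage); ``refit_per_fold=False`` ranks once on the full table
    (the single-ranking shortcut some reports use) and reuses that ranking in
    every fold.  Returns a (k, accuracy) table; the ranking is fitted once
    per fold and shared across the k sweep.
    """
    from musclenet import classify as _classify

    cv_cfg = cv_cfg or _classify.CvConfig()
    nca_params = nca_params or {}
    cols = feature_columns(table)
    k_grid = [int(k) for k in k_grid]
    if any(k < 1 or k > len(cols) for k in k_grid):
        raise ValueError("k_grid values must lie within the feature count")
    y_all = table["group"].to_numpy()
    folds = _classify.fold_indices(table, cv_cfg)

    global_ranking = None
    if not refit_per_fold:
        std_all, _ = standardize(table)
        sel = nca_fit(
            std_all[feature_columns(std_all)].to_numpy(), y_all, seed=cv_cfg.seed,
            **nca_params,
        )
        global_ranking = [feature_columns(std_all)[i] for i in sel.ranking_]

    hits = {k: 0 for k in k_grid}
    total = 0
    for train_idx, test_idx in folds:
        train, test = table.iloc[train_idx], table.iloc[test_idx]
        std_train, scaler = standardize(train)
        std_test = apply_scaler(test, scaler)
        fold_cols = feature_columns(std_train)
        if refit_per_fold:
            sel = nca_fit(
                std_train[fold_cols].to_numpy(),
                train["group"].to_numpy(),
                seed=cv_cfg.seed,
                **nca_params,
            )
            ranking = [fold_cols[i] for i in sel.ranking_]
        else:
            ranking = [c for c in global_ranking if c in fold_cols]
        for k in k_grid:
            chosen = ranking[: min(k, len(ranking))]
            clf = _classify.make_classifier(classifier_name)
            clf.fit(std_train[chosen].to_numpy(), train["group"].to_numpy())
            pred = clf.predict(std_test[chosen].to_numpy())
            hits[k] += int(np.sum(pred == test["group"].to_numpy()))
        total += len(test_idx)
    curve = pd.DataFrame(
        {"k": k_grid, "accuracy": [hits[k] / total for k in k_grid]}
    )
    return curve
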