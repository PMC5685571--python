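"""Elastic-net reduction of the topic/category feature space.

The mixing parameter follows the glmnet convention: ``l1_ratio`` = 0.1 is
a mostly-ridge penalty, chosen small so correlated informative features
can survive together (the grouping effect lasso lacks).  The penalty
strength is picked by K-fold cross-validation on the *training* rows only,
with the 1-SE rule (largest penalty whose CV error is within one standard
error of the minimum).  Features are standardized on training statistics,
which are frozen thereafter.  Affect features never enter selection; they
always join the prediction model directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.utils.validation import check_is_fitted

__all__ = ["split_train_test", "ElasticNetSelector", "elastic_net_select", "SelectedFeatures"]


def split_train_test(
    users: np.ndarray | list, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic user-level train/test partition.

    ``|train| = round(train_fraction * n)``; e.g. 2612 users at fraction
    0.717 give the 1873/739 partition.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0,1), got {train_fraction}")
    users = np.asarray(users)
    if len(users) < 2:
        raise ValueError("need at least 2 users to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(users))
    n_train = int(round(train_fraction * len(users)))
    n_train = min(max(n_train, 1), len(users) - 1)
    return np.sort(users[perm[:n_train]]), np.sort(users[perm[n_train:]])


@dataclass(frozen=True)
class SelectedFeatures:
    """Nonzero-coefficient features surviving the elastic net."""

    features: tuple[tuple[str, float], ...]  # (name, coefficient != 0)
    l1_ratio: float
    alpha: float  # penalty strength actually used

    @property
    def names(self) -> list[str]:
        return [f for f, _ in self.features]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.features, columns=["feature", "coefficient"])


class ElasticNetSelector(TransformerMixin, BaseEstimator):
    """Select features whose elastic-net coefficients are nonzero.

    Parameters
    ----------
    l1_ratio : float, default 0.1
        L1/L2 mixing (glmnet's alpha). 0 is ridge, 1 is lasso.
    alpha : float or None, default None
        Fixed penalty strength; when None it is chosen by cross-validation.
    cv : int, default 10
        Folds for the internal penalty-strength search.
    one_se : bool, default True
        Apply the 1-SE rule to the cross-validated penalty path.
    n_alphas : int, default 100
        Length of the automatically generated penalty path.
    random_state : int or None
        Controls the CV fold shuffle.

    Attributes
    ----------
    alpha_ : float            chosen penalty strength
    coef_ : ndarray           coefficients on the standardized scale
    support_ : bool ndarray   nonzero-coefficient mask
    selected_features_ : list of str (when fitted on a DataFrame)
    """

    def __init__(
        self,
        l1_ratio: float = 0.1,
        alpha: float | None = None,
        cv: int = 10,
        one_se: bool = True,
        n_alphas: int = 100,
        max_iter: int = 5000,
        random_state: int | None = None,
    ):
        self.l1_ratio = l1_ratio
        self.alpha = alpha
        self.cv = cv
        self.one_se = one_se
        self.n_alphas = n_alphas
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape[0] < 10:
            raise ValueError("need at least 10 training rows")
        if np.ptp(y) == 0:
            raise ValueError("y is constant; nothing to select on")
        sd = X.std(axis=0)
        if (sd == 0).all():
            raise ValueError("all feature columns are constant")
        self.mean_ = X.mean(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Z = (X - self.mean_) / self.scale_

        if self.alpha is not None:
            self.alpha_ = float(self.alpha)
        else:
            from sklearn.model_selection import KFold

            folds = KFold(self.cv, shuffle=True, random_state=self.random_state)
            cvfit = ElasticNetCV(
                l1_ratio=self.l1_ratio,
                alphas=self.n_alphas,
                cv=folds,
                max_iter=self.max_iter,
            ).fit(Z, y)
            alphas = cvfit.alphas_  # descending
            mse = cvfit.mse_path_  # (n_alphas, n_folds)
            mean = mse.mean(axis=1)
            if self.one_se:
                se = mse.std(axis=1, ddof=1) / np.sqrt(mse.shape[1])
                best = int(np.argmin(mean))
                limit = mean[best] + se[best]
                # largest penalty (first index: alphas descend) within 1 SE
                self.alpha_ = float(alphas[np.nonzero(mean <= limit)[0][0]])
            else:
                self.alpha_ = float(cvfit.alpha_)
        fit = ElasticNet(
            alpha=self.alpha_, l1_ratio=self.l1_ratio, max_iter=self.max_iter
        ).fit(Z, y)
        self.coef_ = fit.coef_
        self.intercept_ = float(fit.intercept_)
        self.support_ = fit.coef_ != 0
        self.feature_names_in_ = np.asarray(names) if names is not None else None
        if names is not None:
            self.selected_features_ = [
                n for n, keep in zip(names, self.support_) if keep
            ]
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]

    def selected(self) -> SelectedFeatures:
        check_is_fitted(self, "support_")
        if self.feature_names_in_ is None:
            names = [f"x{i}" for i in range(self.n_features_in_)]
        else:
            names = list(self.feature_names_in_)
        feats = tuple(
            (n, float(c)) for n, c in zip(names, self.coef_) if c != 0
        )
        return SelectedFeatures(feats, self.l1_ratio, self.alpha_)


def elastic_net_select(
    X: pd.DataFrame,
    y,
    mixing: float = 0.1,
    seed: int | None = 0,
    cv: int = 10,
    one_se: bool = True,
) -> SelectedFeatures:
    """Fit an :class:`ElasticNetSelector` and return the surviving features."""
    sel = ElasticNetSelector(
        l1_ratio=mixing, cv=cv, one_se=one_se, random_state=seed
    ).fit(X, y)
    return sel.selected()
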