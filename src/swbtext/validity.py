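"""Predictive validity of the well-being profile against depression scores.

The machine-assessed SWB profile bundles out-of-bag predicted SWL with the
three sentiment features (mean sentiment, positive and negative status
frequencies).  Validity is quantified two ways: direct correlations of
each profile field with CES-D, and a random-forest prediction of CES-D
from three nested feature sets (sentiment only; self-reported SWL +
sentiment; machine-predicted SWL + sentiment) plus the jittered-median
baseline, all evaluated on one shared 70/30 user split.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .model import ForestConfig, baseline_predict, evaluate, fit_forest
from .selection import split_train_test

__all__ = [
    "assemble_profile",
    "criterion_correlations",
    "cesd_validity",
    "SENTIMENT_FEATURES",
]

SENTIMENT_FEATURES = ("mean_sentiment", "pos_freq", "neg_freq")


def assemble_profile(oob_swl: pd.Series, affect: pd.DataFrame) -> pd.DataFrame:
    """Bundle predicted SWL with the three sentiment features (4 fields)."""
    missing = [u for u in affect.index if u not in oob_swl.index]
    if missing:
        raise ValueError(f"no OOB SWL prediction for users {missing[:10]}")
    out = affect[list(SENTIMENT_FEATURES)].copy()
    out.insert(0, "predicted_swl", oob_swl.reindex(affect.index))
    return out


def criterion_correlations(
    profile: pd.DataFrame, cesd: pd.Series
) -> pd.DataFrame:
    """Pearson r (+ two-sided p) of each profile field against CES-D."""
    cesd = cesd.reindex(profile.index)
    ok = cesd.notna()
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 users with CES-D, got {int(ok.sum())}")
    rows = []
    for col in profile.columns:
        x = profile.loc[ok, col].to_numpy(float)
        y = cesd[ok].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((col, float("nan"), float("nan")))
            continue
        res = stats.pearsonr(x, y)
        rows.append((col, float(res.statistic), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["field", "r", "p"])


def cesd_validity(
    feature_sets: dict[str, pd.DataFrame],
    cesd: pd.Series,
    train_fraction: float = 0.70,
    forest_cfg: ForestConfig = ForestConfig(),
    seed: int = 0,
    min_users: int = 20,
) -> pd.DataFrame:
    """Random-forest CES-D prediction per feature set, on one shared split.

    ``feature_sets`` maps a row label to a user-indexed feature frame; rows
    are restricted to users with a CES-D score.  Returns a frame with
    columns feature_set, n_features, r, p, rmse (baseline row included).
    """
    cesd = cesd.dropna()
    users = np.asarray(sorted(cesd.index))
    if len(users) < min_users:
        raise ValueError(
            f"only {len(users)} users with CES-D (< {min_users} required)"
        )
    train, test = split_train_test(users, train_fraction, seed)
    y_train = cesd.loc[train].to_numpy(float)
    y_test = cesd.loc[test].to_numpy(float)

    rows = []
    base = baseline_predict(y_train, len(test), seed=seed)
    res = evaluate(base, y_test)
    rows.append(("baseline", 1, res.pearson_r, res.p_value, res.rmse))
    for name, X in feature_sets.items():
        missing = [u for u in users if u not in X.index]
        if missing:
            raise ValueError(f"feature set {name!r} missing users {missing[:10]}")
        cfg = ForestConfig(forest_cfg.ntree, min(forest_cfg.ntry, X.shape[1]), seed)
        model = fit_forest(X.loc[train], y_train, cfg)
        pred = model.predict(X.loc[test])
        res = evaluate(pred, y_test)
        rows.append((name, X.shape[1], res.pearson_r, res.p_value, res.rmse))
    return pd.DataFrame(
        rows, columns=["feature_set", "n_features", "r", "p", "rmse"]
    )
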