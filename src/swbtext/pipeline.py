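"""End-to-end orchestration: corpus -> feature tables -> models -> reports.

One call (or one ``swb run`` command) executes: preprocessing, sentiment /
affect features, topic and category features, train/test split,
elastic-net reduction, the random-forest grid, evaluation of the
feature-set ladder, out-of-bag SWL for the well-being profile, the CES-D
validity comparison, and activity sentiment z-scores.  All randomness
derives from one master seed fanned out to per-stage seeds, and every run
writes a machine-readable manifest sufficient to reproduce its reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activities import (
    activity_z_scores,
    cohens_kappa,
    load_default_activity_lexicon,
    match_activity_statuses,
)
from .affect import affect_feature_frame, affect_swl_correlations, corpus_status_scores
from .corpus import UserCorpus, read_outcomes, read_statuses
from .lexicons import ActivityLexicon, CategoryLexicon, TopicTable, ValenceLexicon
from .model import (
    DEFAULT_GRID,
    ForestConfig,
    baseline_predict,
    evaluate,
    fit_forest,
    grid_search,
    variable_importance,
)
from .preprocess import DEFAULT_SMILEY_MAP, SmileyMap
from .selection import ElasticNetSelector, split_train_test
from .synthetic import GenConfig, SyntheticData, generate_dataset
from .topics import assemble_feature_matrix, category_matrix, topic_wordcount_matrix
from .validity import SENTIMENT_FEATURES, assemble_profile, cesd_validity, criterion_correlations

__all__ = ["RunConfig", "PipelineError", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("swbtext")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``gen`` (synthetic mode) or ``paths`` (real-corpus
    mode) must be given.  ``paths`` maps resource names — ``statuses``,
    ``outcomes``, ``lexicon``, ``topics``, ``categories`` and optionally
    ``activities``, ``smileys`` — to files in the documented CSV/TSV
    schemas.
    """

    gen: GenConfig | None = None
    paths: dict[str, str] | None = None
    min_statuses: int = 30
    train_fraction: float = 0.717
    en_mixing: float = 0.1
    en_cv: int = 10
    grid: tuple[ForestConfig, ...] = DEFAULT_GRID
    cesd_train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.gen is None) == (self.paths is None):
            raise ValueError("exactly one of gen (synthetic) or paths must be set")


@dataclass
class PipelineResult:
    affect_correlations: pd.DataFrame
    selected_features: pd.DataFrame
    best_config: ForestConfig
    grid_table: pd.DataFrame
    swl_models: pd.DataFrame          # Table-2 analogue
    profile_correlations: pd.DataFrame | None
    cesd_validity: pd.DataFrame | None  # Table-3 analogue
    activity_sentiment: pd.DataFrame  # Table-4 analogue
    rater_kappa: tuple[float, float] | None
    manifest: dict
    importance: pd.DataFrame = field(repr=False, default=None)
    feature_matrix: pd.DataFrame = field(repr=False, default=None)
    profile: pd.DataFrame = field(repr=False, default=None)
    train_users: np.ndarray = field(repr=False, default=None)
    test_users: np.ndarray = field(repr=False, default=None)
    test_predictions: pd.Series = field(repr=False, default=None)  # full model
    ground_truth: object = field(repr=False, default=None)  # synthetic mode only


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _load_inputs(cfg: RunConfig):
    if cfg.gen is not None:
        data = generate_dataset(cfg.gen)
        return (
            data.corpus,
            data.truth.outcomes,
            data.lexicon,
            data.table,
            data.categories,
            data.activities,
            DEFAULT_SMILEY_MAP,
            data.truth,
        )
    paths = {k: Path(v) for k, v in cfg.paths.items()}
    corpus = read_statuses(paths["statuses"])
    outcomes = read_outcomes(paths["outcomes"])
    lexicon = ValenceLexicon.from_csv(paths["lexicon"])
    table = TopicTable.from_csv(paths["topics"])
    categories = CategoryLexicon.from_csv(paths["categories"])
    activities = (
        ActivityLexicon.from_csv(paths["activities"])
        if "activities" in paths
        else load_default_activity_lexicon()
    )
    smileys = (
        SmileyMap.from_csv(paths["smileys"])
        if "smileys" in paths
        else DEFAULT_SMILEY_MAP
    )
    return corpus, outcomes, lexicon, table, categories, activities, smileys, None


def run_pipeline(cfg: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis and (optionally) write the report bundle."""
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(outdir / "log.txt", mode="w")
    else:
        fh = None
    sh = logging.StreamHandler(sys.stderr)
    logger.setLevel(logging.INFO)
    handlers = [h for h in (sh, fh) if h is not None]
    for h in handlers:
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(h)
    try:
        return _run(cfg, outdir)
    finally:
        for h in handlers:
            logger.removeHandler(h)
            h.close()


def _run(cfg: RunConfig, outdir: Path | None) -> PipelineResult:
    seeds = {
        name: int(s.generate_state(1)[0] & 0x7FFFFFFF)
        for name, s in zip(
            ["split", "selection", "grid", "oob", "cesd", "baseline"],
            np.random.SeedSequence(cfg.seed).spawn(6),
        )
    }

    corpus, outcomes, lexicon, table, categories, activities, smileys, truth = _stage(
        "load_inputs"
    )(_load_inputs)(cfg)
    logger.info("inputs: %d statuses, %d users with outcomes", len(corpus), len(outcomes))

    @_stage("retention_filter")
    def _filter():
        kept = corpus.filter_min_statuses(cfg.min_statuses)
        if len(kept.user_ids) == 0:
            raise ValueError(
                f"retention filter (< {cfg.min_statuses} statuses) removed all "
                f"{len(corpus.user_ids)} users; 0 remain"
            )
        return kept

    corpus_f = _filter()
    logger.info(
        "retention filter >=%d statuses: %d of %d users kept",
        cfg.min_statuses,
        len(corpus_f.user_ids),
        len(corpus.user_ids),
    )

    tok = _stage("preprocess")(corpus_f.tokenize)(smileys)
    logger.info("preprocessed: %d tokens, vocab %d", len(tok.token_code), len(tok.vocab))

    outcomes = outcomes.set_index("user_id").reindex(tok.user_ids)
    swl = outcomes["swl"].astype(float)
    if swl.isna().any():
        raise PipelineError(
            f"stage 'outcomes' failed: missing SWL for users "
            f"{list(swl.index[swl.isna()])[:10]}"
        )
    cesd = outcomes["cesd"].astype(float)

    @_stage("affect")
    def _affect():
        feats = affect_feature_frame(tok, lexicon)
        return feats, affect_swl_correlations(feats, swl)

    affect, table1 = _affect()

    @_stage("topic_features")
    def _features():
        cats = category_matrix(tok, categories)
        topics = topic_wordcount_matrix(tok, table)
        return assemble_feature_matrix(affect, cats, topics)

    X = _features()
    logger.info("feature matrix: %d users x %d features", *X.shape)

    train, test = _stage("split")(split_train_test)(
        np.asarray(tok.user_ids), cfg.train_fraction, seeds["split"]
    )
    logger.info("split: %d train / %d test users", len(train), len(test))

    @_stage("elastic_net_selection")
    def _select():
        cols = [c for c in X.columns if c.startswith(("cat:", "topic:"))]
        sel = ElasticNetSelector(
            l1_ratio=cfg.en_mixing, cv=cfg.en_cv, random_state=seeds["selection"]
        ).fit(X.loc[train, cols], swl.loc[train])
        return sel.selected()

    selected = _select()
    sel_topics = [f for f in selected.names if f.startswith("topic:")]
    sel_cats = [f for f in selected.names if f.startswith("cat:")]
    logger.info(
        "elastic net (mixing=%.2f, alpha=%.4g): %d topics + %d categories kept",
        selected.l1_ratio,
        selected.alpha,
        len(sel_topics),
        len(sel_cats),
    )

    sentiment_cols = [f"affect:{f}" for f in SENTIMENT_FEATURES]
    full_cols = sel_topics + sel_cats + sentiment_cols

    @_stage("forest_grid")
    def _grid():
        grid = tuple(
            dataclasses.replace(g, seed=seeds["grid"]) for g in cfg.grid
        )
        return grid_search(X.loc[train, full_cols], swl.loc[train], grid)

    best, grid_table = _grid()
    logger.info("grid best: ntree=%d ntry=%d", best.ntree, best.ntry)

    @_stage("swl_models")
    def _ladder():
        y_train = swl.loc[train].to_numpy()
        y_test = swl.loc[test].to_numpy()
        rows = []
        base = baseline_predict(y_train, len(test), seed=seeds["baseline"])
        res = evaluate(base, y_test)
        rows.append(("baseline", 1, res.pearson_r, res.p_value, res.rmse))
        sets = [
            ("selected categories", sel_cats),
            ("selected topics", sel_topics),
            ("selected topics + sentiment", sel_topics + sentiment_cols),
            ("selected topics + categories + sentiment", full_cols),
        ]
        full_pred = full_model = None
        for name, cols in sets:
            if not cols:
                rows.append((name, 0, np.nan, np.nan, np.nan))
                continue
            cfg_fit = ForestConfig(best.ntree, min(best.ntry, len(cols)), seeds["grid"])
            model = fit_forest(X.loc[train, cols], y_train, cfg_fit)
            pred = model.predict(X.loc[test, cols])
            if cols is full_cols:
                full_pred = pd.Series(pred, index=test, name="predicted_swl")
                full_model = model
            res = evaluate(pred, y_test)
            rows.append((name, len(cols), res.pearson_r, res.p_value, res.rmse))
        return (
            pd.DataFrame(rows, columns=["feature_set", "n_features", "r", "p", "rmse"]),
            full_pred,
            full_model,
        )

    table2, test_pred, full_model = _ladder()

    @_stage("variable_importance")
    def _importance():
        if full_model is None:
            return pd.DataFrame(columns=["feature", "importance", "importance_sd"])
        return variable_importance(
            full_model, X.loc[test, full_cols], swl.loc[test], seed=seeds["grid"]
        )

    importance = _importance()

    @_stage("oob_profile")
    def _profile():
        cfg_fit = ForestConfig(best.ntree, best.ntry, seeds["oob"])
        model = fit_forest(X[full_cols], swl.to_numpy(), cfg_fit)
        oob = pd.Series(model.oob_prediction_, index=X.index, name="oob_swl")
        return assemble_profile(oob, affect)

    profile = _profile()

    table3 = profile_corr = None
    if cesd.notna().sum() >= 20:

        @_stage("cesd_validity")
        def _validity():
            corr = criterion_correlations(profile, cesd)
            sent = X[sentiment_cols]
            sets = {
                "sentiment": sent,
                "self-reported SWL + sentiment": sent.assign(swl=swl),
                "machine-predicted SWL + sentiment": sent.assign(
                    predicted_swl=profile["predicted_swl"]
                ),
            }
            rep = cesd_validity(
                sets,
                cesd,
                train_fraction=cfg.cesd_train_fraction,
                forest_cfg=best,
                seed=seeds["cesd"],
            )
            return corr, rep

        profile_corr, table3 = _validity()
        logger.info("CES-D validity computed on %d users", int(cesd.notna().sum()))
    else:
        logger.info(
            "CES-D validity skipped: only %d users with CES-D", int(cesd.notna().sum())
        )

    @_stage("activity_sentiment")
    def _activity():
        matches = match_activity_statuses(tok, activities)
        scores = corpus_status_scores(tok, lexicon)
        res = activity_z_scores(matches, scores)
        kappa = None
        if activities.ratings is not None:
            kappa = cohens_kappa(
                activities.ratings["rating_a"], activities.ratings["rating_b"]
            )
        return res, kappa

    table4, kappa = _activity()

    manifest = {
        "package_version": __version__,
        "master_seed": cfg.seed,
        "stage_seeds": seeds,
        "config": _config_dict(cfg),
        "n_users": int(len(tok.user_ids)),
        "n_statuses": int(tok.n_statuses_total),
        "n_train": int(len(train)),
        "n_test": int(len(test)),
        "selection": {
            "mixing": selected.l1_ratio,
            "alpha": selected.alpha,
            "n_topics_selected": len(sel_topics),
            "n_categories_selected": len(sel_cats),
        },
        "best_forest": {"ntree": best.ntree, "ntry": best.ntry},
        "rater_kappa": None if kappa is None else {"kappa": kappa[0], "p": kappa[1]},
    }

    result = PipelineResult(
        affect_correlations=table1,
        selected_features=selected.to_frame(),
        best_config=best,
        grid_table=grid_table,
        swl_models=table2,
        profile_correlations=profile_corr,
        cesd_validity=table3,
        activity_sentiment=table4,
        rater_kappa=kappa,
        manifest=manifest,
        importance=importance,
        feature_matrix=X,
        profile=profile,
        train_users=train,
        test_users=test,
        test_predictions=test_pred,
        ground_truth=truth,
    )
    if outdir is not None:
        _write_reports(result, outdir)
    return result


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["grid"] = [[g.ntree, g.ntry] for g in cfg.grid]
    return d


def _write_reports(res: PipelineResult, outdir: Path) -> None:
    res.affect_correlations.to_csv(outdir / "table1_affect_correlations.csv")
    res.selected_features.to_csv(outdir / "selected_features.csv", index=False)
    res.grid_table.to_csv(outdir / "grid_search.csv", index=False)
    res.swl_models.to_csv(outdir / "table2_swl_models.csv", index=False)
    if res.importance is not None:
        res.importance.to_csv(outdir / "variable_importance.csv", index=False)
    if res.profile_correlations is not None:
        res.profile_correlations.to_csv(
            outdir / "profile_cesd_correlations.csv", index=False
        )
    if res.cesd_validity is not None:
        res.cesd_validity.to_csv(outdir / "table3_cesd_validity.csv", index=False)
    res.activity_sentiment.to_csv(
        outdir / "table4_activity_sentiment.csv", index=False
    )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(res.manifest, fh, indent=2, sort_keys=True)
    logger.info("reports written to %s", outdir)
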