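"""End-to-end screening experiment: model object, results object, runner.

:class:`ScreeningExperiment` is built from a cohort of labeled user profiles
plus a post-level training corpus (or generated from a config); ``fit()``
executes the whole analysis —

    train SPVC -> build SPVs -> extract SNPSY features -> fit user BoW
    models -> out-of-fold outputted features -> Mann-Whitney screening ->
    per-recipe design matrices -> Yeo-Johnson transform -> nested-CV
    classifier selection -> held-out evaluation

— for the two detection tasks (risk vs focused control, risk vs generic
control) and returns a :class:`ScreeningResults` carrying per-recipe
metrics, screening tables, feature rankings, DeLong comparisons and enough
fitted state to score new cohorts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from .features import (
    image_score_series,
    median_impute,
    snpsy_table,
)
from .lexicon import Lexicon, LexiconPolarityScorer, PolarityScorer
from .modeling import (
    DEFAULT_ALGORITHMS,
    RECIPES,
    RECIPE_LABELS,
    EvalReport,
    FeatureTransform,
    build_design_matrix,
    fit_select_evaluate,
    pooled_feature_matrix,
    recipe_spec,
    transform_features,
)
from .profiles import (
    ConfigurationError,
    UserProfile,
    read_corpus_jsonl,
    read_users_jsonl,
    write_corpus_jsonl,
    write_users_jsonl,
)
from .spvc import SpvcModel, build_spvs, train_spvc, write_spvs_jsonl
from .stats_tests import (
    SelectionResult,
    delong_compare,
    mannwhitney_screen,
    overlap_index,
    rank_features,
)
from .synthetic import CohortConfig, generate_cohort, generate_tweet_corpus
from .text import BowModel, bow_outputted_feature, build_user_documents, fit_user_bow
from .lexicon import default_stopwords

TASKS: dict[str, tuple[str, str]] = {
    "risk_vs_focused": ("risk", "focused_control"),
    "risk_vs_generic": ("risk", "generic_control"),
}


@dataclass
class ExperimentConfig:
    """Full experiment configuration (cohort generation + analysis)."""

    seed: int = 0
    cohort: CohortConfig | None = None
    corpus_n_pos: int = 500
    corpus_n_neg: int = 500
    spvc_threshold: float = 0.5
    spvc_ngram_range: tuple[int, int] = (1, 5)
    spvc_svd_cap: int = 128
    spv_k: int = 15
    bow_ngram_range: tuple[int, int] = (1, 5)
    bow_df_floor: float = 0.05
    bow_max_tokens: int = 2000
    recipes: tuple[str, ...] = RECIPES
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS
    alphas: tuple[float, float] = (0.05, 0.001)
    test_size: float = 0.3
    screening_scope: str = "train"  # "train" (leak-free) | "full" (permissive)
    lexicon_path: str | None = None
    n_outputted_folds: int = 10

    def __post_init__(self) -> None:
        if self.cohort is None:
            self.cohort = CohortConfig(seed=self.seed)
        if self.screening_scope not in ("train", "full"):
            raise ConfigurationError(
                f"screening_scope must be 'train' or 'full', got {self.screening_scope!r}"
            )
        unknown = set(self.recipes) - set(RECIPES)
        if unknown:
            raise ConfigurationError(f"unknown recipes: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must contain a mapping")
        cohort_raw = raw.pop("cohort", None)
        seed = raw.get("seed", 0)
        cohort = None
        if cohort_raw is not None:
            cohort_raw.setdefault("seed", seed)
            from datetime import datetime as _dt

            window = cohort_raw.pop("window", None)
            if window is not None:
                from .profiles import CollectionWindow

                cohort_raw["window"] = CollectionWindow(
                    _dt.fromisoformat(window["start"]), _dt.fromisoformat(window["end"])
                )
            cohort = CohortConfig(**cohort_raw)
        for key in ("spvc_ngram_range", "bow_ngram_range", "alphas", "recipes", "algorithms"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        try:
            return cls(cohort=cohort, **raw)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc

    def lexicon(self) -> Lexicon:
        if self.lexicon_path is None:
            return Lexicon.default()
        path = Path(self.lexicon_path)
        if not path.exists():
            raise ConfigurationError(f"lexicon_path does not exist: {path}")
        return Lexicon.from_json(path)


@dataclass
class TaskArtifacts:
    """Fitted per-task state needed to score unseen cohorts."""

    y: pd.Series
    train_ids: list[str]
    test_ids: list[str]
    bow_models: dict[str, BowModel]
    bow_clf: object  # full-train classifier behind the BoW outputted feature
    snpsy_clf: object
    snpsy_transform: FeatureTransform
    snpsy_medians: pd.Series
    image_train_mean: float
    pooled: pd.DataFrame
    selection: SelectionResult
    recipe_transforms: dict[str, FeatureTransform] = field(default_factory=dict)
    recipe_columns: dict[str, list[str]] = field(default_factory=dict)


class ScreeningExperiment:
    """The screening analysis as a fittable model over a labeled cohort."""

    def __init__(
        self,
        cohort: Sequence[UserProfile],
        corpus: Sequence[tuple],
        config: ExperimentConfig | None = None,
        lexicon: Lexicon | None = None,
        scorer: PolarityScorer | None = None,
    ):
        self.config = config or ExperimentConfig()
        self.cohort = list(cohort)
        self.corpus = list(corpus)
        self.lexicon = lexicon or self.config.lexicon()
        self.scorer = scorer or LexiconPolarityScorer()
        if not self.cohort:
            raise ConfigurationError("cohort is empty")

    @classmethod
    def from_config(cls, config: ExperimentConfig) -> "ScreeningExperiment":
        lexicon = config.lexicon()
        cohort = generate_cohort(config.cohort, lexicon)
        corpus = generate_tweet_corpus(
            config.cohort, config.corpus_n_pos, config.corpus_n_neg, lexicon
        )
        return cls(cohort, corpus, config, lexicon)

    @classmethod
    def from_files(
        cls,
        users_jsonl: str | Path,
        corpus_jsonl: str | Path,
        config: ExperimentConfig | None = None,
    ) -> "ScreeningExperiment":
        return cls(read_users_jsonl(users_jsonl), read_corpus_jsonl(corpus_jsonl), config)

    # -- fitting -------------------------------------------------------------

    def fit(self, spvc: SpvcModel | None = None) -> "ScreeningResults":
        cfg = self.config
        window = cfg.cohort.window
        if spvc is None:
            spvc = train_spvc(
                self.corpus,
                ngram_range=cfg.spvc_ngram_range,
                threshold=cfg.spvc_threshold,
                seed=cfg.seed,
                svd_cap=cfg.spvc_svd_cap,
            )
        spvs = build_spvs(spvc, self.cohort, k=cfg.spv_k)
        snpsy_raw, provenance = snpsy_table(
            self.cohort, spvs, self.lexicon, self.scorer, window
        )
        image = image_score_series(self.cohort)
        groups = pd.Series({u.user_id: u.group for u in self.cohort})
        docs_full = {
            d.user_id: d
            for d in build_user_documents(
                self.cohort, variant="full_profile", max_tokens=cfg.bow_max_tokens
            )
        }
        docs_spv = {
            d.user_id: d
            for d in build_user_documents(
                self.cohort, spvs, variant="spv", max_tokens=cfg.bow_max_tokens
            )
        }

        reports: dict[str, dict[str, EvalReport]] = {}
        artifacts: dict[str, TaskArtifacts] = {}
        rankings: dict[str, dict[str, pd.DataFrame]] = {}
        overlaps: dict[str, pd.DataFrame] = {}
        for task, (pos_group, neg_group) in TASKS.items():
            task_users = [u.user_id for u in self.cohort if u.group in (pos_group, neg_group)]
            y = (groups.loc[task_users] == pos_group).astype(int)
            reports[task], artifacts[task], rankings[task], overlaps[task] = (
                self._fit_task(task, task_users, y, snpsy_raw, image, docs_full, docs_spv)
            )

        return ScreeningResults(
            config=cfg,
            spvc=spvc,
            lexicon=self.lexicon,
            scorer=self.scorer,
            spvs=spvs,
            snpsy_raw=snpsy_raw,
            provenance=provenance,
            image=image,
            groups=groups,
            reports=reports,
            artifacts=artifacts,
            rankings=rankings,
            overlaps=overlaps,
        )

    def _fit_task(self, task, task_users, y, snpsy_raw, image, docs_full, docs_spv):
        cfg = self.config
        seed = cfg.seed
        train_ids, test_ids = train_test_split(
            sorted(task_users),
            test_size=cfg.test_size,
            stratify=y.loc[sorted(task_users)].to_numpy(),
            random_state=seed,
        )
        train_ids, test_ids = list(train_ids), list(test_ids)
        all_ids = train_ids + test_ids
        y = y.loc[all_ids]
        ytr = y.loc[train_ids].to_numpy()

        # SNPSY: impute with train medians
        snpsy_task = snpsy_raw.loc[all_ids]
        snpsy_imp = median_impute(snpsy_task, train_ids)
        snpsy_medians = snpsy_task.loc[train_ids].median().fillna(0.0)

        # user BoW models fit on training documents only
        stop = default_stopwords()
        bow_frames: dict[str, pd.DataFrame] = {}
        bow_models: dict[str, BowModel] = {}
        for variant, docs in (("full_profile", docs_full), ("spv", docs_spv)):
            train_docs = [docs[u] for u in train_ids]
            model, _ = fit_user_bow(
                train_docs,
                ngram_range=cfg.bow_ngram_range,
                df_floor=cfg.bow_df_floor,
                stopwords=stop,
            )
            X_all = model.transform([docs[u] for u in all_ids])
            prefix = "bow_full:" if variant == "full_profile" else "bow_spv:"
            bow_frames[variant] = pd.DataFrame(
                X_all.toarray(),
                index=all_ids,
                columns=[prefix + n for n in model.feature_names],
            )
            bow_models[variant] = model

        # BoW outputted feature (SPV variant): out-of-fold for training users,
        # full-train model for test users; empty-SPV users get the class prior
        Xb = bow_frames["spv"]
        out = bow_outputted_feature(
            Xb.loc[train_ids].to_numpy(),
            ytr,
            X_test=Xb.loc[test_ids].to_numpy(),
            n_folds=cfg.n_outputted_folds,
            seed=seed,
        )
        bow_feature = pd.Series(
            np.concatenate([out.train, out.test]), index=all_ids, name="bow_outputted"
        )
        prior = float(np.mean(ytr))
        empty = [u for u in all_ids if not docs_spv[u].text]
        bow_feature.loc[empty] = prior
        bow_clf = LogisticRegression(max_iter=2000, random_state=seed).fit(
            Xb.loc[train_ids].to_numpy(), ytr
        )

        # SNPSY outputted feature on transformed SNPSY
        snpsy_transform, snpsy_z = transform_features(
            snpsy_imp.loc[train_ids], snpsy_imp
        )
        out_s = bow_outputted_feature(
            snpsy_z.loc[train_ids].to_numpy(),
            ytr,
            X_test=snpsy_z.loc[test_ids].to_numpy(),
            n_folds=cfg.n_outputted_folds,
            seed=seed + 1,
        )
        snpsy_feature = pd.Series(
            np.concatenate([out_s.train, out_s.test]), index=all_ids, name="snpsy_outputted"
        )
        snpsy_clf = LogisticRegression(max_iter=2000, random_state=seed).fit(
            snpsy_z.loc[train_ids].to_numpy(), ytr
        )

        # Mann-Whitney screening over the pooled feature space
        pooled = pooled_feature_matrix(
            snpsy_imp, image.loc[all_ids], {"spv": bow_frames["spv"]}, train_ids
        )
        screen_ids = train_ids if cfg.screening_scope == "train" else all_ids
        selection = mannwhitney_screen(
            pooled.loc[screen_ids], y.loc[screen_ids].to_numpy(), alpha=cfg.alphas[0]
        )

        art = TaskArtifacts(
            y=y,
            train_ids=train_ids,
            test_ids=test_ids,
            bow_models=bow_models,
            bow_clf=bow_clf,
            snpsy_clf=snpsy_clf,
            snpsy_transform=snpsy_transform,
            snpsy_medians=snpsy_medians,
            image_train_mean=float(image.loc[train_ids].mean()),
            pooled=pooled,
            selection=selection,
        )

        task_reports: dict[str, EvalReport] = {}
        for recipe in cfg.recipes:
            X = build_design_matrix(
                recipe,
                snpsy=snpsy_imp,
                bow_matrices=bow_frames,
                bow_feature=bow_feature,
                snpsy_feature=snpsy_feature,
                image=image.loc[all_ids],
                train_index=train_ids,
                selection=selection,
            )
            tr = [u for u in train_ids if u in X.index]
            te = [u for u in test_ids if u in X.index]
            ft, Xz = transform_features(X.loc[tr], X)
            report = fit_select_evaluate(
                Xz.loc[tr],
                y.loc[tr].to_numpy(),
                Xz.loc[te],
                y.loc[te].to_numpy(),
                algorithms=cfg.algorithms,
                seed=seed,
            )
            report.test_ids = te  # used for paired DeLong comparisons
            task_reports[recipe] = report
            art.recipe_transforms[recipe] = ft
            art.recipe_columns[recipe] = list(X.columns)

        # rankings + overlap table on the all-feature combination recipe
        rank_recipe = (
            "images_bow_snpsy_2" if "images_bow_snpsy_2" in cfg.recipes else cfg.recipes[0]
        )
        Xr = build_design_matrix(
            rank_recipe,
            snpsy=snpsy_imp,
            bow_matrices=bow_frames,
            bow_feature=bow_feature,
            snpsy_feature=snpsy_feature,
            image=image.loc[all_ids],
            train_index=train_ids,
            selection=selection,
        )
        tr = [u for u in train_ids if u in Xr.index]
        task_rankings = {
            "impurity": rank_features(
                Xr.loc[tr], y.loc[tr].to_numpy(), mode="impurity", seed=seed
            ),
            "class_correlation": rank_features(
                Xr.loc[tr], y.loc[tr].to_numpy(), mode="class_correlation"
            ),
        }

        top = selection.table.nsmallest(10, "p")
        ovl_rows = []
        for feat in top.index:
            a = pooled.loc[y.index[y == 1], feat].to_numpy()
            b = pooled.loc[y.index[y == 0], feat].to_numpy()
            ovl_rows.append(
                {
                    "feature": feat,
                    "median_risk": float(np.median(a)),
                    "median_control": float(np.median(b)),
                    "ovl": overlap_index(a, b),
                    "p": float(top.loc[feat, "p"]),
                }
            )
        task_overlap = pd.DataFrame(ovl_rows)
        return task_reports, art, task_rankings, task_overlap


@dataclass
class ScreeningResults:
    """Fitted screening analysis: metrics, screening tables, fitted state."""

    config: ExperimentConfig
    spvc: SpvcModel
    lexicon: Lexicon
    scorer: PolarityScorer
    spvs: dict
    snpsy_raw: pd.DataFrame
    provenance: pd.DataFrame
    image: pd.Series
    groups: pd.Series
    reports: dict[str, dict[str, EvalReport]]
    artifacts: dict[str, TaskArtifacts]
    rankings: dict[str, dict[str, pd.DataFrame]]
    overlaps: dict[str, pd.DataFrame]

    def summary(self) -> pd.DataFrame:
        """Per-recipe Pr/R/F1/Ac/AUC and chosen classifier for both tasks."""
        blocks = {}
        for task, reps in self.reports.items():
            rows = {RECIPE_LABELS[r]: rep.as_series() for r, rep in reps.items()}
            blocks[task] = pd.DataFrame(rows).T
        out = pd.concat(blocks, axis=1)
        out.index.name = "model"
        return out

    def selection(self, task: str, alpha: float | None = None) -> SelectionResult:
        sel = self.artifacts[task].selection
        return sel if alpha is None else sel.at_alpha(alpha)

    def delong(self, task: str, recipe_a: str, recipe_b: str) -> tuple[float, float, float]:
        """DeLong comparison of two recipes' held-out score vectors."""
        ra, rb = self.reports[task][recipe_a], self.reports[task][recipe_b]
        ids_a, ids_b = list(ra.test_ids), list(rb.test_ids)
        common = [u for u in ids_a if u in set(ids_b)]
        sa = pd.Series(ra.test_scores, index=ids_a).loc[common]
        sb = pd.Series(rb.test_scores, index=ids_b).loc[common]
        y = self.artifacts[task].y.loc[common]
        return delong_compare(sa.to_numpy(), sb.to_numpy(), y.to_numpy())

    # -- scoring unseen cohorts ------------------------------------------------

    def predict_users(
        self, profiles: Sequence[UserProfile], task: str, recipe: str = "selected_2"
    ) -> pd.DataFrame:
        """Score unseen profiles with a fitted recipe model.

        Returns a DataFrame (user_id, probability, predicted) using the
        test-user rule for outputted features (full-training-set models).
        """
        if not profiles:
            raise ValueError("empty cohort")
        art = self.artifacts[task]
        if recipe not in art.recipe_columns:
            raise ConfigurationError(f"recipe {recipe!r} was not fitted for {task!r}")
        cfg = self.config
        window = cfg.cohort.window
        spvs = build_spvs(self.spvc, profiles, k=cfg.spv_k)
        snpsy_raw, _ = snpsy_table(list(profiles), spvs, self.lexicon, self.scorer, window)
        snpsy = snpsy_raw.fillna(art.snpsy_medians.fillna(0.0))
        image = image_score_series(list(profiles)).fillna(art.image_train_mean)
        ids = list(snpsy.index)

        docs_spv = build_user_documents(list(profiles), spvs, variant="spv",
                                        max_tokens=cfg.bow_max_tokens)
        docs_full = build_user_documents(list(profiles), variant="full_profile",
                                         max_tokens=cfg.bow_max_tokens)
        bow_frames = {}
        for variant, docs in (("full_profile", docs_full), ("spv", docs_spv)):
            model = art.bow_models[variant]
            prefix = "bow_full:" if variant == "full_profile" else "bow_spv:"
            bow_frames[variant] = pd.DataFrame(
                model.transform(docs).toarray(),
                index=ids,
                columns=[prefix + n for n in model.feature_names],
            )
        pos = list(art.bow_clf.classes_).index(1)
        bow_feature = pd.Series(
            art.bow_clf.predict_proba(bow_frames["spv"].to_numpy())[:, pos],
            index=ids, name="bow_outputted",
        )
        prior = float(art.y.loc[art.train_ids].mean())
        empty = [d.user_id for d in docs_spv if not d.text]
        bow_feature.loc[empty] = prior
        snpsy_z = art.snpsy_transform.transform(snpsy)
        pos_s = list(art.snpsy_clf.classes_).index(1)
        snpsy_feature = pd.Series(
            art.snpsy_clf.predict_proba(snpsy_z.to_numpy())[:, pos_s],
            index=ids, name="snpsy_outputted",
        )

        spec = recipe_spec(recipe)
        if spec.selection_alpha is not None:
            pool = pooled_feature_matrix(snpsy, image, bow_frames, None)
            X = pool[art.recipe_columns[recipe]]
        else:
            X = build_design_matrix(
                spec,
                snpsy=snpsy,
                bow_matrices=bow_frames,
                bow_feature=bow_feature,
                snpsy_feature=snpsy_feature,
                image=image,
                train_index=None,
            )
            X = X[art.recipe_columns[recipe]]
        Xz = art.recipe_transforms[recipe].transform(X)
        est = self.reports[task][recipe].model
        pos_f = list(est.classes_).index(1)
        proba = est.predict_proba(Xz.to_numpy())[:, pos_f]
        return pd.DataFrame(
            {"probability": proba, "predicted": (proba > 0.5).astype(int)}, index=X.index
        )

    def doubtful_screen(
        self, profiles: Sequence[UserProfile], task: str = "risk_vs_focused",
        recipe: str = "selected_2",
    ) -> float:
        """Fraction of an unlabeled cohort predicted positive at threshold 0.5."""
        pred = self.predict_users(profiles, task, recipe)
        return float(pred["predicted"].mean())

    def audit_leakage(self) -> bool:
        """Recompute screening and transform parameters from the persisted
        split and assert they match the stored ones (train rows only)."""
        for task, art in self.artifacts.items():
            ids = art.train_ids if self.config.screening_scope == "train" else (
                art.train_ids + art.test_ids
            )
            sel = mannwhitney_screen(
                art.pooled.loc[ids], art.y.loc[ids].to_numpy(),
                alpha=self.config.alphas[0],
            )
            if not np.allclose(sel.table["p"], art.selection.table["p"], equal_nan=True):
                raise AssertionError(f"screening P values not reproducible for {task}")
            imp = median_impute(
                self.snpsy_raw.loc[art.train_ids + art.test_ids], art.train_ids
            )
            ft = FeatureTransform().fit(imp.loc[art.train_ids])
            if not np.allclose(ft.lambdas_, art.snpsy_transform.lambdas_):
                raise AssertionError(f"transform parameters not reproducible for {task}")
        return True

    def spv_coverage(self) -> pd.DataFrame:
        """Users with/without an SPV per group."""
        rows = []
        for group in sorted(self.groups.unique()):
            ids = self.groups.index[self.groups == group]
            has = sum(self.spvs[u].has_spv for u in ids)
            rows.append({"group": group, "with_spv": has, "without_spv": len(ids) - has})
        return pd.DataFrame(rows).set_index("group")

    def to_csv(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        path = outdir / "summary.csv"
        self.summary().to_csv(path)
        written.append(path)
        for task in self.reports:
            p = outdir / f"selection_{task}.csv"
            self.artifacts[task].selection.table.to_csv(p)
            written.append(p)
            p = outdir / f"overlap_{task}.csv"
            self.overlaps[task].to_csv(p, index=False)
            written.append(p)
            for mode, table in self.rankings[task].items():
                p = outdir / f"ranking_{task}_{mode}.csv"
                table.head(25).to_csv(p, index=False)
                written.append(p)
        p = outdir / "snpsy_features.csv"
        self.snpsy_raw.to_csv(p)
        written.append(p)
        p = outdir / "provenance.jsonl"
        with p.open("w") as fh:
            for uid, row in self.provenance.iterrows():
                rec = {"user_id": uid, **{k: row[k] for k in self.provenance.columns}}
                fh.write(json.dumps(rec, default=list, sort_keys=True) + "\n")
        written.append(p)
        return written


# -- manifest + one-command runner -------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class ExperimentManifest:
    config_hash: str
    seed: int
    artifacts: dict[str, str]
    created_utc: str
    package_version: str = "0.1.0"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def run_experiment(
    config: ExperimentConfig | str | Path,
    outdir: str | Path,
    timestamp: bool = True,
) -> ExperimentManifest:
    """Generate -> fit -> evaluate -> serialize everything under ``outdir``."""
    if not isinstance(config, ExperimentConfig):
        config = ExperimentConfig.from_yaml(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    lexicon = config.lexicon()
    cohort = generate_cohort(config.cohort, lexicon)
    corpus = generate_tweet_corpus(
        config.cohort, config.corpus_n_pos, config.corpus_n_neg, lexicon
    )
    write_users_jsonl(cohort, outdir / "users.jsonl")
    write_corpus_jsonl(corpus, outdir / "corpus.jsonl")

    results = ScreeningExperiment(cohort, corpus, config, lexicon).fit()
    write_spvs_jsonl(results.spvs, outdir / "spv.jsonl")
    written = results.to_csv(outdir)
    written += [outdir / "users.jsonl", outdir / "corpus.jsonl", outdir / "spv.jsonl"]

    cfg_repr = json.dumps(
        {k: repr(v) for k, v in sorted(vars(config).items())}, sort_keys=True
    )
    manifest = ExperimentManifest(
        config_hash=hashlib.sha256(cfg_repr.encode()).hexdigest(),
        seed=config.seed,
        artifacts={p.name: _sha256(p) for p in sorted(written)},
        created_utc=(
            datetime.now(timezone.utc).isoformat() if timestamp else "fixed"
        ),
    )
    manifest.write(outdir / "manifest.json")
    return manifest
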