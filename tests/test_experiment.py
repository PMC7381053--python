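"""End-to-end experiment object, artifacts, reproducibility, CLI surface."""

import json
from pathlib import Path

import pytest
import yaml
from click.testing import CliRunner

from spvscreen.cli import main as cli_main
from spvscreen.experiment import (
    ExperimentConfig,
    ScreeningExperiment,
    run_experiment,
)
from spvscreen.profiles import ConfigurationError, read_users_jsonl
from spvscreen.synthetic import CohortConfig, generate_cohort

from conftest import small_cohort_config


def tiny_config(seed=19, **kw) -> ExperimentConfig:
    cohort = small_cohort_config(seed=seed, n_per_group=8, count_scale=1 / 16)
    defaults = dict(
        seed=seed,
        cohort=cohort,
        corpus_n_pos=60,
        corpus_n_neg=60,
        algorithms=("logistic",),
        bow_ngram_range=(1, 2),
        spvc_ngram_range=(1, 2),
    )
    defaults.update(kw)
    return ExperimentConfig(**defaults)


@pytest.fixture(scope="module")
def tiny_results():
    return ScreeningExperiment.from_config(tiny_config()).fit()


class TestFit:
    def test_summary_shape_and_ranges(self, tiny_results):
        table = tiny_results.summary()
        assert table.shape[0] == 10  # all recipes
        for task in ("risk_vs_focused", "risk_vs_generic"):
            metrics = table[task][["Pr", "R", "F1", "Ac", "AUC"]].astype(float)
            assert ((metrics >= 0) & (metrics <= 1)).all().all()

    def test_selection_nesting(self, tiny_results):
        for task in ("risk_vs_focused", "risk_vs_generic"):
            s1 = set(tiny_results.selection(task, 0.05).selected)
            s2 = set(tiny_results.selection(task, 0.001).selected)
            assert s2 <= s1

    def test_leakage_audit(self, tiny_results):
        assert tiny_results.audit_leakage()

    def test_delong_self_comparison(self, tiny_results):
        auc_a, auc_b, p = tiny_results.delong("risk_vs_focused", "snpsy", "snpsy")
        assert auc_a == auc_b and p == 1.0

    def test_rankings_cover_modes(self, tiny_results):
        for task, ranks in tiny_results.rankings.items():
            assert set(ranks) == {"impurity", "class_correlation"}
            assert (ranks["impurity"]["score"] >= 0).all()

    def test_predict_unseen_cohort(self, tiny_results, lexicon):
        cohort = generate_cohort(
            small_cohort_config(seed=555, n_per_group=5, count_scale=1 / 16), lexicon
        )
        pred = tiny_results.predict_users(cohort, "risk_vs_focused", "snpsy")
        assert pred.shape[0] == 15
        assert ((pred["probability"] >= 0) & (pred["probability"] <= 1)).all()

    def test_doubtful_screen_bounds(self, tiny_results, lexicon):
        cohort = generate_cohort(
            small_cohort_config(seed=556, n_per_group=4, count_scale=1 / 16), lexicon
        )
        frac = tiny_results.doubtful_screen(cohort, "risk_vs_focused", "snpsy")
        assert 0.0 <= frac <= 1.0

    def test_empty_cohort_rejected(self, tiny_results):
        with pytest.raises(ValueError):
            tiny_results.doubtful_screen([], "risk_vs_focused", "snpsy")


class TestDoubtfulScreening:
    def test_directionality_on_default_models(self, default_results, lexicon):
        """A risk-distribution cohort screens mostly positive; a
        generic-control-distribution cohort mostly negative."""
        cfg = CohortConfig(seed=4242, n_per_group=20)
        cohort = generate_cohort(cfg, lexicon)
        risk_like = [u for u in cohort if u.group == "risk"]
        generic_like = [u for u in cohort if u.group == "generic_control"]
        frac_risk = default_results.doubtful_screen(
            risk_like, task="risk_vs_focused", recipe="selected_2"
        )
        frac_generic = default_results.doubtful_screen(
            generic_like, task="risk_vs_focused", recipe="selected_2"
        )
        assert frac_risk >= 0.8
        assert frac_generic <= 0.2


class TestRunExperiment:
    def test_artifacts_and_manifest_reproducible(self, tmp_path):
        cfg = tiny_config(seed=23, recipes=("snpsy", "selected_2"))
        m1 = run_experiment(cfg, tmp_path / "run1", timestamp=False)
        cfg2 = tiny_config(seed=23, recipes=("snpsy", "selected_2"))
        m2 = run_experiment(cfg2, tmp_path / "run2", timestamp=False)
        assert m1.artifacts == m2.artifacts  # byte-identical outputs
        assert (tmp_path / "run1" / "summary.csv").exists()
        assert (tmp_path / "run1" / "manifest.json").exists()
        users = read_users_jsonl(tmp_path / "run1" / "users.jsonl")
        assert len(users) == 24

    def test_config_round_trip_from_yaml(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            yaml.safe_dump(
                {
                    "seed": 3,
                    "corpus_n_pos": 40,
                    "algorithms": ["logistic"],
                    "cohort": {"n_per_group": 5},
                }
            )
        )
        cfg = ExperimentConfig.from_yaml(path)
        assert cfg.seed == 3 and cfg.cohort.n_per_group == 5
        assert cfg.algorithms == ("logistic",)

    def test_missing_lexicon_path_is_configuration_error(self, tmp_path):
        cfg = tiny_config(lexicon_path=str(tmp_path / "missing.json"))
        with pytest.raises(ConfigurationError, match="lexicon_path"):
            cfg.lexicon()

    def test_bad_screening_scope_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_config(screening_scope="everything")

    def test_unknown_recipe_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_config(recipes=("snpsy", "bogus"))


class TestCli:
    def test_generate_writes_jsonl(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "users.jsonl"
        result = runner.invoke(
            cli_main,
            ["generate", "--seed", "3", "--n-per-group", "2", "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        users = read_users_jsonl(out)
        assert len(users) == 6

    def test_report_requires_summary(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["report", "--outdir", str(tmp_path)])
        assert result.exit_code != 0

    def test_spvc_train_and_build_chain(self, tmp_path, lexicon):
        from spvscreen.profiles import write_corpus_jsonl, write_users_jsonl
        from spvscreen.synthetic import generate_tweet_corpus

        cfg = small_cohort_config(seed=9, n_per_group=2, count_scale=1 / 16)
        corpus = generate_tweet_corpus(cfg, 40, 40, lexicon)
        write_corpus_jsonl(corpus, tmp_path / "corpus.jsonl")
        write_users_jsonl(generate_cohort(cfg, lexicon), tmp_path / "users.jsonl")

        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["train-spvc", "--corpus", str(tmp_path / "corpus.jsonl"),
             "--out", str(tmp_path / "spvc.joblib")],
        )
        assert res.exit_code == 0, res.output
        assert json.loads(res.output.strip())["f1"] >= 0.0
        res = runner.invoke(
            cli_main,
            ["build-spv", "--users", str(tmp_path / "users.jsonl"),
             "--model", str(tmp_path / "spvc.joblib"),
             "--out", str(tmp_path / "spv.jsonl")],
        )
        assert res.exit_code == 0, res.output
        lines = Path(tmp_path / "spv.jsonl").read_text().strip().splitlines()
        assert len(lines) == 6
        rec = json.loads(lines[0])
        assert {"user_id", "has_spv", "n_spv", "retained"} <= set(rec)
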