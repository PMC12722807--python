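import numpy as np
import pandas as pd
import pytest

from tests.conftest import REPORTED_FOLD_AUCS
from symrec.evaluation import (
    ClassifierSpec,
    bootstrap_ci,
    fit_classifier,
    participant_folds,
    permute_labels,
    summarize,
)


def corpus_frame(n_control=5, n_impaired=5, transcripts_per=1):
    rows = []
    for label, n, prefix in (("control", n_control, "c"), ("impaired", n_impaired, "d")):
        for i in range(n):
            for t in range(transcripts_per):
                rows.append({"participant_id": f"{prefix}{i}", "label": label})
    return pd.DataFrame(rows)


class TestParticipantFolds:
    def test_balanced_stratification(self):
        folds = participant_folds(corpus_frame(5, 5), k=5, seed=0)
        df = corpus_frame(5, 5)
        for fold in range(1, 6):
            members = [p for p, f in folds.fold_of.items() if f == fold]
            labels = sorted(df[df.participant_id.isin(members)].label.unique())
            assert len(members) == 2 and labels == ["control", "impaired"]

    def test_transcripts_travel_together(self):
        df = corpus_frame(5, 5, transcripts_per=3)
        folds = participant_folds(df, k=5, seed=1)
        mask = folds.test_mask(df.participant_id, 1)
        in_fold = set(df.participant_id[mask])
        for p in in_fold:
            assert mask[df.participant_id == p].all()

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            participant_folds(corpus_frame(2, 1), k=5, seed=0)

    def test_mixed_label_participant_rejected(self):
        df = pd.DataFrame(
            {"participant_id": ["p1", "p1"], "label": ["control", "impaired"]}
        )
        with pytest.raises(ValueError, match="inconsistent"):
            participant_folds(df, k=2, seed=0)

    @pytest.mark.parametrize("seed", range(20))
    def test_never_leaks_a_participant_across_split(self, seed):
        df = corpus_frame(8, 8, transcripts_per=2)
        folds = participant_folds(df, k=5, seed=seed)
        pids = list(df.participant_id)
        for fold in range(1, 6):
            test = folds.test_mask(pids, fold)
            assert not ({p for p, t in zip(pids, test) if t}
                        & {p for p, t in zip(pids, test) if not t})


class TestSummarize:
    def test_reported_fold_statistics(self):
        s = summarize(REPORTED_FOLD_AUCS)
        assert round(s.mean, 3) == 0.954
        assert s.min == 0.943
        assert s.max == 0.982
        assert s.std == pytest.approx(np.std(REPORTED_FOLD_AUCS, ddof=1))

    def test_single_value_std_zero_with_warning(self):
        with pytest.warns(UserWarning, match="single fold"):
            s = summarize([0.5])
        assert s.mean == 0.5 and s.std == 0.0

    def test_constant_folds_zero_std(self):
        assert summarize([0.9, 0.9, 0.9]).std == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestBootstrapCI:
    def test_recovers_reported_interval(self):
        lo, hi = bootstrap_ci(REPORTED_FOLD_AUCS, B=10000, seed=0)
        assert lo == pytest.approx(0.945, abs=0.003)
        assert hi == pytest.approx(0.968, abs=0.003)

    def test_constant_list_degenerate_interval(self):
        assert bootstrap_ci([0.9] * 5, B=200, seed=0) == (0.9, 0.9)

    def test_deterministic_under_seed(self):
        assert bootstrap_ci(REPORTED_FOLD_AUCS, seed=3) == bootstrap_ci(
            REPORTED_FOLD_AUCS, seed=3
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            bootstrap_ci([0.9], B=1000, seed=0)
        with pytest.raises(ValueError):
            bootstrap_ci([0.9, 0.8], B=10, seed=0)

    @pytest.mark.parametrize("trial", range(5))
    def test_interval_ordering_sanity(self, trial):
        rng = np.random.default_rng(trial)
        aucs = rng.uniform(0.4, 1.0, size=5)
        lo, hi = bootstrap_ci(aucs, B=2000, seed=trial)
        assert aucs.min() <= lo <= aucs.mean() <= hi <= aucs.max()


SMALL_SPEC = ClassifierSpec(learning_rates=(0.1,), max_depths=(3,), reg_lambdas=(1.0,))


class TestFitClassifier:
    def test_separable_toy_embeddings_perfect_training_auc(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (10, 2)), rng.normal(5, 0.3, (10, 2))])
        y = ["control"] * 10 + ["impaired"] * 10
        clf = fit_classifier(X, y, SMALL_SPEC, seed=0)
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score([0] * 10 + [1] * 10, clf.predict_proba(X)[:, 1]) == 1.0

    def test_grid_of_one_selects_that_configuration(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        y = ["control", "impaired"] * 15
        clf = fit_classifier(X, y, SMALL_SPEC, seed=0)
        assert clf.best_params_ == {"learning_rate": 0.1, "max_depth": 3, "reg_lambda": 1.0}

    def test_shuffled_labels_inner_auc_in_null_band(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 16))
        y = np.array(["control", "impaired"] * 100)
        rng.shuffle(y)
        clf = fit_classifier(X, y, ClassifierSpec(), seed=0)
        assert 0.35 <= clf.best_score_ <= 0.65

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            fit_classifier(np.zeros((4, 2)), ["control"] * 4, SMALL_SPEC, seed=0)


def test_optimistic_single_fit_variant_runs(small_corpus):
    """retrain_per_fold=False trains one shared encoder on all transcripts."""
    from symrec.evaluation import PipelineConfig, evaluate_cv

    config = PipelineConfig(
        epochs=1, n_pairs=64, k=5, B=200, seed=0,
        retrain_per_fold=False, classifier=SMALL_SPEC,
    )
    report = evaluate_cv(small_corpus, config)
    assert len(report.fold_aucs) == 5
    assert all(0.0 <= a <= 1.0 for a in report.fold_aucs)
    assert len(report.predictions) == len(small_corpus)


class TestPermuteLabels:
    def test_preserves_participant_label_multiset_and_grouping(self, small_corpus):
        permuted = permute_labels(small_corpus, seed=0)

        def participant_labels(corpus):
            return sorted(
                {r.participant_id: r.label for r in corpus.records}.values()
            )

        assert participant_labels(permuted) == participant_labels(small_corpus)
        by_part = {}
        for rec in permuted.records:
            by_part.setdefault(rec.participant_id, set()).add(rec.label)
        assert all(len(v) == 1 for v in by_part.values())
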