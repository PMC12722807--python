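"""Word-level reference representation: TF–IDF + regularized logistic regression.

Lexical term-frequency/inverse-document-frequency features capture which
words a speaker uses but discard the temporal and paralinguistic structure
the character-level pipeline targets.  Evaluated under the identical
participant-grouped cross-validation protocol — the fold assignment object is
shared bit-for-bit with the main pipeline — so the comparison isolates the
representation, not the protocol.  Within each fold the vocabulary is fit on
training documents only (a token unique to test documents contributes no
feature), and the logistic regularization strength is chosen by inner
cross-validated AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .chat_io import CorpusTable
from .evaluation import CVReport, FoldAssignment, _as_binary, bootstrap_ci, summarize


@dataclass(frozen=True)
class TfidfConfig:
    """Word-level TF–IDF settings (smoothed idf, unigrams by default)."""

    lowercase: bool = True
    ngram_range: tuple[int, int] = (1, 1)
    min_df: int = 1
    sublinear_tf: bool = False

    def __post_init__(self):
        if self.ngram_range[0] > self.ngram_range[1]:
            raise ValueError("ngram_range lower bound exceeds upper bound")
        if self.min_df < 1:
            raise ValueError("min_df must be >= 1")


def make_vectorizer(config: TfidfConfig = TfidfConfig()) -> TfidfVectorizer:
    return TfidfVectorizer(
        lowercase=config.lowercase,
        ngram_range=config.ngram_range,
        min_df=config.min_df,
        sublinear_tf=config.sublinear_tf,
    )


def tfidf_vectorize(texts, config: TfidfConfig = TfidfConfig()):
    """Fit TF–IDF on `texts`; returns (weight matrix, vocabulary, vectorizer).

    Weights follow the standard smoothed-idf formulation
    ``tf × (ln((1 + n) / (1 + df)) + 1)`` with L2-normalized rows.
    """
    if not len(texts):
        raise ValueError("empty corpus")
    vec = make_vectorizer(config)
    try:
        X = vec.fit_transform(texts)
    except ValueError as exc:
        raise ValueError(f"empty vocabulary after min_df={config.min_df}: {exc}") from exc
    return X, vec.get_feature_names_out(), vec

C_GRID = (0.01, 0.1, 1.0, 10.0)


def logistic_cv(
    texts,
    labels,
    participant_ids,
    folds: FoldAssignment,
    config: TfidfConfig = TfidfConfig(),
    B: int = 10000,
    seed: int = 0,
) -> CVReport:
    """Grouped-CV evaluation of the TF–IDF + logistic baseline.

    Reuses the exact :class:`FoldAssignment` of the main pipeline.  Per fold:
    vectorizer fit on training texts only, logistic model with inner-CV
    selection of C over a small grid, AUC on the held-out fold.
    """
    labels = np.asarray(labels)
    y, _ = _as_binary(labels)
    texts = list(texts)
    fold_aucs = []
    for fold in range(1, folds.k + 1):
        test = folds.test_mask(participant_ids, fold)
        train = ~test
        if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
            raise ValueError(f"single-class split in fold {fold}")
        vec = make_vectorizer(config)
        X_train = vec.fit_transform([t for t, m in zip(texts, train) if m])
        X_test = vec.transform([t for t, m in zip(texts, test) if m])
        inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        search = GridSearchCV(
            LogisticRegression(max_iter=2000),
            {"C": list(C_GRID)},
            scoring="roc_auc",
            cv=inner,
            n_jobs=1,
        )
        search.fit(X_train, y[train])
        scores = search.predict_proba(X_test)[:, 1]
        fold_aucs.append(float(roc_auc_score(y[test], scores)))
    stats = summarize(fold_aucs)
    lo, hi = bootstrap_ci(fold_aucs, B=B, seed=seed)
    return CVReport(
        fold_aucs=fold_aucs,
        mean=stats.mean, std=stats.std, min=stats.min, max=stats.max,
        ci_low=lo, ci_high=hi,
        config_fingerprint="tfidf-logistic",
    )


def tfidf_baseline_cv(corpus: CorpusTable, folds: FoldAssignment,
                      config: TfidfConfig = TfidfConfig(), B: int = 10000,
                      seed: int = 0) -> CVReport:
    """Convenience wrapper running :func:`logistic_cv` on a corpus table."""
    return logistic_cv(corpus.texts, corpus.labels, corpus.participant_ids,
                       folds, config=config, B=B, seed=seed)
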