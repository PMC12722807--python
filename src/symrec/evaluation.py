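"""Leakage-safe evaluation of embedding discriminability.

The protocol: participant-grouped, class-stratified 5-fold cross-validation.
All transcripts of one participant travel together into a single train–test
fold, so no speaker identity leaks across the split.  Within each fold the
twin-branch encoder is trained on the training transcripts only, training
embeddings fit a gradient-boosted tree classifier (XGBoost — a regularized
additive-tree objective, per-example loss plus a per-tree complexity
penalty) whose learning rate, tree depth and L2 regularization are chosen by
inner cross-validated AUC, and the held-out fold is embedded and scored.
Fold-level ROC–AUCs are summarized (mean, sample std, min, max) and a
nonparametric bootstrap of the fold means (default 10,000 resamples, 2.5th
and 97.5th percentiles) gives the 95% confidence interval.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from xgboost import XGBClassifier

from .chat_io import CorpusTable
from .encoding import DEFAULT_TARGET_LENGTH, SymbolEncoder
from .metric_learning import SiameseEncoder
from .recurrence import RecurrenceImager


@dataclass
class FoldAssignment:
    """Participant → fold index (1..k); every participant is in exactly one fold."""

    fold_of: dict[str, int]
    k: int

    def test_mask(self, participant_ids, fold: int) -> np.ndarray:
        return np.array([self.fold_of[p] == fold for p in participant_ids])


@dataclass(frozen=True)
class ClassifierSpec:
    """Gradient-boosted tree stage: search grid and inner-CV selection."""

    learning_rates: tuple[float, ...] = (0.05, 0.1, 0.3)
    max_depths: tuple[int, ...] = (3, 5, 7)
    reg_lambdas: tuple[float, ...] = (0.0, 1.0, 10.0)
    n_estimators: int = 100
    inner_folds: int = 3

    def grid(self) -> dict:
        grid = {
            "learning_rate": list(self.learning_rates),
            "max_depth": list(self.max_depths),
            "reg_lambda": list(self.reg_lambdas),
        }
        if not all(grid.values()):
            raise ValueError("classifier search grid must be non-empty")
        return grid


@dataclass
class FoldSummary:
    mean: float
    std: float
    min: float
    max: float


@dataclass
class CVReport:
    """Fold-level AUCs with summary statistics and bootstrap CI."""

    fold_aucs: list[float]
    mean: float
    std: float
    min: float
    max: float
    ci_low: float
    ci_high: float
    config_fingerprint: str = ""
    predictions: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("predictions")
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


def participant_folds(corpus, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Group-aware, class-stratified fold assignment at the participant level.

    `corpus` is a :class:`~symrec.chat_io.CorpusTable` or a DataFrame with
    ``participant_id`` and ``label`` columns.  Each participant (with all
    their transcripts) lands in exactly one fold; folds are stratified on the
    participant's class.  Participants with inconsistent labels are rejected.
    """
    if isinstance(corpus, CorpusTable):
        df = pd.DataFrame({"participant_id": corpus.participant_ids, "label": corpus.labels})
    else:
        df = corpus[["participant_id", "label"]]
    by_part = df.groupby("participant_id")["label"].agg(set)
    mixed = [p for p, labs in by_part.items() if len(labs) > 1]
    if mixed:
        raise ValueError(f"participants with inconsistent labels: {mixed}")
    participants = np.array(by_part.index)
    labels = np.array([next(iter(labs)) for labs in by_part])
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"need at least {k} participants per class for {k} folds; got {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(participants, labels), start=1):
        for p in participants[test_idx]:
            fold_of[str(p)] = fold
    return FoldAssignment(fold_of=fold_of, k=k)


def _as_binary(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError(f"single-class data: {list(classes)}")
    return (labels == classes[-1]).astype(int), classes


def fit_classifier(embeddings, labels, spec: ClassifierSpec = ClassifierSpec(),
                   seed: int = 0):
    """Grid-search the boosted-tree stage by inner-CV AUC and refit the winner.

    Returns the fitted :class:`~sklearn.model_selection.GridSearchCV`; the
    chosen configuration is in ``.best_params_`` and the selection criterion
    value in ``.best_score_``.
    """
    X = np.asarray(embeddings)
    y, _ = _as_binary(labels)
    base = XGBClassifier(
        n_estimators=spec.n_estimators,
        tree_method="hist",
        eval_metric="logloss",
        random_state=seed,
        n_jobs=1,
        verbosity=0,
    )
    inner = StratifiedKFold(n_splits=spec.inner_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(base, spec.grid(), scoring="roc_auc", cv=inner, n_jobs=1, refit=True)
    search.fit(X, y)
    return search


def summarize(fold_aucs) -> FoldSummary:
    """Arithmetic mean, sample (n−1) std and extremes of the fold AUCs."""
    arr = np.asarray(fold_aucs, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty fold list")
    if arr.size == 1:
        warnings.warn("single fold: standard deviation undefined, reported as 0")
        std = 0.0
    else:
        std = float(np.std(arr, ddof=1))
    return FoldSummary(mean=float(arr.mean()), std=std, min=float(arr.min()),
                       max=float(arr.max()))


def bootstrap_ci(fold_aucs, B: int = 10000, seed: int = 0) -> tuple[float, float]:
    """Nonparametric bootstrap 95% CI for the mean fold AUC.

    Resamples the fold AUCs with replacement `B` times, takes the mean of
    each resample, and returns the empirical 2.5th and 97.5th percentiles.
    """
    arr = np.asarray(fold_aucs, dtype=np.float64)
    if arr.size < 2:
        raise ValueError("need at least 2 fold AUCs to bootstrap")
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(B, arr.size))
    means = arr[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class PipelineConfig:
    """End-to-end configuration for the character-level recurrence pipeline."""

    target_length: int = DEFAULT_TARGET_LENGTH
    mode: str = "exact"
    interp: str = "area"
    epochs: int = 20
    batch_size: int = 32
    n_pairs: int | None = None        # None -> 4 × training images per fold
    margin: float = 1.0
    learning_rate: float = 0.001
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    k: int = 5
    B: int = 10000
    seed: int = 0
    retrain_per_fold: bool = True     # False reproduces the optimistic single-fit variant

    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def evaluate_cv(corpus: CorpusTable, config: PipelineConfig = PipelineConfig()) -> CVReport:
    """Run the full grouped-CV evaluation of the character-level pipeline.

    Encodes every transcript, renders recurrence images once, then per fold
    trains the twin-branch encoder on the training transcripts only, fits the
    boosted-tree classifier on training embeddings (inner-CV grid search) and
    scores the held-out fold.  A runtime leakage guard asserts the train and
    test participant sets are disjoint in every fold.
    """
    labels = np.asarray(corpus.labels)
    participants = corpus.participant_ids
    y, classes = _as_binary(labels)

    codes = SymbolEncoder(target_length=config.target_length).fit_transform(corpus.texts)
    images = RecurrenceImager(mode=config.mode, interp=config.interp).transform(codes)

    ss = np.random.SeedSequence(config.seed).generate_state(4 + config.k)
    folds = participant_folds(corpus, k=config.k, seed=int(ss[0]) % (2**31))

    shared_encoder = None
    if not config.retrain_per_fold:
        shared_encoder = _fit_siamese(images, labels, config, int(ss[1]) % (2**31))

    fold_aucs: list[float] = []
    rows = []
    for fold in range(1, config.k + 1):
        test = folds.test_mask(participants, fold)
        train = ~test
        train_parts = {p for p, t in zip(participants, train) if t}
        test_parts = {p for p, t in zip(participants, test) if t}
        assert not train_parts & test_parts, f"participant leakage in fold {fold}"
        fold_seed = int(ss[3 + fold]) % (2**31)
        try:
            encoder = shared_encoder or _fit_siamese(
                images[train], labels[train], config, fold_seed
            )
            emb_train = encoder.transform(images[train])
            emb_test = encoder.transform(images[test])
            clf = fit_classifier(emb_train, labels[train], config.classifier, seed=fold_seed)
            scores = clf.predict_proba(emb_test)[:, 1]
        except Exception as exc:
            raise RuntimeError(f"fold {fold} failed: {exc}") from exc
        auc = float(roc_auc_score(y[test], scores))
        fold_aucs.append(auc)
        for tid, s, lab in zip(np.array([r.transcript_id for r in corpus.records])[test],
                               scores, labels[test]):
            rows.append({"transcript_id": tid, "score": float(s), "label": lab, "fold": fold})

    stats = summarize(fold_aucs)
    lo, hi = bootstrap_ci(fold_aucs, B=config.B, seed=int(ss[2]) % (2**31))
    return CVReport(
        fold_aucs=fold_aucs,
        mean=stats.mean, std=stats.std, min=stats.min, max=stats.max,
        ci_low=lo, ci_high=hi,
        config_fingerprint=config.fingerprint(),
        predictions=pd.DataFrame(rows),
    )


def _fit_siamese(images, labels, config: PipelineConfig, seed: int) -> SiameseEncoder:
    enc = SiameseEncoder(
        margin=config.margin, learning_rate=config.learning_rate,
        batch_size=config.batch_size, epochs=config.epochs,
        n_pairs=config.n_pairs, random_state=seed,
    )
    return enc.fit(images, labels)


def permute_labels(corpus: CorpusTable, seed: int = 0) -> CorpusTable:
    """Permutation-null corpus: labels reshuffled across participants.

    Each participant keeps one label (so grouping and stratification remain
    well-defined) but the participant → label map is randomly permuted.
    """
    import copy

    parts = sorted({r.participant_id for r in corpus.records})
    orig = {p: next(r.label for r in corpus.records if r.participant_id == p) for p in parts}
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation([orig[p] for p in parts])
    new_label = dict(zip(parts, shuffled))
    records = []
    for rec in corpus.records:
        rec = copy.copy(rec)
        rec.label = str(new_label[rec.participant_id])
        records.append(rec)
    return CorpusTable(records=records)
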