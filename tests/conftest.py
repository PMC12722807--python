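import numpy as np
import pytest

from symrec.chat_io import load_corpus
from symrec.encoding import SymbolEncoder
from symrec.metric_learning import TrainConfig, generate_pairs, train_siamese
from symrec.recurrence import RecurrenceImager
from symrec.synthetic import generate_corpus

#: fold AUCs as printed in the study this package reproduces
REPORTED_FOLD_AUCS = [0.949, 0.951, 0.943, 0.982, 0.944]


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """24-transcript high-contrast corpus over 16 participants."""
    outdir = tmp_path_factory.mktemp("corpus-small")
    paths, meta = generate_corpus(12, 12, outdir, n_participants_per_class=8, seed=123)
    return load_corpus(paths, meta)


@pytest.fixture(scope="session")
def small_images(small_corpus):
    """Recurrence images (n, 128, 128) plus labels for the small corpus."""
    codes = SymbolEncoder(target_length=512).fit_transform(small_corpus.texts)
    images = RecurrenceImager().transform(codes)
    return images, np.array(small_corpus.labels)


@pytest.fixture(scope="session")
def trained_encoder(small_images):
    """Encoder contrastively trained on the first 16 images; last 8 held out."""
    images, labels = small_images
    train_idx = np.concatenate([np.flatnonzero(labels == c)[:8] for c in np.unique(labels)])
    pairs = generate_pairs(labels[train_idx], 96, seed=5)
    encoder, history = train_siamese(
        images[train_idx], pairs, TrainConfig(epochs=3, seed=5)
    )
    held_out = np.setdiff1d(np.arange(len(labels)), train_idx)
    return encoder, history, images, labels, held_out
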