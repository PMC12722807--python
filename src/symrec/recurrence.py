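"""Recurrence plots and RQA diagnostics for symbolic sequences.

A recurrence plot marks the time pairs (i, j) at which a sequence revisits a
state: R_ij = Θ(ε − |x_i − x_j|) with Θ the Heaviside step function (Θ(0)=1).
For character-coded text the intended semantics is *symbolic equivalence* —
R_ij = 1 iff x_i = x_j — since integer codes are arbitrary indices; the
thresholded form with ε = 0.1 × the sequence standard deviation reduces to it
whenever ε < 1.  Both modes are implemented; ``exact`` is the default, and
``heaviside`` logs a warning when ε ≥ 1 (numeric adjacency of arbitrary codes
would then leak into the plot).

Rows/columns in the pad suffix are forced to zero: a pad-pad block would be a
solid artificial recurrent square.  The threshold's standard deviation is the
population std over the *non-pad* codes only, so padding cannot shift it.

Plots are rendered as fixed-size (default 128×128) images in [0, 1] for the
convolutional encoder; optional RQA summaries (recurrence rate, determinism,
longest diagonal) are provided as diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from PIL import Image
from sklearn.base import BaseEstimator, TransformerMixin

from .encoding import PAD_CODE, SymbolSequence

logger = logging.getLogger(__name__)

_INTERP = {
    "area": Image.Resampling.BOX,
    "bilinear": Image.Resampling.BILINEAR,
    "nearest": Image.Resampling.NEAREST,
}


@dataclass
class RecurrencePlot:
    """N×N binary recurrence matrix with its pad-aware bookkeeping."""

    matrix: np.ndarray
    effective_length: int
    epsilon: float
    mode: str
    transcript_id: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("recurrence matrix must be square")


@dataclass
class RecurrenceImage:
    """size×size real-valued image in [0, 1]."""

    pixels: np.ndarray
    transcript_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)


@dataclass(frozen=True)
class RQAMetrics:
    recurrence_rate: float
    determinism: float
    longest_diagonal: int


def _active_codes(seq: SymbolSequence) -> np.ndarray:
    codes = seq.active
    if len(codes) < 2:
        raise ValueError("degenerate sequence: effective length < 2")
    return codes


def epsilon_threshold(seq: SymbolSequence) -> float:
    """0.1 × population standard deviation of the non-pad codes."""
    codes = _active_codes(seq)
    return 0.1 * float(np.std(codes.astype(np.float64)))


def recurrence_matrix(seq: SymbolSequence, mode: str = "exact") -> RecurrencePlot:
    """Build the recurrence plot of a symbol sequence.

    ``exact`` mode: R_ij = 1 iff x_i = x_j (symbolic equivalence).
    ``heaviside`` mode: R_ij = 1 iff |x_i − x_j| ≤ ε with ε from
    :func:`epsilon_threshold`.  Pad rows/columns are zero in both modes.
    """
    if mode not in ("exact", "heaviside"):
        raise ValueError(f"unknown mode {mode!r}")
    codes = _active_codes(seq)
    n_total = len(seq)
    if mode == "exact":
        eps = 0.0
        rec = codes[:, None] == codes[None, :]
    else:
        eps = epsilon_threshold(seq)
        if eps >= 1:
            logger.warning(
                "heaviside threshold eps=%.3f >= 1: numeric adjacency of symbol "
                "codes leaks into the recurrence plot",
                eps,
            )
        diff = np.abs(codes[:, None].astype(np.float64) - codes[None, :].astype(np.float64))
        rec = diff <= eps
    matrix = np.zeros((n_total, n_total), dtype=np.uint8)
    matrix[: len(codes), : len(codes)] = rec
    return RecurrencePlot(
        matrix=matrix,
        effective_length=seq.effective_length,
        epsilon=eps,
        mode=mode,
        transcript_id=seq.transcript_id,
    )


def to_image(plot: RecurrencePlot, size: int = 128, interp: str = "area") -> RecurrenceImage:
    """Resample the recurrence matrix to size×size pixels in [0, 1].

    Area (box) averaging is the default: it preserves local recurrence
    density under downsampling. An all-zero matrix maps to an all-zero image.
    """
    if size < 2:
        raise ValueError("image size must be >= 2")
    if interp not in _INTERP:
        raise ValueError(f"unknown interpolation {interp!r}")
    mat = plot.matrix.astype(np.float32)
    if mat.shape == (size, size):
        pixels = mat.copy()
    else:
        img = Image.fromarray(mat).resize((size, size), _INTERP[interp])
        pixels = np.array(img, dtype=np.float32)
    top = float(pixels.max(initial=0.0))
    if top > 1.0:
        pixels = pixels / top
    np.clip(pixels, 0.0, 1.0, out=pixels)
    return RecurrenceImage(pixels=pixels, transcript_id=plot.transcript_id)


def _diagonal_line_histogram(block: np.ndarray) -> dict[int, int]:
    """Lengths of maximal off-main-diagonal runs of 1s along diagonals."""
    n = block.shape[0]
    hist: dict[int, int] = {}
    for offset in range(1, n):
        for diag in (np.diagonal(block, offset), np.diagonal(block, -offset)):
            run = 0
            for v in diag:
                if v:
                    run += 1
                elif run:
                    hist[run] = hist.get(run, 0) + 1
                    run = 0
            if run:
                hist[run] = hist.get(run, 0) + 1
    return hist


def rqa_metrics(plot: RecurrencePlot, l_min: int = 2) -> RQAMetrics:
    """Recurrence rate, determinism and longest diagonal of the unpadded block.

    recurrence_rate counts all recurrent points (including the main diagonal)
    over effective_length².  determinism is the fraction of *off-main-diagonal*
    recurrent points lying on diagonal line segments of length >= `l_min`
    (0 when there are no off-diagonal points).  longest_diagonal excludes the
    main diagonal.
    """
    if l_min < 2:
        raise ValueError("l_min must be >= 2")
    n = plot.effective_length
    block = plot.matrix[:n, :n].astype(bool)
    rr = float(block.sum()) / float(n * n)
    hist = _diagonal_line_histogram(block)
    total_off = sum(length * count for length, count in hist.items())
    on_lines = sum(length * count for length, count in hist.items() if length >= l_min)
    det = on_lines / total_off if total_off else 0.0
    longest = max(hist, default=0)
    return RQAMetrics(recurrence_rate=rr, determinism=det, longest_diagonal=longest)


def save_image_png(image: RecurrenceImage, path) -> None:
    """Write a recurrence image as 8-bit grayscale PNG."""
    arr = np.round(image.pixels * 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


class RecurrenceImager(TransformerMixin, BaseEstimator):
    """sklearn-style transformer: (n, L) code matrix -> (n, size, size) images.

    Effective lengths are recovered from the trailing pad-zero suffix of each
    row (code 0 never encodes a real character).
    """

    def __init__(self, mode: str = "exact", size: int = 128, interp: str = "area"):
        self.mode = mode
        self.size = size
        self.interp = interp

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X)
        out = np.empty((X.shape[0], self.size, self.size), dtype=np.float32)
        for i, row in enumerate(X):
            nonpad = np.nonzero(row != PAD_CODE)[0]
            eff = int(nonpad[-1]) + 1 if len(nonpad) else 0
            seq = SymbolSequence(codes=row, effective_length=eff)
            out[i] = to_image(recurrence_matrix(seq, self.mode), self.size, self.interp).pixels
        return out
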