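import numpy as np
import pytest

from symrec.encoding import SymbolSequence, encode_text, standardize_length
from symrec.recurrence import (
    RecurrencePlot,
    RecurrenceImager,
    epsilon_threshold,
    recurrence_matrix,
    rqa_metrics,
    to_image,
)


def seq(codes, eff=None):
    codes = np.array(codes)
    return SymbolSequence(codes, eff if eff is not None else len(codes))


def brute_force_matrix(codes, mode, eps=0.0):
    """Independent double-loop oracle for the recurrence definition."""
    n = len(codes)
    out = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        for j in range(n):
            if mode == "exact":
                out[i, j] = 1 if codes[i] == codes[j] else 0
            else:
                out[i, j] = 1 if eps - abs(codes[i] - codes[j]) >= 0 else 0
    return out


class TestEpsilonThreshold:
    def test_hand_computed_std(self):
        assert epsilon_threshold(seq([1, 2, 3])) == pytest.approx(0.1 * 0.816496580927726)

    def test_zero_variance(self):
        assert epsilon_threshold(seq([5, 5, 5, 5])) == 0.0

    def test_two_point_symmetric(self):
        assert epsilon_threshold(seq([1, 1, 27, 27])) == pytest.approx(1.3)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            epsilon_threshold(seq([7]))

    def test_pad_excluded_from_std(self):
        padded = standardize_length(seq([1, 2, 3]), 10)
        assert epsilon_threshold(padded) == epsilon_threshold(seq([1, 2, 3]))


class TestRecurrenceMatrix:
    def test_exact_mode_see(self):
        plot = recurrence_matrix(encode_text("see"), "exact")
        assert plot.matrix.tolist() == [[1, 0, 0], [0, 1, 1], [0, 1, 1]]

    def test_constant_sequence_all_ones(self):
        for mode in ("exact", "heaviside"):
            plot = recurrence_matrix(seq([7, 7, 7, 7]), mode)
            assert (plot.matrix == 1).all()

    def test_heaviside_small_eps_equals_identity(self):
        plot = recurrence_matrix(seq([1, 2, 3]), "heaviside")
        assert plot.epsilon < 1
        assert plot.matrix.tolist() == np.eye(3, dtype=int).tolist()

    def test_pad_region_masked(self):
        padded = standardize_length(seq([19, 5, 5]), 6)
        plot = recurrence_matrix(padded, "exact")
        assert plot.matrix[3:, :].sum() == 0 and plot.matrix[:, 3:].sum() == 0
        assert plot.matrix[:3, :3].tolist() == [[1, 0, 0], [0, 1, 1], [0, 1, 1]]

    def test_heaviside_large_eps_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="symrec.recurrence"):
            recurrence_matrix(seq([1, 1, 27, 27]), "heaviside")
        assert any("eps" in r.message for r in caplog.records)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            recurrence_matrix(seq([1, 2]), "fuzzy")

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_bruteforce_oracle_and_mode_equivalence(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2, 51))
        codes = rng.integers(1, 43, size=n)
        s = seq(codes)
        exact = recurrence_matrix(s, "exact")
        heavi = recurrence_matrix(s, "heaviside")
        assert (exact.matrix == brute_force_matrix(codes, "exact")).all()
        assert (heavi.matrix == brute_force_matrix(codes, "heaviside", heavi.epsilon)).all()
        if heavi.epsilon < 1:
            assert (exact.matrix == heavi.matrix).all()

    @pytest.mark.parametrize("trial", range(5))
    def test_symmetry_and_reflexivity(self, trial):
        rng = np.random.default_rng(100 + trial)
        codes = rng.integers(1, 30, size=int(rng.integers(2, 40)))
        plot = recurrence_matrix(seq(codes), "exact")
        assert (plot.matrix == plot.matrix.T).all()
        assert (np.diag(plot.matrix)[: plot.effective_length] == 1).all()

    def test_shuffle_changes_matrix_preserves_rate(self):
        rng = np.random.default_rng(3)
        codes = np.array([1, 1, 2, 3, 3, 3, 4, 5, 5, 6])
        shuffled = rng.permutation(codes)
        a = recurrence_matrix(seq(codes), "exact")
        b = recurrence_matrix(seq(shuffled), "exact")
        assert not (a.matrix == b.matrix).all()
        assert rqa_metrics(a).recurrence_rate == rqa_metrics(b).recurrence_rate


class TestToImage:
    def test_identity_resize(self):
        mat = np.eye(128, dtype=np.uint8)
        plot = RecurrencePlot(mat, 128, 0.0, "exact")
        assert (to_image(plot, 128, "nearest").pixels == mat).all()

    def test_constant_image_invariant(self):
        plot = RecurrencePlot(np.ones((256, 256), dtype=np.uint8), 256, 0.0, "exact")
        assert (to_image(plot, 128, "area").pixels == 1.0).all()

    def test_checkerboard_area_mean(self):
        board = np.indices((4, 4)).sum(axis=0) % 2
        plot = RecurrencePlot(board.astype(np.uint8), 4, 0.0, "exact")
        assert to_image(plot, 2, "area").pixels.tolist() == [[0.5, 0.5], [0.5, 0.5]]

    def test_all_zero_maps_to_all_zero(self):
        plot = RecurrencePlot(np.zeros((64, 64), dtype=np.uint8), 64, 0.0, "exact")
        assert (to_image(plot).pixels == 0.0).all()

    def test_range_always_unit_interval(self):
        rng = np.random.default_rng(0)
        mat = (rng.random((200, 200)) < 0.3).astype(np.uint8)
        for interp in ("area", "bilinear", "nearest"):
            px = to_image(RecurrencePlot(mat, 200, 0.0, "exact"), 128, interp).pixels
            assert px.min() >= 0.0 and px.max() <= 1.0
            assert px.shape == (128, 128)

    def test_too_small_size_rejected(self):
        plot = RecurrencePlot(np.eye(4, dtype=np.uint8), 4, 0.0, "exact")
        with pytest.raises(ValueError):
            to_image(plot, 1)


def brute_force_rqa(block, l_min):
    """Oracle: enumerate off-main-diagonal runs by explicit walking."""
    n = block.shape[0]
    runs = []
    for off in range(1, n):
        for d in (np.diagonal(block, off), np.diagonal(block, -off)):
            current = 0
            for v in list(d) + [0]:
                if v:
                    current += 1
                else:
                    if current:
                        runs.append(current)
                    current = 0
    total = sum(runs)
    good = sum(r for r in runs if r >= l_min)
    det = good / total if total else 0.0
    return det, max(runs, default=0)


class TestRQAMetrics:
    def test_identity_matrix(self):
        m = rqa_metrics(recurrence_matrix(seq([1, 2, 3]), "exact"))
        assert m.recurrence_rate == pytest.approx(1 / 3)
        assert m.determinism == 0.0
        assert m.longest_diagonal == 0

    def test_fully_recurrent(self):
        m = rqa_metrics(recurrence_matrix(seq([7, 7, 7, 7]), "exact"))
        assert m.recurrence_rate == 1.0
        # off-diagonal points on lines >= 2: 10 of 12 (the two corner points
        # lie on length-1 diagonals), matching the brute-force enumeration
        assert m.determinism == pytest.approx(10 / 12)
        assert m.longest_diagonal == 3

    def test_see_matrix(self):
        m = rqa_metrics(recurrence_matrix(encode_text("see"), "exact"))
        assert m.recurrence_rate == pytest.approx(5 / 9)
        assert m.determinism == 0.0

    def test_l_min_validation(self):
        with pytest.raises(ValueError):
            rqa_metrics(recurrence_matrix(seq([1, 2]), "exact"), l_min=1)

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_bruteforce_oracle(self, trial):
        rng = np.random.default_rng(200 + trial)
        codes = rng.integers(1, 6, size=int(rng.integers(4, 30)))
        plot = recurrence_matrix(seq(codes), "exact")
        m = rqa_metrics(plot, l_min=2)
        det, longest = brute_force_rqa(plot.matrix.astype(bool), 2)
        assert m.determinism == pytest.approx(det)
        assert m.longest_diagonal == longest
        assert m.longest_diagonal <= plot.effective_length - 1


def test_imager_recovers_effective_length_from_padding():
    codes = np.zeros((1, 64), dtype=np.int64)
    codes[0, :10] = np.arange(1, 11)
    images = RecurrenceImager(size=32).transform(codes)
    assert images.shape == (1, 32, 32)
    # pad region (beyond 10/64 of the matrix) stays dark
    assert images[0, 16:, 16:].max() == 0.0
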