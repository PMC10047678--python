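import numpy as np
import pytest

from nlhrv.embedding import EmbeddedSeries, embed
from nlhrv.rqa import (
    LineHistograms,
    RecurrenceMatrix,
    determinism,
    fan_recurrence,
    laminarity,
    line_histograms,
    rqa_measures,
)
from nlhrv.synthetic import GeneratorConfig, generate


def brute_force_fan(X, density):
    """Independent k-NN oracle: per column, k smallest (distance, index) pairs."""
    n = X.shape[0]
    k = int(round(density * n))
    R = np.zeros((n, n), dtype=bool)
    for i in range(n):
        d = np.linalg.norm(X - X[i], axis=1)
        order = sorted(range(n), key=lambda j: (d[j], j))
        R[order[:k], i] = True
    return R


def enumerate_lines(R, theiler, which):
    """Exhaustive run enumeration oracle over diagonals or columns."""
    n = R.shape[0]
    lengths = []
    if which == "diag":
        for off in range(-(n - 1), n):
            if abs(off) < theiler:
                continue
            line = np.diagonal(R, offset=off)
            lengths.extend(_runs(line))
    else:
        for j in range(n):
            lengths.extend(_runs(R[:, j]))
    return lengths


def _runs(line):
    out, run = [], 0
    for v in line:
        if v:
            run += 1
        elif run:
            out.append(run)
            run = 0
    if run:
        out.append(run)
    return out


def hist_from_lengths(lengths):
    return np.bincount(lengths, minlength=2) if lengths else np.zeros(2, dtype=int)


class TestFanRecurrence:
    def test_column_sums_equal_k(self, rng):
        emb = EmbeddedSeries(rng.standard_normal((100, 3)), m=3, tau=1)
        mat = fan_recurrence(emb, density=0.07)
        assert mat.k == 7
        np.testing.assert_array_equal(mat.R.sum(axis=0), np.full(100, 7))

    def test_loi_always_recurrent(self, rng):
        emb = EmbeddedSeries(rng.standard_normal((60, 2)), m=2, tau=1)
        mat = fan_recurrence(emb)
        assert np.all(np.diagonal(mat.R))

    def test_constant_series_tie_break(self):
        emb = EmbeddedSeries(np.zeros((30, 2)), m=2, tau=1)
        mat = fan_recurrence(emb, density=0.2)
        # all distances tie at 0: smaller-index break selects the first k rows
        expected = np.zeros((30, 30), dtype=bool)
        expected[: mat.k, :] = True
        np.testing.assert_array_equal(mat.R, expected)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(20, 61))
            X = rng.standard_normal((n, int(rng.integers(1, 5))))
            emb = EmbeddedSeries(X, m=X.shape[1], tau=1)
            mat = fan_recurrence(emb, density=0.1)
            np.testing.assert_array_equal(mat.R, brute_force_fan(X, 0.1))

    def test_too_short_for_density(self, rng):
        emb = EmbeddedSeries(rng.standard_normal((10, 2)), m=2, tau=1)
        with pytest.raises(ValueError, match="too short"):
            fan_recurrence(emb, density=0.07)


class TestLineHistograms:
    def test_all_ones_5x5(self):
        mat = RecurrenceMatrix(np.ones((5, 5), dtype=bool), 1.0, 5, theiler_window=1)
        hist = line_histograms(mat)
        # eight off-LOI diagonals: lengths 1..4, each twice
        np.testing.assert_array_equal(hist.diag[1:5], [2, 2, 2, 2])
        assert hist.diag.sum() == 8
        # five full columns
        assert hist.vert[5] == 5 and hist.vert.sum() == 5

    def test_identity_matrix(self):
        mat = RecurrenceMatrix(np.eye(5, dtype=bool), 0.2, 1, theiler_window=1)
        hist = line_histograms(mat)
        assert hist.diag.sum() == 0
        assert hist.vert[1] == 5

    def test_handcrafted_6x6(self):
        R = np.zeros((6, 6), dtype=bool)
        for i in range(3):          # one diagonal run of 3 (offset +2)
            R[i, i + 2] = True
        R[5, 0] = True              # two isolated points
        R[0, 5] = True
        mat = RecurrenceMatrix(R, 0.1, 1, theiler_window=1)
        hist = line_histograms(mat)
        assert hist.diag[3] == 1 and hist.diag[1] == 2

    def test_matches_enumeration_oracle_random(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 31))
            R = rng.random((n, n)) < 0.3
            mat = RecurrenceMatrix(R, 0.3, 1, theiler_window=1)
            hist = line_histograms(mat)
            d_oracle = hist_from_lengths(enumerate_lines(R, 1, "diag"))
            v_oracle = hist_from_lengths(enumerate_lines(R, 1, "vert"))
            np.testing.assert_array_equal(
                hist.diag, d_oracle[: hist.diag.size] if d_oracle.size >= hist.diag.size
                else np.pad(d_oracle, (0, hist.diag.size - d_oracle.size))
            )
            np.testing.assert_array_equal(
                hist.vert, v_oracle[: hist.vert.size] if v_oracle.size >= hist.vert.size
                else np.pad(v_oracle, (0, hist.vert.size - v_oracle.size))
            )


class TestDetLam:
    def test_det_direct_evaluation(self):
        hist = LineHistograms(diag=np.array([0, 2, 0, 1]), vert=np.zeros(2, dtype=int))
        assert determinism(hist) == pytest.approx(3 / 5)

    def test_det_bounds(self):
        all_lines = LineHistograms(diag=np.array([0, 0, 3]), vert=np.zeros(2, dtype=int))
        assert determinism(all_lines) == 1.0
        isolated = LineHistograms(diag=np.array([0, 9]), vert=np.zeros(2, dtype=int))
        assert determinism(isolated) == 0.0

    def test_lam_direct_evaluation(self):
        hist = LineHistograms(diag=np.zeros(2, dtype=int), vert=np.array([0, 4, 3]))
        assert laminarity(hist) == pytest.approx(6 / 10)

    def test_checkerboard_has_zero_lam(self):
        R = np.indices((8, 8)).sum(axis=0) % 2 == 0
        mat = RecurrenceMatrix(R, 0.5, 4, theiler_window=1)
        assert laminarity(line_histograms(mat)) == 0.0

    def test_all_ones_lam_is_1(self):
        mat = RecurrenceMatrix(np.ones((6, 6), dtype=bool), 1.0, 6, theiler_window=1)
        assert laminarity(line_histograms(mat)) == 1.0

    def test_monotone_in_min_length(self, rng):
        R = rng.random((40, 40)) < 0.2
        hist = line_histograms(RecurrenceMatrix(R, 0.2, 8, theiler_window=1))
        dets = [determinism(hist, l_min=l) for l in (1, 2, 3, 4)]
        assert all(a >= b for a, b in zip(dets, dets[1:]))
        assert dets[0] == 1.0


class TestOnDynamics:
    def test_sine_is_deterministic(self):
        t = np.arange(400)
        x = 800 + 50 * np.sin(2 * np.pi * t / 40)
        det, _ = rqa_measures(embed(x, m=2, tau=10))
        assert det >= 0.99

    def test_noise_ar_sine_ordering(self, rng):
        noise = 800 + 30 * rng.standard_normal(360)
        ar = generate(GeneratorConfig(kind="ar_null", seed=3, n_beats=360)).intervals
        t = np.arange(360)
        sine = 800 + 50 * np.sin(2 * np.pi * t / 40)
        dets = [rqa_measures(embed(x, m=3, tau=2))[0] for x in (noise, ar, sine)]
        assert dets[0] < dets[1] < dets[2]
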