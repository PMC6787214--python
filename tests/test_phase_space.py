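import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecgpsr import (box_count_series, detect_beats, embed, extract_features,
                    generate_record, make_interval_windows, preprocess,
                    rasterize)
from ecgpsr.features import FeatureSegment


def brute_force_raster(pairs, n):
    """Independent oracle: test every pixel for segment intersection.

    Cells are half-open [i/n,(i+1)/n) x [j/n,(j+1)/n), closed at 1.0,
    tested with a from-scratch Liang-Barsky clip.
    """
    grid = np.zeros((n, n), bool)

    def hits(seg, cell):
        (x0, y0), (x1, y1) = seg
        i, j = cell
        X0, Y0, X1, Y1 = i / n, j / n, (i + 1) / n, (j + 1) / n
        dx, dy = x1 - x0, y1 - y0
        t0, t1 = 0.0, 1.0
        for p, q in ((-dx, x0 - X0), (dx, X1 - x0),
                     (-dy, y0 - Y0), (dy, Y1 - y0)):
            if p == 0:
                if q < 0:
                    return False
            else:
                r = q / p
                if p < 0:
                    if r > t1:
                        return False
                    t0 = max(t0, r)
                else:
                    if r < t0:
                        return False
                    t1 = min(t1, r)
        if t0 > t1:
            return False
        tm = 0.5 * (t0 + t1)
        mx, my = x0 + tm * dx, y0 + tm * dy
        if i < n - 1 and mx >= X1:
            return False
        if j < n - 1 and my >= Y1:
            return False
        return True

    for k in range(len(pairs) - 1):
        for i in range(n):
            for j in range(n):
                if not grid[i, j] and hits((pairs[k], pairs[k + 1]), (i, j)):
                    grid[i, j] = True
    for x, y in pairs:
        grid[min(int(x * n), n - 1), min(int(y * n), n - 1)] = True
    return grid


def segment(samples, kind="QT", beat_index=0, fs=1000.0):
    samples = np.asarray(samples, dtype=float)
    return FeatureSegment(kind=kind, samples=samples, beat_index=beat_index,
                         start=0, end=len(samples), fs=fs)


def make_segments(n, length=120, fs=1000.0, seed=0):
    rng = np.random.default_rng(seed)
    return [segment(rng.random(length), beat_index=i, fs=fs)
            for i in range(n)]


class TestMakeIntervalWindows:
    def test_109_intervals_give_90_windows(self):
        # the w1 + k - 1 identity: 90 windows of 20 span 109 intervals
        wins = make_interval_windows(make_segments(109), w1=20, step=1)
        assert len(wins) == 90

    def test_exactly_one_window_at_boundary(self):
        assert len(make_interval_windows(make_segments(20), w1=20)) == 1

    def test_insufficient_segments_give_none(self):
        assert make_interval_windows(make_segments(19), w1=20) == []

    def test_window_series_is_concatenation(self):
        segs = make_segments(25, length=30)
        wins = make_interval_windows(segs, w1=20)
        expected = np.concatenate([s.samples for s in segs[2:22]])
        assert np.array_equal(wins[2].series, expected)


class TestEmbed:
    def test_pair_count(self):
        pairs = embed(np.linspace(0, 1, 120), delay_ms=20, fs=1000.0)
        assert pairs.shape == (100, 2)

    def test_pair_convention(self):
        x = np.arange(10) / 10.0
        pairs = embed(x, delay_ms=3, fs=1000.0)
        assert np.allclose(pairs[0], [x[3], x[0]])

    def test_constant_series_collapses_to_diagonal_point(self):
        pairs = embed(np.full(50, 0.3), delay_ms=5, fs=1000.0)
        assert np.allclose(pairs, 0.3)

    def test_sine_with_quarter_period_delay_is_a_circle(self):
        fs = 1000.0
        t = np.arange(2000) / fs
        x = 0.5 + 0.4 * np.sin(2 * np.pi * 10 * t)   # period 100 ms
        pairs = embed(x, delay_ms=25, fs=fs)          # quarter period
        r2 = (pairs[:, 0] - 0.5) ** 2 + (pairs[:, 1] - 0.5) ** 2
        assert np.max(np.abs(r2 - 0.4 ** 2)) < 1e-3

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter than delay"):
            embed(np.zeros(10), delay_ms=20, fs=1000.0)


class TestRasterize:
    def test_empty_pairs(self):
        assert rasterize(np.zeros((0, 2)), grid_n=10).n_black == 0

    def test_single_repeated_point(self):
        p = rasterize(np.array([[0.5, 0.5]] * 3), grid_n=10)
        assert p.n_black == 1

    def test_unit_diagonal_marks_exactly_the_diagonal(self):
        p = rasterize(np.array([[0.0, 0.0], [1.0, 1.0]]), grid_n=10)
        assert p.n_black == 10
        assert np.array_equal(np.argwhere(p.grid),
                              np.stack([np.arange(10)] * 2, axis=1))

    def test_conservation_black_plus_white(self):
        rng = np.random.default_rng(0)
        p = rasterize(rng.random((40, 2)), grid_n=25)
        assert p.n_black + p.n_white == 25 * 25

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            rasterize(np.array([[0.0, 1.5]]), grid_n=10)

    def test_line_mode_dominates_point_mode(self):
        rng = np.random.default_rng(1)
        pts = rng.random((50, 2))
        line = rasterize(pts, grid_n=16).grid
        point = rasterize(pts, grid_n=16, mode="point").grid
        assert np.all(line[point])  # every point-cell is also a line-cell

    @settings(max_examples=40, deadline=None)
    @given(st.integers(2, 16), st.integers(2, 20), st.integers(0, 10 ** 6))
    def test_matches_brute_force_oracle(self, n, npts, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((npts, 2))
        got = rasterize(pts, grid_n=n).grid
        assert np.array_equal(got, brute_force_raster(pts, n))


class TestBoxCountSeries:
    def test_count_conservation(self):
        wins = make_interval_windows(make_segments(40), w1=20)
        counts = box_count_series(wins, delay_ms=20, grid_n=50)
        assert counts.k == len(wins)

    def test_identical_windows_identical_counts(self):
        seg = make_segments(20, seed=5)
        win = make_interval_windows(seg, w1=20)[0]
        counts = box_count_series([win] * 5, delay_ms=20, grid_n=50)
        assert len(set(counts.counts.tolist())) == 1

    def test_all_windows_too_short_rejected(self):
        short = [segment(np.full(2, 0.5), beat_index=i) for i in range(20)]
        wins = make_interval_windows(short, w1=20)
        with pytest.raises(ValueError):
            box_count_series(wins, delay_ms=200, grid_n=20)

    def test_unhealthy_windows_count_higher(self, config):
        # the box-count rise that signals the healthy-to-unhealthy switch
        for seed in (1, 2, 3):
            rec = generate_record(30, 30, seed=seed)
            ecg = preprocess(rec.signal)
            arrays = extract_features(ecg, detect_beats(ecg))
            segs = arrays["QT"]
            wins = make_interval_windows(segs, w1=20)
            counts = box_count_series(wins, delay_ms=20).counts
            # windows fully inside each block (labels align with beat index)
            healthy = counts[:5].mean()
            unhealthy = counts[-5:].mean()
            assert unhealthy > healthy


class TestDelaySensitivity:
    def test_short_delay_concentrates_near_diagonal(self, preprocessed):
        # 5 ms delay hugs the diagonal; 20 ms spreads the portrait
        arrays = extract_features(preprocessed, detect_beats(preprocessed))
        win = make_interval_windows(arrays["QT"], w1=10)[0]

        def diag_fraction(delay_ms):
            p = rasterize(embed(win, delay_ms=delay_ms), grid_n=100)
            cells = np.argwhere(p.grid)
            near = np.abs(cells[:, 0] - cells[:, 1]) <= 1
            return near.mean()

        assert diag_fraction(5.0) > diag_fraction(20.0)
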