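"""Filtration construction, nestedness, and multi-parameter containment."""

import itertools

import numpy as np
import pytest

from topomorph.filtrations import (
    MultiFiltrationSpec,
    OneParamFiltration,
    alternating_apply,
    closing_filtration,
    dilation_filtration,
    erosion_filtration,
    grayscale_multifiltration_level,
    is_alternating,
    nondecreasing_path,
    opening_filtration,
    sublevel_filtration,
    tophat_filtrations,
)
from topomorph.morphology import closing, opening, square_se_sequence, threshold


def black(level):
    return level == 0


def alternating_indices(n, k):
    return [
        u
        for u in itertools.product(range(-n, n + 1), repeat=k)
        if is_alternating(u)
    ]


class TestOneParamFiltrations:
    def test_nestedness_violation_raises(self):
        a = np.array([[0, 1], [1, 1]], np.uint8)
        b = np.array([[1, 0], [1, 1]], np.uint8)
        with pytest.raises(ValueError, match="nestedness"):
            OneParamFiltration([a, b])

    def test_non_binary_input_rejected(self):
        seq = square_se_sequence(2)
        with pytest.raises(ValueError):
            erosion_filtration(np.array([[0, 2]]), seq)

    @pytest.mark.parametrize(
        "build",
        [erosion_filtration, dilation_filtration, opening_filtration, closing_filtration],
    )
    def test_levels_nested_on_random_images(self, random_binary, build):
        f = random_binary(10, 10)
        filt = build(f, square_se_sequence(4))
        for i in range(filt.n):
            assert set(map(tuple, np.argwhere(black(filt[i])))) <= set(
                map(tuple, np.argwhere(black(filt[i + 1])))
            )

    def test_level_zero_equals_input_black_set(self, random_binary):
        f = random_binary()
        seq = square_se_sequence(3)
        assert np.array_equal(black(opening_filtration(f, seq)[0]), black(f))
        assert np.array_equal(black(closing_filtration(f, seq)[-1]), black(f))
        assert np.array_equal(black(erosion_filtration(f, seq)[0]), black(f))
        assert np.array_equal(black(dilation_filtration(f, seq)[-1]), black(f))

    def test_all_black_input_erosion_levels_all_black(self):
        f = np.zeros((5, 5), np.uint8)
        filt = erosion_filtration(f, square_se_sequence(3))
        for level in filt.levels:
            assert np.all(level == 0)

    def test_all_white_input_opening_closing_levels_empty(self):
        f = np.ones((6, 6), np.uint8)
        for build in (opening_filtration, closing_filtration):
            filt = build(f, square_se_sequence(3))
            for level in filt.levels:
                assert not black(level).any()

    def test_erosion_grows_black_around_single_white_pixel(self):
        f = np.zeros((7, 7), np.uint8)
        f[3, 3] = 1
        filt = erosion_filtration(f, square_se_sequence(3))
        assert black(filt[0]).sum() == 48
        assert black(filt[1]).sum() == 49  # the white pixel is eroded away

    def test_single_level_sequence(self, random_binary):
        f = random_binary()
        filt = erosion_filtration(f, square_se_sequence(0))
        assert filt.n == 0
        assert np.array_equal(black(filt[0]), black(f))

    def test_closing_relabels_match_reversed_se_order(self, random_binary):
        f = random_binary(10, 10)
        seq = square_se_sequence(4)
        filt = closing_filtration(f, seq, relabel=True)
        assert filt.index_labels == tuple(range(5))
        for i in range(5):
            assert np.array_equal(black(filt[i]), closing(f, seq[4 - i]) == 0)
        neg = closing_filtration(f, seq)
        assert neg.index_labels == tuple(range(-4, 1))
        for a, b in zip(neg.levels, filt.levels):
            assert np.array_equal(a, b)


class TestTopHatFiltrations:
    def test_last_level_is_full_domain(self, random_binary):
        f = random_binary()
        for filt in tophat_filtrations(f, square_se_sequence(3)):
            assert black(filt[filt.n]).all()  # B_0 transform is the zero image

    def test_containment_chain(self, random_binary):
        f = random_binary(8, 8)
        for filt in tophat_filtrations(f, square_se_sequence(4)):
            for i in range(filt.n):
                assert np.all(filt[i + 1] <= filt[i])

    def test_sth_zero_set_is_intersection(self, random_binary):
        f = random_binary(8, 8)
        wth, bth, sth = tophat_filtrations(f, square_se_sequence(3))
        for w, b, s in zip(wth.levels, bth.levels, sth.levels):
            assert np.array_equal(black(s), black(w) & black(b))


class TestSublevelFiltration:
    def test_extreme_thresholds(self, random_gray):
        g = random_gray()
        filt = sublevel_filtration(g, [int(g.min()) - 1, int(g.max())])
        assert not black(filt[0]).any()
        assert black(filt[1]).all()

    def test_levels_match_enumeration(self, random_gray):
        g = random_gray(10, 10)
        ts = [10, 60, 200]
        filt = sublevel_filtration(g, ts)
        for i, t in enumerate(ts):
            assert np.array_equal(black(filt[i]), g <= t)

    def test_unsorted_thresholds_rejected(self, random_gray):
        with pytest.raises(ValueError):
            sublevel_filtration(random_gray(), [5, 3])


class TestAlternatingApply:
    def test_empty_and_zero_are_identity(self, random_binary):
        f = random_binary()
        spec = MultiFiltrationSpec.opening_closing(square_se_sequence(2))
        assert np.array_equal(alternating_apply(f, (), spec), f)
        assert np.array_equal(alternating_apply(f, (0,), spec), f)

    def test_composition_order_rightmost_first(self, random_binary):
        f = random_binary(10, 10)
        seq = square_se_sequence(2)
        spec = MultiFiltrationSpec.opening_closing(seq)
        got = alternating_apply(f, (-1, 1), spec)
        assert np.array_equal(got, closing(opening(f, seq[1]), seq[1]))

    def test_non_alternating_rejected_unless_permissive(self, random_binary):
        f = random_binary()
        spec = MultiFiltrationSpec.opening_closing(square_se_sequence(2))
        with pytest.raises(ValueError, match="alternating"):
            alternating_apply(f, (1, 2), spec)
        alternating_apply(f, (1, 2), spec, permissive=True)

    def test_out_of_range_index_rejected(self, random_binary):
        spec = MultiFiltrationSpec.opening_closing(square_se_sequence(2))
        with pytest.raises(ValueError, match="outside"):
            alternating_apply(random_binary(), (3,), spec)

    def test_memo_reuses_suffix(self, random_binary):
        f = random_binary()
        spec = MultiFiltrationSpec.opening_closing(square_se_sequence(2))
        memo = {}
        a = alternating_apply(f, (-2, 1), spec, memo=memo)
        assert (1,) in memo and (-2, 1) in memo
        assert np.array_equal(memo[(-2, 1)], a)

    @pytest.mark.parametrize(
        "make_spec",
        [MultiFiltrationSpec.opening_closing, MultiFiltrationSpec.erosion_dilation],
    )
    def test_unified_operator_monotone_in_index(self, random_binary, make_spec):
        # i <= j implies M_j(g) <= M_i(g)
        f = random_binary(10, 10)
        spec = make_spec(square_se_sequence(2))
        images = {i: spec.unified(i, f) for i in range(-2, 3)}
        for i in range(-2, 3):
            for j in range(i, 3):
                assert np.all(images[j] <= images[i])

    def test_theorem_containment_small_grid(self, random_binary):
        # X_u subset of X_v for componentwise u <= v, alternating, k = n = 2
        spec = MultiFiltrationSpec.opening_closing(square_se_sequence(2))
        idx = alternating_indices(2, 2)
        for _ in range(5):
            f = random_binary(10, 10)
            memo = {}
            blacks = {
                u: black(alternating_apply(f, u, spec, memo=memo)) for u in idx
            }
            for u in idx:
                for v in idx:
                    if all(a <= b for a, b in zip(u, v)):
                        assert not (blacks[u] & ~blacks[v]).any(), (u, v)


class TestGrayscaleMultifiltration:
    def test_empty_index_gives_sublevel_set(self, random_gray):
        g = random_gray()
        spec = MultiFiltrationSpec.opening_closing(square_se_sequence(2))
        got = grayscale_multifiltration_level(g, 100, (), spec)
        assert np.array_equal(got, g <= 100)

    def test_threshold_and_morphology_commute(self, random_gray):
        g = random_gray(10, 10)
        seq = square_se_sequence(2)
        spec = MultiFiltrationSpec.opening_closing(seq)
        for t in (40, 128, 210):
            for u in ((1,), (-2,), (-1, 2), (2, -1, 1)):
                via_gray = grayscale_multifiltration_level(g, t, u, spec)
                via_binary = black(alternating_apply(threshold(g, t), u, spec))
                assert np.array_equal(via_gray, via_binary), (t, u)

    def test_joint_monotonicity_in_threshold_and_index(self, random_gray):
        g = random_gray(10, 10)
        spec = MultiFiltrationSpec.opening_closing(square_se_sequence(2))
        idx = alternating_indices(2, 2)
        ts = (50, 120, 200)
        cells = {
            (t, u): grayscale_multifiltration_level(g, t, u, spec)
            for t in ts
            for u in idx
        }
        for (t, u), xu in cells.items():
            for (s, v), xv in cells.items():
                if t <= s and all(a <= b for a, b in zip(u, v)):
                    assert not (xu & ~xv).any(), ((t, u), (s, v))


class TestNondecreasingPath:
    def test_constant_path_constant_filtration(self, random_binary):
        f = random_binary()
        spec = MultiFiltrationSpec.opening_closing(square_se_sequence(2))
        filt = nondecreasing_path(f, [(0, 0), (0, 0), (0, 0)], spec)
        for level in filt.levels:
            assert np.array_equal(level, filt[0])

    def test_axis_path_reproduces_opening_filtration(self, random_binary):
        f = random_binary(10, 10)
        seq = square_se_sequence(3)
        spec = MultiFiltrationSpec.opening_closing(seq)
        path = [(i,) for i in range(4)]
        filt = nondecreasing_path(f, path, spec)
        plain = opening_filtration(f, seq)
        for a, b in zip(filt.levels, plain.levels):
            assert np.array_equal(black(a), black(b))

    def test_random_monotone_path_in_three_parameter_grid(self, random_binary, rng):
        f = random_binary(12, 12)
        spec = MultiFiltrationSpec.opening_closing(square_se_sequence(2))
        path = [(-2, 1, -1)]
        for _ in range(4):
            u = list(path[-1])
            axis = rng.integers(0, 3)
            u[axis] = min(u[axis] + 1, 2)
            path.append(tuple(u))
        filt = nondecreasing_path(f, path, spec, permissive=True)
        assert filt.n == len(path) - 1  # construction validates nestedness

    def test_non_monotone_path_rejected(self, random_binary):
        spec = MultiFiltrationSpec.opening_closing(square_se_sequence(2))
        with pytest.raises(ValueError, match="nondecreasing"):
            nondecreasing_path(random_binary(), [(1,), (0,)], spec)
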