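"""Loss oracles: hand-derived values, exhaustive enumeration against
independent brute-force formulas, and the Hausdorff all-pairs oracle."""

import math

import numpy as np
import pytest

from promptseg.losses import (bce_loss, boundary_points, dice_loss,
                              dicebce_loss, focal_loss, hausdorff_distance,
                              hausdorff_surrogate, jaccard_loss, make_loss,
                              tversky_loss, combined_loss)


def all_binary_masks_3x3():
    """All 512 binary 3x3 masks as flattened float rows."""
    bits = (np.arange(512)[:, None] >> np.arange(9)) & 1
    return bits.astype(float)


# -- independent brute-force oracles (plain sums, separate code path) --------

def oracle_dice(p, m):
    num = sum(pi * mi for pi, mi in zip(p, m))
    den = sum(pi * pi for pi in p) + sum(mi * mi for mi in m)
    return 1.0 if den == 0 else 1.0 - 2.0 * num / den


def oracle_jaccard(p, m):
    inter = sum(pi * mi for pi, mi in zip(p, m))
    union = sum(p) + sum(m) - inter
    return 0.0 if union == 0 else 1.0 - inter / union


def oracle_tversky(p, m, a, b):
    tp = sum(pi * mi for pi, mi in zip(p, m))
    fp = sum(pi * (1 - mi) for pi, mi in zip(p, m))
    fn = sum((1 - pi) * mi for pi, mi in zip(p, m))
    den = tp + a * fp + b * fn
    return 0.0 if den == 0 else 1.0 - tp / den


def oracle_focal(p, m, g, eps=1e-7):
    total = 0.0
    for pi, mi in zip(p, m):
        pi = min(max(pi, eps), 1 - eps)
        total += (1 - pi) ** g * math.log(pi) * mi \
            + pi ** g * math.log(1 - pi) * (1 - mi)
    return -total / len(p)


def oracle_bce(p, m, eps=1e-7):
    total = 0.0
    for pi, mi in zip(p, m):
        pi = min(max(pi, eps), 1 - eps)
        total += math.log(pi) * mi + math.log(1 - pi) * (1 - mi)
    return -total / len(p)


def oracle_hausdorff(a, b):
    """Naive all-pairs max-min over 4-connected boundary points."""
    def boundary(mask):
        pts = []
        h, w = mask.shape
        for i in range(h):
            for j in range(w):
                if not mask[i, j]:
                    continue
                if (i == 0 or i == h - 1 or j == 0 or j == w - 1
                        or not mask[i - 1, j] or not mask[i + 1, j]
                        or not mask[i, j - 1] or not mask[i, j + 1]):
                    pts.append((i, j))
        return pts

    pa, pb = boundary(a), boundary(b)
    if not pa and not pb:
        return 0.0
    if not pa or not pb:
        return math.hypot(*a.shape)
    d1 = max(min(math.dist(p, q) for q in pb) for p in pa)
    d2 = max(min(math.dist(q, p) for p in pa) for q in pb)
    return max(d1, d2)


# -- hand-derived single values ----------------------------------------------

class TestHandDerivedValues:
    def test_dice_partial_overlap(self):
        m = np.array([1.0, 1, 0, 0])
        p = np.array([1.0, 0, 0, 0])
        assert dice_loss(p, m, smooth_eps=0) == pytest.approx(1 - 2 / 3)

    def test_dice_perfect_and_disjoint(self):
        m = np.array([1.0, 0, 1, 0])
        assert dice_loss(m, m, smooth_eps=0) == pytest.approx(0.0)
        assert dice_loss(1 - m, m, smooth_eps=0) == pytest.approx(1.0)

    def test_focal_single_pixel_half_confidence(self):
        val = focal_loss(np.array([0.5]), np.array([1.0]), gamma=2.0)
        assert val == pytest.approx(0.25 * math.log(2), rel=1e-6)

    def test_focal_gamma_zero_is_bce(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, 32)
        m = rng.integers(0, 2, 32).astype(float)
        assert focal_loss(p, m, gamma=0.0) == pytest.approx(bce_loss(p, m))

    def test_jaccard_partial_overlap(self):
        m = np.array([1.0, 1, 0, 0])
        p = np.array([1.0, 0, 0, 0])
        assert jaccard_loss(p, m, smooth_eps=0) == pytest.approx(0.5)

    def test_tversky_total_mismatch(self):
        val = tversky_loss(np.array([0.0, 1]), np.array([1.0, 0]),
                           alpha=0.7, beta=0.3, smooth_eps=0)
        assert val == pytest.approx(1.0)

    def test_tversky_half_half_reduces_to_soft_dice(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 64)
        m = rng.integers(0, 2, 64).astype(float)
        tv = tversky_loss(p, m, alpha=0.5, beta=0.5, smooth_eps=0)
        non_squared = 1 - 2 * (p * m).sum() / (p.sum() + m.sum())
        assert tv == pytest.approx(non_squared, abs=1e-12)

    def test_dicebce_hand_value(self):
        val = dicebce_loss(np.array([0.5]), np.array([1.0]), smooth_eps=0)
        assert val == pytest.approx(0.2 + math.log(2), rel=1e-6)

    def test_dicebce_dominates_dice(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.01, 0.99, 50)
        m = rng.integers(0, 2, 50).astype(float)
        assert dicebce_loss(p, m) >= dice_loss(p, m)


# -- exhaustive 3x3 enumeration ----------------------------------------------

class TestExhaustiveEnumeration:
    """All 512 x 512 binary 3x3 mask pairs, eps=0, against the oracles.

    The single empty-vs-empty pair is excluded from the eps=0 ratio
    losses: their denominators are genuinely 0 there (0/0), which is why
    the smoothing eps exists in the first place.
    """

    @pytest.fixture(scope="class")
    def masks(self):
        return all_binary_masks_3x3()

    @pytest.fixture(scope="class")
    def impl(self, masks):
        gt = np.broadcast_to(masks[:, None, :], (512, 512, 9))
        pred = np.broadcast_to(masks[None, :, :], (512, 512, 9))
        with np.errstate(invalid="ignore"):   # the one 0/0 pair -> NaN
            return {
                "dice": dice_loss(pred, gt, smooth_eps=0),
                "jaccard": jaccard_loss(pred, gt, smooth_eps=0),
                "tversky": tversky_loss(pred, gt, 0.7, 0.3, smooth_eps=0),
            }

    def test_matches_python_loop_oracle_on_seeded_pairs(self, masks, impl):
        # pure-python loop oracle on 400 seeded pairs (the full 512^2 grid
        # is covered by the vectorized oracle below)
        rng = np.random.default_rng(7)
        idx = rng.integers(1, 512, size=(400, 2))
        for i, j in idx:
            p, m = masks[j], masks[i]
            assert impl["dice"][i, j] == pytest.approx(oracle_dice(p, m), abs=1e-9)
            assert impl["jaccard"][i, j] == pytest.approx(oracle_jaccard(p, m), abs=1e-9)
            assert impl["tversky"][i, j] == pytest.approx(
                oracle_tversky(p, m, 0.7, 0.3), abs=1e-9)

    def test_matches_vectorized_oracle_on_full_grid(self, masks, impl):
        inter = masks @ masks.T                  # inter[i, j] = |m_i & m_j|
        sums = masks.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            dice_or = 1 - 2 * inter / (sums[:, None] + sums[None, :])
            union = sums[:, None] + sums[None, :] - inter
            jac_or = 1 - inter / union
            fp = sums[None, :] - inter           # pred minus intersection
            fn = sums[:, None] - inter
            tv_or = 1 - inter / (inter + 0.7 * fp + 0.3 * fn)
        ok = np.ones((512, 512), dtype=bool)
        ok[0, 0] = False                         # empty-vs-empty: 0/0
        assert np.allclose(impl["dice"][ok], dice_or[ok], atol=1e-9)
        assert np.allclose(impl["jaccard"][ok], jac_or[ok], atol=1e-9)
        assert np.allclose(impl["tversky"][ok], tv_or[ok], atol=1e-9)

    def test_jaccard_at_least_dice_on_binary(self, impl):
        ok = np.ones((512, 512), dtype=bool)
        ok[0, 0] = False
        assert np.all(impl["jaccard"][ok] >= impl["dice"][ok] - 1e-9)

    def test_all_losses_zero_at_perfect_binary_match(self, masks):
        nonempty = masks[1:]
        for loss in (dice_loss, jaccard_loss):
            assert np.allclose(loss(nonempty, nonempty, smooth_eps=0), 0.0,
                               atol=1e-12)
        assert np.allclose(
            tversky_loss(nonempty, nonempty, 0.7, 0.3, smooth_eps=0), 0.0,
            atol=1e-12)
        # with the default eps, the empty-empty pair is stable (no NaN)
        empty = np.zeros((1, 9))
        assert np.isfinite(dice_loss(empty, empty))
        assert jaccard_loss(empty, empty) == pytest.approx(0.0)


# -- Hausdorff ---------------------------------------------------------------

class TestHausdorff:
    def test_identical_masks_zero(self):
        m = np.zeros((8, 8), dtype=int)
        m[2:5, 2:5] = 1
        assert hausdorff_distance(m, m) == 0.0

    def test_three_four_five(self):
        a = np.zeros((8, 8), dtype=int)
        b = np.zeros((8, 8), dtype=int)
        a[0, 0] = 1
        b[3, 4] = 1
        assert hausdorff_distance(a, b) == pytest.approx(5.0)

    def test_asymmetric_sets_take_max_direction(self):
        a = np.zeros((12, 12), dtype=int)
        b = np.zeros((12, 12), dtype=int)
        a[0, 0] = 1
        a[10, 0] = 1
        b[0, 0] = 1
        assert hausdorff_distance(a, b) == pytest.approx(10.0)

    def test_symmetry_and_empty_conventions(self):
        rng = np.random.default_rng(3)
        a = (rng.random((10, 10)) < 0.3).astype(int)
        b = (rng.random((10, 10)) < 0.3).astype(int)
        assert hausdorff_distance(a, b) == hausdorff_distance(b, a)
        empty = np.zeros((10, 10), dtype=int)
        assert hausdorff_distance(empty, empty) == 0.0
        assert hausdorff_distance(a, empty) == pytest.approx(math.hypot(10, 10))

    def test_matches_all_pairs_oracle_on_seeded_16x16(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            a = (rng.random((16, 16)) < rng.uniform(0.05, 0.5)).astype(int)
            b = (rng.random((16, 16)) < rng.uniform(0.05, 0.5)).astype(int)
            assert hausdorff_distance(a, b) == pytest.approx(
                oracle_hausdorff(a, b), abs=1e-9)

    def test_boundary_excludes_interior(self):
        m = np.zeros((7, 7), dtype=int)
        m[1:6, 1:6] = 1
        pts = set(map(tuple, boundary_points(m)))
        assert (3, 3) not in pts
        assert (1, 1) in pts and (5, 5) in pts


class TestHausdorffSurrogate:
    def test_zero_on_perfect_match_and_nonnegative(self):
        m = np.zeros((16, 16))
        m[4:9, 4:9] = 1
        assert hausdorff_surrogate(m, m) == pytest.approx(0.0)
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, (16, 16))
        assert hausdorff_surrogate(p, m) > 0

    def test_distant_errors_cost_more(self):
        gt = np.zeros((32, 32))
        gt[14:18, 14:18] = 1
        near = gt.copy()
        near[13, 14:18] = 1          # false positives adjacent to the target
        far = gt.copy()
        far[28, 14:18] = 1           # same count of false positives, far away
        assert hausdorff_surrogate(far, gt) > hausdorff_surrogate(near, gt)

    def test_finite_gradient_everywhere(self):
        from promptseg.nn import Tensor
        gt = np.zeros((8, 8))
        gt[2:5, 2:5] = 1
        p = Tensor(np.full((8, 8), 0.5), requires_grad=True)
        hausdorff_surrogate(p, gt).backward()
        assert np.all(np.isfinite(p.grad))


class TestLossFactory:
    def test_unknown_name_lists_valid_losses(self):
        with pytest.raises(ValueError, match="dice.*focal|valid names"):
            make_loss("foo")

    @pytest.mark.parametrize("name", ["dice", "focal", "jaccard", "tversky",
                                      "dicebce", "hausdorff"])
    def test_each_named_loss_is_zero_ish_at_perfect_match(self, name):
        m = np.zeros((16, 16))
        m[4:10, 5:11] = 1
        fn = make_loss(name)
        arg = (m, m) if name == "hausdorff" else (m.ravel(), m.ravel())
        assert float(np.asarray(fn(*arg))) < 1e-5

    def test_weighted_combination(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.01, 0.99, 25)
        m = rng.integers(0, 2, 25).astype(float)
        combo = combined_loss({"dice": 0.5, "jaccard": 2.0})
        expected = 0.5 * dice_loss(p, m) + 2.0 * jaccard_loss(p, m)
        assert combo(p, m) == pytest.approx(expected)
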