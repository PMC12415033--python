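"""IoU-family box losses: hand-computed oracles, invariances, gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kiwidet.losses import (BoxXYXY, ImageExtent, IOU_KINDS, iou,
                            iou_family_loss, mpdiou_grad, mpdiou_loss)
from kiwidet.nn.autograd import Tensor

EXT = ImageExtent(100, 100)

box_strategy = st.tuples(
    st.floats(0, 80), st.floats(0, 80), st.floats(1, 40), st.floats(1, 40)
).map(lambda t: BoxXYXY(t[0], t[1], t[0] + t[2], t[1] + t[3]))


class TestIoU:
    @pytest.mark.parametrize("a,b,expected", [
        (BoxXYXY(0, 0, 10, 10), BoxXYXY(0, 0, 10, 10), 1.0),
        (BoxXYXY(0, 0, 10, 10), BoxXYXY(0, 0, 20, 20), 0.25),
        (BoxXYXY(0, 0, 10, 10), BoxXYXY(50, 50, 60, 60), 0.0),
    ])
    def test_examples(self, a, b, expected):
        assert iou(a, b) == pytest.approx(expected, abs=1e-6)

    def test_zero_area_union_defined_as_zero(self):
        z = BoxXYXY(5, 5, 5, 5)
        assert iou(z, z) == 0.0

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            BoxXYXY(10, 0, 0, 10)


class TestMPDIoU:
    def test_worked_toy_pair(self):
        """1 - 0.25 + 0 + (10^2+10^2)/(100^2+100^2) = 0.76."""
        v = mpdiou_loss(BoxXYXY(0, 0, 10, 10), BoxXYXY(0, 0, 20, 20), EXT)
        assert v == pytest.approx(0.76, abs=1e-6)

    def test_zero_on_coincident(self):
        b = BoxXYXY(3, 4, 30, 40)
        assert mpdiou_loss(b, b, EXT) == pytest.approx(0.0, abs=1e-7)

    def test_invalid_extent(self):
        with pytest.raises(ValueError):
            mpdiou_loss(BoxXYXY(0, 0, 1, 1), BoxXYXY(0, 0, 1, 1), (0, 100))

    @given(box_strategy, box_strategy)
    @settings(max_examples=100, deadline=None)
    def test_lower_bounded_by_one_minus_iou(self, a, b):
        assert mpdiou_loss(a, b, EXT) >= (1 - iou(a, b)) - 1e-6

    @given(box_strategy, box_strategy, st.floats(-20, 20), st.floats(-20, 20))
    @settings(max_examples=60, deadline=None)
    def test_translation_invariance(self, a, b, dx, dy):
        """Joint translation leaves the loss unchanged (distances depend
        only on coordinate differences)."""
        ta = BoxXYXY(a.x1 + dx, a.y1 + dy, a.x2 + dx, a.y2 + dy)
        tb = BoxXYXY(b.x1 + dx, b.y1 + dy, b.x2 + dx, b.y2 + dy)
        assert mpdiou_loss(ta, tb, EXT) == pytest.approx(
            mpdiou_loss(a, b, EXT), abs=1e-5)

    @given(box_strategy, box_strategy)
    @settings(max_examples=60, deadline=None)
    def test_joint_scale_invariance(self, a, b):
        sa = BoxXYXY(2 * a.x1, 2 * a.y1, 2 * a.x2, 2 * a.y2)
        sb = BoxXYXY(2 * b.x1, 2 * b.y1, 2 * b.x2, 2 * b.y2)
        big = ImageExtent(200, 200)
        assert mpdiou_loss(sa, sb, big) == pytest.approx(
            mpdiou_loss(a, b, EXT), abs=1e-5)

    def test_numeric_gradient_matches_analytic(self, rng):
        for _ in range(5):
            c, w, h = rng.uniform(30, 70, 2), *rng.uniform(8, 25, 2)
            pred = np.array([c[0] - w / 2, c[1] - h / 2,
                             c[0] + w / 2, c[1] + h / 2], np.float32)
            c2, w2, h2 = rng.uniform(30, 70, 2), *rng.uniform(8, 25, 2)
            gt = np.array([c2[0] - w2 / 2, c2[1] - h2 / 2,
                           c2[0] + w2 / 2, c2[1] + h2 / 2], np.float32)
            ana = mpdiou_grad(pred, gt, EXT)
            num = np.zeros(4)
            for i in range(4):
                e = np.zeros(4, np.float32)
                e[i] = 1e-3
                num[i] = (mpdiou_loss(pred + e, gt, EXT)
                          - mpdiou_loss(pred - e, gt, EXT)) / 2e-3
            np.testing.assert_allclose(ana, num, atol=1e-4)

    def test_toy_regression_reaches_corner_coincidence(self):
        """Gradient descent on MPDIoU drives a box onto the target."""
        target = np.array([40, 45, 70, 72], np.float32)
        box = Tensor(np.array([[10, 12, 28, 30]], np.float32), requires_grad=True)
        for t in range(800):
            loss = iou_family_loss("mpdiou", box, target, EXT).sum()
            box.grad = None
            loss.backward()
            box.data -= (50.0 * 0.995 ** t) * box.grad
        final = float(iou_family_loss("mpdiou", box, target, EXT).data[0])
        assert final < 1e-3
        np.testing.assert_allclose(box.data[0], target, atol=0.01)


class TestIoUFamily:
    @pytest.mark.parametrize("kind", IOU_KINDS)
    def test_zero_on_identical_boxes(self, kind):
        b = BoxXYXY(10, 20, 42, 50)
        v = float(iou_family_loss(kind, b, b, EXT).data[0])
        assert v == pytest.approx(0.0, abs=1e-5)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            iou_family_loss("bogus", BoxXYXY(0, 0, 1, 1), BoxXYXY(0, 0, 1, 1))

    def test_giou_disjoint_in_one_two(self):
        v = float(iou_family_loss("giou", BoxXYXY(0, 0, 10, 10),
                                  BoxXYXY(90, 90, 100, 100)).data[0])
        assert 1.0 < v <= 2.0

    def test_ciou_degeneracy_vs_mpdiou(self):
        """Same centre, same aspect ratio, different size: CIoU's aspect
        penalty vanishes while MPDIoU's corner penalty does not."""
        p, g = BoxXYXY(40, 40, 60, 60), BoxXYXY(30, 30, 70, 70)
        ciou = float(iou_family_loss("ciou", p, g, EXT).data[0])
        diou = float(iou_family_loss("diou", p, g, EXT).data[0])
        assert ciou == pytest.approx(diou, abs=1e-6)      # aspect term is zero
        mpd = float(iou_family_loss("mpdiou", p, g, EXT).data[0])
        assert mpd - (1 - iou(p, g)) > 1e-4               # corner term is not

    @pytest.mark.parametrize("kind", IOU_KINDS)
    def test_nonnegative_and_bounded_below_by_iou_term(self, kind, rng):
        for _ in range(25):
            a = np.sort(rng.uniform(0, 90, 2))
            b = np.sort(rng.uniform(0, 90, 2))
            p = BoxXYXY(a[0], b[0], a[1] + 1, b[1] + 1)
            c = np.sort(rng.uniform(0, 90, 2))
            d = np.sort(rng.uniform(0, 90, 2))
            g = BoxXYXY(c[0], d[0], c[1] + 1, d[1] + 1)
            v = float(iou_family_loss(kind, p, g, EXT).data[0])
            assert v >= -1e-6
            if kind != "giou":   # giou subtracts nothing from 1 - iou either
                assert v >= (1 - iou(p, g)) - 1e-5
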