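"""Heterogeneous-kernel convolution: cost identities and layer oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kiwidet.hetconv import (HetConvSpec, InvalidPartitionError,
                             hetconv_cost, hetconv_ratio, make_c2f_dualhet,
                             make_hetconv_layer, standard_conv_cost)
from kiwidet.nn.autograd import Tensor
from kiwidet.nn.layers import C2f, Conv2d, HetConv2d


def spec(m=8, n=8, k=3, p=1, d=10):
    return HetConvSpec(in_channels=m, out_channels=n, kernel_size=k, part=p,
                       input_side=d, output_side=d)


class TestCostModel:
    def test_standard_conv_examples(self):
        assert standard_conv_cost(spec(1, 1, 1, d=1)).flops == 1
        r = standard_conv_cost(spec(8, 8, 3, d=10))
        assert r.flops == 10 * 10 * 8 * 8 * 9 == 57600
        assert r.params == 8 * 8 * 9

    def test_hetconv_worked_example(self):
        r = hetconv_cost(spec(8, 8, 3, p=4, d=10))
        assert r.flops == 57600 // 4 + 100 * 8 * 6 == 19200
        assert r.ratio_vs_standard == pytest.approx(1 / 3)

    def test_p1_degenerates_to_standard(self):
        s = spec(8, 16, 3, p=1, d=7)
        assert hetconv_cost(s).flops == standard_conv_cost(s).flops
        assert hetconv_cost(s).params == standard_conv_cost(s).params
        assert hetconv_cost(s).ratio_vs_standard == 1.0

    def test_invalid_partition_rejected(self):
        with pytest.raises(InvalidPartitionError):
            spec(8, 8, p=3)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            HetConvSpec(in_channels=0, out_channels=8)
        with pytest.raises(ValueError):
            HetConvSpec(in_channels=8, out_channels=8, kernel_size=2)

    @given(st.integers(1, 4), st.integers(1, 16), st.integers(0, 2),
           st.integers(1, 3), st.integers(1, 12))
    @settings(max_examples=200, deadline=None)
    def test_cost_identities_over_grid(self, pexp, n, kidx, d, mmul):
        """Additivity (KxK part + 1x1 part) and the closed-form ratio
        1/P + (1 - 1/P)/K^2 hold over a randomized (M, N, P, K, D) grid."""
        p = 2 ** pexp
        k = (1, 3, 5)[kidx]
        m = p * mmul
        s = spec(m, n, k, p, d)
        r = hetconv_cost(s)
        fl_k = d * d * m * n * k * k // p
        fl_1 = d * d * n * (m - m // p)
        assert r.flops == fl_k + fl_1
        assert r.ratio_vs_standard == pytest.approx(hetconv_ratio(p, k))
        # params never exceed the standard conv's
        assert r.params <= standard_conv_cost(s).params

    def test_ratio_strictly_decreases_in_p(self):
        for k in (3, 5):
            ratios = [hetconv_ratio(p, k) for p in (1, 2, 4, 8, 16)]
            assert all(a > b for a, b in zip(ratios, ratios[1:]))

    def test_alternative_filter_costs(self, tmp_path):
        """HetConv sits between grouped and depthwise+pointwise cost;
        the comparison formulas and CSV table stay consistent."""
        from kiwidet.hetconv import (cost_table_csv, depthwise_conv_cost,
                                     group_conv_cost, pointwise_conv_cost)
        s = spec(8, 8, 3, p=4, d=10)
        dw, pw = depthwise_conv_cost(s), pointwise_conv_cost(s)
        gw = group_conv_cost(s, 4)
        het = hetconv_cost(s)
        assert dw.flops + pw.flops < het.flops      # but with added latency
        assert gw.flops < het.flops < standard_conv_cost(s).flops
        p = tmp_path / "t.csv"
        cost_table_csv([s], p)
        header, row = p.read_text().strip().splitlines()
        assert header.split(",")[:5] == ["layer", "M", "N", "K", "P"]
        assert row.split(",")[5] == str(het.flops)


class TestHetConvLayer:
    def test_weight_count_matches_cost(self):
        layer = make_hetconv_layer(spec(8, 8, 3, p=4))
        assert layer.num_params() == 8 * (2 * 9 + 6 * 1) == 192
        assert layer.num_params() == hetconv_cost(spec(8, 8, 3, p=4)).params

    def test_zero_input_gives_zero_output(self):
        layer = make_hetconv_layer(spec(8, 8, 3, p=4))
        out = layer(Tensor(np.zeros((1, 8, 6, 6), np.float32)))
        assert np.all(out.data == 0)

    def test_p1_matches_standard_conv_numerically(self, rng):
        """With shared weights, P=1 HetConv equals a dense conv."""
        conv = Conv2d(4, 6, 3, bias=False)
        het = HetConv2d(4, 6, 3, p_part=1)
        het.w3.data[...] = conv.weight.data
        x = Tensor(rng.normal(size=(2, 4, 8, 8)).astype(np.float32))
        np.testing.assert_allclose(het(x).data, conv(x).data, atol=1e-5)

    def test_matches_explicit_loop_conv(self, rng, loop_conv):
        """HetConv output equals a per-channel loop convolution applied
        to the equivalent sparse dense kernel (interleaved KxK layout:
        filter f uses KxK on channels c with c % P == f % P)."""
        m, n, k, p = 8, 6, 3, 4
        layer = HetConv2d(m, n, k, p_part=p)
        dense = np.zeros((n, m, k, k), np.float32)
        for f in range(n):
            big = [c for c in range(m) if c % p == f % p]
            small = [c for c in range(m) if c % p != f % p]
            dense[f, big] = layer.w3.data[f]
            dense[f, small, k // 2, k // 2] = layer.w1.data[f, :, 0, 0]
        x = rng.normal(size=(2, m, 8, 8)).astype(np.float32)
        ref, _ = loop_conv(x, dense, stride=1, pad=k // 2)
        np.testing.assert_allclose(layer(Tensor(x)).data, ref, atol=1e-5)

    def test_every_channel_gets_spatial_coverage(self):
        """Across the filter bank, each input channel is seen by some
        KxK kernel (the spatial-coverage argument for interleaving)."""
        m, n, p = 8, 8, 4
        covered = set()
        for f in range(n):
            covered.update(c for c in range(m) if c % p == f % p)
        assert covered == set(range(m))

    def test_channel_mismatch_raises(self):
        layer = HetConv2d(8, 8, 3, p_part=4)
        with pytest.raises(ValueError, match="channels"):
            layer(Tensor(np.zeros((1, 6, 8, 8), np.float32)))

    def test_stride_two_shape(self, rng):
        layer = HetConv2d(8, 4, 3, p_part=2, s=2)
        out = layer(Tensor(rng.normal(size=(1, 8, 16, 16)).astype(np.float32)))
        assert out.shape == (1, 4, 8, 8)


class TestC2fDualHet:
    def test_shape_preserved_and_params_below_stock(self, rng):
        stock = C2f(32, 32, 2, shortcut=True)
        dual = make_c2f_dualhet(32, 32, 2, het_p=4)
        x = Tensor(rng.normal(size=(1, 32, 16, 16)).astype(np.float32))
        assert dual(x).shape == x.shape
        assert dual.num_params() < stock.num_params()

    def test_invalid_hidden_partition(self):
        with pytest.raises(InvalidPartitionError):
            make_c2f_dualhet(16, 12, 1, het_p=4)   # hidden width 6
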