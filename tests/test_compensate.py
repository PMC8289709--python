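"""The compensation core: correction equations, clipping, conservation."""

import numpy as np
import pandas as pd
import pytest

from redsea import (
    CellFeatureTable,
    ChannelStack,
    CompensationConfig,
    SegmentationMask,
    SyntheticSpec,
    compensate,
    compute_adjacency,
    extract_border_signals,
    generate_scene,
    make_structuring_element,
    quadrant_fractions,
    reinforced_signal,
    subtracted_signal,
)
from redsea.compensate import extract_original

from _reference import ref_compensate, ref_whole_signals
from conftest import random_small_masks, two_type_cell_types

ELEM = make_structuring_element("star", 2)
ALL_STRATEGIES = [(m, r) for m in ("subtraction", "redsea") for r in ("whole", "border")]


def _pipeline(mask, stack, method="redsea", region="border", channels=None, clip=True):
    adj = compute_adjacency(mask)
    table = extract_original(mask, stack)
    border = extract_border_signals(mask, stack, ELEM)
    channels = channels or stack.channel_names
    cfg = CompensationConfig(method=method, region=region, element=ELEM, channels=channels)
    return compensate(table, adj, border, cfg, clip=clip)


class TestExtractOriginal:
    def test_uniform_channel_total_is_value_times_size(self, single_cell_mask):
        stack = ChannelStack(np.full((1, 7, 7), 3.0), ("x",))
        table = extract_original(single_cell_mask, stack)
        assert table.frame.at[1, "x"] == 3.0 * table.frame.at[1, "size"]
        assert table.frame.at[1, "size"] == 9

    def test_empty_mask_gives_empty_table(self):
        stack = ChannelStack(np.zeros((1, 5, 5)), ("x",))
        table = extract_original(SegmentationMask(np.zeros((5, 5), np.int64)), stack)
        assert len(table.frame) == 0

    def test_totals_and_centroids_match_brute_force(self, small_scene):
        table = extract_original(small_scene.mask, small_scene.stack)
        imgs = {ch: small_scene.stack.channel(ch) for ch in small_scene.stack.channel_names}
        ref = ref_whole_signals(small_scene.mask.labels, imgs)
        for (cell, ch), value in ref.items():
            assert table.frame.at[cell, ch] == pytest.approx(value, abs=1e-9)
        for cell in table.frame.index:
            coords = np.argwhere(small_scene.mask.labels == cell)
            np.testing.assert_allclose(
                [table.frame.at[cell, "centroid_row"], table.frame.at[cell, "centroid_col"]],
                coords.mean(axis=0),
            )


class TestSignalTerms:
    def test_no_neighbors_gives_zero_terms(self, single_cell_mask):
        adj = compute_adjacency(single_cell_mask)
        signals = pd.DataFrame({"x": [5.0]}, index=pd.Index([1], name="cell"))
        assert subtracted_signal(adj, signals, 1, "x") == 0.0
        assert reinforced_signal(adj, signals, 1, "x") == 0.0

    def test_direct_substitution_single_neighbor(self, two_cell_mask):
        # one neighbor with Y_K = 10, coefficient b_12 / P_2 applied directly
        adj = compute_adjacency(two_cell_mask)
        signals = pd.DataFrame({"x": [0.0, 10.0]}, index=pd.Index([1, 2], name="cell"))
        expected = 10.0 * adj.b(1, 2) / adj.perimeter[2]
        assert subtracted_signal(adj, signals, 1, "x") == pytest.approx(expected)
        # the printed-arithmetic case: Y_K=10, b=5, P_K=20 -> 2.5
        assert 10.0 * 5 / 20 == 2.5

    def test_enclosed_cell_reinforcement_returns_full_region_signal(self, enclosed_mask):
        # sum_K b_AK = P_A: reinforcement equals the cell's own region signal
        adj = compute_adjacency(enclosed_mask)
        signals = pd.DataFrame({"x": [8.0, 0.0]}, index=pd.Index([1, 2], name="cell"))
        assert reinforced_signal(adj, signals, 1, "x") == pytest.approx(8.0)

    def test_unknown_cell_raises(self, two_cell_mask):
        adj = compute_adjacency(two_cell_mask)
        signals = pd.DataFrame({"x": [1.0, 1.0]}, index=pd.Index([1, 2], name="cell"))
        with pytest.raises(KeyError):
            subtracted_signal(adj, signals, 9, "x")

    def test_three_cell_chain_matches_hand_sum(self):
        labels = np.zeros((6, 10), np.int64)
        labels[2:4, 1:3] = 1
        labels[2:4, 4:6] = 2
        labels[2:4, 7:9] = 3
        mask = SegmentationMask(labels)
        adj = compute_adjacency(mask)
        signals = pd.DataFrame(
            {"x": [3.0, 7.0, 11.0]}, index=pd.Index([1, 2, 3], name="cell")
        )
        expected = (
            signals.at[1, "x"] * adj.b(2, 1) / adj.perimeter[1]
            + signals.at[3, "x"] * adj.b(2, 3) / adj.perimeter[3]
        )
        assert subtracted_signal(adj, signals, 2, "x") == pytest.approx(expected)


class TestCompensate:
    @pytest.mark.parametrize("method,region", ALL_STRATEGIES)
    def test_isolated_cell_unchanged(self, single_cell_mask, method, region):
        stack = ChannelStack(np.full((1, 7, 7), 2.0), ("x",))
        out = _pipeline(single_cell_mask, stack, method=method, region=region)
        assert out.compensated("x")[1] == out.original("x")[1]

    def test_symmetric_pair_unchanged_under_full_correction(self):
        # two mirror-image cells: subtraction equals reinforcement exactly
        labels = np.zeros((7, 9), np.int64)
        labels[2:5, 1:4] = 1
        labels[2:5, 5:8] = 2
        mask = SegmentationMask(labels)
        stack = ChannelStack(np.full((1, 7, 9), 1.5), ("x",))
        out = _pipeline(mask, stack, method="redsea", region="border")
        np.testing.assert_allclose(
            out.compensated("x").to_numpy(), out.original("x").to_numpy(), rtol=1e-12
        )

    def test_negative_result_clips_to_zero(self, two_cell_mask):
        # cell 1 carries almost nothing; neighbor's border signal overwhelms it
        img = np.zeros((7, 6))
        img[two_cell_mask.labels == 1] = 0.01
        img[two_cell_mask.labels == 2] = 100.0
        stack = ChannelStack(img[None], ("x",))
        out = _pipeline(two_cell_mask, stack, method="subtraction", region="border")
        assert out.compensated("x")[1] == 0.0
        pre = _pipeline(two_cell_mask, stack, method="subtraction", region="border", clip=False)
        assert pre.compensated("x")[1] < 0.0
        assert out.metadata["clipped_cells"]["x"] == 1

    def test_unselected_channels_pass_through_exactly(self, small_scene):
        out = _pipeline(small_scene.mask, small_scene.stack, channels=("CD3",))
        for ch in small_scene.stack.channel_names:
            if ch == "CD3":
                continue
            np.testing.assert_array_equal(
                out.compensated(ch).to_numpy(), out.original(ch).to_numpy()
            )

    @pytest.mark.parametrize("method,region", ALL_STRATEGIES)
    def test_matches_brute_force_on_asymmetric_scene(self, method, region):
        spec = SyntheticSpec(height=32, width=32, n_cells=4, spillover=0.3, seed=5)
        scene = generate_scene(spec)
        out = _pipeline(scene.mask, scene.stack, method=method, region=region)
        imgs = {ch: scene.stack.channel(ch) for ch in scene.stack.channel_names}
        ref = ref_compensate(scene.mask.labels, imgs, ELEM.offsets, method, region)
        for (cell, ch), value in ref.items():
            assert out.compensated(ch)[cell] == pytest.approx(value, abs=1e-9)

    @pytest.mark.parametrize("region", ["whole", "border"])
    def test_preclip_conservation(self, region, small_scene):
        """Reinforcement redistributes exactly what subtraction removes:
        total pre-clip corrected signal equals total original signal."""
        out = _pipeline(
            small_scene.mask, small_scene.stack, method="redsea", region=region, clip=False
        )
        for ch in small_scene.stack.channel_names:
            total_comp = out.compensated(ch).sum()
            total_orig = out.original(ch).sum()
            assert total_comp == pytest.approx(total_orig, rel=1e-6)

    def test_clipping_only_raises_totals(self, small_scene):
        pre = _pipeline(small_scene.mask, small_scene.stack, clip=False)
        post = _pipeline(small_scene.mask, small_scene.stack, clip=True)
        for ch in small_scene.stack.channel_names:
            assert post.compensated(ch).sum() >= pre.compensated(ch).sum() - 1e-9

    @pytest.mark.parametrize("region", ["whole", "border"])
    def test_subtraction_never_exceeds_full_correction(self, region, small_scene):
        sub = _pipeline(small_scene.mask, small_scene.stack, method="subtraction", region=region)
        full = _pipeline(small_scene.mask, small_scene.stack, method="redsea", region=region)
        for ch in small_scene.stack.channel_names:
            assert (sub.compensated(ch) <= full.compensated(ch) + 1e-9).all()

    def test_scale_equivariance(self, small_scene):
        out = _pipeline(small_scene.mask, small_scene.stack)
        scaled_pixels = small_scene.stack.pixels.copy()
        idx = small_scene.stack.channel_names.index("CD3")
        scaled_pixels[idx] *= 3.0
        scaled_stack = ChannelStack(scaled_pixels, small_scene.stack.channel_names)
        out_scaled = _pipeline(small_scene.mask, scaled_stack)
        np.testing.assert_allclose(
            out_scaled.compensated("CD3").to_numpy(),
            3.0 * out.compensated("CD3").to_numpy(),
            rtol=1e-9,
        )

    def test_unknown_channel_in_config_rejected(self, small_scene):
        adj = compute_adjacency(small_scene.mask)
        table = extract_original(small_scene.mask, small_scene.stack)
        border = extract_border_signals(small_scene.mask, small_scene.stack, ELEM)
        cfg = CompensationConfig(channels=("nope",), element=ELEM)
        with pytest.raises(ValueError, match="nope"):
            compensate(table, adj, border, cfg)


class TestSpilloverRemoval:
    @pytest.mark.parametrize("lam", [0.05, 0.2, 0.4])
    def test_double_positive_fraction_drops_under_border_correction(self, lam):
        spec = SyntheticSpec(
            height=96, width=96, n_cells=30, cell_types=two_type_cell_types(),
            spillover=lam, noise="none", seed=17,
        )
        scene = generate_scene(spec)
        out = _pipeline(scene.mask, scene.stack, method="redsea", region="border",
                        channels=("CD3", "CD20"))
        thr = 1.0  # a few counts: spillover puts far more than this on neighbors
        before = quadrant_fractions(out, "CD3", "CD20", thr, thr, use_compensated=False)
        after = quadrant_fractions(out, "CD3", "CD20", thr, thr, use_compensated=True)
        assert after.double_positive < before.double_positive


def test_oracle_equivalence_random_masks_all_strategies():
    """Random packed masks against the brute-force reference for every
    method x region combination."""
    rng = np.random.default_rng(23)
    for i, mask in random_small_masks(8, seed=23):
        h, w = mask.shape
        imgs = {
            "a": rng.poisson(3.0, size=(h, w)).astype(float),
            "b": rng.uniform(0, 5, size=(h, w)),
        }
        stack = ChannelStack(np.stack(list(imgs.values())), tuple(imgs))
        for method, region in ALL_STRATEGIES:
            out = _pipeline(mask, stack, method=method, region=region)
            ref = ref_compensate(mask.labels, imgs, ELEM.offsets, method, region)
            for (cell, ch), value in ref.items():
                assert out.compensated(ch)[cell] == pytest.approx(value, abs=1e-9)
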