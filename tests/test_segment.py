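import numpy as np
import pytest

from cellsegnet.data import extract_patch
from cellsegnet.network import (
    ConvRound,
    Network,
    NetworkSpec,
    TEST_FAMILY,
    receptive_field,
    softmax,
)
from cellsegnet.segment import (
    ActiveContourParams,
    ScoreMap,
    adaptive_threshold_mask,
    ensemble_average,
    predict_scoremap,
    refine_with_active_contours,
    threshold_mask,
)

NO_POOL_SPEC = NetworkSpec(conv_rounds=(ConvRound(3, 4), ConvRound(3, 4)),
                           fc_widths=(8,))  # rf 5, no maxpool


def _scoremap_from_prob(prob):
    probs = np.stack([1 - prob, np.zeros_like(prob), prob])
    return ScoreMap(probabilities=probs,
                    valid_region=(0, prob.shape[0], 0, prob.shape[1]))


class TestDensePatchEquivalence:
    @pytest.mark.parametrize("spec,stride", [
        (TEST_FAMILY[9], 3),          # one maxpool round
        (TEST_FAMILY[13], 5),         # one maxpool round, larger rf
        (NO_POOL_SPEC, 3),            # no pooling at all
        (TEST_FAMILY[21], 7),         # two maxpool rounds
    ])
    def test_dense_output_equals_patch_classification(self, spec, stride):
        rf = receptive_field(spec)
        rng = np.random.default_rng(0)
        net = Network(spec, rng)
        image = rng.normal(size=(spec.input_channels, 64, 64))
        sm = predict_scoremap(image, net)
        r0, r1, c0, c1 = sm.valid_region
        patches, coords = [], []
        for r in range(r0, r1, stride):
            for c in range(c0, c1, stride):
                patches.append(extract_patch(image, r, c, rf))
                coords.append((r, c))
        probs = softmax(net.forward(np.stack(patches)))
        for (r, c), p in zip(coords, probs):
            assert np.abs(p - sm.probabilities[:, r, c]).max() < 1e-4

    def test_per_pixel_probabilities_sum_to_one(self):
        net = Network(TEST_FAMILY[9], np.random.default_rng(1))
        image = np.random.default_rng(2).normal(size=(1, 64, 64))
        sm = predict_scoremap(image, net)
        np.testing.assert_allclose(sm.probabilities.sum(axis=0), 1.0, atol=1e-6)

    def test_shift_equivariance_in_valid_region(self):
        # without padding, translating the input translates the output
        spec = TEST_FAMILY[9]
        net = Network(spec, np.random.default_rng(3))
        rng = np.random.default_rng(4)
        big = rng.normal(size=(1, 72, 72))
        a = net.dense_scores(big[:, :64, :64])
        b = net.dense_scores(big[:, 2:66, 2:66])
        np.testing.assert_allclose(a[:, 2:, 2:], b[:, :-2, :-2], atol=1e-10)

    def test_channel_mismatch_rejected(self):
        net = Network(TEST_FAMILY[9], np.random.default_rng(0))
        with pytest.raises(ValueError, match="channels"):
            predict_scoremap(np.zeros((2, 64, 64)), net)


class TestEnsembleAverage:
    def test_identical_maps_average_to_themselves(self):
        prob = np.random.default_rng(0).uniform(size=(64, 64))
        sm = _scoremap_from_prob(prob)
        for k in (2, 4):  # power-of-two counts keep the mean float-exact
            avg = ensemble_average([sm] * k)
            np.testing.assert_array_equal(avg.probabilities, sm.probabilities)
        avg3 = ensemble_average([sm] * 3)
        np.testing.assert_allclose(avg3.probabilities, sm.probabilities,
                                   atol=1e-15)

    def test_two_one_hot_maps_average_to_half(self):
        a = ScoreMap(probabilities=np.array([[[1.0]], [[0.0]], [[0.0]]]),
                     valid_region=(0, 1, 0, 1))
        b = ScoreMap(probabilities=np.array([[[0.0]], [[1.0]], [[0.0]]]),
                     valid_region=(0, 1, 0, 1))
        avg = ensemble_average([a, b])
        np.testing.assert_allclose(avg.probabilities[:, 0, 0], [0.5, 0.5, 0.0])

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average([])

    def test_default_ensemble_size_is_five(self):
        import inspect

        from cellsegnet.network import train_ensemble

        assert inspect.signature(train_ensemble).parameters["n_models"].default == 5


class TestThresholdMask:
    def test_blob_above_threshold_gets_one_label(self):
        prob = np.full((64, 64), 0.2)
        prob[20:30, 20:30] = 0.7
        mask = threshold_mask(_scoremap_from_prob(prob), threshold=0.6,
                              min_area=10)
        assert mask.max() == 1
        assert (mask[20:30, 20:30] == 1).all()
        assert mask.sum() == 100

    def test_all_below_threshold_gives_empty_mask(self):
        prob = np.full((32, 32), 0.4)
        mask = threshold_mask(_scoremap_from_prob(prob), threshold=0.6)
        assert mask.max() == 0

    def test_lowering_threshold_never_shrinks_mask(self):
        prob = np.random.default_rng(5).uniform(size=(64, 64))
        hi = threshold_mask(_scoremap_from_prob(prob), threshold=0.7, min_area=1)
        lo = threshold_mask(_scoremap_from_prob(prob), threshold=0.4, min_area=1)
        assert ((hi > 0) <= (lo > 0)).all()

    def test_small_components_removed(self):
        prob = np.full((64, 64), 0.1)
        prob[5:7, 5:7] = 0.9       # 4 px
        prob[20:30, 20:30] = 0.9   # 100 px
        mask = threshold_mask(_scoremap_from_prob(prob), threshold=0.6,
                              min_area=20)
        assert mask.max() == 1
        assert mask[5, 5] == 0

    def test_growth_never_merges_instances(self):
        prob = np.full((32, 32), 0.1)
        prob[5:15, 5:14] = 0.9
        prob[5:15, 16:25] = 0.9
        mask = threshold_mask(_scoremap_from_prob(prob), threshold=0.6,
                              min_area=10, grow_px=2)
        assert mask.max() == 2
        grown = threshold_mask(_scoremap_from_prob(prob), threshold=0.6,
                               min_area=10, grow_px=0)
        assert (mask > 0).sum() > (grown > 0).sum()

    def test_invalid_threshold_rejected(self):
        prob = np.full((32, 32), 0.5)
        with pytest.raises(ValueError):
            threshold_mask(_scoremap_from_prob(prob), threshold=1.5)


class TestAdaptiveThresholdMask:
    def test_constant_map_is_empty_for_positive_offset(self):
        prob = np.full((64, 64), 0.5)
        mask = adaptive_threshold_mask(_scoremap_from_prob(prob), window=15,
                                       offset=0.05, min_area=1)
        assert mask.max() == 0

    def test_recovers_dim_blob_that_global_threshold_misses(self):
        prob = np.full((96, 96), 0.1)
        prob[10:25, 10:25] = 0.9    # bright object
        prob[60:75, 60:75] = 0.55   # dim object, below the global 0.6
        sm = _scoremap_from_prob(prob)
        global_mask = threshold_mask(sm, threshold=0.6, min_area=20)
        adaptive = adaptive_threshold_mask(sm, window=31, offset=0.1,
                                           min_area=20)
        assert global_mask.max() == 1
        assert adaptive.max() == 2
        assert (adaptive[60:75, 60:75] > 0).any()

    def test_reduces_to_global_threshold_when_window_dominates(self):
        # a window much larger than the object leaves the local mean at
        # the background level everywhere, so local mean + offset acts as
        # one global threshold and both rules select identical pixels
        prob = np.full((64, 64), 0.2)
        prob[28:36, 28:36] = 0.8
        sm = _scoremap_from_prob(prob)
        adaptive = adaptive_threshold_mask(sm, window=63, offset=0.37,
                                           min_area=1)
        global_mask = threshold_mask(sm, threshold=0.6, min_area=1)
        np.testing.assert_array_equal(adaptive > 0, global_mask > 0)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            adaptive_threshold_mask(_scoremap_from_prob(np.zeros((8, 8))),
                                    window=10)


class TestActiveContourRefinement:
    def _two_touching_cells(self):
        prob = np.zeros((64, 64))
        prob[16:48, 10:32] = 0.95
        prob[16:48, 32:54] = 0.95   # touching along column 32
        seeds = np.zeros((64, 64), dtype=np.int32)
        seeds[28:36, 18:24] = 1
        seeds[28:36, 40:46] = 2
        return _scoremap_from_prob(prob), seeds

    def test_indicator_field_with_two_seeds_gives_two_labels(self):
        sm, seeds = self._two_touching_cells()
        labels = refine_with_active_contours(sm, seeds)
        assert set(np.unique(labels)) == {0, 1, 2}

    def test_every_instance_contains_its_seed(self):
        sm, seeds = self._two_touching_cells()
        labels = refine_with_active_contours(sm, seeds)
        for s in (1, 2):
            vals = labels[seeds == s]
            assert (vals == s).all()

    def test_touching_cells_are_not_merged(self):
        sm, seeds = self._two_touching_cells()
        labels = refine_with_active_contours(sm, seeds)
        # each seed produces exactly one 4-connected instance
        from skimage.measure import label as cc

        for s in (1, 2):
            assert cc(labels == s, connectivity=1).max() == 1

    def test_instance_count_never_exceeds_seed_count(self):
        sm, seeds = self._two_touching_cells()
        labels = refine_with_active_contours(sm, seeds)
        assert labels.max() <= seeds.max()

    def test_no_pixel_belongs_to_two_instances(self):
        # labels are single-valued by construction; assert disjoint coverage
        sm, seeds = self._two_touching_cells()
        labels = refine_with_active_contours(sm, seeds)
        assert ((labels == 1) & (labels == 2)).sum() == 0

    def test_seedless_frame_warns_and_returns_empty(self):
        sm, _ = self._two_touching_cells()
        with pytest.warns(UserWarning, match="no nuclear seeds"):
            labels = refine_with_active_contours(sm, np.zeros((64, 64), np.int32))
        assert labels.max() == 0

    def test_pipeline_is_deterministic(self):
        sm, seeds = self._two_touching_cells()
        p = ActiveContourParams(iterations=50)
        a = refine_with_active_contours(sm, seeds, p)
        b = refine_with_active_contours(sm, seeds, p)
        np.testing.assert_array_equal(a, b)
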