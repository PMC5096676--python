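import numpy as np
import pytest
from skimage.measure import regionprops

from cellsegnet.data import INTERIOR, classmap_from_annotation
from cellsegnet.simulate import (
    ColonyMovieSpec,
    KTRMovieSpec,
    SceneSpec,
    generate_bacteria_colony_movie,
    generate_coculture_scene,
    generate_ktr_movie,
    generate_mammalian_scene,
)


class TestColonyMovie:
    def test_identical_specs_give_bit_identical_movies(self, colony):
        spec, movie, gt = colony
        movie2, gt2 = generate_bacteria_colony_movie(spec)
        np.testing.assert_array_equal(movie, movie2)
        for a, b in zip(gt.instance_masks, gt2.instance_masks):
            np.testing.assert_array_equal(a, b)

    def test_zero_growth_preserves_total_area(self):
        spec = ColonyMovieSpec(initial_cells=3, relative_growth_rate=0.0,
                               division_length=60.0, frames=2, seed=1)
        _, gt = generate_bacteria_colony_movie(spec)
        areas = [(m > 0).sum() for m in gt.instance_masks]
        assert areas[0] == areas[1]

    def test_area_follows_exponential_growth_law(self):
        # no divisions forced: total area tracks A0 * 1.05^t within 2%
        spec = ColonyMovieSpec(initial_cells=3, relative_growth_rate=0.05,
                               division_length=1000.0, initial_length=26.0,
                               frames=20, seed=1)
        _, gt = generate_bacteria_colony_movie(spec)
        assert gt.n_frames == 20 and not gt.truncated
        a0 = (gt.instance_masks[0] > 0).sum()
        for t, mask in enumerate(gt.instance_masks):
            expected = a0 * 1.05 ** t
            assert abs((mask > 0).sum() - expected) / expected < 0.02

    def test_daughter_areas_tile_parent_at_division(self, colony):
        _, _, gt = colony
        assert gt.lineage.divisions  # the fixture does divide
        for parent, d1, d2, frame in gt.lineage.divisions:
            a_parent = gt.lineage.cells[parent].areas[-1]
            a_sum = (gt.lineage.cells[d1].areas[0]
                     + gt.lineage.cells[d2].areas[0])
            assert abs(a_parent - a_sum) <= 2

    def test_lineage_records_every_division(self, colony):
        _, _, gt = colony
        children = {cid for _, d1, d2, _ in gt.lineage.divisions
                    for cid in (d1, d2)}
        with_parent = {cid for cid, t in gt.lineage.cells.items()
                       if t.parent_id is not None}
        assert children == with_parent
        gt.lineage.validate()

    def test_outgrowing_colony_stops_early_with_flag(self):
        spec = ColonyMovieSpec(initial_cells=2, relative_growth_rate=0.3,
                               division_length=26.0, frames=40, seed=0,
                               image_shape=(64, 64))
        _, gt = generate_bacteria_colony_movie(spec)
        assert gt.truncated
        assert gt.n_frames < 40

    def test_class_map_matches_annotation_derivation(self, colony):
        _, _, gt = colony
        for mask, cm in zip(gt.instance_masks, gt.class_maps):
            expected = classmap_from_annotation(mask)
            np.testing.assert_array_equal(cm.labels, expected.labels)

    def test_every_instance_has_interior_pixels(self, colony):
        _, _, gt = colony
        for mask, cm in zip(gt.instance_masks, gt.class_maps):
            for lbl in np.unique(mask):
                if lbl == 0:
                    continue
                assert (cm.labels[mask == lbl] == INTERIOR).any()

    def test_growth_rate_domain_validated(self):
        with pytest.raises(ValueError):
            ColonyMovieSpec(relative_growth_rate=0.6)
        with pytest.raises(ValueError):
            ColonyMovieSpec(frames=1)


class TestMammalianScene:
    def test_zero_cells_gives_empty_mask_and_background_channels(self):
        channels, gt = generate_mammalian_scene(
            SceneSpec(cell_count=0, morphology="blob_B", seed=0))
        assert gt.instance_masks[0].max() == 0
        assert channels.shape[0] == 2

    def test_identical_specs_reproduce_scene(self):
        spec = SceneSpec(cell_count=4, morphology="blob_A", seed=9)
        a, _ = generate_mammalian_scene(spec)
        b, _ = generate_mammalian_scene(spec)
        np.testing.assert_array_equal(a, b)

    def test_each_cell_contains_exactly_one_nucleus(self):
        _, gt = generate_mammalian_scene(
            SceneSpec(cell_count=6, morphology="blob_B", seed=2))
        inst, nuc = gt.instance_masks[0], gt.nucleus_masks[0]
        for lbl in np.unique(inst):
            if lbl == 0:
                continue
            assert (nuc == lbl).any()
            # nucleus pixels lie inside the cell's cytoplasm mask
            assert (inst[nuc == lbl] == lbl).all()

    def test_nucleus_centroid_inside_cytoplasm(self):
        _, gt = generate_mammalian_scene(
            SceneSpec(cell_count=6, morphology="blob_A", seed=3))
        inst, nuc = gt.instance_masks[0], gt.nucleus_masks[0]
        for rp in regionprops(nuc):
            r, c = int(round(rp.centroid[0])), int(round(rp.centroid[1]))
            assert inst[r, c] == rp.label

    def test_nuclear_channel_contrast_exceeds_threefold(self):
        channels, gt = generate_mammalian_scene(
            SceneSpec(cell_count=6, morphology="blob_B", seed=2))
        nuc = gt.nucleus_masks[0]
        inside = channels[1][nuc > 0].mean()
        outside = channels[1][nuc == 0].mean()
        assert inside > 3 * outside

    def test_instance_masks_are_pairwise_disjoint(self):
        _, gt = generate_mammalian_scene(
            SceneSpec(cell_count=8, morphology="blob_B", seed=5))
        # single-valued label image; instances disjoint by construction,
        # but each requested cell must actually exist
        assert len(np.unique(gt.instance_masks[0])) == 9

    def test_infeasible_density_raises(self):
        with pytest.raises(RuntimeError, match="density"):
            generate_mammalian_scene(
                SceneSpec(cell_count=200, morphology="blob_A",
                          image_shape=(64, 64), seed=0))

    def test_rod_morphology_rejected_for_mammalian_scene(self):
        with pytest.raises(ValueError):
            generate_mammalian_scene(SceneSpec(morphology="rod"))


class TestCocultureScene:
    def test_counts_match_request(self):
        a = SceneSpec(cell_count=4, morphology="blob_A", cell_radius=9, seed=1)
        b = SceneSpec(cell_count=5, morphology="blob_B", cell_radius=9, seed=2)
        _, gt = generate_coculture_scene(a, b)
        types = list(gt.per_cell_type.values())
        assert types.count(0) == 4 and types.count(1) == 5
        assert gt.instance_masks[0].max() == 9

    def test_single_type_coculture_has_constant_type(self):
        a = SceneSpec(cell_count=5, morphology="blob_A", cell_radius=9, seed=1)
        b = SceneSpec(cell_count=0, morphology="blob_B", cell_radius=9, seed=2)
        _, gt = generate_coculture_scene(a, b)
        assert set(gt.per_cell_type.values()) == {0}

    def test_morphology_classes_are_separable_by_eccentricity(self):
        a = SceneSpec(cell_count=5, morphology="blob_A", cell_radius=9, seed=4)
        b = SceneSpec(cell_count=5, morphology="blob_B", cell_radius=9, seed=4)
        _, gt = generate_coculture_scene(a, b)
        ecc = {0: [], 1: []}
        for rp in regionprops(gt.instance_masks[0]):
            ecc[gt.per_cell_type[rp.label]].append(rp.eccentricity)
        assert np.mean(ecc[0]) - np.mean(ecc[1]) > 0.3

    def test_identical_morphologies_rejected(self):
        a = SceneSpec(cell_count=2, morphology="blob_A")
        with pytest.raises(ValueError):
            generate_coculture_scene(a, a)

    def test_class_map_has_four_classes(self):
        a = SceneSpec(cell_count=3, morphology="blob_A", cell_radius=9, seed=1)
        b = SceneSpec(cell_count=3, morphology="blob_B", cell_radius=9, seed=2)
        _, gt = generate_coculture_scene(a, b)
        assert gt.class_maps[0].n_classes == 4


class TestKTRMovie:
    def test_constant_schedule_keeps_compartment_means_constant(self):
        schedule = np.full(4, 0.3)
        _, reporter, gt = generate_ktr_movie(schedule, KTRMovieSpec(seed=1))
        comp = gt.compartments
        near_means = [reporter[f][comp["near"] == 1].mean() for f in range(4)]
        assert np.ptp(near_means) < 0.02  # noise-level fluctuation only

    def test_total_reporter_conserved_without_noise(self):
        schedule = np.array([0.1, 0.4, 0.8, 0.2])
        spec = KTRMovieSpec(seed=2, noise_sd=0.0)
        _, reporter, gt = generate_ktr_movie(schedule, spec)
        comp = gt.compartments
        for cid in np.unique(gt.instance_masks[0]):
            if cid == 0:
                continue
            cell = ((comp["nucleus"] == cid) | (comp["near"] == cid)
                    | (comp["far"] == cid))
            totals = [reporter[f][cell].sum() for f in range(len(schedule))]
            assert (max(totals) - min(totals)) / max(totals) < 0.01

    def test_near_far_gap_matches_specification(self):
        spec = KTRMovieSpec(seed=3, noise_sd=0.05)
        fraction = 0.0
        _, reporter, gt = generate_ktr_movie(np.array([fraction]), spec)
        comp = gt.compartments
        near_px = reporter[0][comp["near"] > 0]
        far_px = reporter[0][comp["far"] > 0]
        gap = near_px.mean() - far_px.mean()
        expected = spec.near_mean_max - spec.far_mean
        se = spec.noise_sd * np.sqrt(1 / len(near_px) + 1 / len(far_px))
        assert abs(gap - expected) < 3 * se

    def test_schedule_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            generate_ktr_movie(np.array([0.5, 1.2]), KTRMovieSpec())

    def test_identical_specs_reproduce_movie(self):
        schedule = np.array([0.2, 0.6])
        spec = KTRMovieSpec(seed=4)
        _, a, _ = generate_ktr_movie(schedule, spec)
        _, b, _ = generate_ktr_movie(schedule, spec)
        np.testing.assert_array_equal(a, b)


class TestSceneSpecValidation:
    def test_image_too_small_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(image_shape=(32, 32))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(noise_sd=-0.1)

    def test_unknown_morphology_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(morphology="star")
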