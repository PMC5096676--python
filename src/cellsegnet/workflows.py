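"""Canonical desk-scale studies run end to end on synthetic data.

These functions wire the whole pipeline together at sizes that finish in
minutes on one CPU: simulate a dataset, train, infer densely, and measure.
They are the same experiments the test suite and the reproduction script
run, so their defaults define the package's reference study conditions.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .data import INTERIOR, INTERIOR_B, classmap_from_annotation, concat_datasets, sample_balanced
from .ktr import fit_gmm2, ktr_timeseries
from .metrics import (
    aggregate_indices,
    area_change_error_rate,
    cellular_classification_score,
    coculture_instance_mask,
    match_objects,
)
from .network import (
    NetworkSpec,
    PatchClassifier,
    TEST_FAMILY,
    TrainConfig,
    receptive_field,
)
from .normalize import normalize_for_network
from .segment import predict_scoremap, threshold_mask
from .simulate import (
    ColonyMovieSpec,
    KTRMovieSpec,
    SceneSpec,
    generate_bacteria_colony_movie,
    generate_coculture_scene,
    generate_ktr_movie,
)
from .tracking import (
    division_set,
    instantaneous_growth_rate,
    lap_link,
    link_set,
)

__all__ = [
    "area_jump_statistics",
    "dense_equivalence_check",
    "bacteria_segmentation_study",
    "tracking_fidelity_study",
    "gmm_recovery_study",
    "coculture_classification_study",
    "ktr_compartment_study",
]

#: training colony: dense enough to supply ~20k balanced patches
_COLONY = ColonyMovieSpec(initial_cells=8, relative_growth_rate=0.13,
                          division_length=34.0, frames=12)

#: held-out evaluation colony at the reference (moderate) packing density;
#: segmentation of near-confluent colonies degrades, as with real data
_COLONY_EVAL = ColonyMovieSpec(initial_cells=6, relative_growth_rate=0.13,
                               division_length=34.0, frames=11)


def area_jump_statistics(flagged: int, total: int, jump_factor: float = 1.4):
    """Movie-level area-jump error rate computed on constructed tracks with
    a known number of >=30% jumps.

    Builds a single track with ``total`` frame-to-frame transitions of
    which exactly ``flagged`` multiply the area by ``jump_factor`` (a 40%
    jump, above the 30% criterion) and the rest leave it unchanged, then
    runs the error-rate computation on it.
    """
    from .tracking import Lineage

    areas = [100.0]
    # spread the flagged transitions evenly among the benign ones
    stride = max(total // max(flagged, 1), 1)
    n_flagged = 0
    for k in range(total):
        jump = n_flagged < flagged and k % stride == 0
        areas.append(areas[-1] * (jump_factor if jump else 1.0))
        n_flagged += int(jump)
    lineage = Lineage.from_tracks({1: areas})
    return area_change_error_rate(lineage, threshold_fraction=0.30)


def dense_equivalence_check(seed: int = 0, image_size: int = 64):
    """Max abs difference between the fully convolutional score map and
    patch-by-patch classification at every valid pixel, for a randomly
    initialized 2-round / one-maxpool network."""
    from .data import extract_patch
    from .network import Network, softmax

    spec = TEST_FAMILY[9]
    rng = np.random.default_rng(seed)
    net = Network(spec, rng)
    image = rng.normal(size=(1, image_size, image_size))
    sm = predict_scoremap(image, net)
    rf = receptive_field(spec)
    r0, r1, c0, c1 = sm.valid_region
    patches = []
    for r in range(r0, r1):
        for c in range(c0, c1):
            patches.append(extract_patch(image, r, c, rf))
    probs = softmax(net.forward(np.stack(patches)))
    dense = sm.probabilities[:, r0:r1, c0:c1].reshape(sm.n_classes, -1).T
    return float(np.abs(probs - dense).max()), (r1 - r0) * (c1 - c0)


def _colony_dataset(movie, gt, window: int, per_class_cap: int, seed: int,
                    n_frames: int = 6):
    parts = []
    for f in range(gt.n_frames - n_frames, gt.n_frames):
        img = normalize_for_network(movie[f], window)
        cm = classmap_from_annotation(gt.instance_masks[f])
        parts.append(sample_balanced(cm, img.pixels, window,
                                     per_class_cap=per_class_cap, seed=seed + f))
    return concat_datasets(parts)


def bacteria_segmentation_study(seed: int = 0, n_seeds: int = 3,
                                epochs: int = 6, per_class_cap: int = 1150):
    """Train patch classifiers (receptive field 31) on one synthetic
    colony and score them per cell on a held-out colony.

    Returns a dict with per-seed and median matched per-cell Jaccard
    indices, dataset size, and validation errors.  The defaults give a
    ~20,000-patch balanced dataset and three training seeds.
    """
    train_spec = replace(_COLONY, seed=10 + seed)
    test_spec = replace(_COLONY_EVAL, seed=777 + seed)
    movie, gt = generate_bacteria_colony_movie(train_spec)
    ds = _colony_dataset(movie, gt, 31, per_class_cap, seed)
    movie2, gt2 = generate_bacteria_colony_movie(test_spec)
    frame = gt2.n_frames - 1
    img2 = normalize_for_network(movie2[frame], 31)
    reference = gt2.instance_masks[frame]

    medians, val_errs = [], []
    for k in range(n_seeds):
        res = PatchClassifier(ds, TEST_FAMILY[31]).fit(
            TrainConfig(epochs=epochs, seed=seed + k)
        )
        sm = predict_scoremap(img2, res)
        mask = threshold_mask(sm, threshold=0.6, min_area=20, grow_px=1)
        summary = aggregate_indices(match_objects(reference, mask),
                                    reference, mask)
        matched = summary.per_cell[summary.per_cell.comp_id >= 0]
        medians.append(float(matched.ji.median()))
        val_errs.append(res.final_validation_error)
    return {
        "median_ji": float(np.median(medians)),
        "per_seed_median_ji": medians,
        "validation_errors": val_errs,
        "n_patches": len(ds),
        "n_reference_cells": int(reference.max()),
    }


def tracking_fidelity_study(seed: int = 0):
    """Track ground-truth colony masks (relabeled per frame) and compare
    links, divisions, and the recovered growth rate with the simulator's
    own lineage."""
    spec = replace(_COLONY_EVAL, relative_growth_rate=0.08, seed=3 + seed,
                   frames=12, initial_cells=2, division_length=36.0)
    _, gt = generate_bacteria_colony_movie(spec)
    masks = []
    for m in gt.instance_masks:
        out = np.zeros_like(m)
        for i, lbl in enumerate(np.unique(m)[1:], start=1):
            out[m == lbl] = i
        masks.append(out)
    lineage = lap_link(masks, max_displacement=25)
    truth_links = link_set(gt.lineage)
    truth_divs = division_set(gt.lineage)
    got_links = link_set(lineage)
    got_divs = division_set(lineage)
    link_recovery = 100.0 * len(truth_links & got_links) / max(len(truth_links), 1)
    div_recovery = 100.0 * len(truth_divs & got_divs) / max(len(truth_divs), 1)
    rates = instantaneous_growth_rate(lineage)
    median_rate = float(rates[~rates.division].rate.median())
    jumps = area_change_error_rate(lineage)
    return {
        "link_recovery_pct": link_recovery,
        "division_recovery_pct": div_recovery,
        "spurious_links": len(got_links - truth_links),
        "median_growth_rate": median_rate,
        "true_growth_rate": spec.relative_growth_rate,
        "n_links": len(truth_links),
        "n_divisions": len(truth_divs),
        "area_jump_pct": jumps.percentage,
    }


def gmm_recovery_study(seed: int = 0, n_seeds: int = 20, n: int = 10_000,
                       weights=(0.6, 0.4), means=(1.0, 3.0), sds=(0.1, 0.2)):
    """Fit the two-component mixture to samples from a known mixture and
    report worst-case parameter recovery errors over ``n_seeds`` draws."""
    mu_errs, w_errs = [], []
    for k in range(n_seeds):
        rng = np.random.default_rng(seed * 1000 + k)
        n1 = rng.binomial(n, weights[0])
        x = np.concatenate([
            rng.normal(means[0], sds[0], n1),
            rng.normal(means[1], sds[1], n - n1),
        ])
        fit = fit_gmm2(x, seed=k)
        mu_errs.append(float(np.abs(fit.means - np.array(means)).max()))
        w_errs.append(float(np.abs(fit.weights - np.array(weights)).max()))
    return {
        "max_mean_error": max(mu_errs),
        "max_weight_error": max(w_errs),
        "n": n,
        "n_seeds": n_seeds,
    }


def coculture_classification_study(seed: int = 0, epochs: int = 6,
                                   n_train_scenes: int = 3,
                                   n_eval_scenes: int = 2,
                                   per_class_cap: int = 1100):
    """Train the 4-class test network on synthetic two-morphology
    co-cultures and measure per-cell type-call accuracy on held-out
    scenes (instances derived from the summed type-interior scores)."""
    window = 21
    spec_a = SceneSpec(cell_count=5, morphology="blob_A", cell_radius=9.0)
    spec_b = SceneSpec(cell_count=5, morphology="blob_B", cell_radius=9.0)
    parts = []
    for s in range(n_train_scenes):
        channels, gt = generate_coculture_scene(
            replace(spec_a, seed=100 + seed + s),
            replace(spec_b, seed=200 + seed + s),
        )
        img = normalize_for_network(channels, window)
        parts.append(sample_balanced(gt.class_maps[0], img.pixels, window,
                                     per_class_cap=per_class_cap, seed=seed + s))
    ds = concat_datasets(parts)
    base = TEST_FAMILY[window]
    spec = NetworkSpec(conv_rounds=base.conv_rounds, fc_widths=base.fc_widths,
                       n_classes=4, input_channels=2)
    res = PatchClassifier(ds, spec).fit(TrainConfig(epochs=epochs, seed=seed))

    type_classes = (INTERIOR, INTERIOR_B)
    correct = total = 0
    score_sum_err = 0.0
    for s in range(n_eval_scenes):
        channels, gt = generate_coculture_scene(
            replace(spec_a, seed=900 + seed + s),
            replace(spec_b, seed=800 + seed + s),
        )
        img = normalize_for_network(channels, window)
        sm = predict_scoremap(img, res)
        mask = coculture_instance_mask(sm, type_classes, threshold=0.6,
                                       min_area=50)
        result = cellular_classification_score(sm, mask, type_classes)
        match = match_objects(gt.instance_masks[0], mask)
        truth = {c: gt.per_cell_type[r] for r, c, _ in match.pairs}
        for _, row in result.scores.iterrows():
            cid = int(row.cell_id)
            if cid in truth:
                total += 1
                correct += int(row.predicted_type == truth[cid])
        sums = result.scores[[f"score_{c}" for c in type_classes]].sum(axis=1)
        if len(sums):
            score_sum_err = max(score_sum_err, float(np.abs(sums - 1).max()))
    return {
        "accuracy_pct": 100.0 * correct / total if total else float("nan"),
        "n_cells": total,
        "validation_error": res.final_validation_error,
        "score_sum_max_error": score_sum_err,
        "n_patches": len(ds),
    }


def ktr_compartment_study(seed: int = 0):
    """Measure the two cytoplasm-estimation routes on the two-compartment
    fixture: the mixture's upper component should sit on the perinuclear
    ("near") mean while a wide cytoring lands between the compartments."""
    spec = KTRMovieSpec(seed=5 + seed)
    fraction = 0.15
    schedule = np.full(4, fraction)
    _, reporter, gt = generate_ktr_movie(schedule, spec)
    comp = gt.compartments
    table = ktr_timeseries([comp["nucleus"]] * len(schedule),
                           gt.instance_masks, reporter)
    f0 = table[table.frame == 0]
    near_true = (1 - fraction) * spec.near_mean_max
    gmm_est = float(f0[f0.method == "gmm_upper"].cyto_estimate.mean())
    ring_est = float(f0[f0.method == "cytoring_25"].cyto_estimate.mean())
    return {
        "gmm_upper": gmm_est,
        "cytoring_25": ring_est,
        "near_mean_true": near_true,
        "far_mean_true": spec.far_mean,
        "gmm_rel_error": abs(gmm_est - near_true) / near_true,
        "n_cells": int(gt.instance_masks[0].max()),
    }
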