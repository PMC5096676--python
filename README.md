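# cellsegnet

Conv-net single-cell segmentation and quantification for live-cell
microscopy.

Live-cell imaging experiments stand or fall on image segmentation:
deciding which pixels of a phase-contrast or fluorescence image belong to
which individual cell. `cellsegnet` treats segmentation as per-pixel
classification — a small convolutional network looks at the patch around
each pixel and scores it as *background*, *cell boundary*, or *cell
interior* — and builds the rest of a quantitative pipeline on top of the
resulting masks: per-object accuracy metrics, frame-to-frame tracking with
single-cell growth curves, kinase-translocation-reporter (KTR) ratios,
and simultaneous segmentation + cell-type classification of co-cultures.
It is aimed at quantitative cell biologists and image-analysis developers
who want a transparent, dependency-light (NumPy/SciPy/scikit-image)
implementation of this approach that is testable end to end without any
external data: a synthetic-microscopy module generates phase-like movies
of growing bacterial micro-colonies, mammalian-like scenes with a nuclear
channel, two-morphology co-cultures, and two-compartment reporter movies,
each with exact ground truth.

## The model

A patch classifier is a stack of rounds of convolution with 3–5 px
filters {w₁,…,w_n}, the transfer function relu(x) = max(0, x), and
optional 2×2/stride-2 max-pooling, followed by fully connected layers
W_q f(W_{q−1} f(… f(W₁ **r**))) producing one score per class. Training
minimizes the soft-max cost

    Cost = − Σ_images log( e^{s_correct} / Σ_classes e^{s} )
           + λ Σ_{w ∈ filter weights} w²

by mini-batch gradient descent (SGD or RMSprop) with backpropagation,
with on-the-fly rotation/reflection augmentation and a held-out 10%
validation split. Images are normalized by their median pixel value and
then reduced by their local mean over a window equal to the network's
receptive field (31 px for bacteria, 61 px for mammalian cells), which
makes the pipeline exactly invariant to illumination scaling. A trained
network is applied to whole images fully convolutionally with dilated
(d-regularly sparse) kernels — pixel-for-pixel identical to sliding the
patch classifier — and the softmax-normalized interior score is converted
to instance masks by thresholding (0.6 for bacteria), adaptive
thresholding, or nuclear-seeded active contours with watershed collision
handling. Accuracy is reported per cell as Jaccard JI = |R∩S|/|R∪S| and
Dice DI = 2|R∩S|/(|R|+|S|).

See `docs/methods.md` for the full model description, parameter defaults,
and limitations.

## Worked example

Train a receptive-field-31 classifier on one simulated bacterial colony
and segment a held-out colony:

```python
import numpy as np
from cellsegnet import (ColonyMovieSpec, generate_bacteria_colony_movie,
                        normalize_for_network, sample_balanced,
                        classmap_from_annotation, PatchClassifier, TrainConfig,
                        predict_scoremap, threshold_mask, match_objects,
                        aggregate_indices, lap_link, instantaneous_growth_rate,
                        area_change_error_rate)
from cellsegnet.data import concat_datasets
from cellsegnet.network import TEST_FAMILY

spec = ColonyMovieSpec(initial_cells=8, relative_growth_rate=0.13,
                       division_length=34.0, frames=12, seed=10)
movie, truth = generate_bacteria_colony_movie(spec)

parts = []
for f in range(6, 12):
    image = normalize_for_network(movie[f], receptive_field=31)
    classes = classmap_from_annotation(truth.instance_masks[f])
    parts.append(sample_balanced(classes, image.pixels, patch_size=31,
                                 per_class_cap=1150, seed=f))
dataset = concat_datasets(parts)          # ~20k balanced patches

model = PatchClassifier(dataset, TEST_FAMILY[31])
results = model.fit(TrainConfig(epochs=6, seed=0))
print(results.summary())
```

```
Patch classifier training results
=================================
receptive field:      31 px
conv rounds:          3 [(4, 8, True), (5, 16, True), (5, 16, False)]
fully connected:      q=2, widths (64,)
classes:              3
batch norm / dropout: True / 0.0
optimizer:            rmsprop (lr=0.001, lambda=1e-05)
epochs:               6
final errors:         train 0.0322, validation 0.0356
```

The classifier misclassifies ~3.6% of held-out patches. Segment a colony
it has never seen and score it per cell:

```python
held_out, held_truth = generate_bacteria_colony_movie(
    ColonyMovieSpec(initial_cells=6, relative_growth_rate=0.13,
                    division_length=34.0, frames=11, seed=777))
image = normalize_for_network(held_out[-1], receptive_field=31)
scores = predict_scoremap(image, results)
mask = threshold_mask(scores, threshold=0.6, min_area=20, grow_px=1)
reference = held_truth.instance_masks[-1]
summary = aggregate_indices(match_objects(reference, mask), reference, mask)
print(f"cells: {summary.n_reference} matched: {summary.n_matched}")
print(f"mean JI: {summary.mean_ji:.3f}  mean DI: {summary.mean_di:.3f}")

lineage = lap_link(held_truth.instance_masks, max_displacement=25)
rates = instantaneous_growth_rate(lineage)
jumps = area_change_error_rate(lineage)
print(f"tracks: {len(lineage.cells)}  divisions: {len(lineage.divisions)}")
print(f"median growth rate: {rates[~rates.division].rate.median():.3f} per frame")
print(f"area-jump error rate: {jumps.display}%")
```

```
cells: 12 matched: 11
mean JI: 0.784  mean DI: 0.840
tracks: 18  divisions: 6
median growth rate: 0.132 per frame
area-jump error rate: 0.0%
```

Eleven of twelve cells are recovered with mean per-cell Jaccard 0.78
(unmatched cells count as 0; the matched-only mean is higher), tracking
of the ground-truth masks reconstructs all 18 tracks and 6 divisions, the
median instantaneous growth rate recovers the simulated 0.13 per frame,
and no cell-frame shows a ≥30% area jump — the movie-level signature of
merge errors.

The same stages are scriptable from the shell:

```bash
cellsegnet simulate --kind colony --seed 4 --out runs/sim
cellsegnet train    --config train.yaml --out runs/model
cellsegnet segment  --model runs/model/model.npz \
                    --image runs/sim/channels.tif --frame 9 --out runs/seg
cellsegnet evaluate --reference runs/sim/instance_masks.tif \
                    --computed runs/sim/instance_masks.tif --out runs/eval
cellsegnet track    --masks runs/sim/instance_masks.tif --out runs/tracks
```

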