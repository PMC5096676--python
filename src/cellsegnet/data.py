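"""Training-data construction: class maps, balanced patch sampling,
and dihedral-8 augmentation.

An instance-annotated image (integer label per cell, 0 background) is first
converted to a per-pixel class map over {background, boundary, interior} —
optionally {background, boundary, interior_A, interior_B} for co-culture
semantic segmentation.  Patches centered on annotated pixels are then sampled
with equal per-class representation; patches themselves are extracted lazily
at batch-assembly time, and augmentation (the 8 rotations/reflections of the
square) is applied on the fly so the stored dataset stays small.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BACKGROUND",
    "BOUNDARY",
    "INTERIOR",
    "INTERIOR_B",
    "ClassMap",
    "PatchDataset",
    "classmap_from_annotation",
    "sample_balanced",
    "extract_patch",
    "augment",
    "apply_dihedral",
]

BACKGROUND, BOUNDARY, INTERIOR, INTERIOR_B = 0, 1, 2, 3

#: per-class sampling cap sized so a full-scale annotated image yields a
#: dataset of roughly 3 x 100k = 300k patches
DEFAULT_PER_CLASS_CAP = 100_000

VALIDATION_FRACTION = 0.10

_SHIFTS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class ClassMap:
    """Per-pixel class labels: 0 background, 1 boundary, 2 interior
    (3 = second interior class in 4-class co-culture mode)."""

    labels: np.ndarray
    n_classes: int = 3

    def __post_init__(self) -> None:
        if self.n_classes not in (3, 4):
            raise ValueError("n_classes must be 3 or 4")
        if self.labels.min() < 0 or self.labels.max() >= self.n_classes:
            raise ValueError("labels out of range for n_classes")

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.n_classes)


def classmap_from_annotation(
    instance_mask: np.ndarray,
    boundary_width: int = 1,
    cell_types: dict[int, int] | None = None,
) -> ClassMap:
    """Derive a class map from an integer-labeled instance mask.

    A cell pixel is boundary when any of its 8 neighbors belongs to
    background or to a different cell; the 1-px boundary so obtained is
    dilated (within cell pixels) to ``boundary_width``.  Remaining cell
    pixels are interior; everything else is background.

    When ``cell_types`` maps instance label -> type index (0 or 1), interior
    pixels are split into two classes (4-class semantic mode).
    """
    mask = np.asarray(instance_mask)
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("instance mask must be integer-labeled")
    if boundary_width < 1:
        raise ValueError("boundary_width must be >= 1")
    cells = mask > 0
    padded = np.pad(mask, 1, mode="edge")
    boundary = np.zeros_like(cells)
    for dr, dc in _SHIFTS_8:
        neigh = padded[1 + dr : padded.shape[0] - 1 + dr,
                       1 + dc : padded.shape[1] - 1 + dc]
        boundary |= cells & (neigh != mask)
    for _ in range(boundary_width - 1):
        grown = np.zeros_like(boundary)
        bp = np.pad(boundary, 1, mode="constant")
        for dr, dc in _SHIFTS_8:
            grown |= bp[1 + dr : bp.shape[0] - 1 + dr,
                        1 + dc : bp.shape[1] - 1 + dc]
        boundary = (boundary | grown) & cells

    labels = np.zeros(mask.shape, dtype=np.uint8)
    labels[cells] = INTERIOR
    labels[boundary] = BOUNDARY
    n_classes = 3
    if cell_types is not None:
        n_classes = 4
        interior = cells & ~boundary
        for inst, t in cell_types.items():
            if t not in (0, 1):
                raise ValueError("cell types must be 0 or 1")
            if t == 1:
                labels[interior & (mask == inst)] = INTERIOR_B
    return ClassMap(labels=labels, n_classes=n_classes)


def extract_patch(image: np.ndarray, row: int, col: int, patch_size: int) -> np.ndarray:
    """Extract the (channels, patch_size, patch_size) patch centered on
    (row, col); raises if the patch extends outside the image."""
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = arr[None]
    half = patch_size // 2
    r0, c0 = row - half, col - half
    r1, c1 = r0 + patch_size, c0 + patch_size
    if r0 < 0 or c0 < 0 or r1 > arr.shape[1] or c1 > arr.shape[2]:
        raise ValueError(
            f"patch of size {patch_size} at ({row}, {col}) is outside "
            f"image of shape {arr.shape[1:]}"
        )
    return arr[:, r0:r1, c0:c1]


def apply_dihedral(patch: np.ndarray, transform: int) -> np.ndarray:
    """Apply one of the 8 symmetries of the square (index 0..7) to the
    trailing two axes: transform = 4*flip + rotation."""
    if not 0 <= transform < 8:
        raise ValueError("transform index must be in 0..7")
    k, flip = transform % 4, transform // 4
    out = patch
    if flip:
        out = out[..., ::-1]
    return np.rot90(out, k=k, axes=(-2, -1))


def augment(patch: np.ndarray, label: int, rng: np.random.Generator):
    """Randomly rotate the patch by 0/90/180/270 degrees and randomly
    reflect it; the class label is invariant under these transforms."""
    if patch.shape[-1] != patch.shape[-2]:
        raise ValueError("augmentation requires a square patch")
    t = int(rng.integers(8))
    return apply_dihedral(patch, t), label


@dataclass
class PatchDataset:
    """Class-balanced patch samples referencing normalized source images.

    Patches are stored as (row, col, class) indices into ``images`` (one
    (channels, rows, cols) stack per source scene, with a parallel
    ``image_index`` per sample) and are materialized only when batches are
    assembled.
    """

    images: list[np.ndarray]
    patch_size: int
    image_index: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    labels: np.ndarray
    is_validation: np.ndarray
    n_classes: int
    seed: int
    augmentation: bool = True

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_train(self) -> int:
        return int((~self.is_validation).sum())

    @property
    def n_validation(self) -> int:
        return int(self.is_validation.sum())

    @property
    def input_channels(self) -> int:
        return self.images[0].shape[0]

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def _materialize(self, idx: np.ndarray, rng: np.random.Generator | None):
        n = len(idx)
        X = np.empty(
            (n, self.input_channels, self.patch_size, self.patch_size), dtype=float
        )
        for i, j in enumerate(idx):
            p = extract_patch(
                self.images[self.image_index[j]],
                int(self.rows[j]), int(self.cols[j]), self.patch_size,
            )
            if self.augmentation and rng is not None:
                p, _ = augment(p, int(self.labels[j]), rng)
            X[i] = p
        return X, self.labels[idx].astype(np.int64)

    def training_batches(self, batch_size: int, rng: np.random.Generator):
        """Yield shuffled, on-the-fly-augmented (X, y) training batches."""
        idx = np.flatnonzero(~self.is_validation)
        rng.shuffle(idx)
        for start in range(0, len(idx), batch_size):
            yield self._materialize(idx[start : start + batch_size], rng)

    def validation_set(self, batch_size: int = 1024):
        """Yield un-augmented validation batches."""
        idx = np.flatnonzero(self.is_validation)
        for start in range(0, len(idx), batch_size):
            yield self._materialize(idx[start : start + batch_size], None)

    def to_manifest(self, path: str | Path, image_paths: list[str]) -> None:
        payload = {
            "patch_size": self.patch_size,
            "n_classes": self.n_classes,
            "seed": self.seed,
            "augmentation": self.augmentation,
            "images": image_paths,
            "image_index": self.image_index.tolist(),
            "rows": self.rows.tolist(),
            "cols": self.cols.tolist(),
            "labels": self.labels.tolist(),
            "is_validation": self.is_validation.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def sample_balanced(
    classmap: ClassMap,
    image: np.ndarray,
    patch_size: int,
    per_class_cap: int = DEFAULT_PER_CLASS_CAP,
    seed: int = 0,
    augmentation: bool = True,
) -> PatchDataset:
    """Sample patch centers uniformly without replacement so every class has
    equal representation: min(smallest class availability, per_class_cap)
    samples per class.  Only pixels whose patch lies fully inside the image
    are eligible.  A stratified 10% of each class is held out as validation.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    labels_img = classmap.labels
    if labels_img.shape != arr.shape[1:]:
        raise ValueError("class map and image shapes differ")
    half = patch_size // 2
    eligible = np.zeros(labels_img.shape, dtype=bool)
    eligible[half : labels_img.shape[0] - half, half : labels_img.shape[1] - half] = True

    rng = np.random.default_rng(seed)
    per_class = []
    for c in range(classmap.n_classes):
        locs = np.argwhere((labels_img == c) & eligible)
        if len(locs) == 0:
            raise ValueError(f"class {c} has no eligible pixel for patch sampling")
        per_class.append(locs)
    n_per_class = min(min(len(p) for p in per_class), per_class_cap)

    rows, cols, labels, is_val = [], [], [], []
    for c, locs in enumerate(per_class):
        pick = rng.choice(len(locs), size=n_per_class, replace=False)
        chosen = locs[pick]
        n_val = int(round(VALIDATION_FRACTION * n_per_class))
        val_flags = np.zeros(n_per_class, dtype=bool)
        val_flags[:n_val] = True  # chosen order is already random
        rows.append(chosen[:, 0])
        cols.append(chosen[:, 1])
        labels.append(np.full(n_per_class, c, dtype=np.int64))
        is_val.append(val_flags)

    return PatchDataset(
        images=[arr],
        patch_size=patch_size,
        image_index=np.zeros(classmap.n_classes * n_per_class, dtype=np.int64),
        rows=np.concatenate(rows),
        cols=np.concatenate(cols),
        labels=np.concatenate(labels),
        is_validation=np.concatenate(is_val),
        n_classes=classmap.n_classes,
        seed=seed,
        augmentation=augmentation,
    )


def concat_datasets(datasets: list[PatchDataset]) -> PatchDataset:
    """Merge datasets sampled from different scenes (same patch geometry)."""
    first = datasets[0]
    if any(d.patch_size != first.patch_size or d.n_classes != first.n_classes
           for d in datasets):
        raise ValueError("datasets must share patch_size and n_classes")
    images: list[np.ndarray] = []
    index_parts = []
    for d in datasets:
        offset = len(images)
        images.extend(d.images)
        index_parts.append(d.image_index + offset)
    return PatchDataset(
        images=images,
        patch_size=first.patch_size,
        image_index=np.concatenate(index_parts),
        rows=np.concatenate([d.rows for d in datasets]),
        cols=np.concatenate([d.cols for d in datasets]),
        labels=np.concatenate([d.labels for d in datasets]),
        is_validation=np.concatenate([d.is_validation for d in datasets]),
        n_classes=first.n_classes,
        seed=first.seed,
        augmentation=first.augmentation,
    )
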