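"""Synthetic live-cell microscopy with exact ground truth.

Four data regimes are emulated, mirroring the kinds of images the
segmentation pipeline is meant for:

* phase-contrast movies of growing rod-shaped bacterial micro-colonies,
  with exponential single-cell growth and division into two daughters;
* mammalian-like scenes: textured-cytoplasm blobs in a phase channel plus
  a bright-nucleus fluorescence channel;
* co-cultures of two morphology classes (elongated vs round cells with
  distinct textures), with the true type of every instance recorded;
* kinase-translocation-reporter movies in which each cell's cytoplasm has
  two compartments and only the perinuclear one exchanges fluorescence
  with the nucleus.

Cells are minimal parametric shapes — capsules (rectangles with
semicircular caps) for rods, ellipses perturbed by low-order radial
harmonics for mammalian cells — rendered with a simple phase-contrast
model: interiors darker than background, a 1-2 px bright halo, Gaussian
blur, and additive Gaussian noise.  Every generator derives a single
global RNG from its spec seed, so identical specs give bit-identical
output, and every image comes with instance masks, class maps, and (for
movies) a ground-truth lineage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter
from scipy.ndimage import binary_dilation
from skimage.morphology import disk

from .data import ClassMap, classmap_from_annotation
from .tracking import Lineage

__all__ = [
    "SceneSpec",
    "ColonyMovieSpec",
    "KTRMovieSpec",
    "GroundTruth",
    "generate_bacteria_colony_movie",
    "generate_mammalian_scene",
    "generate_coculture_scene",
    "generate_ktr_movie",
    "save_scene",
]

MORPHOLOGIES = ("rod", "blob_A", "blob_B")

#: phase appearance of the two mammalian morphology classes
_BLOB_STYLE = {
    "blob_A": {"axis_ratio": 2.6, "depth": 0.38, "tex_sigma": 2.5, "tex_amp": 0.05},
    "blob_B": {"axis_ratio": 1.05, "depth": 0.18, "tex_sigma": 0.9, "tex_amp": 0.13},
}


@dataclass(frozen=True)
class SceneSpec:
    """A single synthetic scene.

    ``halo_strength`` scales the bright phase halo around cells;
    ``cell_radius`` is the short semi-axis scale of mammalian blobs (px).
    """

    image_shape: tuple[int, int] = (256, 256)
    cell_count: int = 8
    morphology: str = "blob_A"
    noise_sd: float = 0.05
    halo_strength: float = 0.25
    seed: int = 0
    cell_radius: float = 11.0
    nucleus_radius_frac: float = 0.42

    def __post_init__(self) -> None:
        if min(self.image_shape) < 64:
            raise ValueError("image_shape must be at least (64, 64)")
        if self.cell_count < 0:
            raise ValueError("cell_count must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.morphology not in MORPHOLOGIES:
            raise ValueError(f"morphology must be one of {MORPHOLOGIES}")


@dataclass(frozen=True)
class ColonyMovieSpec:
    """A growing bacterial micro-colony time-lapse.

    ``relative_growth_rate`` is the per-frame fractional area increase of
    every cell; a rod divides when its total length (caps included)
    reaches ``division_length``.
    """

    initial_cells: int = 2
    relative_growth_rate: float = 0.05
    division_length: float = 36.0
    frames: int = 10
    seed: int = 0
    image_shape: tuple[int, int] = (256, 256)
    rod_radius: float = 4.0
    noise_sd: float = 0.03
    halo_strength: float = 0.3
    initial_length: float | None = None  # default: U(0.55, 0.8) x division_length

    def __post_init__(self) -> None:
        if not 0 <= self.relative_growth_rate <= 0.5:
            raise ValueError("relative_growth_rate must be in [0, 0.5]")
        if self.frames < 2:
            raise ValueError("frames must be >= 2")
        if self.initial_cells < 1:
            raise ValueError("initial_cells must be >= 1")


@dataclass(frozen=True)
class KTRMovieSpec:
    """A two-compartment translocation-reporter movie.

    Each (static) cell has a nucleus, a perinuclear "near" compartment of
    width ``near_width`` px that exchanges reporter with the nucleus, and
    a "far" compartment whose per-pixel mean stays at ``far_mean``.  When
    the nuclear fraction is 0 the near compartment's per-pixel mean is
    ``near_mean_max``; total reporter per cell is conserved by
    construction."""

    cell_count: int = 3
    image_shape: tuple[int, int] = (256, 256)
    seed: int = 0
    noise_sd: float = 0.03
    cell_radius: float = 28.0
    nucleus_radius: float = 9.0
    near_width: float = 7.0
    far_mean: float = 1.0
    near_mean_max: float = 3.0
    background: float = 0.02

    def __post_init__(self) -> None:
        if min(self.image_shape) < 64:
            raise ValueError("image_shape must be at least (64, 64)")
        if self.cell_count < 1:
            raise ValueError("cell_count must be >= 1")


@dataclass
class GroundTruth:
    """Exact per-frame truth for a generated scene or movie."""

    instance_masks: list[np.ndarray]
    class_maps: list[ClassMap]
    lineage: Lineage | None = None
    per_cell_type: dict[int, int] | None = None
    nucleus_masks: list[np.ndarray] | None = None
    compartments: dict | None = None
    truncated: bool = False

    @property
    def n_frames(self) -> int:
        return len(self.instance_masks)


# ---------------------------------------------------------------------------
# rods

@dataclass
class _Rod:
    cell_id: int
    center: np.ndarray  # (row, col)
    theta: float
    area: float  # analytic capsule area
    rho: float
    split_from: "_Rod | None" = None  # set during the frame a division renders
    split_side: int = 0

    @property
    def rect_len(self) -> float:
        return max((self.area - np.pi * self.rho ** 2) / (2 * self.rho), 0.1)

    @property
    def length(self) -> float:
        return self.rect_len + 2 * self.rho

    @property
    def axis(self) -> np.ndarray:
        return np.array([np.cos(self.theta), np.sin(self.theta)])

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        h = 0.5 * self.rect_len * self.axis
        return self.center - h, self.center + h


def _segment_distance_field(shape, p0, p1):
    """Distance from every pixel center to the segment p0-p1."""
    rows, cols = np.mgrid[: shape[0], : shape[1]]
    p = np.stack([rows, cols], axis=-1).astype(float)
    d = p1 - p0
    den = float(d @ d)
    if den < 1e-12:
        return np.linalg.norm(p - p0, axis=-1)
    t = np.clip(((p - p0) @ d) / den, 0.0, 1.0)
    proj = p0 + t[..., None] * d
    return np.linalg.norm(p - proj, axis=-1)


def _render_rod_masks(rods: list[_Rod], shape) -> np.ndarray:
    """Instance mask: each pixel goes to the rod whose surface it is
    deepest inside (signed distance), so masks are pairwise disjoint."""
    best = np.full(shape, np.inf)
    labels = np.zeros(shape, dtype=np.int32)
    for rod in rods:
        if rod.split_from is not None:
            parent = rod.split_from
            p0, p1 = parent.endpoints()
            val = _segment_distance_field(shape, p0, p1) - parent.rho
            rows, cols = np.mgrid[: shape[0], : shape[1]]
            axial = ((rows - parent.center[0]) * parent.axis[0]
                     + (cols - parent.center[1]) * parent.axis[1])
            side_ok = axial < 0 if rod.split_side < 0 else axial >= 0
            val = np.where(side_ok, val, np.inf)
        else:
            p0, p1 = rod.endpoints()
            val = _segment_distance_field(shape, p0, p1) - rod.rho
        take = (val < 0) & (val < best)
        labels[take] = rod.cell_id
        best = np.where(take, val, best)
    return labels


def _relax_rods(rods: list[_Rod], shape, iterations: int = 40) -> None:
    """Push overlapping capsules apart (skipping frozen split daughters)."""
    movable = [r for r in rods if r.split_from is None]
    for _ in range(iterations):
        moved = False
        for i in range(len(movable)):
            for j in range(i + 1, len(movable)):
                a, b = movable[i], movable[j]
                dist, pa, pb = _segment_segment_distance(a, b)
                overlap = a.rho + b.rho + 0.6 - dist
                if overlap > 0:
                    moved = True
                    direction = b.center - a.center
                    nrm = np.linalg.norm(direction)
                    direction = direction / nrm if nrm > 1e-9 else np.array([1.0, 0.0])
                    a.center = a.center - 0.5 * overlap * direction
                    b.center = b.center + 0.5 * overlap * direction
        if not moved:
            break


def _segment_segment_distance(a: _Rod, b: _Rod):
    """Minimum distance between the axis segments of two rods (sampled)."""
    a0, a1 = a.endpoints()
    b0, b1 = b.endpoints()
    ts = np.linspace(0.0, 1.0, 9)
    pa = a0[None] + ts[:, None] * (a1 - a0)[None]
    pb = b0[None] + ts[:, None] * (b1 - b0)[None]
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return float(d[i, j]), pa[i], pb[j]


def _outside_frame(rod: _Rod, shape, margin: float = 2.0) -> bool:
    p0, p1 = rod.endpoints()
    for p in (p0, p1):
        if (p[0] - rod.rho < margin or p[1] - rod.rho < margin
                or p[0] + rod.rho > shape[0] - margin
                or p[1] + rod.rho > shape[1] - margin):
            return True
    return False


def _render_phase(cell_mask: np.ndarray, interior_intensity: np.ndarray | float,
                  halo_strength: float, noise_sd: float,
                  rng: np.random.Generator, blur: float = 0.7) -> np.ndarray:
    img = np.ones(cell_mask.shape, dtype=float)
    if np.isscalar(interior_intensity):
        img[cell_mask] = interior_intensity
    else:
        img[cell_mask] = interior_intensity[cell_mask]
    halo = binary_dilation(cell_mask, structure=disk(2)) & ~cell_mask
    img[halo] += halo_strength
    img = gaussian_filter(img, blur)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img


def _observe(lineage: Lineage, mask: np.ndarray, frame: int) -> None:
    for lbl in np.unique(mask):
        if lbl == 0:
            continue
        pts = np.argwhere(mask == lbl)
        lineage.add_observation(int(lbl), frame, len(pts), pts.mean(axis=0))


def generate_bacteria_colony_movie(spec: ColonyMovieSpec):
    """Simulate a growing rod-shaped micro-colony.

    Every cell's area grows by ``relative_growth_rate`` per frame (so area
    follows A0 (1+g)^t exactly in the analytic model); a rod reaching
    ``division_length`` divides at its midplane, and at the division frame
    the two daughters exactly tile the parent's previous footprint, so
    daughter areas sum to the parent's area.  If the colony reaches the
    frame edge the movie stops early with ``truncated=True``.

    Returns ``(movie, GroundTruth)`` with ``movie`` of shape
    (frames, rows, cols).
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    lineage = Lineage()
    rods: list[_Rod] = []
    center = np.array(shape, dtype=float) / 2
    for i in range(spec.initial_cells):
        track = lineage.new_track()
        if spec.initial_length is not None:
            length = spec.initial_length * rng.uniform(0.9, 1.1)
        else:
            length = spec.division_length * rng.uniform(0.55, 0.8)
        rect = length - 2 * spec.rod_radius
        area = 2 * spec.rod_radius * rect + np.pi * spec.rod_radius ** 2
        offset = rng.normal(0.0, 6.0 + 4.0 * i, size=2)
        rods.append(_Rod(cell_id=track.cell_id, center=center + offset,
                         theta=rng.uniform(0, np.pi), area=area,
                         rho=spec.rod_radius))
    _relax_rods(rods, shape)

    frames_img: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    truncated = False
    for t in range(spec.frames):
        if t > 0:
            # divide first (daughters tile the parent's last footprint,
            # frozen this frame), then grow and relax the others
            new_rods: list[_Rod] = []
            for rod in rods:
                if rod.length >= spec.division_length:
                    parent_copy = _Rod(rod.cell_id, rod.center.copy(), rod.theta,
                                       rod.area, rod.rho)
                    jitter = rng.normal(0.0, 0.06, size=2)
                    daughters = []
                    for side, jit in zip((-1, 1), jitter):
                        track = lineage.new_track(parent_id=rod.cell_id)
                        d = _Rod(
                            cell_id=track.cell_id,
                            center=rod.center + side * 0.25 * rod.length * rod.axis,
                            theta=rod.theta + jit,
                            area=rod.area / 2,
                            rho=rod.rho,
                            split_from=parent_copy,
                            split_side=side,
                        )
                        daughters.append(d)
                    lineage.record_division(rod.cell_id, daughters[0].cell_id,
                                            daughters[1].cell_id, t)
                    new_rods.extend(daughters)
                else:
                    rod.area *= 1 + spec.relative_growth_rate
                    new_rods.append(rod)
            rods = new_rods
            _relax_rods(rods, shape)
        if any(_outside_frame(r, shape) for r in rods):
            truncated = True
            break
        mask = _render_rod_masks(rods, shape)
        masks.append(mask)
        _observe(lineage, mask, t)
        frames_img.append(
            _render_phase(mask > 0, 0.45, spec.halo_strength, spec.noise_sd, rng)
        )
        for rod in rods:  # unfreeze split daughters after their first frame
            rod.split_from = None
    if not frames_img:
        raise ValueError("colony does not fit inside the frame at all")
    movie = np.stack(frames_img)
    class_maps = [classmap_from_annotation(m) for m in masks]
    gt = GroundTruth(instance_masks=masks, class_maps=class_maps,
                     lineage=lineage, truncated=truncated)
    return movie, gt


# ---------------------------------------------------------------------------
# mammalian blobs

@dataclass
class _Blob:
    cell_id: int
    center: np.ndarray
    phi: float
    a: float  # long semi-axis
    b: float  # short semi-axis
    eps: np.ndarray  # harmonic amplitudes, orders 2..4
    phases: np.ndarray
    morphology: str = "blob_B"
    nucleus_center: np.ndarray = field(default_factory=lambda: np.zeros(2))
    nucleus_r: float = 4.0

    @property
    def max_radius(self) -> float:
        return self.a * (1 + float(np.abs(self.eps).sum()))


def _blob_mask(blob: _Blob, shape) -> np.ndarray:
    rows, cols = np.mgrid[: shape[0], : shape[1]]
    dr = rows - blob.center[0]
    dc = cols - blob.center[1]
    x = dr * np.cos(blob.phi) + dc * np.sin(blob.phi)
    y = -dr * np.sin(blob.phi) + dc * np.cos(blob.phi)
    theta = np.arctan2(y, x)
    rho = np.hypot(x, y)
    r_ell = blob.a * blob.b / np.sqrt(
        (blob.b * np.cos(theta)) ** 2 + (blob.a * np.sin(theta)) ** 2
    )
    mod = np.ones_like(theta)
    for k, (e, ph) in enumerate(zip(blob.eps, blob.phases), start=2):
        mod += e * np.cos(k * theta + ph)
    return rho <= r_ell * mod


def _nucleus_mask(blob: _Blob, shape) -> np.ndarray:
    rows, cols = np.mgrid[: shape[0], : shape[1]]
    dr = rows - blob.nucleus_center[0]
    dc = cols - blob.nucleus_center[1]
    x = dr * np.cos(blob.phi) + dc * np.sin(blob.phi)
    y = -dr * np.sin(blob.phi) + dc * np.cos(blob.phi)
    elong = 1.3 if blob.a / blob.b > 1.5 else 1.05
    return (x / (blob.nucleus_r * elong)) ** 2 + (y / blob.nucleus_r) ** 2 <= 1.0


def _place_blobs(specs_and_counts, shape, rng, retry_cap: int = 200):
    """Rejection-sample non-overlapping blob centers for a mixed scene;
    returns a list of (_Blob, type_index)."""
    blobs: list[tuple[_Blob, int]] = []
    next_id = 1
    for type_idx, (spec, count) in enumerate(specs_and_counts):
        style = _BLOB_STYLE[spec.morphology]
        for _ in range(count):
            placed = False
            for _attempt in range(retry_cap):
                b_ax = spec.cell_radius * rng.uniform(0.85, 1.15)
                a_ax = b_ax * style["axis_ratio"] * rng.uniform(0.9, 1.1)
                eps = rng.normal(0.0, 0.025, size=3)
                phases = rng.uniform(0, 2 * np.pi, size=3)
                margin = a_ax * 1.2 + 3
                if 2 * margin >= min(shape):
                    raise RuntimeError(
                        f"cells of morphology {spec.morphology} are too large "
                        f"for this density/image size (retry cap reached)"
                    )
                center = np.array([
                    rng.uniform(margin, shape[0] - margin),
                    rng.uniform(margin, shape[1] - margin),
                ])
                cand = _Blob(cell_id=next_id, center=center,
                             phi=rng.uniform(0, np.pi), a=a_ax, b=b_ax,
                             eps=eps, phases=phases, morphology=spec.morphology)
                ok = all(
                    np.linalg.norm(center - other.center)
                    > 0.95 * (cand.max_radius + other.max_radius)
                    for other, _ in blobs
                )
                if ok:
                    nuc_off = rng.normal(0.0, 0.12 * b_ax, size=2)
                    cand.nucleus_center = center + np.clip(nuc_off, -0.25 * b_ax,
                                                           0.25 * b_ax)
                    cand.nucleus_r = spec.nucleus_radius_frac * b_ax
                    blobs.append((cand, type_idx))
                    next_id += 1
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place {count} cells of morphology "
                    f"{spec.morphology} at this density (retry cap reached)"
                )
    return blobs


def _render_blob_scene(blobs, shape, rng, noise_sd, halo_strength):
    """Instance/nucleus masks plus phase and nuclear channels."""
    instance = np.zeros(shape, dtype=np.int32)
    nuclei = np.zeros(shape, dtype=np.int32)
    interior = np.ones(shape, dtype=float)
    # per-type texture fields, shared across cells of the same type
    textures = {}
    for blob, type_idx in blobs:
        style = _BLOB_STYLE[blob.morphology]
        if type_idx not in textures:
            white = rng.normal(0.0, 1.0, size=shape)
            tex = gaussian_filter(white, style["tex_sigma"])
            tex /= tex.std() + 1e-12
            textures[type_idx] = tex * style["tex_amp"]
        m = _blob_mask(blob, shape) & (instance == 0)
        instance[m] = blob.cell_id
        interior[m] = (1 - style["depth"]) + textures[type_idx][m]
        nm = _nucleus_mask(blob, shape) & m
        nuclei[nm] = blob.cell_id
    phase = _render_phase(instance > 0, interior, halo_strength, noise_sd, rng)
    nuclear = np.full(shape, 0.05)
    nuclear[nuclei > 0] = 1.0
    nuclear = gaussian_filter(nuclear, 0.8)
    if noise_sd > 0:
        nuclear = nuclear + rng.normal(0.0, noise_sd, size=shape)
    return instance, nuclei, phase, nuclear


def generate_mammalian_scene(spec: SceneSpec):
    """One mammalian-like scene: perturbed-ellipse cytoplasms in a phase
    channel, each containing exactly one bright nucleus in a second
    (fluorescence) channel.

    Returns ``(channels, GroundTruth)`` with ``channels`` of shape
    (2, rows, cols): phase first, nuclear second.
    """
    if spec.morphology not in ("blob_A", "blob_B"):
        raise ValueError("mammalian scenes require morphology blob_A or blob_B")
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    blobs = _place_blobs([(spec, spec.cell_count)], shape, rng)
    instance, nuclei, phase, nuclear = _render_blob_scene(
        blobs, shape, rng, spec.noise_sd, spec.halo_strength
    )
    gt = GroundTruth(
        instance_masks=[instance],
        class_maps=[classmap_from_annotation(instance)],
        nucleus_masks=[nuclei],
    )
    return np.stack([phase, nuclear]), gt


def generate_coculture_scene(spec_A: SceneSpec, spec_B: SceneSpec):
    """A mixed scene of two morphology classes.

    ``per_cell_type`` in the returned ground truth maps every instance id
    to its class (0 for A, 1 for B), and the class map uses 4 classes so
    the two interiors are distinguishable.  The master seed is spec_A's.
    """
    if spec_A.morphology == spec_B.morphology:
        raise ValueError("co-culture requires two distinct morphologies")
    rng = np.random.default_rng(spec_A.seed)
    shape = spec_A.image_shape
    blobs = _place_blobs(
        [(spec_A, spec_A.cell_count), (spec_B, spec_B.cell_count)], shape, rng
    )
    instance, nuclei, phase, nuclear = _render_blob_scene(
        blobs, shape, rng, spec_A.noise_sd, spec_A.halo_strength
    )
    per_cell_type = {blob.cell_id: t for blob, t in blobs}
    gt = GroundTruth(
        instance_masks=[instance],
        class_maps=[classmap_from_annotation(instance, cell_types=per_cell_type)],
        per_cell_type=per_cell_type,
        nucleus_masks=[nuclei],
    )
    return np.stack([phase, nuclear]), gt


# ---------------------------------------------------------------------------
# KTR movies

def generate_ktr_movie(nuclear_fraction, spec: KTRMovieSpec):
    """Simulate a translocation-reporter movie with a two-compartment
    cytoplasm.

    ``nuclear_fraction`` gives, per frame, the fraction (in [0, 1]) of the
    exchangeable reporter pool residing in the nucleus; the rest sits in
    the perinuclear ("near") compartment, while the distal ("far")
    compartment keeps a constant per-pixel mean.  Total reporter per cell
    is conserved across frames before noise.

    Returns ``(nuclear_marker_movie, reporter_movie, GroundTruth)``;
    compartment instance masks are in ``GroundTruth.compartments`` under
    keys "nucleus", "near", "far".
    """
    schedule = np.asarray(nuclear_fraction, dtype=float)
    if schedule.ndim != 1 or len(schedule) < 1:
        raise ValueError("nuclear_fraction must be a 1-D schedule")
    if schedule.min() < 0 or schedule.max() > 1:
        raise ValueError("nuclear fractions must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape

    scene = SceneSpec(
        image_shape=shape, cell_count=spec.cell_count, morphology="blob_B",
        noise_sd=spec.noise_sd, seed=spec.seed, cell_radius=spec.cell_radius,
        nucleus_radius_frac=spec.nucleus_radius / spec.cell_radius,
    )
    blobs = _place_blobs([(scene, scene.cell_count)], shape, rng)
    instance = np.zeros(shape, dtype=np.int32)
    nuclei = np.zeros(shape, dtype=np.int32)
    near = np.zeros(shape, dtype=np.int32)
    far = np.zeros(shape, dtype=np.int32)
    selem = disk(int(round(spec.near_width)))
    for blob, _ in blobs:
        m = _blob_mask(blob, shape) & (instance == 0)
        instance[m] = blob.cell_id
        nm = _nucleus_mask(blob, shape) & m
        nuclei[nm] = blob.cell_id
        ring = binary_dilation(nm, structure=selem) & m & ~nm
        near[ring] = blob.cell_id
        far[m & ~nm & ~ring] = blob.cell_id

    nuclear_marker = np.full(shape, 0.05)
    nuclear_marker[nuclei > 0] = 1.0
    nuclear_marker = gaussian_filter(nuclear_marker, 0.8)

    marker_frames, reporter_frames = [], []
    for f in schedule:
        reporter = np.full(shape, spec.background)
        for blob, _ in blobs:
            cid = blob.cell_id
            n_near = int((near == cid).sum())
            n_nuc = int((nuclei == cid).sum())
            if n_nuc == 0 or n_near == 0:
                raise RuntimeError("degenerate cell without compartments")
            pool = spec.near_mean_max * n_near  # exchangeable amount
            reporter[far == cid] = spec.far_mean
            reporter[near == cid] = (1 - f) * pool / n_near
            reporter[nuclei == cid] = f * pool / n_nuc
        if spec.noise_sd > 0:
            reporter = reporter + rng.normal(0.0, spec.noise_sd, size=shape)
            marker = nuclear_marker + rng.normal(0.0, spec.noise_sd, size=shape)
        else:
            marker = nuclear_marker.copy()
        marker_frames.append(marker)
        reporter_frames.append(reporter)

    masks = [instance] * len(schedule)
    gt = GroundTruth(
        instance_masks=masks,
        class_maps=[classmap_from_annotation(instance)] * len(schedule),
        nucleus_masks=[nuclei] * len(schedule),
        compartments={"nucleus": nuclei, "near": near, "far": far,
                      "schedule": schedule},
    )
    return np.stack(marker_frames), np.stack(reporter_frames), gt


# ---------------------------------------------------------------------------
# persistence

def save_scene(outdir, channels: np.ndarray, gt: GroundTruth, spec) -> None:
    """Write channels (32-bit multi-page TIFF), instance masks (16-bit
    TIFF), the lineage as CSV, and a JSON echo of the spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "channels.tif",
                     np.asarray(channels, dtype=np.float32),
                     photometric="minisblack")
    masks = np.stack(gt.instance_masks).astype(np.uint16)
    tifffile.imwrite(outdir / "instance_masks.tif", masks,
                     photometric="minisblack")
    if gt.nucleus_masks is not None:
        tifffile.imwrite(outdir / "nucleus_masks.tif",
                         np.stack(gt.nucleus_masks).astype(np.uint16),
                         photometric="minisblack")
    if gt.lineage is not None:
        gt.lineage.to_csv(outdir / "lineage.csv")
    payload = asdict(spec) if hasattr(spec, "__dataclass_fields__") else dict(spec)
    if gt.per_cell_type is not None:
        payload["per_cell_type"] = {str(k): v for k, v in gt.per_cell_type.items()}
    payload["truncated"] = gt.truncated
    (outdir / "spec.json").write_text(json.dumps(payload))
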