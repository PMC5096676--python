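"""Frame-to-frame cell tracking and single-cell growth statistics.

Objects in consecutive instance masks are linked by solving a linear
assignment problem (LAP) in the Jaqaman style: link costs are squared
centroid displacements, gated at a maximum displacement, with birth/death
alternatives priced at a percentile of the observed link costs.  Divisions
are detected when a newly appearing object sits next to a linked object
whose area dropped sharply — a cell that suddenly "loses" ~50% of its area
has usually split in two.  The resulting lineage forest supports
instantaneous growth rates (relative area change per frame) and spatial
growth-rate maps at single-cell resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "CellTrack",
    "Lineage",
    "LapParams",
    "lap_link",
    "instantaneous_growth_rate",
    "growth_rate_map",
    "link_set",
    "division_set",
]

_BIG = 1e12


@dataclass
class CellTrack:
    cell_id: int
    parent_id: int | None = None
    frames: list[int] = field(default_factory=list)
    areas: list[float] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)

    def area_at(self, frame: int) -> float:
        return self.areas[self.frames.index(frame)]


class Lineage:
    """Per-cell tracks with parent links; a forest over cell ids.

    ``divisions`` holds (parent_id, daughter1_id, daughter2_id, frame)
    where ``frame`` is the first frame of the daughters; the parent's track
    ends on the previous frame.
    """

    def __init__(self) -> None:
        self.cells: dict[int, CellTrack] = {}
        self.divisions: list[tuple[int, int, int, int]] = []
        self._next_id = 1

    def new_track(self, parent_id: int | None = None) -> CellTrack:
        track = CellTrack(cell_id=self._next_id, parent_id=parent_id)
        self.cells[self._next_id] = track
        self._next_id += 1
        return track

    def add_observation(self, cell_id: int, frame: int, area: float,
                        centroid: tuple[float, float]) -> None:
        if area <= 0:
            raise ValueError("areas must be positive")
        t = self.cells[cell_id]
        t.frames.append(frame)
        t.areas.append(float(area))
        t.centroids.append((float(centroid[0]), float(centroid[1])))

    def record_division(self, parent: int, d1: int, d2: int, frame: int) -> None:
        self.divisions.append((parent, d1, d2, frame))

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_tracks(cls, areas_by_cell: dict[int, list[float]]) -> "Lineage":
        """Build a lineage from bare per-cell area series (frames 0..n-1,
        no parents); convenient for summary statistics on existing tracks."""
        lin = cls()
        for areas in areas_by_cell.values():
            t = lin.new_track()
            for f, a in enumerate(areas):
                lin.add_observation(t.cell_id, f, a, (0.0, 0.0))
        return lin

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Check the forest structure and division/track consistency."""
        for cid, t in self.cells.items():
            seen = {cid}
            p = t.parent_id
            while p is not None:
                if p in seen:
                    raise ValueError("lineage contains a cycle")
                seen.add(p)
                p = self.cells[p].parent_id
            if t.frames != sorted(t.frames):
                raise ValueError("track frames out of order")
        for parent, d1, d2, frame in self.divisions:
            if self.cells[parent].frames and self.cells[parent].frames[-1] != frame - 1:
                raise ValueError("parent track must end the frame before division")
            for d in (d1, d2):
                if self.cells[d].frames and self.cells[d].frames[0] != frame:
                    raise ValueError("daughter tracks must begin at the division frame")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.cells.values():
            for f, a, (cr, cc) in zip(t.frames, t.areas, t.centroids):
                rows.append(
                    {
                        "cell_id": t.cell_id,
                        "parent_id": -1 if t.parent_id is None else t.parent_id,
                        "frame": f,
                        "area": a,
                        "centroid_row": cr,
                        "centroid_col": cc,
                    }
                )
        return pd.DataFrame(rows).sort_values(["cell_id", "frame"]).reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json_forest(self) -> dict:
        return {
            "cells": {
                str(cid): {
                    "parent": t.parent_id,
                    "frames": t.frames,
                    "areas": t.areas,
                    "centroids": t.centroids,
                }
                for cid, t in self.cells.items()
            },
            "divisions": [list(d) for d in self.divisions],
        }


def _frame_objects(mask: np.ndarray):
    """Labels, areas and centroids of the instances in one mask."""
    labels = np.unique(mask)
    labels = labels[labels > 0]
    areas = np.empty(len(labels))
    centroids = np.empty((len(labels), 2))
    for i, lbl in enumerate(labels):
        pts = np.argwhere(mask == lbl)
        areas[i] = len(pts)
        centroids[i] = pts.mean(axis=0)
    return labels, areas, centroids


@dataclass
class LapParams:
    """LAP linking constants.

    ``max_displacement`` gates links (px); ``birth_cost_percentile`` prices
    the birth/death alternative at this percentile of the observed finite
    link costs (plus 5%) — the default of 100 makes any gated link
    preferable to a death/birth pair; ``division_area_drop`` is the
    fractional area loss that, together with an adjacent new object,
    signals a division.
    """

    max_displacement: float = 25.0
    birth_cost_percentile: float = 100.0
    division_area_drop: float = 0.30


def lap_link(masks: list[np.ndarray], max_displacement: float | None = None,
             params: LapParams | None = None) -> Lineage:
    """Link instance masks across frames into a lineage forest.

    Per frame pair, an augmented assignment matrix (links, births, deaths)
    is solved optimally; an unlinked new object adjacent to a linked object
    whose area dropped by ``division_area_drop`` or more is recorded as the
    second daughter of a division.
    """
    if len(masks) < 2:
        raise ValueError("tracking requires at least 2 frames")
    params = params or LapParams()
    if max_displacement is not None:
        params = LapParams(max_displacement=max_displacement,
                           birth_cost_percentile=params.birth_cost_percentile,
                           division_area_drop=params.division_area_drop)
    gate = params.max_displacement ** 2

    lineage = Lineage()
    labels, areas, cents = _frame_objects(masks[0])
    current: dict[int, int] = {}  # mask label -> cell id in current frame
    for i, lbl in enumerate(labels):
        t = lineage.new_track()
        lineage.add_observation(t.cell_id, 0, areas[i], cents[i])
        current[int(lbl)] = t.cell_id

    prev = (labels, areas, cents)
    for frame in range(1, len(masks)):
        labels_b, areas_b, cents_b = _frame_objects(masks[frame])
        labels_a, areas_a, cents_a = prev
        n, m = len(labels_a), len(labels_b)
        nxt: dict[int, int] = {}

        if n == 0 or m == 0:
            if m:
                warnings.warn(f"frame {frame - 1} empty; starting fresh tracks")
            for j in range(m):
                t = lineage.new_track()
                lineage.add_observation(t.cell_id, frame, areas_b[j], cents_b[j])
                nxt[int(labels_b[j])] = t.cell_id
            current = nxt
            prev = (labels_b, areas_b, cents_b)
            continue

        d2 = ((cents_a[:, None, :] - cents_b[None, :, :]) ** 2).sum(axis=2)
        cost = np.where(d2 <= gate, d2, _BIG)
        finite = d2[d2 <= gate]
        alt = (np.percentile(finite, params.birth_cost_percentile) * 1.05
               if finite.size else gate)
        alt = max(alt, 1e-6)
        big = np.full((n + m, n + m), _BIG)
        big[:n, :m] = cost
        big[np.arange(n), m + np.arange(n)] = alt  # deaths
        big[n + np.arange(m), np.arange(m)] = alt  # births
        big[n:, m:] = cost.T  # lower-right completion block
        rows, cols = linear_sum_assignment(big)

        links: list[tuple[int, int]] = []
        births: list[int] = []
        for r, c in zip(rows, cols):
            if r < n and c < m and cost[r, c] < _BIG:
                links.append((r, c))
            elif r >= n and c < m:
                births.append(c)

        # division detection: births adjacent to a linked object with a
        # >= division_area_drop area loss
        flagged = [
            (i, j) for i, j in links
            if (areas_a[i] - areas_b[j]) / areas_a[i] >= params.division_area_drop
        ]
        divisions: list[tuple[int, int, int]] = []  # (i_parent, j_d1, j_birth)
        used = set()
        for j2 in sorted(births):
            best = None
            for i, j in flagged:
                if j in used:
                    continue
                dist2 = ((cents_b[j] - cents_b[j2]) ** 2).sum()
                if dist2 <= gate and (best is None or dist2 < best[0]):
                    best = (dist2, i, j)
            if best is not None:
                used.add(best[2])
                divisions.append((best[1], best[2], j2))

        consumed_links = {(i, j) for i, j, _ in divisions}
        birth_in_division = {j2 for _, _, j2 in divisions}

        for i, j in links:
            if (i, j) in consumed_links:
                continue
            cid = current[int(labels_a[i])]
            lineage.add_observation(cid, frame, areas_b[j], cents_b[j])
            nxt[int(labels_b[j])] = cid
        for i, j, j2 in divisions:
            parent = current[int(labels_a[i])]
            t1 = lineage.new_track(parent_id=parent)
            t2 = lineage.new_track(parent_id=parent)
            lineage.add_observation(t1.cell_id, frame, areas_b[j], cents_b[j])
            lineage.add_observation(t2.cell_id, frame, areas_b[j2], cents_b[j2])
            lineage.record_division(parent, t1.cell_id, t2.cell_id, frame)
            nxt[int(labels_b[j])] = t1.cell_id
            nxt[int(labels_b[j2])] = t2.cell_id
        for j2 in births:
            if j2 in birth_in_division:
                continue
            t = lineage.new_track()
            lineage.add_observation(t.cell_id, frame, areas_b[j2], cents_b[j2])
            nxt[int(labels_b[j2])] = t.cell_id

        current = nxt
        prev = (labels_b, areas_b, cents_b)

    return lineage


def instantaneous_growth_rate(lineage: Lineage,
                              include_divisions: bool = True) -> pd.DataFrame:
    """Relative frame-to-frame area change per cell.

    For every consecutive frame pair within a track, rate_t =
    (A_{t+1} - A_t) / A_t (relative units per frame).  When
    ``include_divisions``, each division also contributes the two
    parent-to-daughter rates, which are negative (a daughter carries about
    half the parent's area) and flagged in the ``division`` column.
    """
    rows = []
    for t in lineage.cells.values():
        for k in range(len(t.frames) - 1):
            if t.frames[k + 1] != t.frames[k] + 1:
                continue
            rate = (t.areas[k + 1] - t.areas[k]) / t.areas[k]
            rows.append({"cell_id": t.cell_id, "frame": t.frames[k],
                         "rate": rate, "division": False})
    if include_divisions:
        for parent, d1, d2, frame in lineage.divisions:
            pt = lineage.cells[parent]
            if not pt.frames or pt.frames[-1] != frame - 1:
                continue
            a_p = pt.areas[-1]
            for d in (d1, d2):
                dt = lineage.cells[d]
                if dt.frames and dt.frames[0] == frame:
                    rows.append({"cell_id": parent, "frame": frame - 1,
                                 "rate": (dt.areas[0] - a_p) / a_p,
                                 "division": True})
    return pd.DataFrame(rows, columns=["cell_id", "frame", "rate", "division"])


def growth_rate_map(mask: np.ndarray, rates: dict[int, float],
                    sentinel: float = np.nan) -> np.ndarray:
    """Color each instance of a mask by its growth rate; background (and
    any instance without a rate, with a warning) gets the sentinel."""
    out = np.full(mask.shape, sentinel, dtype=float)
    for lbl in np.unique(mask):
        if lbl == 0:
            continue
        if int(lbl) not in rates:
            warnings.warn(f"no growth rate for instance {lbl}; using sentinel")
            continue
        out[mask == lbl] = rates[int(lbl)]
    return out


def plot_growth_rate_map(mask: np.ndarray, rates: dict[int, float], ax=None,
                         cmap: str = "viridis"):
    """Render the spatial growth-rate map with a colorbar."""
    import matplotlib.pyplot as plt

    img = growth_rate_map(mask, rates)
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(img, cmap=cmap)
    ax.figure.colorbar(im, ax=ax, label="growth rate (1/frame)")
    ax.set_axis_off()
    return ax


# -- lineage comparison helpers (exact, centroid-keyed) ---------------------

def _key(frame: int, centroid: tuple[float, float]):
    return (frame, round(centroid[0], 4), round(centroid[1], 4))


def link_set(lineage: Lineage) -> set:
    """Set of ((frame, centroid), (frame+1, centroid)) continuation links."""
    out = set()
    for t in lineage.cells.values():
        for k in range(len(t.frames) - 1):
            if t.frames[k + 1] == t.frames[k] + 1:
                out.add((_key(t.frames[k], t.centroids[k]),
                         _key(t.frames[k + 1], t.centroids[k + 1])))
    return out


def division_set(lineage: Lineage) -> set:
    """Set of (parent observation, frozenset of daughter observations)."""
    out = set()
    for parent, d1, d2, frame in lineage.divisions:
        pt = lineage.cells[parent]
        if not pt.frames:
            continue
        pk = _key(pt.frames[-1], pt.centroids[-1])
        dks = []
        for d in (d1, d2):
            dt = lineage.cells[d]
            if dt.frames:
                dks.append(_key(dt.frames[0], dt.centroids[0]))
        out.add((pk, frozenset(dks)))
    return out
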