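"""Per-object segmentation accuracy, semantic classification scoring, and
movie-level error-rate statistics.

Segmentation accuracy is measured per cell: objects of a reference mask R
and a computed mask S are matched one-to-one by greedy maximum overlap,
then each matched pair contributes a Jaccard index |R∩S|/|R∪S| and a Dice
index 2|R∩S|/(|R|+|S|).  Co-culture type calls use the cellular
classification score — a cell's summed per-pixel type scores, normalized
across types.  The movie-level quality statistic counts frame-to-frame
area jumps of 30% or more, which in bacterial movies almost always means
two cells were merged into one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segment import ScoreMap, _label_components
from .tracking import Lineage

__all__ = [
    "ObjectMatch",
    "ClassificationResult",
    "AreaChangeErrorRate",
    "match_objects",
    "jaccard_dice",
    "aggregate_indices",
    "cellular_classification_score",
    "coculture_instance_mask",
    "area_change_error_rate",
]


@dataclass
class ObjectMatch:
    """A one-to-one matching between reference and computed instances;
    every matched pair has strictly positive pixel overlap."""

    pairs: list[tuple[int, int, int]]  # (reference id, computed id, overlap px)
    unmatched_reference: list[int]
    unmatched_computed: list[int]


def match_objects(reference: np.ndarray, computed: np.ndarray) -> ObjectMatch:
    """Greedy maximum-overlap matching: candidate (R, S) pairs are sorted
    by overlap descending and accepted while both ids are unused."""
    reference = np.asarray(reference)
    computed = np.asarray(computed)
    if reference.shape != computed.shape:
        raise ValueError("masks must share a shape")
    both = (reference > 0) & (computed > 0)
    ref_ids = [int(v) for v in np.unique(reference) if v > 0]
    comp_ids = [int(v) for v in np.unique(computed) if v > 0]
    pairs_idx = np.stack([reference[both], computed[both]], axis=1)
    if len(pairs_idx):
        uniq, counts = np.unique(pairs_idx, axis=0, return_counts=True)
        order = np.argsort(-counts, kind="stable")
        used_r: set[int] = set()
        used_c: set[int] = set()
        accepted = []
        for k in order:
            r, c = int(uniq[k, 0]), int(uniq[k, 1])
            if r in used_r or c in used_c:
                continue
            accepted.append((r, c, int(counts[k])))
            used_r.add(r)
            used_c.add(c)
    else:
        accepted, used_r, used_c = [], set(), set()
    return ObjectMatch(
        pairs=accepted,
        unmatched_reference=[r for r in ref_ids if r not in used_r],
        unmatched_computed=[c for c in comp_ids if c not in used_c],
    )


def jaccard_dice(reference_obj: np.ndarray, computed_obj: np.ndarray):
    """Jaccard and Dice indices of two pixel sets (boolean masks):
    JI = |R∩S| / |R∪S|, DI = 2|R∩S| / (|R| + |S|)."""
    r = np.asarray(reference_obj, dtype=bool)
    s = np.asarray(computed_obj, dtype=bool)
    nr, ns = int(r.sum()), int(s.sum())
    if nr == 0 or ns == 0:
        raise ValueError("objects must be nonempty pixel sets")
    inter = int((r & s).sum())
    ji = inter / (nr + ns - inter)
    di = 2 * inter / (nr + ns)
    return ji, di


@dataclass
class IndexSummary:
    """Aggregate segmentation accuracy.

    ``mean_ji``/``mean_di`` penalize misses (unmatched reference cells
    contribute 0); the ``matched_only`` means average over matched pairs
    alone — both are reported because aggregation conventions differ
    between studies."""

    per_cell: pd.DataFrame
    mean_ji: float
    mean_di: float
    mean_ji_matched_only: float
    mean_di_matched_only: float
    n_reference: int
    n_computed: int
    n_matched: int

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in
             ("mean_ji", "mean_di", "mean_ji_matched_only",
              "mean_di_matched_only", "n_reference", "n_computed", "n_matched")}
        return json.dumps(d)


def aggregate_indices(match: ObjectMatch, reference: np.ndarray,
                      computed: np.ndarray) -> IndexSummary:
    """Per-matched-cell Jaccard/Dice averaged over cells; unmatched
    reference cells count as 0 in the penalized means."""
    rows = []
    for r, c, _ in match.pairs:
        ji, di = jaccard_dice(reference == r, computed == c)
        rows.append({"ref_id": r, "comp_id": c, "ji": ji, "di": di})
    for r in match.unmatched_reference:
        rows.append({"ref_id": r, "comp_id": -1, "ji": 0.0, "di": 0.0})
    df = pd.DataFrame(rows, columns=["ref_id", "comp_id", "ji", "di"])
    matched = df[df.comp_id >= 0]
    return IndexSummary(
        per_cell=df,
        mean_ji=float(df.ji.mean()) if len(df) else float("nan"),
        mean_di=float(df.di.mean()) if len(df) else float("nan"),
        mean_ji_matched_only=float(matched.ji.mean()) if len(matched) else float("nan"),
        mean_di_matched_only=float(matched.di.mean()) if len(matched) else float("nan"),
        n_reference=len(match.pairs) + len(match.unmatched_reference),
        n_computed=len(match.pairs) + len(match.unmatched_computed),
        n_matched=len(match.pairs),
    )


@dataclass
class ClassificationResult:
    """Per-cell type scores over the candidate type classes; scores sum to
    1 per cell and the predicted type is the argmax."""

    scores: pd.DataFrame  # cell_id, score per type, predicted_type
    type_classes: tuple[int, ...]
    flagged: list[int] = field(default_factory=list)  # zero-mass cells

    def accuracy(self, truth: dict[int, int]) -> float:
        """Fraction of cells whose predicted type index matches
        ``truth`` (cell id -> type index)."""
        df = self.scores
        ok = total = 0
        for _, row in df.iterrows():
            cid = int(row.cell_id)
            if cid in truth:
                total += 1
                ok += int(row.predicted_type == truth[cid])
        return ok / total if total else float("nan")


def cellular_classification_score(
    scoremap: ScoreMap, mask: np.ndarray, type_classes: tuple[int, ...]
) -> ClassificationResult:
    """For each cell, sum each type's pixel scores over the cell's pixels
    and normalize by the total over all type classes; the predicted type
    is the argmax.  Cells whose total type-score mass is zero get NaN
    scores and are flagged."""
    mask = np.asarray(mask)
    if mask.shape != scoremap.shape:
        raise ValueError("mask and score map shapes differ")
    for c in type_classes:
        if not 0 <= c < scoremap.n_classes:
            raise ValueError("type class outside the score map's classes")
    rows = []
    flagged = []
    for cid in np.unique(mask):
        if cid == 0:
            continue
        sel = mask == cid
        sums = np.array([scoremap.probabilities[c][sel].sum() for c in type_classes])
        total = sums.sum()
        row = {"cell_id": int(cid)}
        if total <= 0:
            flagged.append(int(cid))
            for k, c in enumerate(type_classes):
                row[f"score_{c}"] = float("nan")
            row["predicted_type"] = -1
        else:
            norm = sums / total
            for k, c in enumerate(type_classes):
                row[f"score_{c}"] = float(norm[k])
            row["predicted_type"] = int(np.argmax(norm))
        rows.append(row)
    return ClassificationResult(
        scores=pd.DataFrame(rows), type_classes=tuple(type_classes),
        flagged=flagged,
    )


def coculture_instance_mask(scoremap: ScoreMap, type_classes: tuple[int, ...],
                            threshold: float = 0.6,
                            min_area: int = 50) -> np.ndarray:
    """Instance mask for a co-culture: threshold the sum of the type
    interior scores (the combined probability that a pixel is any cell's
    interior), then label 4-connected components."""
    summed = np.sum([scoremap.probabilities[c] for c in type_classes], axis=0)
    return _label_components(summed >= threshold, min_area)


@dataclass
class AreaChangeErrorRate:
    """Movie-level segmentation quality: cell-frames with a
    >= threshold area jump, as a percentage of all cell-frames assessed."""

    flagged: int
    total: int
    threshold_fraction: float

    @property
    def percentage(self) -> float:
        return 100.0 * self.flagged / self.total if self.total else float("nan")

    @property
    def display(self) -> float:
        """Percentage rounded for reporting: one decimal below 1%,
        integer above."""
        p = self.percentage
        return round(p, 1) if p < 1 else float(round(p))


def area_change_error_rate(tracks: Lineage,
                           threshold_fraction: float = 0.30) -> AreaChangeErrorRate:
    """Count cell-frames whose area increased by ``threshold_fraction`` or
    more relative to the previous frame — in bacterial movies such a jump
    typically means two cells were merged.  Tracks shorter than 2 frames
    are skipped; the denominator is the number of cell-frame transitions
    assessed."""
    flagged = total = 0
    for t in tracks.cells.values():
        for k in range(len(t.frames) - 1):
            if t.frames[k + 1] != t.frames[k] + 1:
                continue
            total += 1
            if (t.areas[k + 1] - t.areas[k]) / t.areas[k] >= threshold_fraction:
                flagged += 1
    return AreaChangeErrorRate(flagged=flagged, total=total,
                               threshold_fraction=threshold_fraction)
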