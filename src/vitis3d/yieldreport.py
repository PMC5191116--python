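"""Final yield parameters and evaluation metrics.

Yield parameters: components in which at least ``min_berries`` berries were
found count as grape bunches; the berry count and the pooled diameter
distribution over those components are the remaining two parameters.
Evaluation uses recall = TP/(TP+FN), precision = TP/(TP+FP) and the RMSE of
matched berry diameters, with the field-counting conventions: a component
fusing k true bunches counts as one true positive and k-1 false negatives;
one true bunch split into two components yields one true positive and one
false positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .findberries import Berry
from .segment import Component


@dataclass
class YieldReport:
    bunch_count: int
    berry_count: int
    diameters: np.ndarray                 # meters, pooled over surviving components
    berries_per_component: List[int]
    surviving_components: List[int]       # indices into the input component list
    per_meter: Optional[dict] = None

    @property
    def diameter_mean(self) -> float:
        return float(np.mean(self.diameters)) if len(self.diameters) else 0.0

    @property
    def diameter_std(self) -> float:
        return float(np.std(self.diameters)) if len(self.diameters) else 0.0

    def diameter_histogram(self, bin_width: float = 0.001):
        """Normalized diameter histogram (densities), bins in meters."""
        if not len(self.diameters):
            return np.zeros(0), np.zeros(1)
        lo = np.floor(self.diameters.min() / bin_width) * bin_width
        hi = np.ceil(self.diameters.max() / bin_width) * bin_width + bin_width / 2
        edges = np.arange(lo, hi + bin_width, bin_width)
        dens, edges = np.histogram(self.diameters, bins=edges, density=True)
        return dens, edges

    def to_dict(self) -> dict:
        return {
            "bunch_count": self.bunch_count,
            "berry_count": self.berry_count,
            "diameter_mean_mm": self.diameter_mean * 1000.0,
            "diameter_std_mm": self.diameter_std * 1000.0,
            "berries_per_component": list(map(int, self.berries_per_component)),
            "per_meter": self.per_meter,
        }


@dataclass
class EvalResult:
    true_positives: int
    false_positives: int
    false_negatives: int
    rmse: float = float("nan")            # diameters, meters; NaN when not applicable
    undefined: bool = False               # a denominator was zero

    @property
    def recall(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else 0.0

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else 0.0


def finalize_yield(components: Sequence[Component],
                   berries_per_component: Sequence[List[Berry]],
                   min_berries: int = 3,
                   coords: Optional[np.ndarray] = None) -> YieldReport:
    """Reject components with fewer than ``min_berries`` berries and pool
    the rest into the final yield parameters.

    When ``coords`` is given, a per-meter breakdown of bunch counts along
    the row axis (first principal axis of all coordinates) is included.
    """
    if min_berries < 1:
        raise ValueError("min_berries must be >= 1")
    if len(components) != len(berries_per_component):
        raise ValueError("component and berry lists must align")
    surviving = [i for i, berries in enumerate(berries_per_component)
                 if len(berries) >= min_berries]
    diameters = np.array([b.diameter for i in surviving
                          for b in berries_per_component[i]])
    per_meter = None
    if coords is not None and surviving:
        axis_origin = coords.mean(axis=0)
        centered = coords - axis_origin
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        counts: dict[int, int] = {}
        for i in surviving:
            centroid = coords[components[i].indices].mean(axis=0)
            m = int(np.floor((centroid - axis_origin) @ axis))
            counts[m] = counts.get(m, 0) + 1
        per_meter = {f"meter_{m}": c for m, c in sorted(counts.items())}
    return YieldReport(
        bunch_count=len(surviving),
        berry_count=int(sum(len(berries_per_component[i]) for i in surviving)),
        diameters=diameters,
        berries_per_component=[len(berries_per_component[i]) for i in surviving],
        surviving_components=surviving,
        per_meter=per_meter,
    )


def match_and_score_bunches(predicted: Sequence[Component],
                            reference: Sequence[np.ndarray]) -> EvalResult:
    """Greedy one-to-one matching of components to reference bunches by
    maximum point overlap.

    Unmatched references are false negatives (this realizes the fusion
    rule: a component covering k references matches one of them and leaves
    k-1 unmatched); surplus components are false positives.
    """
    ref_sets = [np.asarray(r, dtype=np.int64) for r in reference]
    overlap = np.zeros((len(predicted), len(ref_sets)))
    for i, comp in enumerate(predicted):
        cset = set(comp.indices.tolist())
        for j, ref in enumerate(ref_sets):
            overlap[i, j] = len(cset.intersection(ref.tolist()))
    matched_pred: set[int] = set()
    matched_ref: set[int] = set()
    work = overlap.copy()
    while work.size and work.max() > 0:
        i, j = np.unravel_index(np.argmax(work), work.shape)
        matched_pred.add(int(i))
        matched_ref.add(int(j))
        work[i, :] = 0
        work[:, j] = 0
    tp = len(matched_pred)
    fp = len(predicted) - tp
    fn = len(ref_sets) - len(matched_ref)
    return EvalResult(true_positives=tp, false_positives=fp, false_negatives=fn,
                      undefined=(len(ref_sets) == 0 or len(predicted) == 0))


def score_berries(predicted: Sequence[Berry],
                  reference: Sequence[tuple],
                  match_dist: float = 0.012) -> EvalResult:
    """Optimal one-to-one berry matching under a center-distance cap.

    ``reference`` holds (center, diameter) pairs. RMSE is computed over the
    matched diameters (meters).
    """
    if match_dist <= 0:
        raise ValueError("match_dist must be positive")
    np_, nr = len(predicted), len(reference)
    if np_ == 0 or nr == 0:
        return EvalResult(true_positives=0, false_positives=np_, false_negatives=nr,
                          undefined=True)
    pc = np.array([np.asarray(b.center, dtype=np.float64) for b in predicted])
    pd = np.array([b.diameter for b in predicted])
    rc = np.array([np.asarray(c, dtype=np.float64) for c, _ in reference])
    rd = np.array([d for _, d in reference])
    dist = np.linalg.norm(pc[:, None, :] - rc[None, :, :], axis=2)
    big = match_dist * 1e6
    cost = np.where(dist <= match_dist, dist, big)
    rows, cols = linear_sum_assignment(cost)
    ok = dist[rows, cols] <= match_dist
    tp = int(ok.sum())
    errors = pd[rows[ok]] - rd[cols[ok]]
    rmse = float(np.sqrt(np.mean(errors**2))) if tp else float("nan")
    return EvalResult(true_positives=tp, false_positives=np_ - tp,
                      false_negatives=nr - tp, rmse=rmse)
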