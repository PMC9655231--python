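"""Hotspot evaluation indicators.

Concentration of a detected hotspot set is summarized without ground truth
by four dimensionless indicators.  With n cases captured by hotspots out of
N total, and hotspot area a inside a study region of area A:

* ``HitRate = n / N`` — fraction of all cases captured,
* ``AreaRatio = a / A`` — fraction of the study area flagged,
* ``PAI = HitRate / AreaRatio`` — case density inside hotspots relative to
  the study-area average (prediction accuracy index),
* ``DCR = (n/a) / ((N-n)/(A-a))`` — case density inside hotspots relative
  to the density *outside* them (density contrast ratio).

Shape complexity is summarized by the standardized shape index
``SSI = 1 - 2*sqrt(pi*a) / P`` with P the total hotspot perimeter: 0 for a
circle, approaching 1 for increasingly convoluted patches (1 - 1/LSI with
LSI the landscape shape index referenced to a circle).  When ground truth
is available, cell-level precision / recall / F1 complete the picture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lattice import CellField, GridLattice, patch_perimeter

__all__ = [
    "EvaluationReport",
    "hit_area_indicators",
    "shape_index",
    "confusion_counts",
    "precision_recall_f1",
    "evaluate",
]


@dataclass(frozen=True)
class EvaluationReport:
    """All indicators for one detection result (NaN marks undefined)."""

    n: float
    N: float
    a: float
    A: float
    hit_rate: float
    area_ratio: float
    pai: float
    dcr: float
    perimeter: float
    ssi: float
    tp: int | None = None
    fp: int | None = None
    fn: int | None = None
    tn: int | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None

    def to_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if v is not None}
        return out

    def summary(self) -> str:
        """Indicator table at conventional reporting precision."""

        def pct(v):
            return "undef" if v is None or np.isnan(v) else f"{100 * v:.1f}%"

        def num(v, nd):
            return "undef" if v is None or np.isnan(v) else f"{v:.{nd}f}"

        lines = [
            "Hotspot evaluation",
            "------------------",
            f"cases captured n        {self.n:.0f} / {self.N:.0f}",
            f"hotspot area a          {self.a:g} / {self.A:g}",
            f"HitRate                 {pct(self.hit_rate)}",
            f"AreaRatio               {pct(self.area_ratio)}",
            f"PAI                     {num(self.pai, 2)}",
            f"DCR                     {num(self.dcr, 2)}",
            f"perimeter P             {self.perimeter:g}",
            f"SSI                     {num(self.ssi, 3)}",
        ]
        if self.tp is not None:
            lines += [
                f"TP / FP / FN / TN       {self.tp} / {self.fp} / {self.fn} / {self.tn}",
                f"Precision               {pct(self.precision)}",
                f"Recall                  {pct(self.recall)}",
                f"F1                      {num(self.f1, 3)}",
            ]
        return "\n".join(lines)


def hit_area_indicators(n: float, N: float, a: float, A: float
                        ) -> tuple[float, float, float, float]:
    """(HitRate, AreaRatio, PAI, DCR) from case and area totals.

    DCR is undefined (NaN) when the hotspot covers the whole region
    (a = A) or captures every case (n = N), since the outside density is
    then degenerate.
    """
    if not (0 <= n <= N) or N <= 0:
        raise ValueError(f"need 0 <= n <= N with N > 0, got n={n}, N={N}")
    if not (0 < a <= A):
        raise ValueError(f"need 0 < a <= A, got a={a}, A={A}")
    hit_rate = n / N
    area_ratio = a / A
    pai = hit_rate / area_ratio
    if a == A or n == N:
        dcr = math.nan
    else:
        dcr = (n / a) / ((N - n) / (A - a))
    return hit_rate, area_ratio, pai, dcr


def shape_index(perimeter: float, area: float) -> float:
    """Standardized shape index SSI = 1 - 2*sqrt(pi*area)/perimeter.

    The perimeter of a circle of the given area, 2*sqrt(pi*area), is the
    isoperimetric minimum; any polygonal patch satisfies it, so SSI lies
    in [0, 1).
    """
    if area <= 0:
        raise ValueError(f"area must be positive, got {area}")
    p_min = 2.0 * math.sqrt(math.pi * area)
    if perimeter < p_min * (1 - 1e-12):
        raise ValueError(
            f"perimeter {perimeter} below the circular minimum {p_min} "
            f"for area {area}")
    return 1.0 - p_min / max(perimeter, p_min)


def confusion_counts(detected: np.ndarray, truth: np.ndarray
                     ) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) cell counts for aligned boolean masks."""
    detected = np.asarray(detected, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if detected.shape != truth.shape:
        raise ValueError("detected and truth masks are misaligned")
    tp = int(np.count_nonzero(detected & truth))
    fp = int(np.count_nonzero(detected & ~truth))
    fn = int(np.count_nonzero(~detected & truth))
    tn = detected.size - tp - fp - fn
    return tp, fp, fn, tn


def precision_recall_f1(tp: int, fp: int, fn: int
                        ) -> tuple[float, float, float]:
    """(precision, recall, F1); an undefined ratio is flagged as NaN.

    F1 is 0 when precision = recall = 0 (a total miss with non-empty
    detection and truth), NaN when either ratio is undefined.
    """
    precision = tp / (tp + fp) if (tp + fp) > 0 else math.nan
    recall = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    if math.isnan(precision) or math.isnan(recall):
        f1 = math.nan
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def _total_perimeter(lattice: GridLattice, mask: np.ndarray) -> float:
    """Summed perimeter over rook-connected flagged patches.

    Patches are separated with edge (rook) connectivity so a diagonal-only
    touch does not fuse them; since rook components share no edges, the sum
    of patch perimeters equals the perimeter of the whole mask.
    """
    members = np.flatnonzero(mask)
    if members.size == 0:
        return 0.0
    if lattice.is_regular:
        return patch_perimeter(lattice, members)
    total = 0.0
    # group polygon units into rook components via pairwise shared boundaries
    from .lattice import contiguity_weights

    w = contiguity_weights(lattice, rule="rook").matrix
    sub = w[members][:, members]
    n_comp, labels = _sparse_components(sub)
    for k in range(n_comp):
        total += patch_perimeter(lattice, members[labels == k])
    return total


def _sparse_components(adj) -> tuple[int, np.ndarray]:
    from scipy.sparse.csgraph import connected_components

    return connected_components(adj, directed=False)


def evaluate(labeling, field: CellField, lattice: GridLattice,
             truth: np.ndarray | None = None) -> EvaluationReport:
    """Full indicator report for one hotspot labeling.

    ``labeling`` may be a boolean mask or any object with a ``mask``
    attribute.  With an empty labeling the area is reported as the a = 0
    sentinel and PAI / DCR / SSI are NaN.
    """
    mask = np.asarray(getattr(labeling, "mask", labeling), dtype=bool)
    if mask.shape != (lattice.n_units,) or len(field) != lattice.n_units:
        raise ValueError("labeling, field and lattice are misaligned")
    N = field.total
    A = lattice.total_area
    n = float(field.values[mask].sum())
    a = float(lattice.unit_area[mask].sum())
    if a == 0:
        hit_rate, area_ratio, pai, dcr = 0.0, 0.0, math.nan, math.nan
        perim, ssi = 0.0, math.nan
    else:
        hit_rate, area_ratio, pai, dcr = hit_area_indicators(n, N, a, A)
        perim = _total_perimeter(lattice, mask)
        ssi = shape_index(perim, a)
    report = dict(n=n, N=N, a=a, A=A, hit_rate=hit_rate, area_ratio=area_ratio,
                  pai=pai, dcr=dcr, perimeter=perim, ssi=ssi)
    if truth is not None:
        tp, fp, fn, tn = confusion_counts(mask, truth)
        precision, recall, f1 = precision_recall_f1(tp, fp, fn)
        report.update(tp=tp, fp=fp, fn=fn, tn=tn,
                      precision=precision, recall=recall, f1=f1)
    return EvaluationReport(**report)
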