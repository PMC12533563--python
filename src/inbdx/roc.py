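"""ROC-space analysis of a protocol set: distinct operating points,
summary indices, and the efficient frontier (upper convex hull)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import OperatingPoint, Protocol
from .aggregate import composite_operating_point

__all__ = ["PointGroup", "distinct_points", "roc_frontier", "indices", "roc_table"]

_GROUP_TOL = 1e-9


@dataclass(frozen=True)
class PointGroup:
    """One distinct operating point and the protocols that share it
    (order permutations of a test set under one rule coincide exactly)."""

    point: OperatingPoint
    protocols: tuple[Protocol, ...]


def distinct_points(
    protocols: list[Protocol], tol: float = _GROUP_TOL
) -> list[PointGroup]:
    """Group protocols by composite operating point (absolute tolerance on
    both coordinates, applied to full-precision values)."""
    if not protocols:
        raise ValueError("empty protocol list")
    groups: list[tuple[OperatingPoint, list[Protocol]]] = []
    for proto in protocols:
        op = composite_operating_point(proto)
        for ref, members in groups:
            if (
                abs(ref.sensitivity - op.sensitivity) <= tol
                and abs(ref.specificity - op.specificity) <= tol
            ):
                members.append(proto)
                break
        else:
            groups.append((op, [proto]))
    return [PointGroup(ref, tuple(members)) for ref, members in groups]


def _upper_hull(fpr: np.ndarray, tpr: np.ndarray) -> list[tuple[float, float]]:
    """Vertices of the upper convex hull from (0,0) to (1,1), by monotone
    chain with strict turns (collinear interior points dropped; they are
    re-flagged against the envelope afterwards)."""
    pts = sorted(set(zip(fpr.tolist(), tpr.tolist())) | {(0.0, 0.0), (1.0, 1.0)})
    hull: list[tuple[float, float]] = []
    for pt in pts:
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = hull[-2], hull[-1]
            cross = (x2 - x1) * (pt[1] - y1) - (y2 - y1) * (pt[0] - x1)
            if cross >= 0:  # hull turns up or straight: last vertex not extreme
                hull.pop()
            else:
                break
        hull.append(pt)
    # collapse duplicate x (possible when a point sits at Sp == 1 or 0),
    # keeping the higher envelope value, so np.interp sees increasing x
    best: dict[float, float] = {}
    for x, y in hull:
        best[x] = max(best.get(x, -np.inf), y)
    return sorted(best.items())


def roc_frontier(points: list[OperatingPoint], tol: float = 1e-9) -> list[bool]:
    """Efficiency flags: True for points on the ROC frontier.

    The frontier is the upper convex hull in (1-Sp, Se) space anchored at
    (0, 0) and (1, 1).  Points whose sensitivity falls short of the hull
    envelope at their false-positive rate are inefficient; collinear points
    lying on a hull edge count as efficient (weak dominance is retained).
    """
    if not points:
        return []
    fpr = np.array([1.0 - pt.specificity for pt in points])
    tpr = np.array([pt.sensitivity for pt in points])
    hull = _upper_hull(fpr, tpr)
    hx = np.array([v[0] for v in hull])
    hy = np.array([v[1] for v in hull])
    envelope = np.interp(fpr, hx, hy)
    return list(tpr >= envelope - tol)


def indices(point: OperatingPoint) -> tuple[float, float, float]:
    """Youden index and positive/negative likelihood ratios."""
    return point.youden, point.lr_plus, point.lr_minus


def roc_table(protocols: list[Protocol]) -> pd.DataFrame:
    """Per-protocol ROC summary with an efficiency flag.

    Efficiency is decided on distinct operating points and then expanded to
    every member protocol of each point.
    """
    groups = distinct_points(protocols)
    flags = roc_frontier([g.point for g in groups])
    rows = []
    for g, eff in zip(groups, flags):
        j, lrp, lrm = indices(g.point)
        for proto in g.protocols:
            rows.append(
                {
                    "protocol": proto.id,
                    "sensitivity": g.point.sensitivity,
                    "specificity": g.point.specificity,
                    "youden": j,
                    "lr_plus": lrp,
                    "lr_minus": lrm,
                    "efficient": bool(eff),
                }
            )
    return pd.DataFrame(rows)
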