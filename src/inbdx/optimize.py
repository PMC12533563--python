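"""Protocol enumeration, argmax-INB action selection, protocol thresholds,
and decision-region maps over the (p, rho) unit square.

Within each branch of the value-of-information function the INB of any
protocol is linear in p (the expected testing loss is itself linear in p),
so test and test-treatment thresholds and pairwise transition points are
exact roots of linear equations, filtered by branch validity — no iterative
solver is involved.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DiagnosticTest, Protocol, Rule
from .aggregate import composite_operating_point, expected_test_loss, inb_protocol
from .voi import ThresholdSet

__all__ = [
    "ActionKind",
    "ActionLabel",
    "DecisionMap",
    "enumerate_protocols",
    "best_action",
    "protocol_thresholds_p",
    "transition_threshold_p",
    "global_test_bounds",
    "decision_map",
]

_MAX_TESTS = 6


class ActionKind(str, enum.Enum):
    NO_TEST_NO_TREAT = "no_test_no_treat"
    TREAT_WITHOUT_TESTING = "treat_without_testing"
    TEST = "test"


@dataclass(frozen=True)
class ActionLabel:
    """Optimal action at one (p, rho) point: a default action, or the
    argmax-INB protocol when some protocol has positive INB."""

    kind: ActionKind
    protocol: Protocol | None
    inb_value: float

    def __post_init__(self) -> None:
        if self.kind is ActionKind.TEST:
            if self.protocol is None:
                raise ValueError("TEST label needs a protocol")
            if not self.inb_value > 0:
                raise ValueError("TEST label requires positive INB")
        elif self.protocol is not None:
            raise ValueError("default actions carry no protocol")


def enumerate_protocols(tests: list[DiagnosticTest]) -> list[Protocol]:
    """All protocols over a panel: every single test, every ordered sequence
    of >= 2 distinct tests under AND and under OR, and every ordered
    sequence of odd length >= 3 under the majority rule.

    Three tests yield 33 protocols.  The list is sorted by (length, total
    per-test loss, protocol id) so that a stable argmax realizes the
    preferred tie-break (fewer tests first, then cheaper).
    """
    n = len(tests)
    if not (1 <= n <= _MAX_TESTS):
        est = _protocol_count_estimate(n)
        raise ValueError(
            f"panel of {n} tests not supported (1..{_MAX_TESTS}); "
            f"it would enumerate ~{est} protocols"
        )
    protos: list[Protocol] = [Protocol([t]) for t in tests]
    for k in range(2, n + 1):
        for seq in itertools.permutations(tests, k):
            protos.append(Protocol(seq, Rule.AND))
            protos.append(Protocol(seq, Rule.OR))
            if k % 2 == 1 and k >= 3:
                protos.append(Protocol(seq, Rule.MAJORITY))
    protos.sort(key=lambda pr: (len(pr), pr.total_loss, pr.id))
    return protos


def _protocol_count_estimate(n: int) -> int:
    import math

    perms = lambda k: math.perm(n, k) if n >= k else 0
    total = n
    for k in range(2, n + 1):
        total += 2 * perms(k)
        if k % 2 == 1 and k >= 3:
            total += perms(k)
    return total


def best_action(p: float, rho: float, protocols: list[Protocol]) -> ActionLabel:
    """argmax-INB action at one patient state.

    If no protocol attains positive INB, the default action applies: no
    treatment below the treatment threshold (p < rho), treatment at or
    above it.  Exact INB ties go to the protocol with fewer tests, then
    the lower expected testing loss at this p, then the lexicographically
    smaller id.
    """
    if not protocols:
        raise ValueError("empty protocol list")
    best: Protocol | None = None
    best_inb = -np.inf
    best_key: tuple | None = None
    for proto in protocols:
        inb = inb_protocol(proto, p, rho)
        key = (len(proto), expected_test_loss(proto, p), proto.id)
        if inb > best_inb or (inb == best_inb and best_key is not None and key < best_key):
            best, best_inb, best_key = proto, inb, key
    if best_inb <= 0.0:
        kind = (
            ActionKind.NO_TEST_NO_TREAT if p < rho else ActionKind.TREAT_WITHOUT_TESTING
        )
        return ActionLabel(kind, None, best_inb)
    return ActionLabel(ActionKind.TEST, best, best_inb)


def _inb_line(protocol: Protocol, rho: float, branch: str) -> tuple[float, float]:
    """Intercept and slope of INB(p) on one VI branch at fixed rho.

    branch 'low' is the no-treat default (valid for p < rho), 'high' the
    treat default (valid for p >= rho).
    """
    op = composite_operating_point(protocol)
    r = rho / (1.0 - rho)
    l0 = expected_test_loss(protocol, 0.0)
    l1 = expected_test_loss(protocol, 1.0)
    if branch == "low":
        a = -(1.0 - op.specificity) * r - l0
        b = op.sensitivity + (1.0 - op.specificity) * r - (l1 - l0)
    else:
        a = op.specificity * r - l0
        b = -(1.0 - op.sensitivity) - op.specificity * r - (l1 - l0)
    return a, b


def protocol_thresholds_p(protocol: Protocol, rho: float) -> ThresholdSet:
    """Test and test-treatment thresholds of one protocol at fixed rho.

    The lower threshold is the zero of INB on the no-treat branch within
    [0, rho); the upper one the zero on the treat branch within [rho, 1].
    If INB is positive on a whole branch segment the interval extends to
    that segment's end; components are absent when INB never turns positive.
    """
    if not (0.0 < rho < 1.0):
        raise ValueError(f"rho must lie strictly inside (0, 1), got {rho!r}")
    lower = upper = None
    a_lo, b_lo = _inb_line(protocol, rho, "low")
    a_hi, b_hi = _inb_line(protocol, rho, "high")
    inb_at_rho = a_hi + b_hi * rho  # branches coincide at p = rho
    if inb_at_rho > 0.0:
        # geometry: INB(0) <= 0 <= INB(rho) and INB(1) <= 0 on their branches
        if abs(b_lo) > 0:
            root = -a_lo / b_lo
            lower = root if 0.0 <= root <= rho else (0.0 if a_lo > 0 else None)
        else:
            lower = 0.0 if a_lo > 0 else None
        if abs(b_hi) > 0:
            root = -a_hi / b_hi
            upper = root if rho <= root <= 1.0 else (1.0 if a_hi + b_hi > 0 else None)
        else:
            upper = 1.0 if a_hi > 0 else None
    return ThresholdSet(p_test=lower, p_test_treat=upper)


def transition_threshold_p(
    protocol_i: Protocol, protocol_j: Protocol, rho: float
) -> float | None:
    """p at which the INB lines of two protocols cross, at fixed rho.

    Roots are sought on each VI branch and kept only inside that branch's
    validity region.  When both branches yield a crossing, the one at which
    the protocols' INB is positive (i.e. inside the testing region) is
    preferred.  ``None`` when the lines are parallel or never cross in
    [0, 1].
    """
    if protocol_i.id == protocol_j.id:
        return None
    candidates: list[float] = []
    for branch, lo, hi in (("low", 0.0, rho), ("high", rho, 1.0)):
        ai, bi = _inb_line(protocol_i, rho, branch)
        aj, bj = _inb_line(protocol_j, rho, branch)
        da, db = ai - aj, bi - bj
        if abs(db) < 1e-300:
            continue
        root = -da / db
        if lo <= root <= hi:
            candidates.append(root)
    if not candidates:
        return None
    positive = [
        c for c in candidates if inb_protocol(protocol_i, c, rho) > 0.0
    ]
    pool = positive or candidates
    return min(pool)


def global_test_bounds(
    protocols: list[Protocol], rho: float
) -> tuple[float | None, float | None]:
    """Overall testing range at fixed rho: the minimum lower threshold and
    maximum upper threshold over all protocols that have a testing
    interval.  (None, None) when no protocol is ever worth testing."""
    if not protocols:
        raise ValueError("empty protocol list")
    lowers, uppers = [], []
    for proto in protocols:
        ts = protocol_thresholds_p(proto, rho)
        if ts.p_test is not None:
            lowers.append(ts.p_test)
        if ts.p_test_treat is not None:
            uppers.append(ts.p_test_treat)
    return (min(lowers) if lowers else None, max(uppers) if uppers else None)


@dataclass(frozen=True)
class DecisionMap:
    """Best action over a (p, rho) grid.

    ``labels[i, j]`` indexes ``protocols`` for the cell (rho_grid[i],
    p_grid[j]); -1 marks NO_TEST_NO_TREAT and -2 TREAT_WITHOUT_TESTING.
    ``inb`` holds the corresponding maximal INB (in units of b).
    """

    p_grid: np.ndarray
    rho_grid: np.ndarray
    labels: np.ndarray
    inb: np.ndarray
    protocols: tuple[Protocol, ...]

    NO_TEST = -1
    TREAT = -2

    def __post_init__(self) -> None:
        if self.labels.shape != (len(self.rho_grid), len(self.p_grid)):
            raise ValueError("label matrix does not match grid dimensions")
        if np.any(np.diff(self.p_grid) <= 0) or np.any(np.diff(self.rho_grid) <= 0):
            raise ValueError("grids must be strictly increasing")

    def label_name(self, i: int, j: int) -> str:
        lab = int(self.labels[i, j])
        if lab == self.NO_TEST:
            return "no_test_no_treat"
        if lab == self.TREAT:
            return "treat_without_testing"
        return self.protocols[lab].id

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns p, rho, label, inb."""
        pp, rr = np.meshgrid(self.p_grid, self.rho_grid)
        names = np.empty(self.labels.shape, dtype=object)
        for lab in np.unique(self.labels):
            if lab == self.NO_TEST:
                names[self.labels == lab] = "no_test_no_treat"
            elif lab == self.TREAT:
                names[self.labels == lab] = "treat_without_testing"
            else:
                names[self.labels == lab] = self.protocols[int(lab)].id
        return pd.DataFrame(
            {
                "p": pp.ravel(),
                "rho": rr.ravel(),
                "label": names.ravel(),
                "inb": self.inb.ravel(),
            }
        )


def decision_map(
    tests: list[DiagnosticTest],
    n_grid: int = 501,
    p_grid: np.ndarray | None = None,
    rho_grid: np.ndarray | None = None,
    protocols: list[Protocol] | None = None,
) -> DecisionMap:
    """Rasterize the optimal-action regions over the open unit square.

    The default grid is uniform with ``n_grid`` interior points per axis
    (endpoints excluded: p = 0/1 and rho = 0/1 are degenerate).  The INB of
    every protocol is evaluated on the full grid by broadcasting the two
    linear-in-p branches, then reduced by argmax.
    """
    if protocols is None:
        protocols = enumerate_protocols(tests)
    if p_grid is None:
        p_grid = np.linspace(0.0, 1.0, n_grid + 2)[1:-1]
    if rho_grid is None:
        rho_grid = np.linspace(0.0, 1.0, n_grid + 2)[1:-1]
    p_grid = np.asarray(p_grid, dtype=float)
    rho_grid = np.asarray(rho_grid, dtype=float)
    if len(p_grid) < 2 or len(rho_grid) < 2:
        raise ValueError("grid resolutions must be >= 2")
    p = p_grid[None, :]
    r = (rho_grid / (1.0 - rho_grid))[:, None]
    treat_branch = p >= rho_grid[:, None]
    best_inb = np.full((len(rho_grid), len(p_grid)), -np.inf)
    labels = np.full(best_inb.shape, DecisionMap.NO_TEST, dtype=int)
    for idx, proto in enumerate(protocols):
        op = composite_operating_point(proto)
        l0 = expected_test_loss(proto, 0.0)
        l1 = expected_test_loss(proto, 1.0)
        loss = l0 + (l1 - l0) * p
        vi_low = p * op.sensitivity - (1.0 - p) * (1.0 - op.specificity) * r
        vi_high = -p * (1.0 - op.sensitivity) + (1.0 - p) * op.specificity * r
        inb = np.where(treat_branch, vi_high, vi_low) - loss
        better = inb > best_inb
        best_inb = np.where(better, inb, best_inb)
        labels = np.where(better, idx, labels)
    negative = best_inb <= 0.0
    labels[negative & ~treat_branch] = DecisionMap.NO_TEST
    labels[negative & treat_branch] = DecisionMap.TREAT
    return DecisionMap(p_grid, rho_grid, labels, best_inb, tuple(protocols))
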