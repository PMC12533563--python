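"""Composite operating points and sequence-dependent expected testing losses.

Test results are assumed conditionally independent given disease status, so
composite sensitivities and specificities are order-invariant products:

    AND:  Se = prod Se_i,        Sp = 1 - prod (1 - Sp_i)
    OR:   Se = 1 - prod(1-Se_i), Sp = prod Sp_i
    MAJ:  P(strict majority positive | status), a Poisson-binomial tail.

The order of administration matters only through the expected testing loss:
under AND a test runs iff every earlier test was positive, under OR iff
every earlier one was negative, and under a majority rule while neither the
positives nor the negatives have yet reached a strict majority.  Early
stopping makes the sequential decision identical to the full vote, so the
composite operating point stays order-invariant.
"""

from __future__ import annotations

import itertools
import math

from .core import OperatingPoint, Protocol, Rule
from .voi import value_of_information

__all__ = [
    "composite_operating_point",
    "expected_test_loss",
    "inb_protocol",
    "outcome_enumeration_oracle",
]

_MAX_ENUM = 12  # 2^n outcome vectors; guard against runaway enumeration


def _majority_tail(probs: list[float]) -> float:
    """P(more than half of independent Bernoulli(probs) are successes)."""
    n = len(probs)
    # Poisson-binomial count distribution by dynamic programming
    dist = [1.0] + [0.0] * n
    for q in probs:
        for k in range(len(dist) - 1, 0, -1):
            dist[k] = dist[k] * (1.0 - q) + dist[k - 1] * q
        dist[0] *= 1.0 - q
    return sum(dist[n // 2 + 1 :])


def composite_operating_point(protocol: Protocol) -> OperatingPoint:
    """Sensitivity and specificity of the aggregated protocol decision."""
    ses = [t.sensitivity for t in protocol.tests]
    sps = [t.specificity for t in protocol.tests]
    if len(protocol) == 1:
        return protocol.tests[0].operating_point
    if protocol.rule is Rule.AND:
        se = math.prod(ses)
        sp = 1.0 - math.prod(1.0 - s for s in sps)
    elif protocol.rule is Rule.OR:
        se = 1.0 - math.prod(1.0 - s for s in ses)
        sp = math.prod(sps)
    else:  # MAJORITY
        se = _majority_tail(ses)
        sp = 1.0 - _majority_tail([1.0 - s for s in sps])
    return OperatingPoint(se, sp)


def _administration_probs(protocol: Protocol, conditional_pos: list[float]) -> list[float]:
    """P(test k is administered | disease status), for the given per-test
    positive-result probabilities conditional on that status."""
    n = len(conditional_pos)
    if protocol.rule is Rule.AND or n == 1:
        out, acc = [], 1.0
        for q in conditional_pos:
            out.append(acc)
            acc *= q  # continue only on a positive
        return out
    if protocol.rule is Rule.OR:
        out, acc = [], 1.0
        for q in conditional_pos:
            out.append(acc)
            acc *= 1.0 - q  # continue only on a negative
        return out
    # MAJORITY: test k runs while neither side holds a strict majority of n.
    # Track the positive count over the administered prefix; the prefix
    # result distribution is unaffected by stopping.
    need = n // 2 + 1
    out = [1.0]
    dist = [1.0]  # P(j positives among first k-1 tests)
    for k in range(1, n):
        q = conditional_pos[k - 1]
        new = [0.0] * (len(dist) + 1)
        for j, pr in enumerate(dist):
            new[j] += pr * (1.0 - q)
            new[j + 1] += pr * q
        dist = new
        undecided = sum(
            pr for j, pr in enumerate(dist) if j < need and (k - j) < need
        )
        out.append(undecided)
    return out


def expected_test_loss(protocol: Protocol, p: float) -> float:
    """Expected normalized testing loss of running the protocol at
    pre-test probability p; linear in p."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p!r}")
    pos_d = [t.sensitivity for t in protocol.tests]
    pos_h = [1.0 - t.specificity for t in protocol.tests]
    admin_d = _administration_probs(protocol, pos_d)
    admin_h = _administration_probs(protocol, pos_h)
    return sum(
        t.loss_over_b * (p * ad + (1.0 - p) * ah)
        for t, ad, ah in zip(protocol.tests, admin_d, admin_h)
    )


def inb_protocol(protocol: Protocol, p: float, rho: float) -> float:
    """Incremental net benefit of the protocol, in units of b.

    The informational part depends only on the test set and rule; the
    expected-loss part depends on the administration order.
    """
    vi = value_of_information(p, rho, composite_operating_point(protocol))
    return vi - expected_test_loss(protocol, p)


def outcome_enumeration_oracle(
    protocol: Protocol, p: float
) -> tuple[OperatingPoint, float]:
    """Brute-force check of the closed forms by enumerating all 2^n result
    vectors, replaying the sequential stopping rule on each, and
    accumulating the decision probabilities and expected administered loss.

    Independent of the product/DP code paths above; intended for protocols
    of modest length (n <= 12).
    """
    n = len(protocol)
    if n > _MAX_ENUM:
        raise ValueError(f"enumeration oracle limited to {_MAX_ENUM} tests, got {n}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p!r}")
    need = n // 2 + 1
    se = 0.0  # P(decision positive | diseased)
    sp = 0.0  # P(decision negative | healthy)
    exp_loss = 0.0
    for outcome in itertools.product((1, 0), repeat=n):
        # replay the sequence with early stopping
        administered = []
        pos = neg = 0
        for k, res in enumerate(outcome):
            administered.append(k)
            pos += res
            neg += 1 - res
            if protocol.rule is Rule.AND and res == 0:
                break
            if protocol.rule is Rule.OR and res == 1:
                break
            if protocol.rule is Rule.MAJORITY and n > 1 and (pos >= need or neg >= need):
                break
        if protocol.rule is Rule.AND or n == 1:
            decision_pos = all(outcome[k] for k in administered)
        elif protocol.rule is Rule.OR:
            decision_pos = any(outcome[k] for k in administered)
        else:
            decision_pos = pos >= need
        prob_d = prob_h = 1.0
        for k, res in enumerate(outcome):
            t = protocol.tests[k]
            prob_d *= t.sensitivity if res else 1.0 - t.sensitivity
            prob_h *= (1.0 - t.specificity) if res else t.specificity
        if decision_pos:
            se += prob_d
        else:
            sp += prob_h
        loss = sum(protocol.tests[k].loss_over_b for k in administered)
        exp_loss += (p * prob_d + (1.0 - p) * prob_h) * loss
    return OperatingPoint(se, sp), exp_loss
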