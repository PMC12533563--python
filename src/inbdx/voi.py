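"""Value of diagnostic information and single-test incremental net benefit.

Everything here is expressed in units of the treatment benefit b.  Writing
r = rho/(1-rho) = l/b for the loss-benefit odds, the expected utility of
unconditional treatment is p - (1-p) r, and the value of information of a
test with operating point (Se, Sp) is

    VI(p, rho) = p Se - (1-p)(1-Sp) r          if p < rho   (default: no treat)
               = -p (1-Se) + (1-p) Sp r        if p >= rho  (default: treat)

i.e. the expected-utility gain of deciding on the test result rather than
taking the better default action.  Both branches are linear in p and in r,
and they coincide at p = rho, where VI = p*J with J the Youden index.  The
incremental net benefit of a single test subtracts its normalized loss:
INB = VI - l_Dx/b.  Solving INB = 0 per branch yields closed-form test and
test-treatment thresholds in p (given rho) and in rho (given p).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import DiagnosticTest, OperatingPoint

__all__ = [
    "ThresholdSet",
    "expected_utility_treatment",
    "value_of_information",
    "inb_single",
    "single_test_thresholds_p",
    "single_test_thresholds_rho",
    "pairwise_transition_p",
    "pairwise_transition_rho",
]


@dataclass(frozen=True)
class ThresholdSet:
    """Test and test-treatment thresholds of one protocol.

    ``p_test`` and ``p_test_treat`` bound the pre-test-probability interval
    in which testing beats both default actions, at fixed rho;
    ``rho_lower`` and ``rho_upper`` bound the trade-off interval at fixed p.
    Components are ``None`` when the corresponding bound does not exist
    (testing never, or always, indicated on that side).
    """

    p_test: float | None = None
    p_test_treat: float | None = None
    rho_lower: float | None = None
    rho_upper: float | None = None

    def __post_init__(self) -> None:
        for name in ("p_test", "p_test_treat", "rho_lower", "rho_upper"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if (
            self.p_test is not None
            and self.p_test_treat is not None
            and self.p_test > self.p_test_treat + 1e-12
        ):
            raise ValueError("p_test must not exceed p_test_treat")
        if (
            self.rho_lower is not None
            and self.rho_upper is not None
            and self.rho_lower > self.rho_upper + 1e-12
        ):
            raise ValueError("rho_lower must not exceed rho_upper")


def _check_domain(p: float, rho: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p!r}")
    if not (0.0 < rho < 1.0):
        raise ValueError(f"rho must lie strictly inside (0, 1), got {rho!r}")


def expected_utility_treatment(p: float, rho: float) -> float:
    """Expected utility of treating unconditionally, in units of b.

    Positive iff treatment beats no-treatment without testing; zero exactly
    at the treatment threshold p = rho.
    """
    _check_domain(p, rho)
    return p - (1.0 - p) * rho / (1.0 - rho)


def value_of_information(p: float, rho: float, point: OperatingPoint) -> float:
    """Expected-utility gain of testing over the best default action.

    At p == rho the two branches agree; the treat-default branch is used.
    """
    _check_domain(p, rho)
    r = rho / (1.0 - rho)
    se, sp = point.sensitivity, point.specificity
    if p < rho:
        return p * se - (1.0 - p) * (1.0 - sp) * r
    return -p * (1.0 - se) + (1.0 - p) * sp * r


def inb_single(test: DiagnosticTest, p: float, rho: float) -> float:
    """Incremental net benefit of one test: VI minus its normalized loss."""
    return value_of_information(p, rho, test.operating_point) - test.loss_over_b


def single_test_thresholds_p(test: DiagnosticTest, rho: float) -> ThresholdSet:
    """Closed-form test and test-treatment thresholds in p at fixed rho.

    Lower (no-treat branch):  p_Dx   = [rho(1-Sp) + (1-rho) l/b]
                                       / [rho(1-Sp) + (1-rho) Se]
    Upper (treat branch):     p_Dx^- = [rho Sp - (1-rho) l/b]
                                       / [rho Sp + (1-rho)(1-Se)]

    Components are absent when they fall outside [0, 1] or when the testing
    interval is empty (the test is never worth its loss at this rho).
    """
    if not (0.0 < rho < 1.0):
        raise ValueError(f"rho must lie strictly inside (0, 1), got {rho!r}")
    se, sp, lob = test.sensitivity, test.specificity, test.loss_over_b
    lo_num = rho * (1.0 - sp) + (1.0 - rho) * lob
    lo_den = rho * (1.0 - sp) + (1.0 - rho) * se
    hi_num = rho * sp - (1.0 - rho) * lob
    hi_den = rho * sp + (1.0 - rho) * (1.0 - se)
    lower = lo_num / lo_den if lo_den > 0 else None
    upper = hi_num / hi_den if hi_den > 0 else None
    if lower is not None and not (0.0 <= lower <= 1.0):
        lower = None
    if upper is not None and not (0.0 <= upper <= 1.0):
        upper = None
    if lower is not None and upper is not None and lower > upper:
        return ThresholdSet()  # empty testing interval
    return ThresholdSet(p_test=lower, p_test_treat=upper)


def single_test_thresholds_rho(test: DiagnosticTest, p: float) -> ThresholdSet:
    """Closed-form testing bounds in rho at fixed p.

    With a cost- and harm-free test the bounds reduce to Bayes quantities:
    the upper bound is the positive predictive value and the lower bound is
    one minus the negative predictive value.  Bounds outside (0, 1), or
    violating their branch condition (lower needs rho <= p, upper rho > p),
    are reported as absent.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie strictly inside (0, 1), got {p!r}")
    se, sp, lob = test.sensitivity, test.specificity, test.loss_over_b
    lo_num = p * (1.0 - se) + lob
    lo_den = p * (1.0 - se) + (1.0 - p) * sp + lob
    hi_num = p * se - lob
    hi_den = p * se + (1.0 - p) * (1.0 - sp) - lob
    lower = lo_num / lo_den if lo_den > 0 else None
    upper = hi_num / hi_den if hi_den > 0 else None
    # branch validity: the lower bound comes from the treat-default branch
    # (rho <= p), the upper one from the no-treat branch (rho > p)
    if lower is not None and not (0.0 < lower <= p):
        lower = None
    if upper is not None and not (p < upper < 1.0):
        upper = None
    return ThresholdSet(rho_lower=lower, rho_upper=upper)


def pairwise_transition_p(
    test_i: DiagnosticTest, test_j: DiagnosticTest, rho: float
) -> float | None:
    """Disease probability at which preference switches between two tests.

    The INB difference of two single tests is the same linear function of p
    on both branches, so the crossing

        p_ij = [rho dSp - (1-rho) dl/b] / [rho dSp - (1-rho) dSe]

    is branch-free.  Returns ``None`` for parallel INB lines or a crossing
    outside [0, 1].
    """
    if not (0.0 < rho < 1.0):
        raise ValueError(f"rho must lie strictly inside (0, 1), got {rho!r}")
    d_se = test_i.sensitivity - test_j.sensitivity
    d_sp = test_i.specificity - test_j.specificity
    d_l = test_i.loss_over_b - test_j.loss_over_b
    num = rho * d_sp - (1.0 - rho) * d_l
    den = rho * d_sp - (1.0 - rho) * d_se
    if abs(den) < 1e-300:
        return None
    p = num / den
    return p if 0.0 <= p <= 1.0 else None


def pairwise_transition_rho(
    test_i: DiagnosticTest, test_j: DiagnosticTest, p: float
) -> float | None:
    """Trade-off at which preference switches between two tests, at fixed p.

        rho_ij = [p dSe - dl/b] / [p dSe - (1-p) dSp - dl/b]

    Returns ``None`` when the INB curves do not cross inside (0, 1).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p!r}")
    d_se = test_i.sensitivity - test_j.sensitivity
    d_sp = test_i.specificity - test_j.specificity
    d_l = test_i.loss_over_b - test_j.loss_over_b
    num = p * d_se - d_l
    den = p * d_se - (1.0 - p) * d_sp - d_l
    if abs(den) < 1e-300:
        return None
    rho = num / den
    return rho if 0.0 < rho < 1.0 else None
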