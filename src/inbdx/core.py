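"""Domain types for net-benefit analysis of diagnostic testing.

All utilities are handled internally in units of the treatment benefit *b*
(i.e., divided through by *b*), so that a treatment frame is fully described
by the cost-benefit trade-off ``rho = l / (l + b)`` and each test by its
operating point plus the dimensionless testing loss ``l_Dx / b``.  Absolute
currency values are accepted on input and reproduced on output, but never
required: two of the packaged case studies only supply ratios.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import yaml

logger = logging.getLogger("inbdx")

__all__ = [
    "TreatmentFrame",
    "DiagnosticTest",
    "OperatingPoint",
    "Rule",
    "Protocol",
    "PatientState",
    "make_treatment_frame",
    "test_loss_over_b",
    "parse_protocol",
    "load_panel",
    "dump_panel",
]

_EPS = 1e-12


def _check_prob(x: float, name: str) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {x!r}")


@dataclass(frozen=True)
class TreatmentFrame:
    """Benefit and loss of treatment, and their trade-off.

    ``benefit`` is the utility gain b of treating a diseased patient,
    ``loss`` the utility loss l of treating a healthy one, and
    ``rho = l / (l + b)`` the trade-off, which equals the treatment-threshold
    probability.  Any consistent subset may be supplied; missing members are
    derived when possible.  Optional components record how b and l were
    built from a willingness-to-pay per QALY, QALY gains/losses, and the
    treatment cost: ``b = lambda*qg - cRx`` and ``l = lambda*ql + cRx``.
    """

    benefit: float | None = None
    loss: float | None = None
    rho: float | None = None
    willingness_lambda: float | None = None
    qaly_gain: float | None = None
    qaly_loss: float | None = None
    treatment_cost: float | None = None

    def __post_init__(self) -> None:
        b, l, rho = self.benefit, self.loss, self.rho
        if b is not None and b <= 0:
            raise ValueError(f"treatment benefit must be positive, got {b!r}")
        if l is not None and l <= 0:
            raise ValueError(f"treatment loss must be positive, got {l!r}")
        if rho is None and b is not None and l is not None:
            object.__setattr__(self, "rho", l / (l + b))
        elif rho is not None:
            if not (0.0 < rho < 1.0):
                raise ValueError(
                    f"rho must lie strictly inside (0, 1), got {rho!r}; "
                    "rho = 0 or 1 is a degenerate trade-off"
                )
            if b is not None and l is None:
                object.__setattr__(self, "loss", b * rho / (1.0 - rho))
            elif l is not None and b is None:
                object.__setattr__(self, "benefit", l * (1.0 - rho) / rho)
            elif b is not None and l is not None:
                implied = l / (l + b)
                if abs(implied - rho) > 1e-9:
                    raise ValueError(
                        f"inconsistent frame: rho={rho!r} but l/(l+b)={implied!r}"
                    )

    @property
    def odds(self) -> float:
        """rho / (1 - rho) = l / b, the loss-benefit ratio."""
        if self.rho is None:
            raise ValueError("frame has no trade-off: set rho or both benefit and loss")
        return self.rho / (1.0 - self.rho)

    def require_rho(self) -> float:
        if self.rho is None:
            raise ValueError("frame has no trade-off: set rho or both benefit and loss")
        return self.rho


def make_treatment_frame(
    lambda_: float, qg: float, ql: float, cRx: float
) -> TreatmentFrame:
    """Build a treatment frame from QALY components.

    b = lambda*qg - cRx  and  l = lambda*ql + cRx; both must come out
    positive for the trade-off to be well defined.
    """
    if min(lambda_, qg, ql, cRx) < 0:
        raise ValueError("lambda, qg, ql, cRx must all be non-negative")
    b = lambda_ * qg - cRx
    l = lambda_ * ql + cRx
    if b <= 0:
        raise ValueError(
            f"non-positive treatment benefit: lambda*qg - cRx = {b!r}; "
            "treatment must be worth its cost for a diseased patient"
        )
    if l <= 0:
        raise ValueError(f"non-positive treatment loss: lambda*ql + cRx = {l!r}")
    return TreatmentFrame(
        benefit=b,
        loss=l,
        willingness_lambda=lambda_,
        qaly_gain=qg,
        qaly_loss=ql,
        treatment_cost=cRx,
    )


def test_loss_over_b(cDx: float, qhDx: float, lambda_: float, b: float) -> float:
    """Normalized utility loss of one test: (lambda*qhDx + cDx) / b."""
    if min(cDx, qhDx, lambda_) < 0:
        raise ValueError("cDx, qhDx and lambda must be non-negative")
    if b <= 0:
        raise ValueError(f"treatment benefit must be positive, got {b!r}")
    return (lambda_ * qhDx + cDx) / b


@dataclass(frozen=True)
class OperatingPoint:
    """A (sensitivity, specificity) pair in ROC space."""

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        _check_prob(self.sensitivity, "sensitivity")
        _check_prob(self.specificity, "specificity")

    @property
    def youden(self) -> float:
        return self.sensitivity - (1.0 - self.specificity)

    @property
    def lr_plus(self) -> float:
        fpr = 1.0 - self.specificity
        return self.sensitivity / fpr if fpr > 0 else math.inf

    @property
    def lr_minus(self) -> float:
        if self.specificity == 0:
            return math.inf
        return (1.0 - self.sensitivity) / self.specificity


@dataclass(frozen=True)
class DiagnosticTest:
    """One binary diagnostic test.

    ``loss_over_b`` is the normalized utility loss of administering the test,
    l_Dx / b = (lambda*qhDx + cDx) / b.  It may be given directly (ratio-only
    panels) or derived from cost/harm components via a treatment frame.
    """

    name: str
    sensitivity: float
    specificity: float
    cost: float = 0.0
    harm: float = 0.0
    loss_over_b: float = 0.0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("test name must be non-empty")
        _check_prob(self.sensitivity, "sensitivity")
        _check_prob(self.specificity, "specificity")
        if self.cost < 0 or self.harm < 0 or self.loss_over_b < 0:
            raise ValueError("cost, harm and loss_over_b must be non-negative")
        if self.sensitivity + self.specificity <= 1.0:
            logger.warning(
                "test %r is no better than chance (Se + Sp = %.3f <= 1)",
                self.name,
                self.sensitivity + self.specificity,
            )

    @classmethod
    def from_components(
        cls,
        name: str,
        sensitivity: float,
        specificity: float,
        cost: float,
        harm: float,
        frame: TreatmentFrame,
        lambda_: float | None = None,
    ) -> "DiagnosticTest":
        lam = lambda_ if lambda_ is not None else (frame.willingness_lambda or 0.0)
        if frame.benefit is None:
            raise ValueError("frame must carry an absolute benefit to scale test losses")
        lob = test_loss_over_b(cost, harm, lam, frame.benefit)
        return cls(name, sensitivity, specificity, cost, harm, lob)

    @property
    def operating_point(self) -> OperatingPoint:
        return OperatingPoint(self.sensitivity, self.specificity)

    @property
    def youden(self) -> float:
        return self.operating_point.youden


class Rule(str, enum.Enum):
    """Positivity criterion for a multi-test protocol."""

    AND = "and"  # treat only if every test positive; stop at first negative
    OR = "or"  # treat if any test positive; stop at first positive
    MAJORITY = "majority"  # treat if most tests positive; stop once decided

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Protocol:
    """An ordered sequence of tests with a positivity rule.

    The rule is irrelevant for a single test.  Majority protocols must have
    odd length >= 3 so a strict majority always exists.
    """

    tests: tuple[DiagnosticTest, ...]
    rule: Rule = Rule.AND

    def __init__(self, tests: Sequence[DiagnosticTest], rule: Rule | str = Rule.AND):
        object.__setattr__(self, "tests", tuple(tests))
        object.__setattr__(self, "rule", Rule(rule))
        if len(self.tests) < 1:
            raise ValueError("protocol needs at least one test")
        names = [t.name for t in self.tests]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate test names in protocol: {names}")
        if self.rule is Rule.MAJORITY and len(self.tests) > 1:
            n = len(self.tests)
            if n % 2 == 0 or n < 3:
                raise ValueError(
                    f"majority protocols need odd length >= 3, got {n}"
                )

    def __len__(self) -> int:
        return len(self.tests)

    @property
    def id(self) -> str:
        """Canonical protocol string, e.g. ``A&B``, ``A|B``, ``maj(A,B,C)``."""
        names = [t.name for t in self.tests]
        if len(names) == 1:
            return names[0]
        if self.rule is Rule.AND:
            return "&".join(names)
        if self.rule is Rule.OR:
            return "|".join(names)
        return "maj(" + ",".join(names) + ")"

    @property
    def total_loss(self) -> float:
        return sum(t.loss_over_b for t in self.tests)


@dataclass(frozen=True)
class PatientState:
    """Pre-test disease probability and treatment trade-off of one patient."""

    p: float
    rho: float

    def __post_init__(self) -> None:
        _check_prob(self.p, "p")
        if not (0.0 < self.rho < 1.0):
            raise ValueError(f"rho must lie strictly inside (0, 1), got {self.rho!r}")


def parse_protocol(
    spec: str, tests: Mapping[str, DiagnosticTest] | Iterable[DiagnosticTest]
) -> Protocol:
    """Parse a protocol string against a panel of named tests.

    Grammar: ``A`` (single test), ``A&B&C`` (conjunctive), ``A|B|C``
    (disjunctive), ``maj(A,B,C)`` (majority).  Mixing ``&`` and ``|`` in one
    protocol is rejected; mixed expression trees are out of scope.
    """
    if not isinstance(tests, Mapping):
        tests = {t.name: t for t in tests}
    s = spec.strip()
    if not s:
        raise ValueError("empty protocol string")

    def lookup(name: str) -> DiagnosticTest:
        name = name.strip()
        if name not in tests:
            raise KeyError(
                f"unknown test {name!r}; available: {sorted(tests)}"
            )
        return tests[name]

    low = s.lower()
    if low.startswith("maj(") and s.endswith(")"):
        inner = s[4:-1]
        members = [lookup(n) for n in inner.split(",")]
        return Protocol(members, Rule.MAJORITY)
    if "&" in s and "|" in s:
        raise ValueError(
            f"mixed '&' and '|' in {spec!r}: only pure conjunction, pure "
            "disjunction, or maj(...) protocols are supported"
        )
    if "&" in s:
        return Protocol([lookup(n) for n in s.split("&")], Rule.AND)
    if "|" in s:
        return Protocol([lookup(n) for n in s.split("|")], Rule.OR)
    return Protocol([lookup(s)], Rule.AND)


# ---------------------------------------------------------------------------
# Config I/O (YAML): a panel is a treatment frame plus a list of tests.

def _frame_from_dict(d: Mapping) -> TreatmentFrame:
    known = {
        "benefit",
        "loss",
        "rho",
        "willingness_lambda",
        "qaly_gain",
        "qaly_loss",
        "treatment_cost",
    }
    extra = set(d) - known
    if extra:
        raise ValueError(f"unknown treatment-frame fields: {sorted(extra)}")
    return TreatmentFrame(**{k: float(v) for k, v in d.items()})


def _test_from_dict(d: Mapping, frame: TreatmentFrame) -> DiagnosticTest:
    known = {"name", "sensitivity", "specificity", "cost", "harm", "loss_over_b"}
    extra = set(d) - known
    if extra:
        raise ValueError(f"unknown test fields for {d.get('name')!r}: {sorted(extra)}")
    for req in ("name", "sensitivity", "specificity"):
        if req not in d:
            raise ValueError(f"test entry missing required field {req!r}: {d!r}")
    name = str(d["name"])
    se, sp = float(d["sensitivity"]), float(d["specificity"])
    cost = float(d.get("cost", 0.0))
    harm = float(d.get("harm", 0.0))
    if "loss_over_b" in d:
        lob = float(d["loss_over_b"])
    elif cost or harm:
        if frame.benefit is None:
            raise ValueError(
                f"test {name!r} gives cost/harm but the frame has no benefit "
                "to normalize by; supply loss_over_b or frame.benefit"
            )
        lob = test_loss_over_b(cost, harm, frame.willingness_lambda or 0.0, frame.benefit)
    else:
        lob = 0.0
    return DiagnosticTest(name, se, sp, cost, harm, lob)


def load_panel(source) -> tuple[list[DiagnosticTest], TreatmentFrame]:
    """Read a test panel and treatment frame from a YAML file or stream.

    Schema::

        frame: {benefit: 75000, willingness_lambda: 100000, ...}
        tests:
          - {name: FIT, sensitivity: 0.733, specificity: 0.964, cost: 19}
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "tests" not in doc:
        raise ValueError("panel config must be a mapping with a 'tests' list")
    frame = _frame_from_dict(doc.get("frame") or {})
    tests = [_test_from_dict(t, frame) for t in doc["tests"]]
    if not tests:
        raise ValueError("panel config lists no tests")
    names = [t.name for t in tests]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate test names in panel: {names}")
    return tests, frame


def dump_panel(
    tests: Sequence[DiagnosticTest], frame: TreatmentFrame, path
) -> None:
    """Write a panel back to YAML in the same schema ``load_panel`` reads."""
    frame_d = {
        k: getattr(frame, k)
        for k in (
            "benefit",
            "loss",
            "rho",
            "willingness_lambda",
            "qaly_gain",
            "qaly_loss",
            "treatment_cost",
        )
        if getattr(frame, k) is not None
    }
    doc = {
        "frame": frame_d,
        "tests": [
            {
                "name": t.name,
                "sensitivity": t.sensitivity,
                "specificity": t.specificity,
                "cost": t.cost,
                "harm": t.harm,
                "loss_over_b": t.loss_over_b,
            }
            for t in tests
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
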