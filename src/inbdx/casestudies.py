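"""Packaged parameter panels for three worked applications — prostate
cancer, colorectal cancer, and stable coronary artery disease — plus a
seeded random-panel generator for property tests.

Each fixture ships as a YAML file in the same schema the CLI reads for
user-supplied panels, so ``--case prostate`` and ``--config panel.yaml``
are interchangeable.  Every parameter carries a provenance note pointing
at its clinical source.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .core import DiagnosticTest, TreatmentFrame, _frame_from_dict, _test_from_dict

__all__ = ["CaseStudy", "CASE_NAMES", "load_case_study", "case_path", "random_panel"]

CASE_NAMES = ("prostate", "colorectal", "cad")


@dataclass(frozen=True)
class CaseStudy:
    name: str
    tests: tuple[DiagnosticTest, ...]
    frame: TreatmentFrame
    notes: dict[str, str]

    def test(self, name: str) -> DiagnosticTest:
        for t in self.tests:
            if t.name == name:
                return t
        raise KeyError(f"no test {name!r} in case study {self.name!r}")

    @property
    def tests_by_name(self) -> dict[str, DiagnosticTest]:
        return {t.name: t for t in self.tests}


def case_path(name: str):
    """Path-like resource handle for a packaged case-study YAML file."""
    if name not in CASE_NAMES:
        raise KeyError(
            f"unknown case study {name!r}; available: {', '.join(CASE_NAMES)}"
        )
    return resources.files("inbdx.data").joinpath(f"{name}.yaml")


def load_case_study(name: str) -> CaseStudy:
    """Load one of the packaged case studies by name."""
    doc = yaml.safe_load(case_path(name).read_text())
    frame = _frame_from_dict(doc.get("frame") or {})
    tests = tuple(_test_from_dict(t, frame) for t in doc["tests"])
    return CaseStudy(
        name=doc.get("name", name),
        tests=tests,
        frame=frame,
        notes={str(k): str(v) for k, v in (doc.get("notes") or {}).items()},
    )


def random_panel(n_tests: int, seed: int) -> list[DiagnosticTest]:
    """Deterministic pseudo-random panel for property tests.

    Se, Sp ~ U(0.5, 1) keep tests informative; loss_over_b ~ U(0, 0.05)
    spans the realistic range of normalized testing losses (the packaged
    panels sit between 2.5e-4 and 0.1).
    """
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    rng = np.random.default_rng(seed)
    return [
        DiagnosticTest(
            name=f"T{i}",
            sensitivity=float(rng.uniform(0.5, 1.0)),
            specificity=float(rng.uniform(0.5, 1.0)),
            loss_over_b=float(rng.uniform(0.0, 0.05)),
        )
        for i in range(n_tests)
    ]
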