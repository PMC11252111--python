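"""Expert-survey scoring of the final summaries.

Two experts rate the presented summaries on five questions (1-10 scale):
informativeness, accuracy of the ASD/TD contrast, simplicity, content
richness, and usefulness.  A per-summary quality score averages the
truthfulness/relevance dimension (questions 1-2) with the clarity dimension
(questions 3-5); the global quality score is the mean over summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["SurveyResponse", "summary_quality", "global_quality"]


@dataclass(frozen=True)
class SurveyResponse:
    """Per-question expert averages (1-10) over ``n`` assessed summaries."""

    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    n: int = 1

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "p4", "p5"):
            v = float(getattr(self, name))
            if not (1.0 <= v <= 10.0):
                raise ValueError(f"{name}={v} outside the 1-10 rating scale")
        if self.n < 1:
            raise ValueError("n must be at least 1")


def summary_quality(r: SurveyResponse) -> float:
    """Per-summary quality: ((P1+P2)/2 + (P3+P4+P5)/3) / 2."""
    return ((r.p1 + r.p2) / 2.0 + (r.p3 + r.p4 + r.p5) / 3.0) / 2.0


def global_quality(scores: Sequence[float]) -> float:
    """Global quality: arithmetic mean of per-summary quality scores."""
    scores = list(scores)
    if not scores:
        raise ValueError("global quality of an empty score list")
    return sum(scores) / len(scores)
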