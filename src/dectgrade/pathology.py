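"""Histologic subtype compositions and 3-level tumor grading.

Comprehensive subtyping records the percentage of each adenocarcinoma
growth pattern (lepidic, acinar, papillary, micropapillary, solid) in the
resected tumor, to the nearest 5%.  The predominant pattern — with central
fibrosis disregarded — determines the grade: adenocarcinoma in situ (AIS),
minimally invasive adenocarcinoma (MIA) and lepidic-predominant tumors are
grade 1; acinar- or papillary-predominant tumors grade 2; micropapillary-
or solid-predominant tumors grade 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidCompositionError, InvalidPatternError

INVASIVE_PATTERNS = ("lepidic", "acinar", "papillary", "micropapillary", "solid")

#: Clinical aggressiveness ranking used only to break exact percentage ties.
AGGRESSIVENESS_RANK = {
    "lepidic": 1, "acinar": 2, "papillary": 3, "micropapillary": 4, "solid": 5,
}

PATTERN_GRADE = {
    "lepidic": 1, "acinar": 2, "papillary": 2, "micropapillary": 3, "solid": 3,
}

HISTOLOGY_CLASSES = ("AIS", "MIA", "invasive")

#: Recording granularity of comprehensive subtyping (percent).
PERCENT_GRANULARITY = 5.0


@dataclass
class SubtypeComposition:
    """Percentages of each growth pattern plus central fibrosis.

    ``percentages`` maps pattern name to percent of tumor area; patterns may
    be omitted (treated as 0).  ``histology_class`` distinguishes AIS and
    MIA, which are grade 1 regardless of pattern, from invasive tumors.
    """

    percentages: dict[str, float] = field(default_factory=dict)
    central_fibrosis: float = 0.0
    histology_class: str = "invasive"

    def __post_init__(self) -> None:
        unknown = [p for p in self.percentages if p not in INVASIVE_PATTERNS]
        if unknown:
            raise InvalidPatternError(f"unknown pattern name(s): {unknown}")
        if self.histology_class not in HISTOLOGY_CLASSES:
            raise InvalidPatternError(
                f"histology_class must be one of {HISTOLOGY_CLASSES}, "
                f"got {self.histology_class!r}"
            )
        vals = list(self.percentages.values()) + [self.central_fibrosis]
        if any(v < 0 for v in vals):
            raise InvalidCompositionError("percentages must be nonnegative")
        subtype_total = sum(self.percentages.values())
        if subtype_total > 100.0 + 1e-9:
            raise InvalidCompositionError(
                f"subtype percentages sum to {subtype_total}, exceeding 100"
            )
        off_grid = [
            v for v in vals if abs(v / PERCENT_GRANULARITY - round(v / PERCENT_GRANULARITY)) > 1e-9
        ]
        if off_grid:
            warnings.warn(
                f"percentages {off_grid} are not multiples of "
                f"{PERCENT_GRANULARITY}%; recording granularity is nominally 5%",
                stacklevel=2,
            )


@dataclass(frozen=True)
class GradeLabel:
    """Assigned tumor grade with the pattern that determined it."""

    grade: int
    predominant_pattern: str
    predominant_percentage: float
    tie: bool = False


def predominant_pattern(c: SubtypeComposition) -> tuple[str, float, bool]:
    """Pattern with the largest percentage, central fibrosis disregarded.

    Exact ties are broken toward the more aggressive pattern and flagged in
    the returned triple ``(pattern, percentage, tie)``.
    """
    nonzero = {p: v for p, v in c.percentages.items() if v > 0}
    if not nonzero:
        raise InvalidCompositionError("all subtype percentages are zero")
    top = max(nonzero.values())
    winners = [p for p, v in nonzero.items() if np.isclose(v, top)]
    winner = max(winners, key=lambda p: AGGRESSIVENESS_RANK[p])
    return winner, float(top), len(winners) > 1


def assign_grade(c: SubtypeComposition) -> GradeLabel:
    """Map a subtype composition to the 3-level grade.

    AIS and MIA are grade 1 regardless of recorded patterns; invasive tumors
    are graded by their predominant pattern.
    """
    if c.histology_class in ("AIS", "MIA"):
        if c.percentages and any(v > 0 for v in c.percentages.values()):
            pattern, pct, tie = predominant_pattern(c)
        else:
            pattern, pct, tie = c.histology_class, 100.0, False
        return GradeLabel(grade=1, predominant_pattern=pattern,
                          predominant_percentage=pct, tie=tie)
    pattern, pct, tie = predominant_pattern(c)
    return GradeLabel(grade=PATTERN_GRADE[pattern], predominant_pattern=pattern,
                      predominant_percentage=pct, tie=tie)
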