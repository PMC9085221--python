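"""The decisive-gene verdict engine.

Combines the cumulative Z curve, the sequential boundaries and the
required information size into one of four conclusions per locus and
ethnicity stratum:

``conclusive_risk`` / ``conclusive_protective``
    the Z curve crossed the monitoring boundary, in the direction of an
    odds ratio above / below 1 for the minor allele;
``conclusive_null``
    the Z curve entered the futility wedge, or the accumulated subjects
    reached the RIS without a significance crossing;
``inconclusive``
    none of the above — the verdict reports how many more subjects are
    still needed (RIS minus accumulated subjects).

Strata are classified fully independently: no information is borrowed
across ethnicities.  Direction labels refer to the minor allele as coded
in the design config; each verdict carries a note recording that
orientation.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .meta_engine import PooledResult
from .sequential import BoundarySet, SequentialDesign, evaluate_crossing

__all__ = [
    "VerdictCategory",
    "HetLabel",
    "DgsVerdict",
    "CrossTab",
    "classify_locus",
    "heterogeneity_label",
    "cross_tab",
    "remaining_samples",
]


class VerdictCategory(str, enum.Enum):
    CONCLUSIVE_RISK = "conclusive_risk"
    CONCLUSIVE_PROTECTIVE = "conclusive_protective"
    CONCLUSIVE_NULL = "conclusive_null"
    INCONCLUSIVE = "inconclusive"


class HetLabel(str, enum.Enum):
    HIGH = "high"
    LOW = "low"


def heterogeneity_label(i2_percent: float) -> HetLabel:
    """High heterogeneity iff I-squared exceeds 50% strictly (50 is low)."""
    return HetLabel.HIGH if i2_percent > 50.0 else HetLabel.LOW


def remaining_samples(design: SequentialDesign, cumulative_subjects: int) -> int:
    """Subjects still to accumulate before the RIS: max(0, ris - n)."""
    return max(0, design.ris - int(cumulative_subjects))


@dataclass(frozen=True)
class DgsVerdict:
    locus_id: str
    ethnicity: str
    category: VerdictCategory
    remaining_subjects: int
    het_label: HetLabel
    pooled: PooledResult | None = None
    crossing_look: int | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if (self.category is VerdictCategory.INCONCLUSIVE) != (self.remaining_subjects > 0):
            raise ValueError(
                "remaining_subjects must be positive exactly for inconclusive verdicts"
            )


def classify_locus(
    series: Sequence[PooledResult],
    design: SequentialDesign,
    boundaries: BoundarySet,
    ethnicity: str = "",
    minor_allele_note: str = "minor allele per design reference is the exposure",
) -> DgsVerdict:
    """Classify one locus/stratum from its cumulative pooling series.

    The significance crossing takes precedence; absent one, a futility
    crossing or RIS completion yields a conclusive null; otherwise the
    verdict is inconclusive with the exact remaining-subject count.  A
    nominally significant final pooled p-value without a boundary crossing
    stays inconclusive and is remarked on in the note.
    """
    if not series:
        raise ValueError("cannot classify an empty cumulative series")
    z_series = [r.z for r in series]
    n_series = [r.cumulative_subjects for r in series]
    report = evaluate_crossing(z_series, n_series, design, boundaries)
    final = series[-1]
    note = minor_allele_note

    if report.significance_look is not None:
        at_cross = series[report.significance_look]
        category = (
            VerdictCategory.CONCLUSIVE_RISK
            if at_cross.pooled_log_or > 0
            else VerdictCategory.CONCLUSIVE_PROTECTIVE
        )
        return DgsVerdict(
            locus_id=design.locus_id,
            ethnicity=ethnicity,
            category=category,
            remaining_subjects=0,
            het_label=heterogeneity_label(final.i2),
            pooled=final,
            crossing_look=report.significance_look,
            note=note,
        )

    if report.futility_look is not None or report.ris_reached:
        return DgsVerdict(
            locus_id=design.locus_id,
            ethnicity=ethnicity,
            category=VerdictCategory.CONCLUSIVE_NULL,
            remaining_subjects=0,
            het_label=heterogeneity_label(final.i2),
            pooled=final,
            crossing_look=report.futility_look,
            note=note,
        )

    if final.p_value < design.alpha:
        note += "; nominally significant but no boundary crossing"
    return DgsVerdict(
        locus_id=design.locus_id,
        ethnicity=ethnicity,
        category=VerdictCategory.INCONCLUSIVE,
        remaining_subjects=remaining_samples(design, final.cumulative_subjects),
        het_label=heterogeneity_label(final.i2),
        pooled=final,
        crossing_look=None,
        note=note,
    )


# -- cross-tabulation --------------------------------------------------------

_CATEGORY_COLUMNS = (
    VerdictCategory.CONCLUSIVE_RISK,
    VerdictCategory.CONCLUSIVE_PROTECTIVE,
    VerdictCategory.CONCLUSIVE_NULL,
    VerdictCategory.INCONCLUSIVE,
)


@dataclass(frozen=True)
class CrossTab:
    """2x4 grid of {high, low heterogeneity} x verdict category.

    ``cells`` maps ``(het_label, category)`` to a sorted tuple of locus ids;
    every classified locus appears in exactly one cell.
    """

    cells: dict[tuple[HetLabel, VerdictCategory], tuple[str, ...]]

    def count(self, het: HetLabel, category: VerdictCategory) -> int:
        return len(self.cells.get((het, category), ()))

    def row_count(self, het: HetLabel) -> int:
        return sum(self.count(het, c) for c in _CATEGORY_COLUMNS)

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.cells.values())

    def to_text(self) -> str:
        """Plain-text grid with one row per heterogeneity level."""
        headers = ["", "risk", "protect", "not_association", "still_need_samples"]
        lines = ["\t".join(headers)]
        for het in (HetLabel.HIGH, HetLabel.LOW):
            row = [het.value]
            for cat in _CATEGORY_COLUMNS:
                row.append(",".join(self.cells.get((het, cat), ())) or "-")
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def cross_tab(verdicts: Iterable[DgsVerdict]) -> CrossTab:
    """Cross-tabulate verdict categories against heterogeneity labels."""
    cells: dict[tuple[HetLabel, VerdictCategory], list[str]] = {}
    for v in verdicts:
        cells.setdefault((v.het_label, v.category), []).append(v.locus_id)
    return CrossTab(
        cells={key: tuple(sorted(ids)) for key, ids in cells.items()}
    )
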