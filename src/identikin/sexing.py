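"""Genetic sex inference from per-chromosome mapped-read counts.

A diploid female carries two X and no Y, a male one of each, so the
length-normalized X:Y coverage ratio separates the sexes by roughly an
order of magnitude (female Y coverage comes only from mismapped reads).
Absolute ratios depend on mapping and normalization conventions, so
classification thresholds are calibrated from individuals of known sex
rather than fixed a priori.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .containers import ChromCounts

MALE = "male"
FEMALE = "female"
UNDETERMINED = "undetermined"

#: multiplicative widening applied to the calibration ranges
DEFAULT_MARGIN = 0.25


@dataclass(frozen=True)
class SexThresholds:
    """Decision band on the X:Y coverage-ratio scale.

    Ratios at or below ``male_upper`` call male, at or above
    ``female_lower`` call female; the open interval between them is an
    explicit undetermined band.
    """

    male_upper: float
    female_lower: float

    def __post_init__(self) -> None:
        if not self.male_upper < self.female_lower:
            raise ValueError(
                f"male_upper ({self.male_upper}) must be below "
                f"female_lower ({self.female_lower})"
            )


@dataclass(frozen=True)
class SexCall:
    sample: str
    ratio: float
    call: str  # male / female / undetermined
    y_absent: bool = False  # Y mapped count was zero (ratio is +inf)


def xy_ratio(counts: ChromCounts) -> float:
    """Length-normalized X:Y coverage ratio.

    Returns ``(mapped_X / length_X) / (mapped_Y / length_Y)``. A zero Y
    count returns ``+inf`` (interpreted downstream as strongly female).
    """
    x = counts.get("X")
    y = counts.get("Y")
    x_cov = x["mapped"] / x["length"]
    if y["mapped"] == 0:
        return math.inf
    return float(x_cov / (y["mapped"] / y["length"]))


def calibrate_thresholds(
    labeled_ratios: Iterable[tuple[float, str]],
    margin: float = DEFAULT_MARGIN,
) -> SexThresholds:
    """Derive thresholds from X:Y ratios of known-sex individuals.

    ``male_upper`` is the largest male ratio widened by ``margin``;
    ``female_lower`` the smallest finite female ratio narrowed by it.
    Overlapping widened bands are rejected rather than split.
    """
    males = [r for r, s in labeled_ratios if s == MALE]
    females = [r for r, s in labeled_ratios if s == FEMALE]
    if not males or not females:
        raise ValueError("calibration needs at least one known male and one known female")
    finite_females = [r for r in females if math.isfinite(r)] or females
    male_upper = max(males) * (1 + margin)
    female_lower = min(finite_females) * (1 - margin)
    if male_upper >= female_lower:
        raise ValueError(
            "male and female ratio clusters overlap after margin widening "
            f"(male_upper={male_upper:.3f} >= female_lower={female_lower:.3f}); "
            "check the labeled calibration set"
        )
    return SexThresholds(male_upper=male_upper, female_lower=female_lower)


def classify_sex(ratio: float, thresholds: SexThresholds, sample: str = "") -> SexCall:
    """Classify one X:Y ratio; ties at a threshold resolve to the labeled side."""
    if ratio <= thresholds.male_upper:
        call = MALE
    elif ratio >= thresholds.female_lower:
        call = FEMALE
    else:
        call = UNDETERMINED
    return SexCall(sample=sample, ratio=ratio, call=call, y_absent=math.isinf(ratio))


def classify_counts(
    counts: Sequence[ChromCounts], thresholds: SexThresholds
) -> list[SexCall]:
    return [classify_sex(xy_ratio(c), thresholds, sample=c.sample) for c in counts]
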