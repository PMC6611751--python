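"""Biopsy-level adjusted grade-group determination.

A biopsy's grade group is derived from how much of it is Gleason pattern 3
versus pattern >=4.  Because patterns 4 and 5 are merged upstream, the
standard five ISUP grade groups collapse to four "adjusted" grade groups:

    majority + minority   adjusted GG
    GP3  + GP3            1   (Gleason score <= 6)
    GP3  + GP>=4          2   (3 + >=4)
    GP>=4 + GP3           3   (>=4 + 3)
    GP>=4 + GP>=4         4   (Gleason score >= 8)

A pattern is considered present only if at least ``min_fraction`` (default
4.5%) of the biopsy's classified patches carry it, which suppresses noise
from isolated false-positive patches.  When only one pattern is present it
is doubled (counted as both majority and minority); when neither is, the
biopsy is reported BENIGN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fusion import FusedClass

BENIGN = "BENIGN"

DEFAULT_MIN_FRACTION = 0.045

#: (majority, minority) -> adjusted grade group
ADJUSTED_GG_MAP: dict[tuple[str, str], int] = {
    ("GP3", "GP3"): 1,
    ("GP3", "GP4PLUS"): 2,
    ("GP4PLUS", "GP3"): 3,
    ("GP4PLUS", "GP4PLUS"): 4,
}


@dataclass
class GradingConfig:
    min_fraction: float = DEFAULT_MIN_FRACTION
    mapping: Mapping[tuple[str, str], int] = field(default_factory=lambda: dict(ADJUSTED_GG_MAP))

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_fraction <= 1.0:
            raise ValueError("min_fraction must be in [0, 1]")
        for maj in ("GP3", "GP4PLUS"):
            for mino in ("GP3", "GP4PLUS"):
                if (maj, mino) not in self.mapping:
                    raise ValueError(f"mapping is missing the pair ({maj}, {mino})")


@dataclass
class SlideGrade:
    biopsy_id: str
    frac_gp3: float
    frac_gp4plus: float
    majority: str | None
    minority: str | None
    adjusted_gg: int | str  # 1..4 or BENIGN


def compute_fractions(labels: Sequence[FusedClass | str]) -> tuple[float, float]:
    """Fractions of GP3 and GP>=4 among all classified patches of a biopsy.

    The denominator is every classified patch, non-atypical ones included,
    so the fractions estimate area fractions of the whole biopsy.
    """
    if len(labels) == 0:
        raise ValueError("cannot compute fractions of an empty label list")
    norm = [l if isinstance(l, str) else l.name for l in labels]
    norm = [l.upper() for l in norm]
    n = len(norm)
    return norm.count("GP3") / n, norm.count("GP4PLUS") / n


def assign_adjusted_gg(
    frac_gp3: float,
    frac_gp4plus: float,
    cfg: GradingConfig | None = None,
    biopsy_id: str = "",
) -> SlideGrade:
    """Apply the presence threshold and the majority/minority summation rule.

    Patterns below ``cfg.min_fraction`` are treated as absent.  Both absent
    -> BENIGN; one present -> it is doubled; both present -> the larger
    fraction is the majority (an exact tie grades up: GP>=4 is taken as
    majority).  The adjusted grade group follows the mapping table.
    """
    cfg = cfg or GradingConfig()
    for name, frac in (("frac_gp3", frac_gp3), ("frac_gp4plus", frac_gp4plus)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name}={frac} outside [0, 1]")
    if frac_gp3 + frac_gp4plus > 1.0 + 1e-9:
        raise ValueError("fractions sum to more than 1")
    gp3_present = frac_gp3 >= cfg.min_fraction and frac_gp3 > 0
    gp4_present = frac_gp4plus >= cfg.min_fraction and frac_gp4plus > 0
    if not gp3_present and not gp4_present:
        return SlideGrade(biopsy_id, frac_gp3, frac_gp4plus, None, None, BENIGN)
    if gp3_present and gp4_present:
        if frac_gp4plus >= frac_gp3:  # tie grades up
            majority, minority = "GP4PLUS", "GP3"
        else:
            majority, minority = "GP3", "GP4PLUS"
    elif gp3_present:
        majority = minority = "GP3"  # doubling rule
    else:
        majority = minority = "GP4PLUS"
    gg = cfg.mapping[(majority, minority)]
    return SlideGrade(biopsy_id, frac_gp3, frac_gp4plus, majority, minority, gg)


def grade_cohort(fused: pd.DataFrame, cfg: GradingConfig | None = None) -> list[SlideGrade]:
    """One SlideGrade per biopsy from a fused-label table.

    ``fused`` needs columns ``biopsy_id`` and ``fused_label`` (values
    non_atypical / gp3 / gp4plus).  Output is sorted by biopsy_id.
    """
    cfg = cfg or GradingConfig()
    grades = []
    for biopsy_id, group in fused.groupby("biopsy_id", sort=True):
        labels = [str(l) for l in group["fused_label"]]
        frac3, frac4 = compute_fractions(
            ["GP3" if l == "gp3" else "GP4PLUS" if l == "gp4plus" else "NON_ATYPICAL" for l in labels]
        )
        grades.append(assign_adjusted_gg(frac3, frac4, cfg, biopsy_id=str(biopsy_id)))
    return grades


def grade_from_area_fractions(
    area_fractions: Mapping[str, float],
    cfg: GradingConfig | None = None,
    biopsy_id: str = "",
) -> SlideGrade:
    """Reference-standard grade from annotated surface-area fractions.

    The reference grade uses the surface area of the annotated GP3 and
    GP>=4 regions relative to the biopsy's total annotated area, whereas the
    predicted grade uses classified-patch fractions; both paths share the
    same threshold-and-sum rule.
    """
    return assign_adjusted_gg(
        float(area_fractions.get("gp3", area_fractions.get("GP3", 0.0))),
        float(area_fractions.get("gp4plus", area_fractions.get("GP4PLUS", 0.0))),
        cfg,
        biopsy_id=biopsy_id,
    )


def grades_to_frame(grades: Iterable[SlideGrade]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "biopsy_id": g.biopsy_id,
                "frac_gp3": g.frac_gp3,
                "frac_gp4plus": g.frac_gp4plus,
                "majority": g.majority,
                "minority": g.minority,
                "adjusted_gg": g.adjusted_gg,
            }
            for g in grades
        ]
    )


def gg_to_ordinal(gg: int | str) -> int:
    """Map BENIGN/1/2/3/4 onto the ordinal scale 0..4 for agreement statistics."""
    return 0 if gg == BENIGN else int(gg)
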