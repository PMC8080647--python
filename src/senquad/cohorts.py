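"""Deterministic cohort grouping rules for tissue analyses.

Age dichotomies (by decade band or by median age), age quartiles, and the
two tumor-stage dichotomies used for the early- vs late-stage contrasts:
scheme A puts only stage I (the noninvasive, localized state) in the early
group; scheme B splits I/II vs III/IV. Stage strings are normalized by
stripping a leading "stage" token and trailing substage letters (IA → I,
IIIB → III); stage 0, stage X and unparseable annotations are excluded, not
coerced.
"""

from __future__ import annotations

import math
import re
import warnings
from typing import Sequence

import numpy as np

__all__ = [
    "group_age_decades",
    "group_age_median",
    "group_age_quartiles",
    "group_stage",
]

OLD_DECADES = (50, 60, 70)
YOUNG_DECADES = (20, 30, 40)

_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4}
_ARABIC = {"1": 1, "2": 2, "3": 3, "4": 4}


class GroupingError(ValueError):
    pass


def _parse_decade(code: object) -> int:
    """Parse a decade code: 60, "60", "60-69" → 60."""
    text = str(code).strip()
    m = re.fullmatch(r"(\d+)\s*(?:-\s*\d+)?", text)
    if not m:
        raise GroupingError(f"unparseable age decade code {code!r}")
    value = int(m.group(1))
    if value % 10 != 0:
        raise GroupingError(f"age decade code {code!r} is not a decade multiple")
    return value


def group_age_decades(decades: Sequence[object]) -> list[str]:
    """Dichotomize decade-banded ages: 50/60/70 → old, 20/30/40 → young.

    Decades outside both ranges are labeled ``excluded`` with a warning
    (ages reported only in 10-year bands, as in GTEx).
    """
    labels: list[str] = []
    n_excluded = 0
    for code in decades:
        d = _parse_decade(code)
        if d in OLD_DECADES:
            labels.append("old")
        elif d in YOUNG_DECADES:
            labels.append("young")
        else:
            labels.append("excluded")
            n_excluded += 1
    if n_excluded:
        warnings.warn(
            f"{n_excluded} sample(s) outside decades 20-70 excluded from the "
            "age dichotomy",
            stacklevel=2,
        )
    return labels


def group_age_median(
    ages: Sequence[float], median: float | None = None
) -> list[str]:
    """Dichotomize by the (sample or supplied) median age.

    age > median → old, age ≤ median → young (ties fall on the young side,
    mirroring the quadrant ≤-split rule).
    """
    arr = [float(a) for a in ages]
    for a in arr:
        if not math.isfinite(a):
            raise GroupingError(f"non-finite age {a!r}")
    if len(arr) < 2 and median is None:
        raise GroupingError("need ≥2 ages to compute a median")
    split = float(np.median(arr)) if median is None else float(median)
    return ["old" if a > split else "young" for a in arr]


def group_age_quartiles(ages: Sequence[float]) -> list[str]:
    """Quartile bins A1 (youngest) … A4 (oldest) at the 25/50/75 percentiles.

    A value equal to a boundary falls in the lower bin; with heavy ties all
    samples can land in A1.
    """
    arr = np.asarray([float(a) for a in ages], dtype=float)
    if not np.isfinite(arr).all():
        raise GroupingError("non-finite age in input")
    if arr.size < 4:
        raise GroupingError(f"need ≥4 ages for quartiles, got {arr.size}")
    q25, q50, q75 = np.percentile(arr, [25, 50, 75])
    labels = np.where(
        arr <= q25, "A1", np.where(arr <= q50, "A2", np.where(arr <= q75, "A3", "A4"))
    )
    return list(labels)


def normalize_stage(stage: object) -> int | None:
    """Normalize a pathologic-stage string to 1–4, or None if unusable.

    Strips a leading "stage" token and trailing substage letters
    ("Stage IIIB" → 3). Stage 0, "Stage X" and anything unparseable → None.
    """
    if stage is None or (isinstance(stage, float) and math.isnan(stage)):
        return None
    text = str(stage).strip().upper()
    text = re.sub(r"^STAGE\s*", "", text)
    m = re.fullmatch(r"(IV|III|II|I|[1-4])([A-C]\d?)?", text)
    if not m:
        return None
    token = m.group(1)
    return _ROMAN.get(token) or _ARABIC.get(token)


def group_stage(stages: Sequence[object], scheme: str = "A") -> list[str]:
    """Dichotomize tumor stages into early vs late.

    Scheme A: stage I → early; II, III, IV → late (early = the noninvasive,
    localized state only). Scheme B: I, II → early; III, IV → late.
    Unparseable or absent stages are labeled ``excluded`` with a warning.
    """
    scheme = scheme.upper()
    if scheme not in ("A", "B"):
        raise GroupingError(f"unknown stage scheme {scheme!r}; use 'A' or 'B'")
    early_max = 1 if scheme == "A" else 2
    labels: list[str] = []
    n_excluded = 0
    for s in stages:
        num = normalize_stage(s)
        if num is None:
            labels.append("excluded")
            n_excluded += 1
        else:
            labels.append("early" if num <= early_max else "late")
    if n_excluded:
        warnings.warn(
            f"{n_excluded} sample(s) with unusable stage annotation excluded",
            stacklevel=2,
        )
    return labels
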