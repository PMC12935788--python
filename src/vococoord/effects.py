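"""Effect-size patterns over ranked eigenvalue spectra.

Per-recording spectra are first averaged within each (subject,
category) cell — rank-aligned, element-wise — so subjects with more
recordings do not dominate. For a pair of categories, Cohen's d is then
computed at every eigenvalue rank across the subject means
("subtracting category 2 from category 1"). The shape of d across
ranks is the effect-size pattern:

* positive-to-negative (front ranks positive, back ranks negative):
  category 1 concentrates more variance in its leading eigenvalues,
  i.e. category 1 has LOWER coordination complexity;
* negative-to-positive: category 1 has HIGHER complexity;
* anything else: unclear.

The classification rule compares the mean d over the front third of
ranks against the mean over the back third, with a small-effect floor
``theta`` (default 0.2) on both.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .corrstruct import ComboSpec, EigenSpectrum
from .errors import (
    InsufficientGroupError,
    InsufficientPatternError,
    InvalidInputError,
    UndefinedEffectError,
)

__all__ = [
    "LOWER_COMPLEXITY_IN_1",
    "HIGHER_COMPLEXITY_IN_1",
    "UNCLEAR",
    "SubjectCategorySpectrum",
    "EffectSizePattern",
    "PatternClassification",
    "average_by_subject",
    "cohens_d",
    "effect_pattern",
    "classify_pattern",
]

LOWER_COMPLEXITY_IN_1 = "lower_complexity_in_1"
HIGHER_COMPLEXITY_IN_1 = "higher_complexity_in_1"
UNCLEAR = "unclear"

_FLIP = {
    LOWER_COMPLEXITY_IN_1: HIGHER_COMPLEXITY_IN_1,
    HIGHER_COMPLEXITY_IN_1: LOWER_COMPLEXITY_IN_1,
    UNCLEAR: UNCLEAR,
}


@dataclass
class SubjectCategorySpectrum:
    """Element-wise mean of one subject's ranked spectra in one category."""

    subject_id: str
    category: str
    combo: ComboSpec
    mean_eigenvalues: np.ndarray
    n_recordings: int

    def __post_init__(self) -> None:
        self.mean_eigenvalues = np.asarray(self.mean_eigenvalues, dtype=np.float64)


@dataclass
class PatternClassification:
    """Label plus the front/back-third diagnostics behind it."""

    label: str
    front_mean: float
    back_mean: float


@dataclass
class EffectSizePattern:
    """Per-rank Cohen's d between two categories for one combination.

    ``d[r]`` compares the rank-``r`` eigenvalue across subjects of
    category 1 against category 2 (category 2 subtracted from category
    1). Missing ranks (undefined d) are NaN.
    """

    category_1: str
    category_2: str
    combo: ComboSpec
    d: np.ndarray
    n_subjects_1: int
    n_subjects_2: int
    label: str
    front_mean: float
    back_mean: float

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64)


def average_by_subject(
    spectra: "list[EigenSpectrum]",
) -> list[SubjectCategorySpectrum]:
    """Average ranked spectra element-wise within each (subject, category).

    Spectra are rank-aligned and NOT re-sorted after averaging. All
    spectra must share one combination.
    """
    if not spectra:
        raise InvalidInputError("no spectra given")
    combo = spectra[0].combo
    for s in spectra:
        if (s.combo.name, s.combo.channels, s.combo.n_delays) != (
            combo.name, combo.channels, combo.n_delays,
        ):
            raise InvalidInputError(
                f"mixed combos: {s.combo.name!r} vs {combo.name!r}"
            )
        if len(s) != combo.size:
            raise InvalidInputError(
                f"spectrum length {len(s)} != combo size {combo.size}"
            )

    cells: dict[tuple[str, str], list[np.ndarray]] = defaultdict(list)
    for s in spectra:
        cells[(s.subject_id, s.category)].append(s.eigenvalues)
    out = []
    for (subject_id, category), stack in sorted(cells.items()):
        out.append(
            SubjectCategorySpectrum(
                subject_id=subject_id,
                category=category,
                combo=combo,
                mean_eigenvalues=np.mean(stack, axis=0),
                n_recordings=len(stack),
            )
        )
    return out


def cohens_d(group_1, group_2) -> float:
    """Unpaired Cohen's d with pooled standard deviation.

    ``(mean1 - mean2) / s_pooled`` where ``s_pooled`` pools the two
    sample variances (n-1 denominators). Raises
    :class:`InsufficientGroupError` for groups smaller than two and
    :class:`UndefinedEffectError` when the pooled variance is zero.
    """
    g1 = np.asarray(group_1, dtype=np.float64)
    g2 = np.asarray(group_2, dtype=np.float64)
    n1, n2 = g1.size, g2.size
    if n1 < 2 or n2 < 2:
        raise InsufficientGroupError(
            f"each group needs >= 2 values, got {n1} and {n2}"
        )
    v1 = g1.var(ddof=1)
    v2 = g2.var(ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if pooled <= 0.0:
        raise UndefinedEffectError("pooled variance is zero")
    return float((g1.mean() - g2.mean()) / math.sqrt(pooled))


def classify_pattern(
    d: np.ndarray, theta: float = 0.2, min_ranks: int = 6
) -> PatternClassification:
    """Classify an effect-size pattern by its front/back-third means.

    With ``N`` ranks and ``k = ceil(N / 3)``: positive-to-negative
    (``front_mean >= +theta`` and ``back_mean <= -theta``) labels
    category 1 lower-complexity; the mirrored shape labels it
    higher-complexity; anything else is unclear. NaN (missing) ranks
    are excluded from the means; fewer than ``min_ranks`` non-missing
    ranks raises :class:`InsufficientPatternError`.
    """
    d = np.asarray(d, dtype=np.float64)
    n_ok = int(np.isfinite(d).sum())
    if n_ok < min_ranks:
        raise InsufficientPatternError(
            f"only {n_ok} non-missing ranks; need {min_ranks}"
        )
    k = math.ceil(d.size / 3)
    front = d[:k]
    back = d[-k:]
    if not (np.any(np.isfinite(front)) and np.any(np.isfinite(back))):
        raise InsufficientPatternError("front or back third entirely missing")
    front_mean = float(np.nanmean(front))
    back_mean = float(np.nanmean(back))
    if front_mean >= theta and back_mean <= -theta:
        label = LOWER_COMPLEXITY_IN_1
    elif front_mean <= -theta and back_mean >= theta:
        label = HIGHER_COMPLEXITY_IN_1
    else:
        label = UNCLEAR
    return PatternClassification(label=label, front_mean=front_mean, back_mean=back_mean)


def effect_pattern(
    s1: list[SubjectCategorySpectrum],
    s2: list[SubjectCategorySpectrum],
    combo: ComboSpec | None = None,
    theta: float = 0.2,
) -> EffectSizePattern:
    """Per-rank Cohen's d between two categories, with classification.

    ``s1`` and ``s2`` are the subject-mean spectra of categories 1 and
    2. Ranks where d is undefined (zero pooled variance) are recorded
    as NaN and excluded from the classification means.
    """
    if len(s1) < 2 or len(s2) < 2:
        raise InsufficientGroupError(
            f"need >= 2 subjects per category, got {len(s1)} and {len(s2)}"
        )
    if combo is None:
        combo = s1[0].combo
    size = combo.size
    a = np.stack([s.mean_eigenvalues for s in s1])  # (subjects, ranks)
    b = np.stack([s.mean_eigenvalues for s in s2])
    if a.shape[1] != size or b.shape[1] != size:
        raise InvalidInputError("spectrum length does not match combo size")

    d = np.full(size, np.nan)
    for r in range(size):
        try:
            d[r] = cohens_d(a[:, r], b[:, r])
        except UndefinedEffectError:
            pass  # recorded as missing
    cls = classify_pattern(d, theta=theta)
    return EffectSizePattern(
        category_1=s1[0].category,
        category_2=s2[0].category,
        combo=combo,
        d=d,
        n_subjects_1=len(s1),
        n_subjects_2=len(s2),
        label=cls.label,
        front_mean=cls.front_mean,
        back_mean=cls.back_mean,
    )
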