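"""Evaluation statistics for comparing forest metrics and ordinal ratings.

Two continuous forest metrics are compared with *major axis* (model II)
regression: both variables are measured with error and neither is naturally
the response, so the fitted line is the major axis of the bivariate
covariance ellipse — the direction of the leading eigenvector of the 2x2
sample covariance matrix, passing through the centroid.  Unlike OLS, the
fit is symmetric: swapping x and y inverts the slope and leaves r^2 and the
p-value unchanged.  Significance comes from a two-tailed permutation test
on the Pearson correlation (the observed statistic is included in the
numerator), which makes no distributional assumption.

Ordinal ratings (users' and foresters' appraisals) are compared with
continuous metrics by one-way ANOVA followed by Tukey's honestly
significant difference test; group differences are summarized as a compact
letter display (groups sharing a letter are not significantly different at
the chosen alpha).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .inventory import RATING_CODES, ValidationError


class DegenerateFitError(ValueError):
    """Raised when a regression input has zero variance."""


@dataclass(frozen=True)
class MajorAxisFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    permutations: int
    seed: int


@dataclass(frozen=True)
class GroupSummary:
    code: int
    n: int
    mean: float
    sd: float
    letters: str


@dataclass(frozen=True)
class GroupComparison:
    groups: tuple[GroupSummary, ...]
    f_statistic: float
    p_value: float
    alpha: float
    excluded_codes: tuple[int, ...] = ()

    @property
    def tukey_letters(self) -> dict[int, str]:
        return {g.code: g.letters for g in self.groups}


def major_axis_slope_intercept(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope/intercept of the major axis of the sample covariance ellipse.

    Closed form from the 2x2 covariance matrix: with sxx, syy, sxy the
    sample (co)variances, the major-axis slope is
    ``(syy - sxx + sqrt((syy - sxx)^2 + 4 sxy^2)) / (2 sxy)`` — it carries
    the sign of the covariance.  When sxy = 0 the axis is coordinate-aligned:
    slope 0 if x has the larger variance, +inf (vertical axis; intercept
    NaN) otherwise.
    """
    sxx = float(np.var(x, ddof=1))
    syy = float(np.var(y, ddof=1))
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    if sxy == 0.0:
        if sxx >= syy:
            slope = 0.0
        else:
            return math.inf, float("nan")
    else:
        slope = (syy - sxx + math.hypot(syy - sxx, 2.0 * sxy)) / (2.0 * sxy)
    intercept = float(np.mean(y)) - slope * float(np.mean(x))
    return slope, intercept


def major_axis_fit(
    x, y, permutations: int = 999, seed: int = 0
) -> MajorAxisFit:
    """Major axis (model II) regression with a permutation p-value.

    ``r_squared`` is the squared Pearson correlation; the p-value is the
    two-tailed permutation probability of an |r| at least as large as
    observed, over ``permutations`` random shuffles of y (observed
    configuration counted in the numerator).  Deterministic given the seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"major axis regression needs n >= 3, got {n}")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        raise DegenerateFitError("x and y must both have nonzero variance")

    slope, intercept = major_axis_slope_intercept(x, y)
    r_obs = float(np.corrcoef(x, y)[0, 1])

    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    hits = 1  # the observed statistic
    for _ in range(permutations):
        r_perm = float(xc @ rng.permutation(yc)) / denom
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            hits += 1
    p = hits / (permutations + 1)
    return MajorAxisFit(
        slope=slope, intercept=intercept, r_squared=r_obs**2,
        p_value=p, n=n, permutations=permutations, seed=seed,
    )


def compact_letter_display(
    codes: list[int], significant: dict[tuple[int, int], bool]
) -> dict[int, str]:
    """Assign letters so that two groups share a letter iff their pairwise
    difference is *not* significant (insert-and-absorb algorithm)."""
    def is_sig(a: int, b: int) -> bool:
        return significant.get((a, b), significant.get((b, a), False))

    letter_sets: list[set[int]] = [set(codes)]
    for i, a in enumerate(codes):
        for b in codes[i + 1:]:
            if not is_sig(a, b):
                continue
            for s in [s for s in letter_sets if a in s and b in s]:
                letter_sets.remove(s)
                letter_sets.extend([s - {a}, s - {b}])
            # absorb sets contained in another
            letter_sets = [
                s for s in letter_sets
                if s and not any(s < t for t in letter_sets)
            ]
    # deduplicate while preserving order by smallest member
    unique_sets: list[set[int]] = []
    for s in letter_sets:
        if s not in unique_sets:
            unique_sets.append(s)
    unique_sets.sort(key=lambda s: min(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[int, str] = {c: "" for c in codes}
    for letter, s in zip(alphabet, unique_sets):
        for c in sorted(s):
            out[c] += letter
    return out


def anova_ordinal(values, codes, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA of a continuous metric across ordinal rating groups,
    with Tukey HSD pairwise comparisons and a compact letter display.

    Groups with fewer than 2 observations are excluded with a warning.
    For the both-ways check of two ordinal variables, call again with the
    arguments swapped (the ordinal codes are then the response).
    """
    values = np.asarray(values, dtype=float)
    codes = np.asarray(codes)
    if values.shape != codes.shape:
        raise ValueError("values and codes must have equal length")
    group_codes = sorted({int(c) for c in codes})
    usable, excluded = [], []
    for c in group_codes:
        if (codes == c).sum() >= 2:
            usable.append(c)
        else:
            excluded.append(c)
            warnings.warn(f"rating group {c} has < 2 observations; excluded")
    if len(usable) < 2:
        raise ValueError("ANOVA needs >= 2 groups with >= 2 observations each")
    mask = np.isin(codes, usable)
    v, g = values[mask], codes[mask].astype(int)

    samples = [v[g == c] for c in usable]
    f_stat, p = sps.f_oneway(*samples)

    tukey = pairwise_tukeyhsd(v, g, alpha=alpha)
    # statsmodels orders pairs as combinations of the sorted unique groups
    pairs = list(itertools.combinations([int(c) for c in tukey.groupsunique], 2))
    significant = {pair: bool(rej) for pair, rej in zip(pairs, tukey.reject)}
    letters = compact_letter_display(usable, significant)

    groups = tuple(
        GroupSummary(
            code=c, n=int(s.size), mean=float(s.mean()),
            sd=float(s.std(ddof=1)), letters=letters[c],
        )
        for c, s in zip(usable, samples)
    )
    return GroupComparison(
        groups=groups, f_statistic=float(f_stat), p_value=float(p),
        alpha=alpha, excluded_codes=tuple(excluded),
    )


#: answer vocabularies for the four ordinal rating variables
_USER_LABELS = {"decrease": -1, "no change": 0, "increase": 1}
_FORESTER_LABELS = {"very low": -2, "low": -1, "normal": 0, "high": 1, "very high": 2}
RATING_VOCABULARY: dict[str, dict[str, int]] = {
    "delta_density_user": _USER_LABELS,
    "delta_area_user": _USER_LABELS,
    "density_forester": _FORESTER_LABELS,
    "diversity_forester": _FORESTER_LABELS,
}


def code_rating(variable: str, label: str) -> int:
    """Integer code of an ordinal answer (e.g. ``("density_forester",
    "normal") -> 0``).  Labels are matched after whitespace/case
    normalization; unknown labels raise."""
    if variable not in RATING_VOCABULARY:
        raise ValidationError(f"unknown rating variable {variable!r}")
    key = " ".join(str(label).split()).casefold()
    vocab = RATING_VOCABULARY[variable]
    if key not in vocab:
        raise ValidationError(
            f"{variable}: unknown answer {label!r}; expected one of {sorted(vocab)}"
        )
    code = vocab[key]
    assert code in RATING_CODES[variable]
    return code
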