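"""Landmark-derived phenotypes and their group comparisons.

Two phenotypes are computed from 3D landmarks: straight-line skull
length (the Euclidean distance between two cranial landmarks, mm) and
molar crown area (mm^2), the area of the convex hull of 25 crown-outline
landmarks after projection onto their two dominant principal axes.
Both are invariant under rigid motions of the coordinate frame.

Group means are compared with Welch's unequal-variance t-test with
Welch-Satterthwaite degrees of freedom.  The study convention for the
one-sided alternative is control > treatment (smaller phenotypes were
predicted under dietary restriction), so ``a`` is the control sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.spatial import ConvexHull

from .io_formats import LandmarkSet, SpecimenDesign, ValidationError

__all__ = [
    "WelchResult",
    "PhenotypeResult",
    "interlandmark_distance",
    "skull_length",
    "crown_area",
    "welch_test",
    "phenotype_table",
]

_DEGENERACY_TOL = 1e-9


@dataclass(frozen=True)
class WelchResult:
    """Welch two-sample test output (t, real-valued df, p, one-sided CI)."""

    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    alternative: str
    ci_lower: float


@dataclass(frozen=True)
class PhenotypeResult:
    """One trait's per-specimen values, group means and Welch comparison."""

    trait: str
    values: Mapping[str, float]
    control_mean: float
    treatment_mean: float
    welch: WelchResult


def interlandmark_distance(lm: LandmarkSet, a_label: str, b_label: str) -> float:
    """Euclidean distance (mm) between two named landmarks."""
    positions = {label: np.array([x, y, z]) for label, x, y, z in lm.landmarks}
    for label in (a_label, b_label):
        if label not in positions:
            raise ValidationError(
                f"{lm.specimen_id}: unknown landmark label {label!r}"
            )
    return float(np.linalg.norm(positions[a_label] - positions[b_label]))


def skull_length(lm: LandmarkSet) -> float:
    """Straight-line skull length: distance between the two skull landmarks."""
    if lm.role != "skull":
        raise ValidationError(f"{lm.specimen_id}: expected a skull landmark set")
    coords = lm.coords
    return float(np.linalg.norm(coords[0] - coords[1]))


def crown_area(lm: LandmarkSet) -> float:
    """Convex-hull crown footprint area (mm^2) of the 25 molar landmarks.

    The landmarks are centered and projected onto the plane spanned by
    the two largest principal axes of their covariance; the area of the
    planar convex hull is returned.  Rigid rotations and translations of
    the input leave the result unchanged.
    """
    if lm.role != "molar":
        raise ValidationError(f"{lm.specimen_id}: expected a molar landmark set")
    coords = lm.coords
    centered = coords - coords.mean(axis=0)
    # principal axes of the landmark cloud
    _, singular, vt = np.linalg.svd(centered, full_matrices=False)
    if singular[1] <= _DEGENERACY_TOL * max(singular[0], 1.0):
        raise ValidationError(
            f"{lm.specimen_id}: landmarks are collinear — no crown plane"
        )
    planar = centered @ vt[:2].T
    hull = ConvexHull(planar)
    return float(hull.volume)  # 2-D hull: "volume" is the enclosed area


def welch_test(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "a_greater",
) -> WelchResult:
    """Welch's unequal-variance t-test of mean(a) vs mean(b).

    ``alternative`` is ``a_greater`` (one-sided, H1: mean(a) > mean(b))
    or ``two_sided``.  ``ci_lower`` is the lower 95% confidence bound on
    mean(a) - mean(b) (one-sided bound for ``a_greater``).
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if a_arr.size < 2 or b_arr.size < 2:
        raise ValidationError("each group needs at least two values")
    if np.var(a_arr, ddof=1) == 0.0 and np.var(b_arr, ddof=1) == 0.0:
        raise ValidationError("both groups have zero variance")
    if alternative not in ("a_greater", "two_sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    scipy_alt = "greater" if alternative == "a_greater" else "two-sided"
    res = stats.ttest_ind(a_arr, b_arr, equal_var=False, alternative=scipy_alt)
    ci = res.confidence_interval(0.95)
    return WelchResult(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        mean_a=float(a_arr.mean()),
        mean_b=float(b_arr.mean()),
        alternative=alternative,
        ci_lower=float(ci.low),
    )


def phenotype_table(
    landmark_sets: Sequence[LandmarkSet],
    design: Sequence[SpecimenDesign],
    alternative: str = "a_greater",
) -> list[PhenotypeResult]:
    """Compute both phenotypes and their control-vs-treatment Welch tests.

    Skull sets yield ``skull_length_mm``; molar sets yield
    ``crown_area_mm2``.  ``a`` in the Welch test is the control group.
    """
    arm = {d.specimen_id: d.arm for d in design}
    results = []
    for trait, role, measure in (
        ("skull_length_mm", "skull", skull_length),
        ("crown_area_mm2", "molar", crown_area),
    ):
        values = {
            lm.specimen_id: measure(lm) for lm in landmark_sets if lm.role == role
        }
        if not values:
            continue
        unknown = sorted(set(values) - set(arm))
        if unknown:
            raise ValidationError(f"specimens missing from design: {unknown}")
        control = [v for sid, v in values.items() if arm[sid] == "control"]
        treatment = [v for sid, v in values.items() if arm[sid] == "treatment"]
        welch = welch_test(control, treatment, alternative=alternative)
        results.append(
            PhenotypeResult(
                trait=trait,
                values=values,
                control_mean=welch.mean_a,
                treatment_mean=welch.mean_b,
                welch=welch,
            )
        )
    return results
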