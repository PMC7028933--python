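"""Volumetric response assessment for serial preclinical tumor MRI.

Translates the planumetric RANO/iRANO criteria (biperpendicular diameter
product) to three-dimensional lesion-volume criteria for a three-time-point
design (baseline MRI1, on-therapy MRI2, post-therapy MRI3):

* CR  — complete regression, %V(MRI3–MRI1) = −100
* PR  — %V(MRI3–MRI1) ≤ −65 or %V(MRI3–MRI2) ≤ −65
* PD  — %V(MRI3–MRI1) ≥ +40, unless the lesion regressed ≥ 30% between
        MRI2 and MRI3 (unconfirmed progression, i.e. pseudoprogression,
        rescued to SD)
* SD  — everything else

The ±65/+40 volumetric thresholds are the spherical-tumor conversion of the
RANO 50% decrease / 25% increase in the diameter product (area ∝ d²,
volume ∝ d³), rounded to the nearest 5%.  CR/PR/SD animals are grouped as
responders (R), PD as non-responders (NR).

Growth patterns classify the sign of the two inter-scan changes:
G1 (−,−) direct response, G2 (+,−) pseudoprogression-then-response,
G3 (+,+) progression, G4 (−,+) late progression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError


class Category(str, Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"


class GrowthPattern(str, Enum):
    G1 = "G1"
    G2 = "G2"
    G3 = "G3"
    G4 = "G4"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class VolumeTrajectory:
    """One animal's lesion volumes (mm³) at the three serial MRIs."""

    animal_id: str
    v1: float
    v2: float
    v3: float
    arm: str = "ICB"

    def __post_init__(self) -> None:
        for name in ("v1", "v2", "v3"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.v1 <= 0:
            raise ValueError(f"baseline volume v1 must be > 0, got {self.v1}")
        if self.v2 < 0 or self.v3 < 0:
            raise ValueError("volumes must be non-negative")


@dataclass(frozen=True)
class ResponseCriteriaConfig:
    """Thresholds (as fractions) of the volumetric response criteria.

    Defaults are the spherical-conversion values: PR at −65%, PD at +40%,
    pseudoprogression rescue at −30% regression MRI2→MRI3.  ``strict_growth``
    labels zero inter-scan change as ``indeterminate`` instead of folding it
    into the non-growth branch.
    """

    pr_threshold: float = -0.65
    pd_threshold: float = 0.40
    rescue_threshold: float = -0.30
    cr_threshold: float = -1.0
    strict_growth: bool = False

    def __post_init__(self) -> None:
        if not (self.cr_threshold == -1.0 <= self.pr_threshold < 0 < self.pd_threshold):
            raise ValueError("need cr = -1.0 <= pr < 0 < pd")
        if self.rescue_threshold >= 0:
            raise ValueError("rescue_threshold must be negative")


@dataclass(frozen=True)
class ResponseCall:
    animal_id: str
    arm: str
    category: Category
    responder: bool
    growth_pattern: GrowthPattern
    pseudoprogression_rescued: bool
    pct_v31: float
    pct_v21: float | None
    pct_v32: float | None


@dataclass(frozen=True)
class CohortSummary:
    n_per_arm: dict[str, int]
    category_counts: dict[str, dict[str, int]]
    response_rate: dict[str, float]
    contingency: np.ndarray = field(repr=False)
    fisher_p: float | None = None


def relative_change(v_from: float, v_to: float) -> float:
    """Percent change 100·(v_to − v_from)/v_from; v_from must be positive."""
    if not math.isfinite(v_from) or v_from <= 0:
        raise ValueError(f"baseline volume must be > 0, got {v_from}")
    if not math.isfinite(v_to) or v_to < 0:
        raise ValueError(f"follow-up volume must be >= 0, got {v_to}")
    # ratio first: total regression must give exactly -100
    return 100.0 * ((v_to - v_from) / v_from)


def classify_growth_pattern(
    traj: VolumeTrajectory, *, strict: bool = False
) -> GrowthPattern:
    """Sign pattern of (%V MRI2–MRI1, %V MRI3–MRI2) → G1..G4.

    Zero change falls into the non-growth (negative) branch unless
    ``strict``, in which case it is ``indeterminate``.  A lesion that
    vanished at MRI2 but regrew at MRI3 has no defined %V(MRI3–MRI2).
    """
    if traj.v2 == 0 and traj.v3 > 0:
        raise ValueError(
            "growth pattern undefined: v2 = 0 with v3 > 0 (regrowth from CR)"
        )
    p21 = relative_change(traj.v1, traj.v2)
    p32 = relative_change(traj.v2, traj.v3) if traj.v2 > 0 else 0.0
    if strict and (p21 == 0.0 or p32 == 0.0):
        return GrowthPattern.INDETERMINATE
    grew_12 = p21 > 0.0
    grew_23 = p32 > 0.0
    if not grew_12 and not grew_23:
        return GrowthPattern.G1
    if grew_12 and not grew_23:
        return GrowthPattern.G2
    if grew_12 and grew_23:
        return GrowthPattern.G3
    return GrowthPattern.G4


def classify_response(
    traj: VolumeTrajectory, cfg: ResponseCriteriaConfig | None = None
) -> ResponseCall:
    """Classify one volume trajectory into CR/PR/SD/PD with growth pattern.

    Boundary conventions: exactly −65% is PR; exactly +40% enters the PD
    branch and is rescued to SD only if %V(MRI3–MRI2) ≤ −30%.
    """
    cfg = cfg or ResponseCriteriaConfig()
    p31 = relative_change(traj.v1, traj.v3)
    p21 = relative_change(traj.v1, traj.v2)
    p32 = relative_change(traj.v2, traj.v3) if traj.v2 > 0 else None

    pr_pct = 100.0 * cfg.pr_threshold
    pd_pct = 100.0 * cfg.pd_threshold
    rescue_pct = 100.0 * cfg.rescue_threshold

    rescued = False
    if p31 == 100.0 * cfg.cr_threshold:
        category = Category.CR
    elif p31 <= pr_pct or (p32 is not None and p32 <= pr_pct):
        category = Category.PR
    elif p31 >= pd_pct:
        if p32 is not None and p32 <= rescue_pct:
            category = Category.SD
            rescued = True
        else:
            category = Category.PD
    else:
        category = Category.SD

    try:
        pattern = classify_growth_pattern(traj, strict=cfg.strict_growth)
    except ValueError:
        pattern = GrowthPattern.INDETERMINATE

    return ResponseCall(
        animal_id=traj.animal_id,
        arm=traj.arm,
        category=category,
        responder=category is not Category.PD,
        growth_pattern=pattern,
        pseudoprogression_rescued=rescued,
        pct_v31=p31,
        pct_v21=p21,
        pct_v32=p32,
    )


def classify_cohort(
    trajectories: Iterable[VolumeTrajectory],
    cfg: ResponseCriteriaConfig | None = None,
) -> list[ResponseCall]:
    return [classify_response(t, cfg) for t in trajectories]


def planumetric_to_volumetric_threshold(area_fraction: float) -> float:
    """Convert a fractional change in the biperpendicular diameter product
    (area) to the equivalent fractional volume change for a spherical lesion.

    Area scales with d², volume with d³, hence (1+a)^(3/2) − 1.
    """
    if area_fraction <= -1:
        raise ValueError("area_fraction must be > -1")
    return (1.0 + area_fraction) ** 1.5 - 1.0


def volumetric_to_planumetric_threshold(volume_fraction: float) -> float:
    """Inverse of :func:`planumetric_to_volumetric_threshold`."""
    if volume_fraction <= -1:
        raise ValueError("volume_fraction must be > -1")
    return (1.0 + volume_fraction) ** (2.0 / 3.0) - 1.0


def volumetric_threshold_percent(area_fraction: float, *, round_to: float = 5.0) -> float:
    """Volumetric threshold in percent, rounded to the nearest ``round_to``%.

    Reproduces the printed criteria: a +25% area increase → +40% volume,
    a −50% area decrease → −65% volume.
    """
    pct = 100.0 * planumetric_to_volumetric_threshold(area_fraction)
    return round_to * round(pct / round_to)


def _slice_diameters(points: np.ndarray, spacing: np.ndarray) -> tuple[float, float]:
    """Maximal diameter and maximal perpendicular extent of a set of pixel
    centers (physical 2D coordinates).

    Distances are center-to-center; a degenerate direction (single pixel, or
    a collinear row's width) falls back to the pixel extent along it.
    """
    if len(points) == 1:
        return float(max(spacing)), float(min(spacing))
    try:
        hull = points[ConvexHull(points).vertices]
    except QhullError:  # collinear pixels
        hull = points
    diff = hull[:, None, :] - hull[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    if dist[i, j] == 0:
        return float(max(spacing)), float(min(spacing))
    u = (hull[i] - hull[j]) / dist[i, j]
    d1 = float(dist[i, j])
    v = np.array([-u[1], u[0]])
    proj = hull @ v
    span = float(proj.max() - proj.min())
    if span == 0.0:  # collinear: width is one pixel
        span = float(abs(v[0]) * spacing[0] + abs(v[1]) * spacing[1])
    return d1, span


def bidimensional_product(mask: np.ndarray, spacing: Sequence[float]) -> float:
    """RANO biperpendicular diameter product (mm²).

    On the axial slice (third array axis) with the largest lesion
    cross-section, multiplies the maximal in-plane diameter by the maximal
    diameter perpendicular to it.  Diameters include the pixel footprint, so
    a single voxel at 1 mm spacing measures 1 mm².
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError("spacing must be three positive values")
    if not mask.any():
        raise ValueError("empty lesion mask")
    counts = mask.sum(axis=(0, 1))
    z = int(np.argmax(counts))
    ii, jj = np.nonzero(mask[:, :, z])
    pts = np.column_stack([ii * spacing[0], jj * spacing[1]])
    d1, d2 = _slice_diameters(pts, spacing[:2])
    return d1 * d2


def fisher_exact_2x2(table: Sequence[Sequence[float]]) -> float:
    """Two-sided Fisher exact p for a 2×2 contingency table.

    Two-sided by the point-probability rule: sum of hypergeometric
    probabilities of all tables with the observed margins whose probability
    does not exceed that of the observed table.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ValueError("table entries must be non-negative integers")
    return float(stats.fisher_exact(arr.astype(int), alternative="two-sided")[1])


def summarize_cohort(calls: Iterable[ResponseCall]) -> CohortSummary:
    """Per-arm category counts, response rates (%), and — for a two-arm
    cohort — the Fisher exact p on the responder × arm table."""
    calls = list(calls)
    if not calls:
        raise ValueError("no response calls supplied")
    arms = sorted({c.arm for c in calls})
    n_per_arm: dict[str, int] = {}
    cat_counts: dict[str, dict[str, int]] = {}
    rates: dict[str, float] = {}
    cont = np.zeros((2, len(arms)), dtype=int)
    for k, arm in enumerate(arms):
        sub = [c for c in calls if c.arm == arm]
        if not sub:
            raise ValueError(f"empty arm {arm!r}")
        n_per_arm[arm] = len(sub)
        cat_counts[arm] = {
            cat.value: sum(1 for c in sub if c.category is cat) for cat in Category
        }
        n_resp = sum(1 for c in sub if c.responder)
        rates[arm] = 100.0 * n_resp / len(sub)
        cont[0, k] = n_resp
        cont[1, k] = len(sub) - n_resp
    fisher_p = fisher_exact_2x2(cont) if len(arms) == 2 else None
    return CohortSummary(
        n_per_arm=n_per_arm,
        category_counts=cat_counts,
        response_rate=rates,
        contingency=cont,
        fisher_p=fisher_p,
    )


def response_rate(n_responders: int, n_total: int) -> float:
    """Response rate in percent."""
    if n_total <= 0 or n_responders < 0 or n_responders > n_total:
        raise ValueError("need 0 <= n_responders <= n_total, n_total > 0")
    return 100.0 * n_responders / n_total


def trajectories_from_dataframe(df: pd.DataFrame) -> list[VolumeTrajectory]:
    """Build trajectories from a table with columns animal_id, arm, v1, v2, v3."""
    required = {"animal_id", "v1", "v2", "v3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    arm = df["arm"] if "arm" in df.columns else pd.Series("ICB", index=df.index)
    return [
        VolumeTrajectory(
            animal_id=str(r.animal_id), v1=float(r.v1), v2=float(r.v2),
            v3=float(r.v3), arm=str(a),
        )
        for r, a in zip(df.itertuples(index=False), arm)
    ]


def calls_to_dataframe(calls: Iterable[ResponseCall]) -> pd.DataFrame:
    rows = [
        {
            "animal_id": c.animal_id,
            "arm": c.arm,
            "category": c.category.value,
            "responder": c.responder,
            "growth_pattern": c.growth_pattern.value,
            "pseudoprogression_rescued": c.pseudoprogression_rescued,
            "pct_v31": c.pct_v31,
            "pct_v21": c.pct_v21,
            "pct_v32": c.pct_v32,
        }
        for c in calls
    ]
    return pd.DataFrame(rows)
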