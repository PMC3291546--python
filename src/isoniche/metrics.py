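"""Distance-based niche statistics in the (d13C, d15N) plane.

All statistics are built from Euclidean distances to arithmetic-mean
centroids, following the multivariate variance-decomposition view of group
dispersion:

* total niche width (TNW): mean distance of a group's samples to the group
  centroid;
* individual niche breadth: distance between an individual's muscle and
  collagen points (a two-tissue temporal contrast);
* within-individual component (WIC): mean distance of samples to their own
  individual's centroid;
* WIC/TNW: individual-specialization index (0 = specialists, 1 = individual
  generalists spanning the population niche);
* difference dispersion: distances of per-individual (muscle - collagen)
  difference vectors to their group centroid — between-individual variation
  in individual strategy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .samples import SampleSet

__all__ = [
    "IsotopePoint",
    "GroupKey",
    "DistanceRecord",
    "IndividualContrast",
    "NicheMetrics",
    "InsufficientTissuesError",
    "group_centroid",
    "centroid_distances",
    "total_niche_width",
    "individual_contrast",
    "individual_contrasts",
    "within_individual_component",
    "difference_dispersion",
    "specialization_index",
    "group_keys",
    "all_group_metrics",
]

Grouping = Literal["habitat_age", "habitat_age_tissue"]

PAIR_TISSUES = ("muscle", "collagen")


class InsufficientTissuesError(ValueError):
    """An individual lacks one of the two tissues needed for a contrast."""

    def __init__(self, individual_id: str, present: Sequence[str]):
        self.individual_id = individual_id
        super().__init__(
            f"individual {individual_id!r} needs both muscle and collagen samples; "
            f"has {sorted(present)!r}"
        )


@dataclass(frozen=True)
class IsotopePoint:
    """A point in the isotope plane: c = d13C, n = d15N (per-mil)."""

    c: float
    n: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.c) and math.isfinite(self.n)):
            raise ValueError(f"coordinates must be finite, got ({self.c!r}, {self.n!r})")

    def distance_to(self, other: "IsotopePoint") -> float:
        return math.hypot(self.c - other.c, self.n - other.n)


@dataclass(frozen=True)
class GroupKey:
    """Grouping context: habitat x age, optionally refined by tissue."""

    habitat: str
    age: str
    tissue: str | None = None

    def __post_init__(self) -> None:
        if not self.habitat or not self.age:
            raise ValueError("habitat and age are always required in a GroupKey")

    def label(self) -> str:
        parts = [self.habitat, self.age]
        if self.tissue is not None:
            parts.append(self.tissue)
        return "/".join(parts)


@dataclass(frozen=True)
class DistanceRecord:
    """Distance of one sample (or one contrast vector) to its group centroid."""

    individual_id: str
    tissue: str | None
    group: GroupKey
    distance: float

    def __post_init__(self) -> None:
        if self.distance < 0 or not math.isfinite(self.distance):
            raise ValueError(f"distance must be finite and >= 0, got {self.distance!r}")


@dataclass(frozen=True)
class IndividualContrast:
    """Muscle-minus-collagen difference vector and its Euclidean norm."""

    individual_id: str
    habitat: str
    age: str
    diff: IsotopePoint
    breadth: float
    province: str = ""


@dataclass(frozen=True)
class NicheMetrics:
    group: GroupKey
    tnw: float
    wic: float
    wic_tnw: float
    n_samples: int
    n_individuals: int


def group_centroid(points: Iterable[IsotopePoint]) -> IsotopePoint:
    """Componentwise arithmetic mean of a non-empty point collection."""
    pts = list(points)
    if not pts:
        raise ValueError("cannot take the centroid of an empty point collection")
    c = sum(p.c for p in pts) / len(pts)
    n = sum(p.n for p in pts) / len(pts)
    return IsotopePoint(c, n)


def group_keys(s: SampleSet, grouping: Grouping = "habitat_age") -> list[GroupKey]:
    """Observed factor combinations, in first-appearance order."""
    seen: dict[GroupKey, None] = {}
    for sample in s:
        tissue = sample.tissue if grouping == "habitat_age_tissue" else None
        seen.setdefault(GroupKey(sample.habitat, sample.age, tissue), None)
    return list(seen)


def _samples_in_group(s: SampleSet, group: GroupKey) -> list:
    return [
        x for x in s
        if x.habitat == group.habitat and x.age == group.age
        and (group.tissue is None or x.tissue == group.tissue)
    ]


def _distances_to_centroid(points: np.ndarray) -> np.ndarray:
    centroid = points.mean(axis=0)
    return np.linalg.norm(points - centroid, axis=1)


def centroid_distances(s: SampleSet, grouping: Grouping = "habitat_age_tissue") -> list[DistanceRecord]:
    """One record per sample: Euclidean distance to its own group's centroid.

    The default grouping refines by tissue, matching the total-niche-breadth
    analysis; ``habitat_age`` pools tissues.
    """
    if len(s) == 0:
        raise ValueError("empty SampleSet")
    records: list[DistanceRecord] = []
    for group in group_keys(s, grouping):
        members = _samples_in_group(s, group)
        pts = np.array([m.point for m in members], dtype=float)
        dists = _distances_to_centroid(pts)
        for member, dist in zip(members, dists):
            records.append(
                DistanceRecord(
                    individual_id=member.individual_id,
                    tissue=member.tissue,
                    group=group,
                    distance=float(dist),
                )
            )
    return records


def total_niche_width(s: SampleSet, group: GroupKey) -> float:
    """Mean distance of the group's samples to the group centroid.

    Tissues are pooled unless the key carries a tissue level.  Requires at
    least two samples.
    """
    members = _samples_in_group(s, group)
    if len(members) < 2:
        raise ValueError(
            f"group {group.label()!r} has {len(members)} sample(s); need >= 2 for TNW"
        )
    pts = np.array([m.point for m in members], dtype=float)
    return float(_distances_to_centroid(pts).mean())


def individual_contrast(s: SampleSet, individual_id: str) -> IndividualContrast:
    """Muscle-minus-collagen difference vector for one individual."""
    mine = s.for_individual(individual_id)
    if not mine:
        raise InsufficientTissuesError(individual_id, [])
    by_tissue = {x.tissue: x for x in mine}
    if not all(t in by_tissue for t in PAIR_TISSUES):
        raise InsufficientTissuesError(individual_id, list(by_tissue))
    muscle, collagen = by_tissue["muscle"], by_tissue["collagen"]
    diff = IsotopePoint(muscle.d13c - collagen.d13c, muscle.d15n - collagen.d15n)
    return IndividualContrast(
        individual_id=individual_id,
        habitat=muscle.habitat,
        age=muscle.age,
        diff=diff,
        breadth=math.hypot(diff.c, diff.n),
        province=muscle.province,
    )


def individual_contrasts(s: SampleSet) -> tuple[list[IndividualContrast], list[str]]:
    """Contrasts for every individual holding both tissues.

    Returns ``(contrasts, skipped_ids)``; individuals lacking a tissue are
    listed rather than raised so a partial design still yields output.
    """
    contrasts: list[IndividualContrast] = []
    skipped: list[str] = []
    for ind in s.individuals():
        try:
            contrasts.append(individual_contrast(s, ind))
        except InsufficientTissuesError:
            skipped.append(ind)
    return contrasts, skipped


def _paired_individuals(s: SampleSet, group: GroupKey) -> dict[str, dict[str, tuple[float, float]]]:
    """individual -> {tissue: point} for individuals in the (habitat, age)
    group that carry both muscle and collagen."""
    pool: dict[str, dict[str, tuple[float, float]]] = {}
    for x in s:
        if x.habitat == group.habitat and x.age == group.age and x.tissue in PAIR_TISSUES:
            pool.setdefault(x.individual_id, {})[x.tissue] = x.point
    return {k: v for k, v in pool.items() if len(v) == 2}


def within_individual_component(s: SampleSet, group: GroupKey) -> float:
    """Mean distance of muscle/collagen samples to their individual centroid.

    Each of an individual's two samples lies at half the pair distance from
    the individual midpoint, so WIC equals the mean pair distance over
    contributing individuals divided by two.  Individuals lacking a tissue
    are excluded.
    """
    paired = _paired_individuals(s, group)
    if not paired:
        raise ValueError(
            f"group {group.label()!r} has no individual with both muscle and collagen"
        )
    breadths = [
        math.hypot(v["muscle"][0] - v["collagen"][0], v["muscle"][1] - v["collagen"][1])
        for v in paired.values()
    ]
    # per-sample distances are breadth/2 for each of the two samples
    return float(np.mean(breadths) / 2.0)


def difference_dispersion(contrasts: Sequence[IndividualContrast]) -> list[DistanceRecord]:
    """Distance of each individual's difference vector to the habitat x age
    centroid of difference vectors — dispersion of individual strategies."""
    if not contrasts:
        raise ValueError("no contrasts supplied")
    records: list[DistanceRecord] = []
    groups: dict[GroupKey, list[IndividualContrast]] = {}
    for c in contrasts:
        groups.setdefault(GroupKey(c.habitat, c.age), []).append(c)
    for group, members in groups.items():
        pts = np.array([(m.diff.c, m.diff.n) for m in members], dtype=float)
        dists = _distances_to_centroid(pts)
        for member, dist in zip(members, dists):
            records.append(
                DistanceRecord(
                    individual_id=member.individual_id,
                    tissue=None,
                    group=group,
                    distance=float(dist),
                )
            )
    return records


def specialization_index(
    s: SampleSet,
    group: GroupKey,
    *,
    tnw_scope: Literal["paired", "all"] = "paired",
) -> NicheMetrics:
    """WIC/TNW specialization index for one habitat x age group.

    With the default ``tnw_scope="paired"`` both WIC and TNW are computed on
    the same sample universe: the muscle and collagen samples of individuals
    possessing both tissues.  ``tnw_scope="all"`` instead measures TNW over
    every sample of the group (all tissues); the choice is recorded by the
    caller, not here.
    """
    if group.tissue is not None:
        raise ValueError("specialization index is defined at habitat x age level")
    paired = _paired_individuals(s, group)
    if not paired:
        raise ValueError(
            f"group {group.label()!r} has no individual with both muscle and collagen"
        )
    wic = within_individual_component(s, group)

    if tnw_scope == "paired":
        pts = np.array(
            [pt for v in paired.values() for pt in (v["muscle"], v["collagen"])],
            dtype=float,
        )
        n_samples = len(pts)
        if n_samples < 2:
            raise ValueError("need >= 2 samples for TNW")
        tnw = float(_distances_to_centroid(pts).mean())
    elif tnw_scope == "all":
        tnw = total_niche_width(s, group)
        n_samples = len(_samples_in_group(s, group))
    else:
        raise ValueError(f"unknown tnw_scope {tnw_scope!r}")

    if tnw == 0.0:
        raise ValueError(
            f"group {group.label()!r} has zero total niche width; WIC/TNW undefined"
        )
    return NicheMetrics(
        group=group,
        tnw=tnw,
        wic=wic,
        wic_tnw=wic / tnw,
        n_samples=n_samples,
        n_individuals=len(paired),
    )


def individual_ratios(s: SampleSet, group: GroupKey) -> dict[str, float]:
    """Per-individual specialization ratio within one habitat x age group.

    For each individual with both muscle and collagen: (mean distance of its
    two samples to its own midpoint) / (mean distance of its two samples to
    the group centroid of the paired-sample pool).  Group-averaging the
    numerator and denominator separately recovers WIC and TNW; the
    per-individual version supplies replicate structure for modeling.
    """
    paired = _paired_individuals(s, group)
    if not paired:
        raise ValueError(
            f"group {group.label()!r} has no individual with both muscle and collagen"
        )
    pts = np.array(
        [pt for v in paired.values() for pt in (v["muscle"], v["collagen"])], dtype=float
    )
    centroid = pts.mean(axis=0)
    out: dict[str, float] = {}
    for ind, v in paired.items():
        m = np.array(v["muscle"], dtype=float)
        c = np.array(v["collagen"], dtype=float)
        own = float(np.linalg.norm(m - c)) / 2.0
        to_group = float(
            (np.linalg.norm(m - centroid) + np.linalg.norm(c - centroid)) / 2.0
        )
        out[ind] = own / to_group if to_group > 0 else float("nan")
    return out


def all_group_metrics(
    s: SampleSet, *, tnw_scope: Literal["paired", "all"] = "paired"
) -> tuple[list[NicheMetrics], list[str]]:
    """Specialization metrics for every observed habitat x age group.

    Groups where the index is undefined (no paired individual, or zero TNW)
    are skipped and reported in the second return value.
    """
    out: list[NicheMetrics] = []
    skipped: list[str] = []
    for group in group_keys(s, "habitat_age"):
        try:
            out.append(specialization_index(s, group, tnw_scope=tnw_scope))
        except ValueError as exc:
            skipped.append(f"{group.label()}: {exc}")
    return out, skipped
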