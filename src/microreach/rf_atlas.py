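"""Discretized forelimb atlas, receptive-field class templates, and overlap metrics.

Cutaneous receptive fields of cerebellar C3-zone units fall into ten canonical
forelimb territories (the Ekerot classification), running from the most distal
(class 1: digits) to the most proximal (class 10: medial shoulder / upper arm).
This module represents a receptive field as a set of named skin regions on a
15-region forelimb lattice, assigns class labels by area-weighted Jaccard
similarity against per-class templates, and scores the overlap between two
fields (e.g. the complex-spike and simple-spike fields of one Purkinje cell)
as a percentage of their combined extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean, stdev
from typing import Iterable, Mapping, Sequence

__all__ = [
    "REGIONS",
    "REGION_ADJACENCY",
    "ReceptiveField",
    "ClassTemplate",
    "CLASS_TEMPLATES",
    "classify_rf",
    "overlap_percent",
    "overlap_report",
]

#: Atlas regions and their relative (dimensionless) areas.  Unit weights by
#: default: the figurine drawings carry no area calibration, so every named
#: region counts equally unless the caller supplies weights.
REGIONS: dict[str, float] = {
    "digits_dorsal": 1.0,
    "digits_ventral": 1.0,
    "paw_dorsal": 1.0,
    "paw_ventral": 1.0,
    "wrist": 1.0,
    "forearm_dorsal": 1.0,
    "forearm_ventral": 1.0,
    "forearm_lateral": 1.0,
    "forearm_medial": 1.0,
    "elbow": 1.0,
    "upper_arm_lateral": 1.0,
    "upper_arm_medial": 1.0,
    "shoulder_lateral": 1.0,
    "shoulder_medial": 1.0,
    "neck": 1.0,
}

#: Proximo-distal adjacency of the atlas regions; used by the synthetic
#: generator to jitter field borders into anatomically neighbouring skin.
REGION_ADJACENCY: dict[str, tuple[str, ...]] = {
    "digits_dorsal": ("digits_ventral", "paw_dorsal"),
    "digits_ventral": ("digits_dorsal", "paw_ventral"),
    "paw_dorsal": ("digits_dorsal", "paw_ventral", "wrist"),
    "paw_ventral": ("digits_ventral", "paw_dorsal", "wrist"),
    "wrist": (
        "paw_dorsal",
        "paw_ventral",
        "forearm_dorsal",
        "forearm_ventral",
        "forearm_lateral",
        "forearm_medial",
    ),
    "forearm_dorsal": ("wrist", "elbow", "forearm_lateral", "forearm_medial"),
    "forearm_ventral": ("wrist", "elbow", "forearm_lateral", "forearm_medial"),
    "forearm_lateral": ("wrist", "forearm_dorsal", "forearm_ventral", "elbow"),
    "forearm_medial": ("wrist", "forearm_dorsal", "forearm_ventral", "elbow"),
    "elbow": (
        "forearm_dorsal",
        "forearm_ventral",
        "forearm_lateral",
        "forearm_medial",
        "upper_arm_lateral",
        "upper_arm_medial",
    ),
    "upper_arm_lateral": ("elbow", "shoulder_lateral"),
    "upper_arm_medial": ("elbow", "shoulder_medial"),
    "shoulder_lateral": ("upper_arm_lateral", "neck", "shoulder_medial"),
    "shoulder_medial": ("upper_arm_medial", "neck", "shoulder_lateral"),
    "neck": ("shoulder_lateral", "shoulder_medial"),
}

INTENSITIES = ("strong", "weak")


@dataclass(frozen=True)
class ReceptiveField:
    """A receptive field as a set of (region, intensity) pairs.

    ``strong`` marks the core of the field (the skin producing the strongest
    response), ``weak`` the surrounding total extent.  A region appears at
    most once.
    """

    regions: frozenset[tuple[str, str]]

    def __init__(self, regions: Iterable[tuple[str, str]]):
        pairs = list(regions)
        seen: dict[str, str] = {}
        for region, intensity in pairs:
            if region not in REGIONS:
                raise ValueError(f"unknown atlas region: {region!r}")
            if intensity not in INTENSITIES:
                raise ValueError(f"intensity must be one of {INTENSITIES}: {intensity!r}")
            if region in seen:
                raise ValueError(f"region appears more than once: {region!r}")
            seen[region] = intensity
        object.__setattr__(self, "regions", frozenset(seen.items()))

    @property
    def full_extent(self) -> frozenset[str]:
        """All regions of the field (strong and weak)."""
        return frozenset(r for r, _ in self.regions)

    @property
    def core(self) -> frozenset[str]:
        """Strong regions only."""
        return frozenset(r for r, i in self.regions if i == "strong")

    def __bool__(self) -> bool:
        return bool(self.regions)


@dataclass(frozen=True)
class ClassTemplate:
    """Canonical skin territory of one receptive-field class.

    ``core_regions`` is the central skin always included in fields of the
    class; ``full_regions`` adds the typical surrounding extent
    (core ⊆ full).
    """

    class_id: int
    core_regions: frozenset[str]
    full_regions: frozenset[str]

    def __post_init__(self):
        if not 1 <= self.class_id <= 10:
            raise ValueError("class_id must be 1..10")
        if not self.core_regions <= self.full_regions:
            raise ValueError("core_regions must be a subset of full_regions")
        unknown = self.full_regions - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown atlas regions: {sorted(unknown)}")

    def as_receptive_field(self) -> ReceptiveField:
        return ReceptiveField(
            [(r, "strong") for r in sorted(self.core_regions)]
            + [(r, "weak") for r in sorted(self.full_regions - self.core_regions)]
        )


def _template(cid: int, core: Sequence[str], extra: Sequence[str] = ()) -> ClassTemplate:
    core_set = frozenset(core)
    return ClassTemplate(cid, core_set, core_set | frozenset(extra))


#: Ten class templates, distal (class 1, digits) to proximal (class 10,
#: medial shoulder/upper arm).  Class 7 (lateral forearm + upper arm) is
#: included even though no recorded unit carried it in the awake data.
CLASS_TEMPLATES: dict[int, ClassTemplate] = {
    t.class_id: t
    for t in (
        _template(1, ["digits_dorsal", "digits_ventral"]),
        _template(2, ["digits_dorsal", "digits_ventral", "paw_dorsal", "paw_ventral"], ["wrist"]),
        _template(3, ["paw_dorsal", "forearm_dorsal"], ["digits_dorsal", "wrist"]),
        _template(4, ["paw_ventral"], ["digits_ventral", "wrist"]),
        _template(5, ["paw_ventral", "wrist", "forearm_ventral"]),
        _template(6, ["forearm_lateral"], ["elbow"]),
        _template(7, ["forearm_lateral", "upper_arm_lateral"], ["elbow"]),
        _template(8, ["shoulder_lateral", "upper_arm_lateral", "neck"]),
        _template(9, ["forearm_medial"], ["paw_dorsal", "wrist"]),
        _template(10, ["shoulder_medial", "upper_arm_medial"]),
    )
}


def _weighted_area(regions: frozenset[str], weights: Mapping[str, float]) -> float:
    return float(sum(weights[r] for r in regions))


def _jaccard(a: frozenset[str], b: frozenset[str], weights: Mapping[str, float]) -> float:
    union = _weighted_area(a | b, weights)
    if union == 0.0:
        return 0.0
    return _weighted_area(a & b, weights) / union


def classify_rf(
    rf: ReceptiveField,
    templates: Mapping[int, ClassTemplate] | None = None,
    weights: Mapping[str, float] | None = None,
    strong_only: bool = False,
) -> tuple[int | None, float]:
    """Assign a receptive field to the most similar class template.

    Similarity is the area-weighted Jaccard index between the field's full
    extent and each template's ``full_regions`` (or core vs. core when
    ``strong_only``).  Ties are broken toward the lowest class id.  An empty
    field is unclassifiable and returns ``(None, 0.0)``.
    """
    templates = CLASS_TEMPLATES if templates is None else templates
    weights = REGIONS if weights is None else weights
    if not rf:
        return None, 0.0
    rf_set = rf.core if strong_only else rf.full_extent
    if strong_only and not rf_set:
        return None, 0.0
    best_id, best_score = None, -1.0
    for cid in sorted(templates):
        t = templates[cid]
        t_set = t.core_regions if strong_only else t.full_regions
        score = _jaccard(rf_set, t_set, weights)
        if score > best_score:  # strict: ties keep the lowest class id
            best_id, best_score = cid, score
    return best_id, best_score


def overlap_percent(
    rf_a: ReceptiveField,
    rf_b: ReceptiveField,
    weights: Mapping[str, float] | None = None,
    strong_only: bool = False,
) -> float:
    """Overlap of two fields as a percentage of their combined extent.

    100 × area(A ∩ B) / area(A ∪ B), area-weighted; by default on the full
    extents (strong ∪ weak), with a strong-core-only variant behind
    ``strong_only``.  Symmetric; 100 for identical fields, 0 for disjoint.
    """
    weights = REGIONS if weights is None else weights
    if not rf_a or not rf_b:
        raise ValueError("overlap_percent requires two non-empty receptive fields")
    a = rf_a.core if strong_only else rf_a.full_extent
    b = rf_b.core if strong_only else rf_b.full_extent
    if not a or not b:
        raise ValueError("strong-only overlap requires non-empty cores")
    return 100.0 * _jaccard(a, b, weights)


@dataclass
class OverlapReport:
    """Group summary of paired complex-spike / simple-spike field overlaps."""

    concordant: list[float] = field(default_factory=list)
    discordant: list[float] = field(default_factory=list)

    @staticmethod
    def _summary(values: list[float]) -> dict[str, float | int]:
        if not values:
            return {"n": 0, "mean": float("nan"), "sd": float("nan")}
        sd = stdev(values) if len(values) > 1 else 0.0
        return {"n": len(values), "mean": mean(values), "sd": sd}

    def summary(self) -> dict[str, dict[str, float | int]]:
        return {
            "concordant": self._summary(self.concordant),
            "discordant": self._summary(self.discordant),
        }


def overlap_report(
    pairs: Sequence[tuple[ReceptiveField, ReceptiveField]],
    templates: Mapping[int, ClassTemplate] | None = None,
    weights: Mapping[str, float] | None = None,
) -> OverlapReport:
    """Split field pairs by class concordance and summarise their overlaps.

    A pair is concordant when :func:`classify_rf` assigns the same class to
    both members (the typical case where a Purkinje cell's complex-spike and
    simple-spike fields share a territory); overlap percentages are pooled
    per group and reported as mean ± SD.
    """
    if not pairs:
        raise ValueError("overlap_report requires at least one pair")
    report = OverlapReport()
    for rf_a, rf_b in pairs:
        cls_a, _ = classify_rf(rf_a, templates, weights)
        cls_b, _ = classify_rf(rf_b, templates, weights)
        ov = overlap_percent(rf_a, rf_b, weights)
        if cls_a is not None and cls_a == cls_b:
            report.concordant.append(ov)
        else:
            report.discordant.append(ov)
    return report
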