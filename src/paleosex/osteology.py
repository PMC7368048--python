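"""Osteological trait scoring and expert-estimate ingestion.

The scoring scheme records 20 named skeletal traits on a five-point scale
(-2 strongly female-leaning .. +2 strongly male-leaning, 0 ambiguous).  The
published workflow relies on expert synthesis of these scores, so the
primary entry point is :func:`ingest_expert_estimate`, which parses expert
categorical labels.  :func:`aggregate_traits` is an explicitly artifact-
defined surrogate aggregation (weighted mean with pelvic traits up-weighted)
that makes the osteological track testable end-to-end; it is never used for
the published fixture cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import Certainty, Method, Sex, SexEstimate

__all__ = [
    "PELVIC_TRAITS",
    "CRANIAL_TRAITS",
    "ROBUSTICITY_TRAITS",
    "ALL_TRAITS",
    "OsteoTraitScores",
    "AggregationCutoffs",
    "ingest_expert_estimate",
    "aggregate_traits",
]

PELVIC_TRAITS: tuple[str, ...] = (
    "subpubic_concavity",
    "shape_of_pubis",
    "ventral_arc",
    "dorsal_pits",
    "acetabulum_size",
    "greater_sciatic_notch",
    "preauricular_sulcus",
    "auricular_surface",
    "acetabulum_dimensions",
)

CRANIAL_TRAITS: tuple[str, ...] = (
    "nuchal_crest",
    "mastoid_process",
    "supraorbital_margin",
    "supraorbital_ridge",
    "mental_eminence",
    "ascending_ramus",
)

ROBUSTICITY_TRAITS: tuple[str, ...] = (
    "glenoid_fossa_size",
    "vertical_humeral_head",
    "humeral_epicondyle_width",
    "femoral_head_diameter",
    "femoral_bicondyle_width",
)

ALL_TRAITS: tuple[str, ...] = PELVIC_TRAITS + CRANIAL_TRAITS + ROBUSTICITY_TRAITS

_VALID_SCORES = {-2, -1, 0, 1, 2}


@dataclass
class OsteoTraitScores:
    """Per-individual trait scores; juveniles carry no scorable traits."""

    sample_id: str
    scores: dict[str, int | None]
    adult: bool = True

    def __post_init__(self) -> None:
        if set(self.scores) != set(ALL_TRAITS):
            unknown = sorted(set(self.scores) - set(ALL_TRAITS))
            missing = sorted(set(ALL_TRAITS) - set(self.scores))
            raise ValueError(
                f"scores must cover exactly the 20 named traits "
                f"(unknown={unknown}, missing={missing})"
            )
        for trait, score in self.scores.items():
            if score is not None and score not in _VALID_SCORES:
                raise ValueError(f"{trait}: score must be in {{-2..2}}, got {score}")
        if not self.adult and any(s is not None for s in self.scores.values()):
            raise ValueError("juveniles must have all trait scores missing")

    def available(self) -> dict[str, int]:
        return {t: s for t, s in self.scores.items() if s is not None}


@dataclass(frozen=True)
class AggregationCutoffs:
    definitive: float = 1.5
    probable: float = 0.75
    possible: float = 0.25

    def __post_init__(self) -> None:
        if not self.possible < self.probable < self.definitive:
            raise ValueError("require possible < probable < definitive")


_EXPERT_LABELS: dict[str, tuple[Sex, Certainty]] = {
    "F": (Sex.XX, Certainty.DEFINITIVE),
    "M": (Sex.XY, Certainty.DEFINITIVE),
    "probable F": (Sex.XX, Certainty.PROBABLE),
    "probable M": (Sex.XY, Certainty.PROBABLE),
    "possible F": (Sex.XX, Certainty.POSSIBLE),
    "possible M": (Sex.XY, Certainty.POSSIBLE),
    "Indet": (Sex.INDETERMINATE, Certainty.NONE),
    # fixture dialect: asterisk marks the conditional tier without
    # distinguishing probable from possible; mapped to the higher tier
    "F*": (Sex.XX, Certainty.PROBABLE),
    "M*": (Sex.XY, Certainty.PROBABLE),
}


def ingest_expert_estimate(label: str) -> SexEstimate:
    """Parse an expert categorical sex label into a :class:`SexEstimate`."""
    try:
        sex, certainty = _EXPERT_LABELS[label.strip()]
    except KeyError:
        raise ValueError(f"unknown osteological label {label!r}") from None
    return SexEstimate(method=Method.OSTEOLOGY, sex=sex, certainty=certainty)


def aggregate_traits(
    traits: OsteoTraitScores,
    pelvic_weight: float = 2.0,
    cutoffs: AggregationCutoffs | None = None,
) -> SexEstimate:
    """Surrogate aggregation of trait scores into a categorical estimate.

    Weighted mean of available scores with pelvic traits weighted
    ``pelvic_weight`` x others; the absolute mean is compared against the tier
    cutoffs and the sign gives the sex.  Juveniles and all-missing score sets
    are indeterminate.
    """
    cutoffs = cutoffs or AggregationCutoffs()
    available = traits.available() if traits.adult else {}
    if not available:
        return SexEstimate(
            Method.OSTEOLOGY,
            Sex.INDETERMINATE,
            Certainty.NONE,
            diagnostic="juvenile or no scorable traits",
        )
    num = 0.0
    den = 0.0
    for trait, score in available.items():
        w = pelvic_weight if trait in PELVIC_TRAITS else 1.0
        num += w * score
        den += w
    mean = num / den
    magnitude = abs(mean)
    sex = Sex.XY if mean > 0 else Sex.XX
    if magnitude >= cutoffs.definitive:
        return SexEstimate(Method.OSTEOLOGY, sex, Certainty.DEFINITIVE)
    if magnitude >= cutoffs.probable:
        return SexEstimate(Method.OSTEOLOGY, sex, Certainty.PROBABLE)
    if magnitude >= cutoffs.possible:
        return SexEstimate(Method.OSTEOLOGY, sex, Certainty.POSSIBLE)
    return SexEstimate(Method.OSTEOLOGY, Sex.INDETERMINATE, Certainty.NONE)
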