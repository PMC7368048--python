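"""Amelogenin-based sex classification from enamel peptide tables.

Peptides are assigned X/Y specificity by substring containment against the
bundled amelogenin isoform pair; chromosome-specific signal is summed into a
cumulative intensity per mg enamel (CI/mg).  Males are called from unique
Y-isoform peptide counts; females from a four-parameter-logistic probability
of female sex evaluated on log10 of the X-isoform CI/mg.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import (
    Certainty,
    Method,
    PeptideObservation,
    Sex,
    SexEstimate,
    ThresholdConfig,
    load_amelogenin_fasta,
)

__all__ = [
    "Specificity",
    "PrFModel",
    "ProteomicResult",
    "CumulativeIntensity",
    "BlankQCResult",
    "strip_modifications",
    "assign_specificity",
    "cumulative_intensity",
    "pr_female",
    "classify_proteomic",
    "evaluate_sample",
    "blank_qc",
]


class Specificity(str, enum.Enum):
    X_SPECIFIC = "X_specific"
    Y_SPECIFIC = "Y_specific"
    SHARED = "shared"
    UNMATCHED = "unmatched"


@dataclass(frozen=True)
class PrFModel:
    """Four-parameter logistic for probability of female sex.

    Pr(F) = ceiling + (floor - ceiling) / (1 + (x / midpoint)**slope),
    where x is log10 of the X-isoform CI/mg.  Strictly increasing in x from
    ``floor`` (x -> 0+) to ``ceiling`` (x -> inf).
    """

    floor: float = 0.059
    midpoint: float = 7.54
    slope: float = 13.99
    ceiling: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.floor < self.ceiling:
            raise ValueError("require 0 <= floor < ceiling")
        if self.midpoint <= 0 or self.slope <= 0:
            raise ValueError("midpoint and slope must be positive")


@dataclass(frozen=True)
class CumulativeIntensity:
    value: float
    per_mg: bool  # False when enamel mass was unavailable (raw sum)


@dataclass(frozen=True)
class BlankQCResult:
    passed: bool
    n_x_specific: int
    n_y_specific: int
    message: str


@dataclass(frozen=True)
class ProteomicResult:
    sample_id: str
    n_amely_unique: int
    amelx_ci: CumulativeIntensity
    amely_ci: CumulativeIntensity
    x_log10: float | None
    prf: float | None
    estimate: SexEstimate
    specificity_counts: dict[Specificity, int]


_PAREN_MOD = re.compile(r"\([^)]*\)|\[[^\]]*\]")
_TRAILING_MOD = re.compile(r"\s*\+\s*[A-Za-z].*$")


def strip_modifications(sequence: str) -> str:
    """Strip inline and trailing modification annotations from a peptide.

    Handles dialects like ``PEPT(+.98)IDE``, ``PEPT[+15.99]IDE`` and
    ``PEPTIDE + Oxidation (M)``; any residual non-letter characters are
    dropped.
    """
    s = _TRAILING_MOD.sub("", sequence)
    s = _PAREN_MOD.sub("", s)
    s = re.sub(r"[^A-Za-z]", "", s)
    return s.upper()


def assign_specificity(
    peptide: str,
    amelx_seq: str | None = None,
    amely_seq: str | None = None,
    il_equivalent: bool = False,
) -> Specificity:
    """Assign X/Y specificity by substring containment against both isoforms.

    Modification annotations are stripped first.  With ``il_equivalent`` the
    isobaric residues I and L are treated as identical.  Isoform sequences
    default to the bundled pair.
    """
    if amelx_seq is None or amely_seq is None:
        isoforms = load_amelogenin_fasta()
        amelx_seq = amelx_seq or isoforms["AMELX"]
        amely_seq = amely_seq or isoforms["AMELY"]
    stripped = strip_modifications(peptide)
    if not stripped:
        raise ValueError(f"peptide {peptide!r} is empty after modification stripping")

    def norm(s: str) -> str:
        s = s.upper()
        return s.replace("I", "L") if il_equivalent else s

    pep = norm(stripped)
    in_x = pep in norm(amelx_seq)
    in_y = pep in norm(amely_seq)
    if in_x and in_y:
        return Specificity.SHARED
    if in_x:
        return Specificity.X_SPECIFIC
    if in_y:
        return Specificity.Y_SPECIFIC
    return Specificity.UNMATCHED


def _partition(
    observations: Iterable[PeptideObservation],
    amelx_seq: str | None,
    amely_seq: str | None,
    il_equivalent: bool,
) -> dict[Specificity, list[PeptideObservation]]:
    out: dict[Specificity, list[PeptideObservation]] = {s: [] for s in Specificity}
    for obs in observations:
        out[assign_specificity(obs.sequence, amelx_seq, amely_seq, il_equivalent)].append(obs)
    return out


def cumulative_intensity(
    observations: Sequence[PeptideObservation],
    target: Specificity,
    mass_mg: float | None,
) -> CumulativeIntensity:
    """Sum intensities of target-specific observations, normalized per mg.

    All PTM variants of a sequence contribute.  A missing enamel mass returns
    the raw sum flagged ``per_mg=False`` rather than a silently-wrong value.
    """
    if target not in (Specificity.X_SPECIFIC, Specificity.Y_SPECIFIC):
        raise ValueError("target must be X_specific or Y_specific")
    total = float(sum(obs.intensity for obs in observations))
    if mass_mg is None:
        return CumulativeIntensity(value=total, per_mg=False)
    if mass_mg <= 0:
        raise ValueError(f"enamel mass must be positive, got {mass_mg}")
    return CumulativeIntensity(value=total / mass_mg, per_mg=True)


def pr_female(x: float, model: PrFModel | None = None) -> float:
    """Evaluate the probability-of-female logistic at x = log10(AMELX CI/mg)."""
    model = model or PrFModel()
    if x <= 0:
        raise ValueError(
            f"x must be > 0 (log10 CI/mg below 1 is outside the calibrated domain), got {x}"
        )
    return model.ceiling + (model.floor - model.ceiling) / (
        1.0 + (x / model.midpoint) ** model.slope
    )


def classify_proteomic(
    n_amely_unique: int,
    amelx_ci_per_mg: float | None,
    config: ThresholdConfig | None = None,
    model: PrFModel | None = None,
) -> tuple[SexEstimate, float | None, float | None]:
    """Male/female/indeterminate call from Y-peptide count and X signal.

    The male rule (unique Y-isoform peptides > ``min_amely_peptides``) takes
    precedence; otherwise Pr(F) computed from log10(AMELX CI/mg) calls female
    at >= ``prf_cutoff`` and indeterminate below.  Returns
    (estimate, x_log10, prf).
    """
    config = config or ThresholdConfig()
    if n_amely_unique > config.min_amely_peptides:
        return (
            SexEstimate(Method.PROTEOMIC, Sex.XY, Certainty.DEFINITIVE),
            None,
            None,
        )
    if amelx_ci_per_mg is None or amelx_ci_per_mg <= 0:
        return (
            SexEstimate(
                Method.PROTEOMIC,
                Sex.INDETERMINATE,
                Certainty.NONE,
                diagnostic="no amelogenin signal",
            ),
            None,
            None,
        )
    x = math.log10(amelx_ci_per_mg)
    if x <= 0:
        return (
            SexEstimate(
                Method.PROTEOMIC,
                Sex.INDETERMINATE,
                Certainty.NONE,
                diagnostic=f"log10 AMELX CI/mg = {x:.3g} outside calibrated domain",
            ),
            x,
            None,
        )
    prf = pr_female(x, model)
    if prf >= config.prf_cutoff:
        return SexEstimate(Method.PROTEOMIC, Sex.XX, Certainty.DEFINITIVE), x, prf
    return (
        SexEstimate(
            Method.PROTEOMIC,
            Sex.INDETERMINATE,
            Certainty.NONE,
            diagnostic=f"Pr(F) = {prf:.3g} below cutoff",
        ),
        x,
        prf,
    )


def evaluate_sample(
    sample_id: str,
    observations: Sequence[PeptideObservation],
    mass_mg: float | None,
    config: ThresholdConfig | None = None,
    model: PrFModel | None = None,
    amelx_seq: str | None = None,
    amely_seq: str | None = None,
    il_equivalent: bool = False,
) -> ProteomicResult:
    """Full per-sample proteomic pipeline: filter, sum, model, classify."""
    config = config or ThresholdConfig()
    parts = _partition(observations, amelx_seq, amely_seq, il_equivalent)
    x_obs = parts[Specificity.X_SPECIFIC]
    y_obs = parts[Specificity.Y_SPECIFIC]
    # unique peptides counted by distinct stripped sequence; PTM variants of
    # one sequence count once here but all contribute intensity
    n_amely_unique = len({strip_modifications(o.sequence) for o in y_obs})
    amelx_ci = cumulative_intensity(x_obs, Specificity.X_SPECIFIC, mass_mg)
    amely_ci = cumulative_intensity(y_obs, Specificity.Y_SPECIFIC, mass_mg)
    estimate, x_log10, prf = classify_proteomic(
        n_amely_unique,
        amelx_ci.value if amelx_ci.per_mg else None,
        config,
        model,
    )
    if not amelx_ci.per_mg and estimate.sex is Sex.INDETERMINATE and x_obs:
        estimate = SexEstimate(
            Method.PROTEOMIC,
            Sex.INDETERMINATE,
            Certainty.NONE,
            diagnostic="enamel mass unavailable; Pr(F) not evaluated on unnormalized signal",
        )
    return ProteomicResult(
        sample_id=sample_id,
        n_amely_unique=n_amely_unique,
        amelx_ci=amelx_ci,
        amely_ci=amely_ci,
        x_log10=x_log10,
        prf=prf,
        estimate=estimate,
        specificity_counts={s: len(parts[s]) for s in Specificity},
    )


def blank_qc(
    blank_observations: Sequence[PeptideObservation],
    max_x_spectra: int = 1,
    amelx_seq: str | None = None,
    amely_seq: str | None = None,
) -> BlankQCResult:
    """Contamination check for blank runs.

    Passes when no Y-specific spectra are present and X-specific spectra do
    not exceed ``max_x_spectra`` (default 1, matching observed carryover
    tolerance).
    """
    parts = _partition(blank_observations, amelx_seq, amely_seq, il_equivalent=False)
    n_x = len(parts[Specificity.X_SPECIFIC])
    n_y = len(parts[Specificity.Y_SPECIFIC])
    if n_y > 0:
        return BlankQCResult(False, n_x, n_y, f"{n_y} Y-specific spectra in blank")
    if n_x > max_x_spectra:
        return BlankQCResult(
            False, n_x, n_y, f"{n_x} X-specific spectra exceed tolerance {max_x_spectra}"
        )
    return BlankQCResult(True, n_x, n_y, "clean")
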