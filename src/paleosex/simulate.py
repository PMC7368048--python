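"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator produces, per sample: a true karyotype, an age drawn from two
site-like occupation windows, a DNA depth from an age-dependent decay model
(calibrated to lose about one order of magnitude per ~2,000 years), a
multinomial chromosome read-count table, an amelogenin peptide table whose
signal is statistically independent of DNA depth, and sex-conditional
osteological trait scores with juvenile missingness.  Truth is returned
separately from the cohort so pipeline tests cannot leak it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    AUTOSOMES,
    CANONICAL_CHROMOSOMES,
    ChromosomeCounts,
    CohortTable,
    Method,
    PeptideObservation,
    SampleRecord,
    Sex,
    ThresholdConfig,
    load_amelogenin_fasta,
    load_chromosome_lengths,
)
from .genomic import compute_rx, compute_ry
from .osteology import ALL_TRAITS, OsteoTraitScores, aggregate_traits
from .proteomic import Specificity, assign_specificity, evaluate_sample

__all__ = [
    "SimConfig",
    "simulate_chromosome_counts",
    "simulate_peptide_table",
    "simulate_osteo_traits",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a synthetic cohort; ``seed`` is mandatory."""

    seed: int
    n_samples: int = 100
    sex_ratio: float = 0.5  # probability of XY
    # (log10 mean reads at age 0, per-year decay in log10 units, lognormal sd)
    depth_model: tuple[float, float, float] = (5.2, 5.0e-4, 1.2)
    epsilon_y: float = 0.002  # Y-mismapping leakage for XX individuals
    y_mappability: float = 0.25  # effective Y-length fraction
    # (log10 AMELX CI/mg mean, sd); age-invariant by construction
    protein_model: tuple[float, float] = (9.0, 0.6)
    amely_peptide_rate: float = 80.0  # mean unique Y peptides for XY, overdispersed
    juvenile_fraction: float = 0.25
    trait_missing_rate: float = 0.30
    dna_failure_rate: float = 0.02
    teeth_absent_rate: float = 0.0
    # two site-like occupation windows (cal BP)
    age_clusters: tuple[tuple[int, int], tuple[int, int]] = ((100, 600), (1610, 2240))

    def __post_init__(self) -> None:
        for name in (
            "sex_ratio",
            "epsilon_y",
            "y_mappability",
            "juvenile_fraction",
            "trait_missing_rate",
            "dna_failure_rate",
            "teeth_absent_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.depth_model[2] <= 0 or self.protein_model[1] <= 0:
            raise ValueError("model standard deviations must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def _chromosome_weights(karyotype: Sex, config: SimConfig) -> np.ndarray:
    """Sampling weights ∝ copy number × effective chromosome length."""
    lengths = load_chromosome_lengths()
    weights = []
    for chrom in CANONICAL_CHROMOSOMES:
        length = lengths[chrom]
        if chrom == "X":
            copy = 2.0 if karyotype is Sex.XX else 1.0
        elif chrom == "Y":
            eff = length * config.y_mappability
            if karyotype is Sex.XY:
                weights.append(1.0 * eff)
            else:
                weights.append(config.epsilon_y * eff)
            continue
        else:
            copy = 2.0
        weights.append(copy * length)
    w = np.array(weights, dtype=float)
    return w / w.sum()


def simulate_chromosome_counts(
    karyotype: Sex,
    total_reads: int,
    config: SimConfig,
    seed: int | np.random.Generator | None = None,
) -> ChromosomeCounts:
    """Multinomial read-count draw over the 24 canonical chromosomes."""
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    if karyotype not in (Sex.XX, Sex.XY):
        raise ValueError("karyotype must be XX or XY")
    rng = _as_rng(seed if seed is not None else config.seed)
    probs = _chromosome_weights(karyotype, config)
    draw = rng.multinomial(total_reads, probs)
    lengths = load_chromosome_lengths()
    entries = {
        chrom: (lengths[chrom], int(k))
        for chrom, k in zip(CANONICAL_CHROMOSOMES, draw)
    }
    return ChromosomeCounts(sample_id="synthetic", entries=entries)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# peptide simulation
# ---------------------------------------------------------------------------

_WINDOW_SIZES = range(8, 16)


def _candidate_peptides() -> dict[Specificity, list[str]]:
    """All distinct isoform subsequences of length 8..15, by specificity."""
    isoforms = load_amelogenin_fasta()
    amelx, amely = isoforms["AMELX"], isoforms["AMELY"]
    seen: set[str] = set()
    out: dict[Specificity, list[str]] = {s: [] for s in Specificity}
    for seq in (amelx, amely):
        for size in _WINDOW_SIZES:
            for start in range(0, len(seq) - size + 1):
                pep = seq[start : start + size]
                if pep in seen:
                    continue
                seen.add(pep)
                out[assign_specificity(pep, amelx, amely)].append(pep)
    return out


_CANDIDATES: dict[Specificity, list[str]] | None = None


def _candidates() -> dict[Specificity, list[str]]:
    global _CANDIDATES
    if _CANDIDATES is None:
        _CANDIDATES = _candidate_peptides()
    return _CANDIDATES


def _emit_observations(
    rng: np.random.Generator,
    peptides: list[str],
    total_intensity: float,
    accession: str,
) -> list[PeptideObservation]:
    """Split a total intensity over peptides; some get two PTM variants."""
    if not peptides:
        return []
    shares = rng.dirichlet(np.full(len(peptides), 1.5)) * total_intensity
    obs: list[PeptideObservation] = []
    for pep, share in zip(peptides, shares):
        if rng.random() < 0.3:
            frac = rng.uniform(0.2, 0.8)
            obs.append(PeptideObservation(pep, "", share * frac, accession))
            obs.append(
                PeptideObservation(
                    f"{pep} + Deamidation (NQ)", "Deamidation (NQ)", share * (1 - frac), accession
                )
            )
        else:
            obs.append(PeptideObservation(pep, "", share, accession))
    return obs


def simulate_peptide_table(
    sex: Sex,
    config: SimConfig,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[PeptideObservation], float]:
    """Synthetic per-sample peptide table drawn from the bundled isoforms.

    Returns (observations, enamel_mass_mg).  X-specific peptides are present
    for everyone; Y-specific peptides only for XY (overdispersed count with a
    floor of 3); shared peptides are included as distractors that the
    specificity filter must remove.
    """
    rng = _as_rng(seed if seed is not None else config.seed)
    cands = _candidates()
    mass_mg = float(rng.uniform(5.0, 50.0))
    mean_x, sd_x = config.protein_model
    x_log_ci = rng.normal(mean_x, sd_x)
    total_x = (10.0**x_log_ci) * mass_mg

    n_x = min(int(rng.integers(10, 40)), len(cands[Specificity.X_SPECIFIC]))
    x_peps = list(rng.choice(cands[Specificity.X_SPECIFIC], size=n_x, replace=False))
    obs = _emit_observations(rng, x_peps, total_x, "AMELX")

    if sex is Sex.XY:
        # overdispersed count via gamma-Poisson, floored at 3
        lam = rng.gamma(shape=2.0, scale=config.amely_peptide_rate / 2.0)
        n_y = max(3, int(rng.poisson(lam)))
        n_y = min(n_y, len(cands[Specificity.Y_SPECIFIC]))
        y_peps = list(rng.choice(cands[Specificity.Y_SPECIFIC], size=n_y, replace=False))
        y_log_ci = rng.normal(mean_x - 0.7, sd_x)
        obs += _emit_observations(rng, y_peps, (10.0**y_log_ci) * mass_mg, "AMELY")

    n_shared = min(int(rng.integers(5, 15)), len(cands[Specificity.SHARED]))
    shared = list(rng.choice(cands[Specificity.SHARED], size=n_shared, replace=False))
    obs += _emit_observations(rng, shared, (10.0 ** rng.normal(mean_x - 0.3, sd_x)) * mass_mg, "AMEL_SHARED")

    order = rng.permutation(len(obs))
    return [obs[i] for i in order], mass_mg


def simulate_osteo_traits(
    sample_id: str,
    sex: Sex,
    adult: bool,
    config: SimConfig,
    seed: int | np.random.Generator | None = None,
) -> OsteoTraitScores:
    """Sex-conditional five-point trait scores; juveniles all-missing."""
    rng = _as_rng(seed if seed is not None else config.seed)
    if not adult:
        return OsteoTraitScores(
            sample_id=sample_id, scores={t: None for t in ALL_TRAITS}, adult=False
        )
    latent = 1.3 if sex is Sex.XY else -1.3
    scores: dict[str, int | None] = {}
    for trait in ALL_TRAITS:
        if rng.random() < config.trait_missing_rate:
            scores[trait] = None
        else:
            scores[trait] = int(np.clip(round(rng.normal(latent, 0.7)), -2, 2))
    return OsteoTraitScores(sample_id=sample_id, scores=scores, adult=True)


@dataclass
class SimulatedSample:
    record: SampleRecord
    counts: ChromosomeCounts
    peptides: list[PeptideObservation]
    mass_mg: float | None
    traits: OsteoTraitScores


def simulate_cohort(
    config: SimConfig,
    thresholds: ThresholdConfig | None = None,
    return_samples: bool = False,
):
    """Generate a cohort and run the full pipeline on it.

    Returns ``(CohortTable, truth)`` where ``truth`` is a DataFrame with the
    hidden generative state (true sex, age, depth, juvenile flag); with
    ``return_samples`` the raw per-sample materials are returned as well.
    """
    thresholds = thresholds or ThresholdConfig()
    rng = np.random.default_rng(config.seed)
    records: list[SampleRecord] = []
    truth_rows: list[dict] = []
    samples: list[SimulatedSample] = []

    for i in range(config.n_samples):
        sex = Sex.XY if rng.random() < config.sex_ratio else Sex.XX
        cluster = int(rng.random() < 0.5)
        lo, hi = config.age_clusters[cluster]
        age = int(rng.uniform(lo, hi))
        site = "SIM-A" if cluster == 0 else "SIM-B"
        sample_id = f"{site}-{i:04d}"
        juvenile = rng.random() < config.juvenile_fraction

        mean0, decay, sd = config.depth_model
        if rng.random() < config.dna_failure_rate:
            total_reads = 0
        else:
            total_reads = int(round(10.0 ** rng.normal(mean0 - decay * age, sd)))

        counts = simulate_chromosome_counts(sex, total_reads, config, rng)
        counts = dataclasses.replace(counts, sample_id=sample_id)
        ry = compute_ry(counts, thresholds)
        rx = compute_rx(counts, thresholds)

        estimates = {Method.GENOMIC_RY: ry.estimate, Method.GENOMIC_RX: rx.estimate}

        teeth_present = rng.random() >= config.teeth_absent_rate
        peptides: list[PeptideObservation] = []
        mass_mg: float | None = None
        amelx_ci = amely_ci = None
        if teeth_present:
            peptides, mass_mg = simulate_peptide_table(sex, config, rng)
            prot = evaluate_sample(sample_id, peptides, mass_mg, thresholds)
            estimates[Method.PROTEOMIC] = prot.estimate
            amelx_ci = prot.amelx_ci.value
            amely_ci = prot.amely_ci.value

        traits = simulate_osteo_traits(sample_id, sex, not juvenile, config, rng)
        estimates[Method.OSTEOLOGY] = aggregate_traits(traits)

        records.append(
            SampleRecord(
                sample_id=sample_id,
                site=site,
                estimates=estimates,
                total_mapped_reads=total_reads,
                age_cal_bp=age,
                enamel_mass_mg=mass_mg,
                amelx_ci_per_mg=amelx_ci,
                amely_ci_per_mg=amely_ci,
            )
        )
        truth_rows.append(
            {
                "sample_id": sample_id,
                "true_sex": sex.value,
                "age_cal_bp": age,
                "site": site,
                "total_reads": total_reads,
                "juvenile": juvenile,
            }
        )
        if return_samples:
            samples.append(SimulatedSample(records[-1], counts, peptides, mass_mg, traits))

    cohort = CohortTable(records=records, provenance="synthetic")
    truth = pd.DataFrame(truth_rows)
    if return_samples:
        return cohort, truth, samples
    return cohort, truth
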