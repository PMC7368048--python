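"""Karyotype classification from chromosome read counts.

Two ratio statistics are implemented:

* ``RY`` — Y-mapped reads over all sex-chromosome-mapped reads, with a Wald
  binomial 95% CI.  Near 0 for XX, elevated for XY.
* ``RX`` — mean over the 22 autosomes of (X read rate / autosomal read
  rate), rate = mapped reads per bp, with a normal CI from the dispersion of
  the 22 per-autosome ratios.  Near 1 for XX, near 0.5 for XY.

Classification compares the whole confidence interval against a male and a
female decision region: an interval entirely inside a region is definitive,
one that reaches into exactly one region is conditional ("consistent
with..."), and one touching neither or both regions is indeterminate.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    AUTOSOMES,
    CANONICAL_CHROMOSOMES,
    ChromosomeCounts,
    Certainty,
    Method,
    Sex,
    SexEstimate,
    ThresholdConfig,
)

__all__ = [
    "Statistic",
    "Region",
    "RatioResult",
    "classify_interval",
    "compute_ry",
    "compute_rx",
    "downsample_counts",
    "depth_reliability_curve",
]


class Statistic(str, enum.Enum):
    RY = "RY"
    RX = "RX"


@dataclass(frozen=True)
class Region:
    """A one-sided decision region on the statistic axis.

    ``side`` is "above" for {v : v > threshold} and "below" for
    {v : v < threshold}.
    """

    threshold: float
    side: str  # "above" | "below"

    def __post_init__(self) -> None:
        if self.side not in ("above", "below"):
            raise ValueError(f"side must be 'above' or 'below', got {self.side!r}")

    def contains_interval(self, lo: float, hi: float) -> bool:
        """Whole interval strictly inside the region (endpoint on the
        threshold does NOT count as inside)."""
        return lo > self.threshold if self.side == "above" else hi < self.threshold

    def touches_interval(self, lo: float, hi: float) -> bool:
        """Interval reaches the region; an endpoint exactly on the threshold
        counts as touching (conservative: yields conditional, not definitive)."""
        return hi >= self.threshold if self.side == "above" else lo <= self.threshold


@dataclass(frozen=True)
class RatioResult:
    statistic: Statistic
    point: float
    ci_low: float
    ci_high: float
    estimate: SexEstimate
    thresholds_used: ThresholdConfig
    n_sex_reads: int | None = None  # RY only
    per_autosome_ratios: tuple[float, ...] | None = None  # RX only
    total_mapped: int | None = None

    def __post_init__(self) -> None:
        if not math.isnan(self.point) and not self.ci_low <= self.point <= self.ci_high:
            raise ValueError("require ci_low <= point <= ci_high")
        if self.per_autosome_ratios is not None and len(self.per_autosome_ratios) != 22:
            raise ValueError("per_autosome_ratios must have exactly 22 entries")


def classify_interval(
    point: float,
    ci_low: float,
    ci_high: float,
    male_region: Region,
    female_region: Region,
    method: Method,
    low_data_flag: bool = False,
) -> SexEstimate:
    """Classify a confidence interval against male/female decision regions.

    Rules:
      * CI entirely inside the male region   -> definitive XY
      * CI entirely inside the female region -> definitive XX
      * CI touching exactly one region       -> conditional, that region's sex
      * CI touching both or neither region   -> indeterminate
    """
    if male_region.side == female_region.side:
        raise ValueError("male and female regions must lie on opposite sides")
    if male_region.contains_interval(ci_low, ci_high):
        return SexEstimate(method, Sex.XY, Certainty.DEFINITIVE, low_data_flag)
    if female_region.contains_interval(ci_low, ci_high):
        return SexEstimate(method, Sex.XX, Certainty.DEFINITIVE, low_data_flag)
    touches_m = male_region.touches_interval(ci_low, ci_high)
    touches_f = female_region.touches_interval(ci_low, ci_high)
    if touches_m and not touches_f:
        return SexEstimate(method, Sex.XY, Certainty.CONDITIONAL, low_data_flag)
    if touches_f and not touches_m:
        return SexEstimate(method, Sex.XX, Certainty.CONDITIONAL, low_data_flag)
    return SexEstimate(method, Sex.INDETERMINATE, Certainty.NONE, low_data_flag)


def _low_data(counts: ChromosomeCounts, config: ThresholdConfig) -> bool:
    # advisory only: data is "low" when it fails BOTH sufficiency criteria
    return (
        counts.total_mapped() < config.min_total_reads
        and counts.sex_chromosome_reads() < config.min_sexchrom_reads
    )


def compute_ry(
    counts: ChromosomeCounts, config: ThresholdConfig | None = None
) -> RatioResult:
    """Y-fraction statistic n_Y / (n_X + n_Y) with Wald binomial 95% CI.

    Zero sex-chromosome reads produce an indeterminate result object (failed
    extractions are expected cohort members), never an exception.
    """
    config = config or ThresholdConfig()
    n_y = counts.mapped("Y")
    n_x = counts.mapped("X")
    n = n_x + n_y
    flag = _low_data(counts, config)
    if n == 0:
        estimate = SexEstimate(
            Method.GENOMIC_RY,
            Sex.INDETERMINATE,
            Certainty.NONE,
            low_data_flag=flag,
            diagnostic="no sex-chromosome reads",
        )
        return RatioResult(
            statistic=Statistic.RY,
            point=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            estimate=estimate,
            thresholds_used=config,
            n_sex_reads=0,
            total_mapped=counts.total_mapped(),
        )
    point = n_y / n
    half = config.ci_multiplier * math.sqrt(point * (1.0 - point) / n)
    lo = max(0.0, point - half)
    hi = min(1.0, point + half)
    estimate = classify_interval(
        point,
        lo,
        hi,
        male_region=Region(config.ry_male, "above"),
        female_region=Region(config.ry_female, "below"),
        method=Method.GENOMIC_RY,
        low_data_flag=flag,
    )
    return RatioResult(
        statistic=Statistic.RY,
        point=point,
        ci_low=lo,
        ci_high=hi,
        estimate=estimate,
        thresholds_used=config,
        n_sex_reads=n,
        total_mapped=counts.total_mapped(),
    )


def compute_rx(
    counts: ChromosomeCounts, config: ThresholdConfig | None = None
) -> RatioResult:
    """X-dosage statistic: mean over autosomes of rate_X / rate_autosome.

    The 95% CI is mean ± multiplier * sd / sqrt(22) with the sample standard
    deviation (n-1) of the 22 per-autosome ratios.  Any autosome with zero
    mapped reads makes the statistic undefined -> indeterminate result.
    """
    config = config or ThresholdConfig()
    flag = _low_data(counts, config)
    zero_autosomes = [c for c in AUTOSOMES if counts.mapped(c) == 0]
    if zero_autosomes:
        estimate = SexEstimate(
            Method.GENOMIC_RX,
            Sex.INDETERMINATE,
            Certainty.NONE,
            low_data_flag=flag,
            diagnostic=f"autosomes with zero mapped reads: {zero_autosomes[:5]}",
        )
        return RatioResult(
            statistic=Statistic.RX,
            point=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            estimate=estimate,
            thresholds_used=config,
            total_mapped=counts.total_mapped(),
        )
    rate_x = counts.mapped("X") / counts.length("X")
    ratios = np.array(
        [rate_x / (counts.mapped(c) / counts.length(c)) for c in AUTOSOMES]
    )
    point = float(ratios.mean())
    sd = float(ratios.std(ddof=1))
    half = config.ci_multiplier * sd / math.sqrt(len(ratios))
    lo, hi = point - half, point + half
    estimate = classify_interval(
        point,
        lo,
        hi,
        male_region=Region(config.rx_male, "below"),
        female_region=Region(config.rx_female, "above"),
        method=Method.GENOMIC_RX,
        low_data_flag=flag,
    )
    return RatioResult(
        statistic=Statistic.RX,
        point=point,
        ci_low=lo,
        ci_high=hi,
        estimate=estimate,
        thresholds_used=config,
        per_autosome_ratios=tuple(float(r) for r in ratios),
        total_mapped=counts.total_mapped(),
    )


def downsample_counts(
    counts: ChromosomeCounts,
    target_total: int,
    seed: int | np.random.Generator,
) -> ChromosomeCounts:
    """Down-sample mapped reads without replacement across chromosomes.

    Draws from the multivariate hypergeometric distribution so expected
    per-chromosome proportions are preserved exactly.
    """
    total = counts.total_mapped()
    if target_total > total:
        raise ValueError(f"target {target_total} exceeds total mapped reads {total}")
    if target_total == total:
        return dataclasses.replace(counts)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    colors = [counts.mapped(c) for c in CANONICAL_CHROMOSOMES]
    draw = rng.multivariate_hypergeometric(colors, target_total)
    entries = {
        chrom: (counts.length(chrom), int(k))
        for chrom, k in zip(CANONICAL_CHROMOSOMES, draw)
    }
    return ChromosomeCounts(sample_id=counts.sample_id, entries=entries)


def depth_reliability_curve(
    counts: ChromosomeCounts,
    depth_grid: list[int],
    replicates: int,
    seed: int,
    config: ThresholdConfig | None = None,
    true_sex: Sex | None = None,
    statistics: tuple[Statistic, ...] = (Statistic.RY, Statistic.RX),
) -> pd.DataFrame:
    """Category fractions of re-classified down-sampled replicates per depth.

    Returns a tidy frame with one row per (depth, statistic) and columns
    ``frac_definitive``, ``frac_conditional``, ``frac_indeterminate`` and —
    when ``true_sex`` is given — ``frac_conflict`` (called sex differs from
    truth).
    """
    if not depth_grid:
        raise ValueError("empty depth grid")
    config = config or ThresholdConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depth_grid:
        tallies = {
            stat: {"definitive": 0, "conditional": 0, "indeterminate": 0, "conflict": 0}
            for stat in statistics
        }
        for _ in range(replicates):
            sub = downsample_counts(counts, depth, rng)
            for stat in statistics:
                result = compute_ry(sub, config) if stat is Statistic.RY else compute_rx(sub, config)
                est = result.estimate
                if not est.is_called:
                    tallies[stat]["indeterminate"] += 1
                elif est.is_definitive:
                    tallies[stat]["definitive"] += 1
                else:
                    tallies[stat]["conditional"] += 1
                if true_sex is not None and est.is_called and est.sex is not true_sex:
                    tallies[stat]["conflict"] += 1
        for stat in statistics:
            t = tallies[stat]
            row = {
                "depth": depth,
                "statistic": stat.value,
                "frac_definitive": t["definitive"] / replicates,
                "frac_conditional": t["conditional"] / replicates,
                "frac_indeterminate": t["indeterminate"] / replicates,
            }
            if true_sex is not None:
                row["frac_conflict"] = t["conflict"] / replicates
            rows.append(row)
    return pd.DataFrame(rows)


def clopper_pearson_interval(n_y: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial CI, offered as a non-default alternative to Wald."""
    if n == 0:
        raise ValueError("n must be >= 1")
    lo = 0.0 if n_y == 0 else stats.beta.ppf(alpha / 2, n_y, n - n_y + 1)
    hi = 1.0 if n_y == n else stats.beta.ppf(1 - alpha / 2, n_y + 1, n - n_y)
    return float(lo), float(hi)
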