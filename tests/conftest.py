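import numpy as np
import pytest

from paleosex.core import (
    AUTOSOMES,
    CANONICAL_CHROMOSOMES,
    ChromosomeCounts,
    ThresholdConfig,
    load_chromosome_lengths,
    load_fixture_cohort,
)


@pytest.fixture(scope="session")
def fixture_cohort():
    return load_fixture_cohort()


@pytest.fixture(scope="session")
def chrom_lengths():
    return load_chromosome_lengths()


@pytest.fixture(scope="session")
def thresholds():
    return ThresholdConfig()


def build_counts(
    sample_id="toy",
    autosome_reads=1000,
    x_reads=1000,
    y_reads=0,
    autosome_length=1_000_000,
    x_length=1_000_000,
    y_length=1_000_000,
):
    """Counts with uniform autosomes; handy for exact-rate constructions."""
    entries = {}
    for chrom in AUTOSOMES:
        reads = autosome_reads[chrom] if isinstance(autosome_reads, dict) else autosome_reads
        entries[chrom] = (autosome_length, reads)
    entries["X"] = (x_length, x_reads)
    entries["Y"] = (y_length, y_reads)
    return ChromosomeCounts(sample_id=sample_id, entries=entries)


def realistic_counts(rng, total, y_fraction_of_sex=0.0, sex_fraction=0.03, lengths=None):
    """Counts with hg19-like lengths and a controlled sex-read composition."""
    lengths = lengths or load_chromosome_lengths()
    n_sex = int(round(total * sex_fraction))
    n_y = int(round(n_sex * y_fraction_of_sex))
    n_x = n_sex - n_y
    n_auto = total - n_sex
    auto_lengths = np.array([lengths[c] for c in AUTOSOMES], dtype=float)
    probs = auto_lengths / auto_lengths.sum()
    draws = rng.multinomial(n_auto, probs)
    entries = {c: (lengths[c], int(k)) for c, k in zip(AUTOSOMES, draws)}
    entries["X"] = (lengths["X"], n_x)
    entries["Y"] = (lengths["Y"], n_y)
    return ChromosomeCounts(sample_id="realistic", entries=entries)
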