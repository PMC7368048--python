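"""Shared domain types and table I/O for the three-track sex-estimation pipeline.

The package compares three independent lines of evidence about the biological
sex of archaeological skeletal samples:

* genomic   — per-chromosome mapped-read counts (samtools-idxstats dialect),
* proteomic — amelogenin peptide intensities from tooth enamel,
* osteology — expert categorical estimates from skeletal trait scoring.

All three tracks express their verdict as a :class:`SexEstimate`, which is the
common currency consumed by the concordance statistics.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AUTOSOMES",
    "CANONICAL_CHROMOSOMES",
    "Method",
    "Sex",
    "Certainty",
    "SexEstimate",
    "ThresholdConfig",
    "ChromosomeCounts",
    "SampleRecord",
    "CohortTable",
    "PeptideObservation",
    "IdxstatsDiscards",
    "read_idxstats",
    "read_peptide_table",
    "load_fixture_cohort",
    "load_chromosome_lengths",
    "load_amelogenin_fasta",
    "write_report",
    "read_report",
]

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
CANONICAL_CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("X", "Y")

_DATA_PACKAGE = "paleosex.data"


class Method(str, enum.Enum):
    """The four estimation tracks (two genomic statistics count separately)."""

    OSTEOLOGY = "osteology"
    GENOMIC_RY = "genomic_ry"
    GENOMIC_RX = "genomic_rx"
    PROTEOMIC = "proteomic"


class Sex(str, enum.Enum):
    XX = "XX"
    XY = "XY"
    INDETERMINATE = "indeterminate"


class Certainty(str, enum.Enum):
    DEFINITIVE = "definitive"
    CONDITIONAL = "conditional"  # genomic methods only
    PROBABLE = "probable"  # osteology only
    POSSIBLE = "possible"  # osteology only
    NONE = "none"  # paired with Sex.INDETERMINATE

    @property
    def is_conditional_tier(self) -> bool:
        """True for every non-definitive, non-none tier.

        Osteological "probable"/"possible" count as conditional-tier when
        partitioning agreement tables.
        """
        return self in (
            Certainty.CONDITIONAL,
            Certainty.PROBABLE,
            Certainty.POSSIBLE,
        )


@dataclass(frozen=True)
class SexEstimate:
    """A single method's verdict for one sample."""

    method: Method
    sex: Sex
    certainty: Certainty
    low_data_flag: bool = False
    diagnostic: str | None = None

    def __post_init__(self) -> None:
        if (self.sex is Sex.INDETERMINATE) != (self.certainty is Certainty.NONE):
            raise ValueError(
                "sex=indeterminate iff certainty=none "
                f"(got sex={self.sex.value}, certainty={self.certainty.value})"
            )

    @property
    def is_called(self) -> bool:
        return self.sex is not Sex.INDETERMINATE

    @property
    def is_definitive(self) -> bool:
        return self.certainty is Certainty.DEFINITIVE


@dataclass(frozen=True)
class ThresholdConfig:
    """Classification thresholds and data-sufficiency limits.

    Defaults follow the published decision geometry: the Y-fraction statistic
    calls male above 0.075 and female below 0.016; the X-dosage statistic
    calls male below 0.60 and female above 0.80.  ``min_total_reads`` /
    ``min_sexchrom_reads`` gate the advisory low-data flag only — they never
    change a category.
    """

    ry_male: float = 0.075
    ry_female: float = 0.016
    rx_male: float = 0.60
    rx_female: float = 0.80
    ci_multiplier: float = 1.96
    min_total_reads: int = 100_000
    min_sexchrom_reads: int = 3_000
    min_amely_peptides: int = 2  # exclusive: male requires count > this
    prf_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if not self.ry_female < self.ry_male:
            raise ValueError("require ry_female < ry_male")
        if not self.rx_male < self.rx_female:
            raise ValueError("require rx_male < rx_female")
        for name in ("ry_male", "ry_female", "rx_male", "rx_female", "prf_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        if self.ci_multiplier <= 0:
            raise ValueError("ci_multiplier must be positive")

    def with_overrides(self, **kwargs) -> "ThresholdConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ChromosomeCounts:
    """Per-chromosome (length, mapped-read) table for a single sample.

    ``entries`` maps canonical chromosome names ("1".."22","X","Y") to
    ``(length_bp, mapped_reads)`` pairs.  All 24 canonical chromosomes must be
    present after dialect normalization.
    """

    sample_id: str
    entries: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_CHROMOSOMES if c not in self.entries]
        if missing:
            raise ValueError(f"missing canonical chromosomes: {missing}")
        for chrom, (length, mapped) in self.entries.items():
            if chrom not in CANONICAL_CHROMOSOMES:
                raise ValueError(f"non-canonical chromosome {chrom!r}")
            if length <= 0:
                raise ValueError(f"chromosome {chrom}: length must be > 0")
            if mapped < 0:
                raise ValueError(f"chromosome {chrom}: mapped reads must be >= 0")
        object.__setattr__(self, "entries", dict(self.entries))

    def length(self, chrom: str) -> int:
        return self.entries[chrom][0]

    def mapped(self, chrom: str) -> int:
        return self.entries[chrom][1]

    def total_mapped(self) -> int:
        return sum(m for _, m in self.entries.values())

    def sex_chromosome_reads(self) -> int:
        return self.mapped("X") + self.mapped("Y")


@dataclass
class SampleRecord:
    """One cohort row: covariates plus the per-method estimates."""

    sample_id: str
    site: str
    estimates: dict[Method, SexEstimate]
    total_mapped_reads: int | None = None
    age_cal_bp: int | None = None
    enamel_mass_mg: float | None = None
    amelx_ci_per_mg: float | None = None
    amely_ci_per_mg: float | None = None
    raw_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.estimates:
            raise ValueError(f"{self.sample_id}: at least one estimate required")

    def estimate(self, method: Method) -> SexEstimate | None:
        return self.estimates.get(method)


@dataclass
class CohortTable:
    """Ordered collection of :class:`SampleRecord` with unique sample ids."""

    records: list[SampleRecord]
    provenance: str = "user"  # fixture | user | synthetic

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, sample_id: str) -> SampleRecord:
        for rec in self.records:
            if rec.sample_id == sample_id:
                return rec
        raise KeyError(sample_id)

    def methods(self) -> set[Method]:
        out: set[Method] = set()
        for rec in self.records:
            out.update(rec.estimates)
        return out


@dataclass(frozen=True)
class PeptideObservation:
    """One quantified peptide-spectrum row from a spectral-matching export."""

    sequence: str
    modifications: str
    intensity: float
    accession: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        if not math.isfinite(self.intensity) or self.intensity < 0:
            raise ValueError(f"intensity must be finite and >= 0, got {self.intensity}")


@dataclass(frozen=True)
class IdxstatsDiscards:
    """Rows dropped during idxstats normalization, for audit."""

    n_dropped: int
    dropped_names: tuple[str, ...]


# ---------------------------------------------------------------------------
# chromosome-name dialects
# ---------------------------------------------------------------------------

def _canonical_chromosome(raw: str) -> str | None:
    """Map a raw idxstats chromosome name to canonical form, or None to drop."""
    name = raw.strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if name in CANONICAL_CHROMOSOMES:
        return name
    # some references ship numeric sex chromosomes
    if name == "23":
        return "X"
    if name == "24":
        return "Y"
    return None


def read_idxstats(
    path: str | Path, sample_id: str | None = None
) -> tuple[ChromosomeCounts, IdxstatsDiscards]:
    """Read a samtools-idxstats TSV into canonical :class:`ChromosomeCounts`.

    Accepts "chr"-prefixed and bare names as well as numeric 23/24 sex
    chromosomes.  Unplaced scaffolds, the mitochondrion and the unmapped "*"
    row are dropped and tallied in the returned discard report.  The
    unmapped-read column (4th) is parsed but ignored.
    """
    path = Path(path)
    entries: dict[str, tuple[int, int]] = {}
    dropped: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            raw_name, raw_len, raw_mapped = fields[0], fields[1], fields[2]
            chrom = _canonical_chromosome(raw_name)
            if chrom is None:
                dropped.append(raw_name)
                continue
            try:
                length = int(raw_len)
                mapped = int(raw_mapped)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer length/count") from exc
            if mapped < 0:
                raise ValueError(f"{path}:{lineno}: negative mapped count for {chrom}")
            if chrom in entries:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {chrom}")
            entries[chrom] = (length, mapped)
    missing = [c for c in CANONICAL_CHROMOSOMES if c not in entries]
    if missing:
        raise ValueError(f"{path}: missing canonical chromosomes: {missing}")
    counts = ChromosomeCounts(sample_id=sample_id or path.stem, entries=entries)
    return counts, IdxstatsDiscards(len(dropped), tuple(dropped))


def write_idxstats(counts: ChromosomeCounts, path: str | Path) -> None:
    """Write counts back out in 4-column idxstats dialect (unmapped = 0)."""
    path = Path(path)
    with path.open("w") as fh:
        for chrom in CANONICAL_CHROMOSOMES:
            length, mapped = counts.entries[chrom]
            fh.write(f"{chrom}\t{length}\t{mapped}\t0\n")


def read_peptide_table(path: str | Path) -> list[PeptideObservation]:
    """Read a peptide quantification CSV.

    Requires header columns ``sequence, modifications, intensity,
    protein_accession`` (order free, extras ignored).  Intensities may use
    scientific notation; negative or unparseable rows raise with the
    offending line number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"sequence", "modifications", "intensity", "protein_accession"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns: {sorted(missing)}")
    out: list[PeptideObservation] = []
    for idx, row in df.iterrows():
        lineno = idx + 2  # header is line 1
        try:
            intensity = float(row["intensity"])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparseable intensity {row['intensity']!r}") from exc
        if intensity < 0:
            raise ValueError(f"{path}:{lineno}: negative intensity {intensity}")
        if not row["sequence"]:
            raise ValueError(f"{path}:{lineno}: empty peptide sequence")
        out.append(
            PeptideObservation(
                sequence=row["sequence"],
                modifications=row["modifications"],
                intensity=intensity,
                accession=row["protein_accession"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# packaged fixture
# ---------------------------------------------------------------------------

_SITE_NAMES = {
    "ST": "CA-ALA-565/H",
    "RTKT": "CA-ALA-704/H",
}

_GENOMIC_LABELS = {
    "F": (Sex.XX, Certainty.DEFINITIVE),
    "M": (Sex.XY, Certainty.DEFINITIVE),
    "F*": (Sex.XX, Certainty.CONDITIONAL),
    "M*": (Sex.XY, Certainty.CONDITIONAL),
    "Indet": (Sex.INDETERMINATE, Certainty.NONE),
}


def _parse_genomic_label(label: str, method: Method) -> SexEstimate:
    try:
        sex, certainty = _GENOMIC_LABELS[label]
    except KeyError:
        raise ValueError(f"unknown genomic label {label!r}") from None
    return SexEstimate(method=method, sex=sex, certainty=certainty)


def _parse_proteomic_label(label: str) -> SexEstimate:
    # proteomic estimates in the fixture cohort are always definitive
    if label == "F":
        return SexEstimate(Method.PROTEOMIC, Sex.XX, Certainty.DEFINITIVE)
    if label == "M":
        return SexEstimate(Method.PROTEOMIC, Sex.XY, Certainty.DEFINITIVE)
    if label == "Indet":
        return SexEstimate(Method.PROTEOMIC, Sex.INDETERMINATE, Certainty.NONE)
    raise ValueError(f"unknown proteomic label {label!r}")


def site_from_sample_id(sample_id: str) -> str:
    prefix = sample_id.split("-", 1)[0]
    if prefix not in _SITE_NAMES:
        raise ValueError(f"cannot decode site from sample id {sample_id!r}")
    return prefix


def site_full_name(site_code: str) -> str:
    return _SITE_NAMES[site_code]


def load_fixture_cohort() -> CohortTable:
    """Load the packaged 55-sample published cohort.

    Each record carries the verbatim printed labels (``raw_labels``) and the
    parsed structured estimates for all four methods.
    """
    from .osteology import ingest_expert_estimate

    ref = resources.files(_DATA_PACKAGE).joinpath("table2_cohort.tsv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    records: list[SampleRecord] = []
    for _, row in df.iterrows():
        estimates = {
            Method.OSTEOLOGY: ingest_expert_estimate(row["oste"]),
            Method.GENOMIC_RY: _parse_genomic_label(row["ry"], Method.GENOMIC_RY),
            Method.GENOMIC_RX: _parse_genomic_label(row["rx"], Method.GENOMIC_RX),
            Method.PROTEOMIC: _parse_proteomic_label(row["prot"]),
        }
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                site=site_from_sample_id(row["sample_id"]),
                estimates=estimates,
                total_mapped_reads=int(row["total_mapped_reads"]),
                raw_labels={
                    "oste": row["oste"],
                    "ry": row["ry"],
                    "rx": row["rx"],
                    "prot": row["prot"],
                },
            )
        )
    return CohortTable(records=records, provenance="fixture")


def load_chromosome_lengths() -> dict[str, int]:
    """Bundled hg19-style canonical chromosome lengths (bp)."""
    ref = resources.files(_DATA_PACKAGE).joinpath("hg19_chrom_lengths.tsv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", dtype={"chromosome": str, "length_bp": int})
    return dict(zip(df["chromosome"], df["length_bp"]))


def load_amelogenin_fasta() -> dict[str, str]:
    """Bundled amelogenin X/Y isoform sequences, keyed 'AMELX'/'AMELY'."""
    from Bio import SeqIO

    ref = resources.files(_DATA_PACKAGE).joinpath("amelogenin_isoforms.fasta")
    out: dict[str, str] = {}
    with resources.as_file(ref) as p:
        for record in SeqIO.parse(str(p), "fasta"):
            key = record.id.split()[0]
            out[key] = str(record.seq).upper()
    if set(out) != {"AMELX", "AMELY"}:
        raise ValueError(f"unexpected isoform ids in bundled FASTA: {sorted(out)}")
    return out


# ---------------------------------------------------------------------------
# cohort report serialization
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "sample_id",
    "site",
    "total_mapped_reads",
    "age_cal_bp",
    "enamel_mass_mg",
    "amelx_ci_per_mg",
    "amely_ci_per_mg",
]


def _estimate_to_cells(est: SexEstimate | None) -> dict[str, object]:
    if est is None:
        return {"sex": "", "certainty": "", "low_data": ""}
    return {
        "sex": est.sex.value,
        "certainty": est.certainty.value,
        "low_data": int(est.low_data_flag),
    }


def cohort_to_frame(cohort: CohortTable) -> pd.DataFrame:
    """Flatten a cohort into one row per sample for reporting."""
    rows = []
    for rec in cohort:
        row: dict[str, object] = {
            "sample_id": rec.sample_id,
            "site": rec.site,
            "total_mapped_reads": rec.total_mapped_reads,
            "age_cal_bp": rec.age_cal_bp,
            "enamel_mass_mg": rec.enamel_mass_mg,
            "amelx_ci_per_mg": rec.amelx_ci_per_mg,
            "amely_ci_per_mg": rec.amely_ci_per_mg,
        }
        for method in Method:
            cells = _estimate_to_cells(rec.estimate(method))
            for key, val in cells.items():
                row[f"{method.value}_{key}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(cohort: CohortTable, path: str | Path, format: str = "tsv") -> None:
    """Serialize a cohort to TSV or JSON; round-trips via :func:`read_report`."""
    if len(cohort) == 0:
        raise ValueError("refusing to write an empty cohort")
    path = Path(path)
    if format == "tsv":
        cohort_to_frame(cohort).to_csv(path, sep="\t", index=False)
    elif format == "json":
        payload = {
            "provenance": cohort.provenance,
            "records": cohort_to_frame(cohort).to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1, default=_json_default))
    else:
        raise ValueError(f"unknown report format {format!r}")


def _json_default(obj):
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {obj!r}")


def _cells_to_estimate(method: Method, sex: str, certainty: str, low_data) -> SexEstimate | None:
    if sex in ("", None) or (isinstance(sex, float) and math.isnan(sex)):
        return None
    flag = bool(int(low_data)) if low_data not in ("", None) and not _isnan(low_data) else False
    return SexEstimate(
        method=method,
        sex=Sex(sex),
        certainty=Certainty(certainty),
        low_data_flag=flag,
    )


def _isnan(x) -> bool:
    return isinstance(x, float) and math.isnan(x)


def _opt_int(x) -> int | None:
    if x in ("", None) or _isnan(x):
        return None
    return int(x)


def _opt_float(x) -> float | None:
    if x in ("", None) or _isnan(x):
        return None
    return float(x)


def read_report(path: str | Path, format: str = "tsv") -> CohortTable:
    """Inverse of :func:`write_report`."""
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        provenance = "user"
    elif format == "json":
        payload = json.loads(path.read_text())
        df = pd.DataFrame(payload["records"])
        provenance = payload.get("provenance", "user")
    else:
        raise ValueError(f"unknown report format {format!r}")
    records = []
    for _, row in df.iterrows():
        estimates: dict[Method, SexEstimate] = {}
        for method in Method:
            est = _cells_to_estimate(
                method,
                row.get(f"{method.value}_sex"),
                row.get(f"{method.value}_certainty"),
                row.get(f"{method.value}_low_data"),
            )
            if est is not None:
                estimates[method] = est
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                site=str(row["site"]),
                estimates=estimates,
                total_mapped_reads=_opt_int(row.get("total_mapped_reads")),
                age_cal_bp=_opt_int(row.get("age_cal_bp")),
                enamel_mass_mg=_opt_float(row.get("enamel_mass_mg")),
                amelx_ci_per_mg=_opt_float(row.get("amelx_ci_per_mg")),
                amely_ci_per_mg=_opt_float(row.get("amely_ci_per_mg")),
            )
        )
    return CohortTable(records=records, provenance=provenance)
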