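"""Shared domain types for the DNA/RNA allele-frequency analysis.

Coordinates are 0-based, half-open everywhere inside the package; VCF output
is 1-based per the format, BED output is native 0-based half-open.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class ConsequenceClass(str, enum.Enum):
    """Coding consequence of an SNV against one transcript model."""

    SILENT = "silent"
    NONSYNONYMOUS = "nonsynonymous"
    PTC_NOT_LAST_EXON = "PTC_not_last_exon"
    PTC_LAST_EXON = "PTC_last_exon"
    NONCODING = "noncoding"


class Analyte(str, enum.Enum):
    DNA = "DNA"
    RNA = "RNA"


class SampleSource(str, enum.Enum):
    TUMOR = "tumor"
    GERMLINE = "germline"


@dataclass(frozen=True)
class GenomeSegment:
    """A genomic interval with a constant absolute (integer) copy number."""

    chrom: str
    start: int
    end: int
    cn: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"segment start must be < end: {self}")
        if self.cn < 1:
            raise ValueError(f"copy number must be >= 1: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SnvRecord:
    """One somatic single-nucleotide variant.

    ``multiplicity`` is the number of allelic copies at the locus carrying
    the mutant base; it is bounded by the segment copy number.
    """

    snv_id: str
    chrom: str
    pos: int  # 0-based
    ref_base: str
    alt_base: str
    gene_id: str
    transcript_id: str
    segment_cn: int
    multiplicity: int
    consequence: ConsequenceClass

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError(f"ref and alt must differ at {self.snv_id}")
        if not (1 <= self.multiplicity <= self.segment_cn):
            raise ValueError(
                f"multiplicity {self.multiplicity} outside 1..CN={self.segment_cn} "
                f"at {self.snv_id}"
            )


@dataclass(frozen=True)
class AlleleCounts:
    """Mutant/total read counts for one SNV in one replicate of one library."""

    mutant_reads: int
    total_reads: int
    analyte: Analyte = Analyte.DNA
    sample: SampleSource = SampleSource.TUMOR
    replicate: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.mutant_reads <= self.total_reads):
            raise ValueError(
                f"need 0 <= mutant ({self.mutant_reads}) <= total ({self.total_reads})"
            )


@dataclass(frozen=True)
class AlleleFractionEstimate:
    """Point estimate of a mutation allele fraction with its binomial SE."""

    p: float
    se: float
    n_effective: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"allele fraction outside [0,1]: {self.p}")
        if self.se < 0:
            raise ValueError(f"negative standard error: {self.se}")


@dataclass
class SampleModel:
    """Sample-wide parameters tying coverage ratios and allele fractions
    to absolute copy number.

    ``coverage_scale`` maps an observed tumor:germline depth ratio r to an
    effective locus copy content: E[r] = (rho*cn + 2*(1-rho)) / coverage_scale.
    """

    purity: float
    psi: float
    coverage_scale: float
    loglik: float = float("nan")
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity must be in (0,1]: {self.purity}")
        if self.psi <= 0 or self.coverage_scale <= 0:
            raise ValueError("psi and coverage_scale must be positive")


@dataclass(frozen=True)
class LatticeFit:
    """Maximum-likelihood (copy number, multiplicity) assignment for one SNV."""

    cn: int
    m: int
    loglik: float
    runner_up_margin: float

    def __post_init__(self) -> None:
        if not (1 <= self.m <= self.cn):
            raise ValueError(f"need 1 <= m <= cn, got m={self.m}, cn={self.cn}")


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


class AnnotationError(ValueError):
    """Transcript model inconsistent with the reference or the SNV."""
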