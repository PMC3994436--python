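"""Mutation allele fractions from read counts, with replicate weighting
and coverage filters.

The allele fraction at an SNV is the number of mutation-containing reads
divided by all reads overlapping the position. Replicates are combined by
inverse-variance (error-weighted) averaging using binomial standard errors,
so measurements with more reads get more weight. SNVs enter the downstream
analysis only when at least ``min_reads`` DNA reads and ``min_reads`` RNA
reads (pooled over replicates) overlap the position, and a germline
binomial filter removes loci where lack of germline coverage could have
masked a heterozygous germline variant.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AlleleCounts, AlleleFractionEstimate

DEFAULT_MIN_READS = 10
DEFAULT_ALPHA = 0.05
DEFAULT_ERROR_RATE = 1e-3


def allele_fraction(counts: AlleleCounts) -> AlleleFractionEstimate:
    """Point estimate k/n with a pseudocount-stabilized binomial SE.

    The SE uses the +2/+4 (Agresti-Coull style) stabilization
    p~=(k+2)/(n+4), n~=n+4, so that k=0 and k=n still carry finite weight
    in the inverse-variance combination.
    """
    k, n = counts.mutant_reads, counts.total_reads
    if n < 1:
        raise ValueError("allele fraction undefined for zero coverage; filter first")
    p_tilde = (k + 2) / (n + 4)
    se = math.sqrt(p_tilde * (1.0 - p_tilde) / (n + 4))
    return AlleleFractionEstimate(p=k / n, se=se, n_effective=n)


def combine_replicates(
    estimates: Sequence[AlleleFractionEstimate],
) -> AlleleFractionEstimate:
    """Inverse-variance weighted mean of replicate allele fractions.

    Weights are w_i = 1/se_i^2, the combined SE is sqrt(1/sum(w_i)); a
    replicate with more reads has a smaller SE and hence a larger weight.
    A single estimate is returned unchanged.
    """
    if len(estimates) == 0:
        raise ValueError("no estimates to combine")
    if len(estimates) == 1:
        return estimates[0]
    w = np.array([1.0 / e.se**2 for e in estimates])
    p = float(np.average([e.p for e in estimates], weights=w))
    p = min(1.0, max(0.0, p))
    return AlleleFractionEstimate(
        p=p,
        se=float(math.sqrt(1.0 / w.sum())),
        n_effective=int(sum(e.n_effective for e in estimates)),
    )


def pooled_counts(counts: Iterable[AlleleCounts]) -> tuple[int, int]:
    """Sum mutant and total reads over replicates."""
    ks, ns = 0, 0
    for c in counts:
        ks += c.mutant_reads
        ns += c.total_reads
    return ks, ns


def min_read_filter(
    dna: Iterable[AlleleCounts],
    rna: Iterable[AlleleCounts],
    min_reads: int = DEFAULT_MIN_READS,
) -> bool:
    """Keep an SNV only if pooled DNA and pooled RNA coverage both reach
    ``min_reads`` ("at least ten" is inclusive)."""
    _, n_dna = pooled_counts(dna)
    _, n_rna = pooled_counts(rna)
    return n_dna >= min_reads and n_rna >= min_reads


def germline_binomial_filter(
    tumor_dna: Iterable[AlleleCounts],
    germline_dna: Iterable[AlleleCounts],
    alpha: float = DEFAULT_ALPHA,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> bool:
    """Guard against tumor-only coverage artifacts at putative somatic SNVs.

    Keep only if (i) germline coverage is deep enough that a heterozygous
    germline variant would almost surely have shown a mutant read:
    P(0 mutant | het) = 0.5^n_germline < alpha; and (ii) the observed
    germline mutant fraction is consistent with sequencing error alone
    (one-sided exact binomial test against ``error_rate`` at level alpha).
    """
    k_g, n_g = pooled_counts(germline_dna)
    if n_g == 0:
        return False
    if 0.5**n_g >= alpha:
        return False
    if k_g > 0:
        pval = stats.binomtest(k_g, n_g, error_rate, alternative="greater").pvalue
        if pval < alpha:
            return False
    return True


def expressed_fraction(rna_mutant_reads: Sequence[int]) -> float:
    """Fraction of SNVs with at least one mutant RNA read (presence calls).

    Callers are expected to pass only SNVs that survive the coverage filter.
    """
    arr = np.asarray(list(rna_mutant_reads))
    if arr.size == 0:
        raise ValueError("no SNVs given")
    return float(np.mean(arr >= 1))


# --- table-level pipeline -------------------------------------------------


def _counts_of(grp: pd.DataFrame) -> list[AlleleCounts]:
    return [
        AlleleCounts(int(r.mutant_reads), int(r.total_reads), replicate=int(r.replicate))
        for r in grp.itertuples()
    ]


def allele_fraction_table(
    counts: pd.DataFrame,
    min_reads: int = DEFAULT_MIN_READS,
    alpha: float = DEFAULT_ALPHA,
    error_rate: float = DEFAULT_ERROR_RATE,
) -> pd.DataFrame:
    """Per-SNV replicate-combined DNA and RNA allele fractions plus filters.

    Consumes the tidy counts table (snv_id, sample, analyte, replicate,
    mutant_reads, total_reads) and emits one row per SNV with columns
    p_dna, se_dna, p_rna, se_rna, pooled coverages and filter decisions.
    """
    rows = []
    for snv_id, grp in counts.groupby("snv_id", sort=False):
        dna_t = grp[(grp["sample"] == "tumor") & (grp["analyte"] == "DNA")]
        dna_g = grp[(grp["sample"] == "germline") & (grp["analyte"] == "DNA")]
        rna_t = grp[(grp["sample"] == "tumor") & (grp["analyte"] == "RNA")]

        def _combined(sub: pd.DataFrame) -> AlleleFractionEstimate | None:
            ests = [
                allele_fraction(c) for c in _counts_of(sub) if c.total_reads >= 1
            ]
            return combine_replicates(ests) if ests else None

        dna_est = _combined(dna_t)
        rna_est = _combined(rna_t)
        k_dna, n_dna = pooled_counts(_counts_of(dna_t))
        k_rna, n_rna = pooled_counts(_counts_of(rna_t))
        k_g, n_g = pooled_counts(_counts_of(dna_g))

        keep_cov = min_read_filter(_counts_of(dna_t), _counts_of(rna_t), min_reads)
        keep_germ = germline_binomial_filter(
            _counts_of(dna_t), _counts_of(dna_g), alpha=alpha, error_rate=error_rate
        )
        rows.append(
            dict(
                snv_id=snv_id,
                p_dna=dna_est.p if dna_est else np.nan,
                se_dna=dna_est.se if dna_est else np.nan,
                p_rna=rna_est.p if rna_est else np.nan,
                se_rna=rna_est.se if rna_est else np.nan,
                dna_mutant_reads=k_dna,
                dna_total_reads=n_dna,
                rna_mutant_reads=k_rna,
                rna_total_reads=n_rna,
                germline_mutant_reads=k_g,
                germline_total_reads=n_g,
                pass_min_reads=keep_cov,
                pass_germline_filter=keep_germ,
                pass_filters=keep_cov and keep_germ,
            )
        )
    return pd.DataFrame(rows)
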