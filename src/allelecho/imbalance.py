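"""RNA vs DNA mutation allele-frequency imbalance statistics.

The imbalance score of an SNV is I = 100 * (p_RNA - p_DNA), in percentage
points: near zero when the mutant allele is transcribed in proportion to
its DNA dosage, strongly negative when the mutant transcript is depleted
(e.g. by nonsense-mediated decay). Group comparisons use a two-sample
t-test (pooled variance by default) and squared Pearson correlation, and
SNVs are stratified by RNA coverage and by consequence class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_HIGH_COVERAGE = 65
DEFAULT_LOW_COVERAGE = 15
DEFAULT_OUTLIER_THRESHOLD = 25.0


def imbalance(p_rna, p_dna):
    """Imbalance score in percentage points: 100 * (p_RNA - p_DNA)."""
    p_rna = np.asarray(p_rna, dtype=float)
    p_dna = np.asarray(p_dna, dtype=float)
    if np.any((p_rna < 0) | (p_rna > 1) | (p_dna < 0) | (p_dna > 1)):
        raise ValueError("allele fractions must lie in [0,1]")
    out = 100.0 * (p_rna - p_dna)
    return float(out) if out.ndim == 0 else out


def correlate(p_dna: Sequence[float], p_rna: Sequence[float]) -> float:
    """Squared Pearson correlation of DNA vs RNA allele fractions.

    Returns NaN (with a warning) if either vector has zero variance.
    """
    x = np.asarray(p_dna, dtype=float)
    y = np.asarray(p_rna, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        warnings.warn("zero-variance input; correlation undefined")
        return float("nan")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


@dataclass
class GroupStats:
    """Summary of one stratum of SNVs."""

    n: int
    mean_imbalance: float
    sd_imbalance: float
    r2: float
    flags: list[str]

    @classmethod
    def from_records(cls, df: pd.DataFrame) -> "GroupStats":
        flags = []
        n = len(df)
        if n == 0:
            return cls(0, float("nan"), float("nan"), float("nan"), ["empty"])
        i = df["imbalance"].to_numpy(dtype=float)
        mean_i = float(np.mean(i))
        sd_i = float(np.std(i, ddof=1)) if n >= 2 else float("nan")
        if n >= 2 and np.isnan(sd_i):  # pragma: no cover
            flags.append("sd_undefined")
        if n >= 3:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r2 = correlate(df["p_dna"], df["p_rna"])
            if np.isnan(r2):
                flags.append("r2_undefined")
        else:
            r2 = float("nan")
            flags.append("too_few_for_r2")
        return cls(n, mean_i, sd_i, r2, flags)


def coverage_strata(
    records: pd.DataFrame,
    high_cutoff: int = DEFAULT_HIGH_COVERAGE,
    low_cutoff: int = DEFAULT_LOW_COVERAGE,
) -> tuple[GroupStats, GroupStats]:
    """Summaries of the well-covered (>= high_cutoff RNA reads) and poorly
    covered (< low_cutoff) SNV strata; sampling noise makes the low stratum's
    imbalance SD larger."""
    high = records[records["rna_total_reads"] >= high_cutoff]
    low = records[records["rna_total_reads"] < low_cutoff]
    return GroupStats.from_records(high), GroupStats.from_records(low)


def compare_groups(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> float:
    """Two-sample t-test p-value for a difference in mean imbalance.

    Pooled-variance (classic) test by default; ``equal_var=False`` gives
    Welch's test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
        return 1.0
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def build_records(
    af: pd.DataFrame, cn: pd.DataFrame, consequences: pd.DataFrame
) -> pd.DataFrame:
    """Join allele fractions, lattice fits and consequence strata into the
    per-SNV imbalance table (filtered SNVs only)."""
    df = af[af["pass_filters"]].merge(cn, on="snv_id", how="left")
    df = df.merge(consequences, on="snv_id", how="left")
    df["imbalance"] = imbalance(df["p_rna"].to_numpy(), df["p_dna"].to_numpy())
    return df


def summarize(
    records: pd.DataFrame,
    high_cutoff: int = DEFAULT_HIGH_COVERAGE,
    low_cutoff: int = DEFAULT_LOW_COVERAGE,
    outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD,
) -> dict:
    """All headline statistics of the analysis as one JSON-serializable dict."""
    out: dict = {"n_snvs": int(len(records))}
    out["expressed_fraction"] = float(np.mean(records["rna_mutant_reads"] >= 1))
    out["r2_all"] = (
        correlate(records["p_dna"], records["p_rna"]) if len(records) >= 3 else None
    )
    out["n_outliers"] = int((records["imbalance"].abs() > outlier_threshold).sum())
    out["outlier_threshold"] = outlier_threshold

    hi, lo = coverage_strata(records, high_cutoff, low_cutoff)
    out["coverage_strata"] = {
        f"rna_ge_{high_cutoff}": asdict(hi),
        f"rna_lt_{low_cutoff}": asdict(lo),
    }

    groups = {}
    for name, sub in records.groupby("ptc_group"):
        groups[str(name)] = asdict(GroupStats.from_records(sub))
    out["ptc_groups"] = groups

    def _maybe_p(a_lbl: str, b_lbl: str) -> float | None:
        a = records.loc[records["ptc_group"] == a_lbl, "imbalance"]
        b = records.loc[records["ptc_group"] == b_lbl, "imbalance"]
        if len(a) >= 2 and len(b) >= 2:
            return compare_groups(a, b)
        return None

    out["p_no_ptc_vs_ptc_not_last"] = _maybe_p("no_PTC", "PTC_not_last_exon")
    out["p_no_ptc_vs_ptc_last"] = _maybe_p("no_PTC", "PTC_last_exon")

    coding = {}
    for name, sub in records.groupby("coding_group"):
        coding[str(name)] = asdict(GroupStats.from_records(sub))
    out["coding_groups"] = coding
    sil = records.loc[records["coding_group"] == "silent", "imbalance"]
    nsy = records.loc[records["coding_group"] == "nonsynonymous", "imbalance"]
    out["p_silent_vs_nonsynonymous"] = (
        compare_groups(sil, nsy) if len(sil) >= 2 and len(nsy) >= 2 else None
    )
    return out


def report(
    records: pd.DataFrame,
    out_dir,
    high_cutoff: int = DEFAULT_HIGH_COVERAGE,
    low_cutoff: int = DEFAULT_LOW_COVERAGE,
    outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD,
    figures: bool = True,
) -> dict:
    """Write imbalance.tsv, summary.json and diagnostic figures.

    Returns the summary dict. Re-running on identical inputs reproduces
    identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records.to_csv(out / "imbalance.tsv", sep="\t", index=False)
    summary = summarize(records, high_cutoff, low_cutoff, outlier_threshold)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, allow_nan=True)
        fh.write("\n")
    if figures:
        _figures(records, out, high_cutoff, low_cutoff)
    return summary


def _figures(records: pd.DataFrame, out: Path, high_cutoff: int, low_cutoff: int) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 5))
    sc = axes[0].scatter(
        100 * records["p_dna"], 100 * records["p_rna"],
        c=records.get("cn"), cmap="viridis", s=18, alpha=0.7,
    )
    fig.colorbar(sc, ax=axes[0], label="copy number")
    axes[0].plot([0, 100], [0, 100], "k--", lw=0.8)
    axes[0].set_xlabel("DNA mutation allele frequency (%)")
    axes[0].set_ylabel("RNA mutation allele frequency (%)")
    sc2 = axes[1].scatter(
        100 * records["p_dna"], 100 * records["p_rna"],
        c=np.log10(records["rna_total_reads"].clip(lower=1)),
        cmap="plasma", s=18, alpha=0.7,
    )
    fig.colorbar(sc2, ax=axes[1], label="log10 RNA reads")
    axes[1].plot([0, 100], [0, 100], "k--", lw=0.8)
    axes[1].set_xlabel("DNA mutation allele frequency (%)")
    fig.tight_layout()
    fig.savefig(out / "dna_vs_rna.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 5))
    bins = np.linspace(-100, 100, 81)
    for grp, color in [
        ("no_PTC", "black"),
        ("PTC_not_last_exon", "red"),
        ("PTC_last_exon", "green"),
    ]:
        vals = records.loc[records["ptc_group"] == grp, "imbalance"]
        if len(vals):
            ax.hist(vals, bins=bins, histtype="step", label=f"{grp} (n={len(vals)})",
                    color=color, density=True)
    ax.set_xlabel("imbalance I = 100*(p_RNA - p_DNA)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "imbalance_by_ptc_group.png", dpi=120)
    plt.close(fig)
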