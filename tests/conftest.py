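"""Shared simulated datasets (session-scoped: each is built once)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from allelecho.allelefrac import allele_fraction, allele_fraction_table
from allelecho.annot import strata
from allelecho.cnfit import assign_all, fit_sample_model
from allelecho.core import AlleleCounts
from allelecho.imbalance import imbalance
from allelecho.sim import SimConfig, simulate_counts, simulate_genome


def fit_dataset(cfg: SimConfig):
    """Simulate, estimate allele fractions, fit the sample model and assign
    lattice points; returns everything tests need to compare with truth."""
    truth = simulate_genome(cfg)
    counts = simulate_counts(truth)
    af = allele_fraction_table(counts)
    usable = af[(af.dna_total_reads >= 10) & (af.germline_total_reads > 0)].reset_index(
        drop=True
    )
    pooled = [
        allele_fraction(AlleleCounts(int(r.dna_mutant_reads), int(r.dna_total_reads)))
        for r in usable.itertuples()
    ]
    ratios = (usable.dna_total_reads / usable.germline_total_reads).to_numpy()
    germ = usable.germline_total_reads.to_numpy(dtype=float)
    model = fit_sample_model(ratios, pooled, germline_totals=germ)
    fits = assign_all(pooled, ratios, model, germline_totals=germ)
    true_by_id = {s.snv_id: s for s in truth.snvs}
    return dict(
        truth=truth, counts=counts, af=af, usable=usable, pooled=pooled,
        ratios=ratios, germline_totals=germ, model=model, fits=fits,
        true_by_id=true_by_id,
    )


@pytest.fixture(scope="session")
def recovery_data():
    """500 SNVs, mean depth 100, pure tumor: the parameter-recovery setting."""
    return fit_dataset(SimConfig(n_snvs=500, dna_depth_mean=100, seed=1))


def imbalance_records(
    nmd_efficiency: float,
    seed: int = 0,
    rna_depth_mean: float = 200.0,
    rna_depth_sigma: float = 0.5,
) -> pd.DataFrame:
    """Filtered per-SNV imbalance table for a deeply sequenced fixture."""
    cfg = SimConfig(
        n_snvs=1000, dna_depth_mean=100, rna_depth_mean=rna_depth_mean,
        rna_depth_sigma=rna_depth_sigma, nmd_efficiency=nmd_efficiency, seed=seed,
    )
    truth = simulate_genome(cfg)
    counts = simulate_counts(truth)
    af = allele_fraction_table(counts)
    lab = strata([s.consequence for s in truth.snvs])
    lab["snv_id"] = [s.snv_id for s in truth.snvs]
    df = af[af.pass_filters].merge(lab, on="snv_id")
    df["imbalance"] = imbalance(df.p_rna.to_numpy(), df.p_dna.to_numpy())
    return df


@pytest.fixture(scope="session")
def nmd_free_records():
    return imbalance_records(nmd_efficiency=0.0)


@pytest.fixture(scope="session")
def nmd_records():
    return imbalance_records(nmd_efficiency=0.8)
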