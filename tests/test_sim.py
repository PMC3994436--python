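"""Simulator: lattice structure, determinism, sampling laws, fixture I/O."""

import hashlib
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from allelecho.annot import classify
from allelecho.core import ConfigurationError, ConsequenceClass
from allelecho.sim import (
    SimConfig,
    expected_rna_fraction,
    read_counts,
    read_segments_bed,
    read_vcf,
    simulate_counts,
    simulate_genome,
    true_dna_af,
    write_fixture,
)


class TestTrueDnaAf:
    @pytest.mark.parametrize(
        "m,cn,rho,expected",
        [
            (1, 3, 1.0, 1 / 3),  # one mutant copy in a triploid region
            (2, 2, 1.0, 1.0),  # homozygous
            (5, 5, 1.0, 1.0),
            (1, 2, 0.5, 0.25),  # half the cells are normal diploid
        ],
    )
    def test_lattice_formula(self, m, cn, rho, expected):
        assert true_dna_af(m, cn, rho) == pytest.approx(expected)

    def test_rejects_bad_purity_and_multiplicity(self):
        with pytest.raises(ValueError):
            true_dna_af(1, 2, 0.0)
        with pytest.raises(ValueError):
            true_dna_af(3, 2, 1.0)


class TestSimulateGenome:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_snvs=40, seed=11)
        t1, t2 = simulate_genome(cfg), simulate_genome(cfg)
        assert [s.snv_id for s in t1.snvs] == [s.snv_id for s in t2.snvs]
        assert [(s.pos, s.segment_cn, s.multiplicity) for s in t1.snvs] == [
            (s.pos, s.segment_cn, s.multiplicity) for s in t2.snvs
        ]
        assert t1.reference == t2.reference

    def test_diploid_only_weights_force_diploid_lattice(self):
        cfg = SimConfig(n_snvs=60, segment_cn_weights={2: 1.0}, seed=4)
        truth = simulate_genome(cfg)
        for s in truth.snvs:
            assert s.segment_cn == 2 and s.multiplicity in (1, 2)
            assert true_dna_af(s.multiplicity, s.segment_cn) in (0.5, 1.0)

    def test_requested_snv_count_honored(self):
        truth = simulate_genome(SimConfig(n_snvs=3023, seed=2))
        assert len(truth.snvs) == 3023

    def test_pure_sample_lattice_property(self):
        truth = simulate_genome(SimConfig(n_snvs=120, seed=9))
        allowed = {m / cn for cn in range(1, 6) for m in range(1, cn + 1)}
        for s in truth.snvs:
            assert true_dna_af(s.multiplicity, s.segment_cn) in allowed

    def test_mean_ploidy_is_length_weighted_cn(self):
        truth = simulate_genome(SimConfig(n_snvs=50, seed=3))
        total = sum(s.length for s in truth.segments)
        psi = sum(s.length * s.cn for s in truth.segments) / total
        assert truth.mean_ploidy == pytest.approx(psi)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_genome(SimConfig(frac_silent=1.4))
        with pytest.raises(ConfigurationError):
            simulate_genome(SimConfig(segment_cn_weights={2: 0.5, 3: 0.2}))
        with pytest.raises(ConfigurationError):
            simulate_genome(SimConfig(purity=0.0))

    def test_consequence_labels_verified_by_annotation(self):
        """The generator's consequence labels must be reproducible from the
        emitted transcript models and reference sequence."""
        truth = simulate_genome(SimConfig(n_snvs=80, seed=6))
        strands = set()
        for snv in truth.snvs:
            tx = truth.transcripts[snv.transcript_id]
            strands.add(tx.strand)
            assert classify(snv, tx, truth.reference).klass == snv.consequence
        assert strands == {"+", "-"}  # both orientations exercised


class TestSimulateCounts:
    def test_conservation_and_determinism(self):
        cfg = SimConfig(n_snvs=50, seed=5)
        truth = simulate_genome(cfg)
        c1, c2 = simulate_counts(truth), simulate_counts(truth)
        assert (c1["mutant_reads"] <= c1["total_reads"]).all()
        pd.testing.assert_frame_equal(c1, c2)

    def test_germline_has_no_mutant_reads_by_default(self):
        truth = simulate_genome(SimConfig(n_snvs=40, seed=8))
        counts = simulate_counts(truth)
        germ = counts[counts["sample"] == "germline"]
        assert (germ["mutant_reads"] == 0).all()

    def test_law_of_large_numbers_at_high_depth(self):
        """Empirical mutant fraction converges to the lattice value."""
        cfg = SimConfig(n_snvs=200, dna_depth_mean=10_000, seed=12)
        truth = simulate_genome(cfg)
        counts = simulate_counts(truth)
        dna = counts[(counts["sample"] == "tumor") & (counts["analyte"] == "DNA")]
        pooled = dna.groupby("snv_id")[["mutant_reads", "total_reads"]].sum()
        for snv in truth.snvs:
            p = true_dna_af(snv.multiplicity, snv.segment_cn)
            k = pooled.loc[snv.snv_id, "mutant_reads"]
            n = pooled.loc[snv.snv_id, "total_reads"]
            se = np.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(k / n - p) <= max(3 * se, 3 / n)

    def test_nmd_limits(self):
        # e=1: every mutant PTC transcript degraded -> zero mutant RNA reads
        assert expected_rna_fraction(0.5, 1.0, True) == 0.0
        # e=0: RNA fraction equals DNA fraction for all classes
        assert expected_rna_fraction(0.37, 0.0, True) == pytest.approx(0.37)
        cfg = SimConfig(
            n_snvs=150, nmd_efficiency=1.0, frac_ptc_not_last=0.5, frac_ptc_last=0.2,
            rna_depth_mean=300, rna_depth_sigma=0.2, seed=13,
        )
        truth = simulate_genome(cfg)
        counts = simulate_counts(truth)
        rna = counts[counts["analyte"] == "RNA"].groupby("snv_id")["mutant_reads"].sum()
        by_id = {s.snv_id: s for s in truth.snvs}
        for snv_id, k in rna.items():
            if by_id[snv_id].consequence == ConsequenceClass.PTC_NOT_LAST_EXON:
                assert k == 0

    def test_last_exon_ptc_keeps_dna_fraction(self):
        """NMD does not touch PTCs in the last exon: expected RNA fraction
        stays at the DNA lattice value."""
        assert expected_rna_fraction(0.5, 0.9, False) == 0.5


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    cfg = SimConfig(n_snvs=30, seed=21)
    truth = simulate_genome(cfg)
    counts = simulate_counts(truth)
    out = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(truth, counts, out)
    return truth, counts, paths


class TestFixtureIO:
    def test_counts_round_trip_exact(self, fixture_dir):
        truth, counts, paths = fixture_dir
        pd.testing.assert_frame_equal(read_counts(paths["counts"]), counts)

    def test_bed_round_trip(self, fixture_dir):
        truth, _, paths = fixture_dir
        assert read_segments_bed(paths["bed"]) == truth.segments

    def test_vcf_is_one_based_and_round_trips(self, fixture_dir):
        truth, _, paths = fixture_dir
        by_id = {s.snv_id: s for s in truth.snvs}
        with open(paths["vcf"]) as fh:
            data_lines = [l for l in fh if not l.startswith("#")]
        for line in data_lines:
            chrom, pos, vid = line.split("\t")[:3]
            assert int(pos) == by_id[vid].pos + 1
        back = read_vcf(paths["vcf"])
        assert [(s.snv_id, s.pos, s.ref_base, s.alt_base, s.segment_cn, s.multiplicity)
                for s in back] == [
            (s.snv_id, s.pos, s.ref_base, s.alt_base, s.segment_cn, s.multiplicity)
            for s in truth.snvs
        ]

    def test_byte_identical_across_runs(self, fixture_dir, tmp_path):
        truth, counts, paths = fixture_dir
        cfg = SimConfig(n_snvs=30, seed=21)
        truth2 = simulate_genome(cfg)
        counts2 = simulate_counts(truth2)
        paths2 = write_fixture(truth2, counts2, tmp_path)
        for key in paths:
            h1 = hashlib.sha256(Path(paths[key]).read_bytes()).hexdigest()
            h2 = hashlib.sha256(Path(paths2[key]).read_bytes()).hexdigest()
            assert h1 == h2, f"{key} differs between identically seeded runs"
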