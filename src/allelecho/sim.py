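"""Synthetic tumor genomes and replicate DNA/RNA read counts.

The generator emulates the statistical structure the downstream analysis
assumes: a genome partitioned into segments of integer copy number 1-5,
heterozygous-to-homozygous somatic SNVs whose true DNA allele fraction sits
on the discrete lattice m*rho / (CN*rho + 2*(1-rho)), replicate tumor and
germline DNA libraries plus replicate tumor RNA libraries with Poisson
depths and binomial mutant-read sampling, and nonsense-mediated decay (NMD)
that depletes the mutant transcript pool of SNVs creating a premature
termination codon (PTC) before the last exon.

Every gene carries a concrete transcript model (3 exons, ATG...stop CDS,
random strand) and a reference sequence, so consequence labels drawn by the
generator are verifiable by the annotation module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annot import TranscriptModel, write_transcript_table
from .core import (
    Analyte,
    ConfigurationError,
    ConsequenceClass,
    GenomeSegment,
    SampleSource,
    SnvRecord,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# codon rewritten at the mutated site, per consequence:
# (reference codon, offset of the mutated base, alternate base on the coding strand)
_TARGET_CODONS = {
    ConsequenceClass.SILENT: ("GGC", 2, "A"),  # Gly -> Gly
    ConsequenceClass.NONSYNONYMOUS: ("GAG", 1, "C"),  # Glu -> Ala
    ConsequenceClass.PTC_NOT_LAST_EXON: ("TGG", 2, "A"),  # Trp -> stop (TGA)
    ConsequenceClass.PTC_LAST_EXON: ("TGG", 2, "A"),
}

_UTR = 30  # nt of UTR on each side of the CDS
_GENE_PITCH = 1000  # genomic spacing between gene slots
_CHROM_MARGIN = 100

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if str(Seq(a + b + c).translate()) != "*"
    and a + b + c != "ATG"  # avoid internal starts looking special
]


@dataclass
class SimConfig:
    """Knobs of the synthetic study.

    Defaults describe a homogeneous (purity 1) tumor cell line sequenced in
    duplicate, with a genome rich in triploid-pentaploid segments and a
    small minority of PTC-causing SNVs, most of them NMD substrates.
    """

    n_segments: int = 20
    segment_cn_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.05, 2: 0.30, 3: 0.30, 4: 0.20, 5: 0.15}
    )
    n_snvs: int = 1000
    dna_depth_mean: float = 140.0
    rna_depth_mean: float = 60.0
    rna_depth_sigma: float = 1.0  # log-normal dispersion of expression levels
    n_replicates: int = 2
    purity: float = 1.0
    nmd_efficiency: float = 0.8
    frac_ptc_not_last: float = 0.02
    frac_ptc_last: float = 0.01
    frac_silent: float = 0.30
    germline_error_rate: float = 0.0
    depth_overdispersion: float = 0.0  # gamma-Poisson; 0 = pure Poisson
    cn_max: int = 5
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_ptc_not_last": self.frac_ptc_not_last,
            "frac_ptc_last": self.frac_ptc_last,
            "frac_silent": self.frac_silent,
            "nmd_efficiency": self.nmd_efficiency,
            "germline_error_rate": self.germline_error_rate,
        }
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.frac_ptc_not_last + self.frac_ptc_last + self.frac_silent > 1.0 + 1e-9:
            raise ConfigurationError("consequence fractions sum to more than 1")
        if not (0.0 < self.purity <= 1.0):
            raise ConfigurationError(f"purity must be in (0,1], got {self.purity}")
        if self.dna_depth_mean <= 0 or self.rna_depth_mean <= 0:
            raise ConfigurationError("depth means must be positive")
        if self.n_segments < 1 or self.n_snvs < 1 or self.n_replicates < 1:
            raise ConfigurationError("counts must be >= 1")
        w = self.segment_cn_weights
        if any(cn < 1 or cn > self.cn_max for cn in w):
            raise ConfigurationError(f"copy numbers must lie in 1..{self.cn_max}")
        if any(x < 0 for x in w.values()) or abs(sum(w.values()) - 1.0) > 1e-6:
            raise ConfigurationError("segment_cn_weights must be non-negative and sum to 1")


@dataclass
class SimTruth:
    """Ground truth of one simulated sample."""

    segments: list[GenomeSegment]
    snvs: list[SnvRecord]
    expression_level: dict[str, float]
    mean_ploidy: float
    reference: dict[str, str]
    transcripts: dict[str, TranscriptModel]
    config: SimConfig


def true_dna_af(multiplicity: int, cn: int, purity: float = 1.0) -> float:
    """Expected DNA mutation allele fraction for m mutant copies out of CN.

    With tumor purity rho, the contaminating normal cells contribute two
    wild-type copies each: AF = m*rho / (CN*rho + 2*(1-rho)). For a pure
    sample this is simply m/CN.
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity must be in (0,1], got {purity}")
    if not (1 <= multiplicity <= cn):
        raise ValueError(f"need 1 <= m <= CN, got m={multiplicity}, CN={cn}")
    return multiplicity * purity / (cn * purity + 2.0 * (1.0 - purity))


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def _build_gene(rng: np.random.Generator, consequence: ConsequenceClass):
    """Construct one 3-exon gene realizing ``consequence`` at a single SNV.

    Returns (mrna_chunks, intron_lens, strand, snv_mrna_pos, alt_mrna,
    cds_mrna_range). Chunks are 5'->3' mRNA pieces, one per exon.
    """
    n_codons = int(rng.integers(80, 161))
    codons = ["ATG"] + [
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)
    ] + ["TAA"]

    if consequence == ConsequenceClass.PTC_NOT_LAST_EXON:
        target_exon = int(rng.integers(0, 2))
    elif consequence == ConsequenceClass.PTC_LAST_EXON:
        target_exon = 2
    else:
        target_exon = int(rng.integers(0, 3))

    L = 2 * _UTR + 3 * n_codons
    for _ in range(200):
        cut1 = int(rng.integers(40, L - 80))
        cut2 = int(rng.integers(cut1 + 40, L - 40))
        bounds = [(0, cut1), (cut1, cut2), (cut2, L)]
        lo, hi = bounds[target_exon]
        # codons fully inside the target exon, excluding start and stop codons
        kmin = max(1, -(-(lo - _UTR) // 3))
        kmax = min(n_codons - 2, (hi - _UTR) // 3 - 1)
        if consequence != ConsequenceClass.NONCODING and kmin <= kmax:
            break
    else:  # pragma: no cover - essentially impossible with these margins
        raise RuntimeError("failed to place target codon")

    k = int(rng.integers(kmin, kmax + 1))
    codon, offset, alt = _TARGET_CODONS[consequence]
    codons[k] = codon

    mrna = (
        "".join(chr(c) for c in _random_seq(rng, _UTR).view(np.uint8))
        + "".join(codons)
        + "".join(chr(c) for c in _random_seq(rng, _UTR).view(np.uint8))
    )
    chunks = [mrna[s:e] for s, e in bounds]
    introns = [int(rng.integers(80, 151)) for _ in range(2)]
    strand = "+" if rng.random() < 0.5 else "-"
    snv_mrna_pos = _UTR + 3 * k + offset
    cds_range = (_UTR, _UTR + 3 * n_codons)
    return chunks, introns, strand, snv_mrna_pos, alt, cds_range


def _place_gene(chunks, introns, strand, g0):
    """Genomic exon intervals (ascending) and their sequences for a gene at g0."""
    lens = [len(c) for c in chunks]
    if strand == "+":
        order = [0, 1, 2]
        seqs = chunks
    else:  # transcript 5' end at the high-coordinate side
        order = [2, 1, 0]
        seqs = [_revcomp(chunks[i]) for i in order]
    exon_lens = [lens[i] for i in order]
    intr = introns if strand == "+" else introns[::-1]
    starts = [g0, g0 + exon_lens[0] + intr[0]]
    starts.append(starts[1] + exon_lens[1] + intr[1])
    intervals = [(s, s + l) for s, l in zip(starts, exon_lens)]
    return intervals, seqs, order


def _map_mrna_to_genomic(mrna_pos, chunks, intervals, order, strand):
    """Map an mRNA coordinate to its genomic position."""
    cum = 0
    for j, chunk in enumerate(chunks):
        if mrna_pos < cum + len(chunk):
            off = mrna_pos - cum
            gi = order.index(j)
            s, e = intervals[gi]
            return s + off if strand == "+" else e - 1 - off
        cum += len(chunk)
    raise ValueError(f"mRNA position {mrna_pos} outside transcript")


def simulate_genome(config: SimConfig) -> SimTruth:
    """Draw segments, genes and SNVs. Deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    cns = sorted(config.segment_cn_weights)
    weights = np.array([config.segment_cn_weights[c] for c in cns], dtype=float)
    seg_cn = rng.choice(cns, size=config.n_segments, p=weights / weights.sum())

    snv_segment = rng.integers(0, config.n_segments, size=config.n_snvs)
    p_ns = max(
        0.0, 1.0 - config.frac_silent - config.frac_ptc_not_last - config.frac_ptc_last
    )
    csq_classes = [
        ConsequenceClass.SILENT,
        ConsequenceClass.NONSYNONYMOUS,
        ConsequenceClass.PTC_NOT_LAST_EXON,
        ConsequenceClass.PTC_LAST_EXON,
    ]
    probs = np.array(
        [config.frac_silent, p_ns, config.frac_ptc_not_last, config.frac_ptc_last]
    )
    csq_draw = rng.choice(len(csq_classes), size=config.n_snvs, p=probs / probs.sum())

    genes_per_seg = np.bincount(snv_segment, minlength=config.n_segments)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_segments)]
    chrom_len = {
        chrom_names[i]: max(1, int(genes_per_seg[i])) * _GENE_PITCH + 2 * _CHROM_MARGIN
        for i in range(config.n_segments)
    }
    chrom_seq = {c: _random_seq(rng, n).copy() for c, n in chrom_len.items()}

    slot_counter = dict.fromkeys(chrom_names, 0)
    snvs: list[SnvRecord] = []
    transcripts: dict[str, TranscriptModel] = {}
    for i in range(config.n_snvs):
        seg_i = int(snv_segment[i])
        chrom = chrom_names[seg_i]
        cn = int(seg_cn[seg_i])
        m = int(rng.integers(1, cn + 1))
        csq = csq_classes[csq_draw[i]]

        chunks, introns, strand, snv_mrna, alt_mrna, cds_range = _build_gene(rng, csq)
        g0 = _CHROM_MARGIN + slot_counter[chrom] * _GENE_PITCH
        slot_counter[chrom] += 1
        intervals, seqs, order = _place_gene(chunks, introns, strand, g0)
        arr = chrom_seq[chrom]
        for (s, e), seq in zip(intervals, seqs):
            arr[s:e] = np.frombuffer(seq.encode(), dtype="S1")

        pos = _map_mrna_to_genomic(snv_mrna, chunks, intervals, order, strand)
        cds_g = sorted(
            (
                _map_mrna_to_genomic(cds_range[0], chunks, intervals, order, strand),
                _map_mrna_to_genomic(cds_range[1] - 1, chunks, intervals, order, strand),
            )
        )
        gene_id = f"gene{i + 1:05d}"
        tx_id = f"tx{i + 1:05d}"
        transcripts[tx_id] = TranscriptModel(
            transcript_id=tx_id,
            chrom=chrom,
            strand=strand,
            exons=intervals,
            cds_start=cds_g[0],
            cds_end=cds_g[1] + 1,
        )
        ref_base = arr[pos].tobytes().decode()
        alt_base = alt_mrna if strand == "+" else _COMPLEMENT[alt_mrna]
        snvs.append(
            SnvRecord(
                snv_id=f"snv{i + 1:05d}",
                chrom=chrom,
                pos=int(pos),
                ref_base=ref_base,
                alt_base=alt_base,
                gene_id=gene_id,
                transcript_id=tx_id,
                segment_cn=cn,
                multiplicity=m,
                consequence=csq,
            )
        )

    segments = [
        GenomeSegment(chrom_names[i], 0, chrom_len[chrom_names[i]], int(seg_cn[i]))
        for i in range(config.n_segments)
    ]
    total_len = sum(s.length for s in segments)
    psi = sum(s.length * s.cn for s in segments) / total_len

    expr = rng.lognormal(mean=0.0, sigma=config.rna_depth_sigma, size=config.n_snvs)
    expression = {snvs[i].gene_id: float(expr[i]) for i in range(config.n_snvs)}

    reference = {c: chrom_seq[c].tobytes().decode() for c in chrom_names}
    return SimTruth(
        segments=segments,
        snvs=snvs,
        expression_level=expression,
        mean_ploidy=psi,
        reference=reference,
        transcripts=transcripts,
        config=config,
    )


def expected_rna_fraction(p_dna: float, nmd_efficiency: float, is_nmd_target: bool) -> float:
    """Mutant allele fraction in RNA after NMD depletes the mutant pool.

    A fraction e of mutant transcripts is degraded, so the expected RNA
    mutant fraction is (1-e)p / ((1-e)p + (1-p)); non-targets keep p.
    """
    if not is_nmd_target:
        return p_dna
    kept = (1.0 - nmd_efficiency) * p_dna
    denom = kept + (1.0 - p_dna)
    return kept / denom if denom > 0 else 0.0


def _draw_depth(rng: np.random.Generator, rate: float, overdispersion: float) -> int:
    if rate <= 0:
        return 0
    if overdispersion > 0:
        rate = rate * rng.gamma(1.0 / overdispersion, overdispersion)
    return int(rng.poisson(rate))


def simulate_counts(truth: SimTruth, config: SimConfig | None = None) -> pd.DataFrame:
    """Replicate read counts for every SNV: tumor DNA, germline DNA, tumor RNA.

    Germline is diploid everywhere with (by default) zero mutant reads; tumor
    DNA depth scales with the locus copy content relative to the mean ploidy
    (library-size normalization, so equal total sequencing per sample); RNA
    depth follows the gene's expression level, shrunk by the NMD loss for
    PTC-before-last-exon SNVs. Deterministic given the config seed.
    """
    cfg = config or truth.config
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 1])
    rho = cfg.purity
    psi_eff = rho * truth.mean_ploidy + 2.0 * (1.0 - rho)
    expr_norm = float(np.exp(cfg.rna_depth_sigma**2 / 2.0))

    rows = []
    for snv in truth.snvs:
        p = true_dna_af(snv.multiplicity, snv.segment_cn, rho)
        is_nmd = snv.consequence == ConsequenceClass.PTC_NOT_LAST_EXON
        q = expected_rna_fraction(p, cfg.nmd_efficiency, is_nmd)
        pool = ((1.0 - cfg.nmd_efficiency) * p + (1.0 - p)) if is_nmd else 1.0
        tumor_rate = cfg.dna_depth_mean * (rho * snv.segment_cn + 2.0 * (1.0 - rho)) / psi_eff
        rna_rate = cfg.rna_depth_mean * truth.expression_level[snv.gene_id] / expr_norm * pool

        for rep in range(cfg.n_replicates):
            n_t = _draw_depth(rng, tumor_rate, cfg.depth_overdispersion)
            k_t = int(rng.binomial(n_t, p)) if n_t else 0
            rows.append((snv.snv_id, "tumor", "DNA", rep, k_t, n_t))
        for rep in range(cfg.n_replicates):
            n_g = _draw_depth(rng, cfg.dna_depth_mean, cfg.depth_overdispersion)
            k_g = int(rng.binomial(n_g, cfg.germline_error_rate)) if n_g else 0
            rows.append((snv.snv_id, "germline", "DNA", rep, k_g, n_g))
        for rep in range(cfg.n_replicates):
            n_r = _draw_depth(rng, rna_rate, cfg.depth_overdispersion)
            k_r = int(rng.binomial(n_r, q)) if n_r else 0
            rows.append((snv.snv_id, "tumor", "RNA", rep, k_r, n_r))

    return pd.DataFrame(
        rows,
        columns=["snv_id", "sample", "analyte", "replicate", "mutant_reads", "total_reads"],
    )


# --- fixture I/O ----------------------------------------------------------

COUNTS_COLUMNS = ["snv_id", "sample", "analyte", "replicate", "mutant_reads", "total_reads"]


def write_fixture(truth: SimTruth, counts: pd.DataFrame, out_dir) -> dict[str, Path]:
    """Serialize a simulated study to standard file formats.

    Emits mutations.vcf (1-based), segments.bed (0-based half-open, 4th
    column CN), counts.tsv, transcripts.tsv, ref.fa and truth.json. Output
    is byte-identical for identical inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "mutations.vcf",
        "bed": out / "segments.bed",
        "counts": out / "counts.tsv",
        "transcripts": out / "transcripts.tsv",
        "fasta": out / "ref.fa",
        "truth": out / "truth.json",
    }

    header = pysam.VariantHeader()
    for seg in truth.segments:
        header.contigs.add(seg.chrom, length=len(truth.reference[seg.chrom]))
    header.info.add("GENE", 1, "String", "Gene identifier")
    header.info.add("TX", 1, "String", "Transcript identifier")
    header.info.add("CN", 1, "Integer", "True segment copy number")
    header.info.add("M", 1, "Integer", "True mutant multiplicity")
    header.info.add("CSQ", 1, "String", "True consequence class")
    with pysam.VariantFile(str(paths["vcf"]), "w", header=header) as vcf:
        for snv in truth.snvs:
            rec = vcf.new_record(
                contig=snv.chrom,
                start=snv.pos,
                stop=snv.pos + 1,
                alleles=(snv.ref_base, snv.alt_base),
                id=snv.snv_id,
            )
            rec.info["GENE"] = snv.gene_id
            rec.info["TX"] = snv.transcript_id
            rec.info["CN"] = snv.segment_cn
            rec.info["M"] = snv.multiplicity
            rec.info["CSQ"] = snv.consequence.value
            vcf.write(rec)

    with open(paths["bed"], "w") as fh:
        for seg in truth.segments:
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.cn}\n")

    counts.to_csv(paths["counts"], sep="\t", index=False)
    write_transcript_table(list(truth.transcripts.values()), paths["transcripts"])

    records = [
        SeqRecord(Seq(truth.reference[c]), id=c, description="")
        for c in sorted(truth.reference, key=lambda x: int(x.replace("chr", "")))
    ]
    SeqIO.write(records, str(paths["fasta"]), "fasta")

    truth_doc = {
        "mean_ploidy": truth.mean_ploidy,
        "purity": truth.config.purity,
        "config": asdict(truth.config),
        "snvs": [
            {
                "snv_id": s.snv_id,
                "gene_id": s.gene_id,
                "transcript_id": s.transcript_id,
                "cn": s.segment_cn,
                "m": s.multiplicity,
                "consequence": s.consequence.value,
                "true_dna_af": true_dna_af(s.multiplicity, s.segment_cn, truth.config.purity),
                "expression_level": truth.expression_level[s.gene_id],
            }
            for s in truth.snvs
        ],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    return df


def read_segments_bed(path) -> list[GenomeSegment]:
    segs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, cn = line.split()[:4]
            segs.append(GenomeSegment(chrom, int(start), int(end), int(cn)))
    return segs


def read_vcf(path) -> list[SnvRecord]:
    """Load SNV records (with truth INFO keys when present) from a VCF."""
    snvs = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info: Mapping = rec.info
            snvs.append(
                SnvRecord(
                    snv_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    chrom=rec.chrom,
                    pos=rec.start,
                    ref_base=rec.ref,
                    alt_base=rec.alts[0],
                    gene_id=str(info.get("GENE", "")),
                    transcript_id=str(info.get("TX", "")),
                    segment_cn=int(info.get("CN", 1)),
                    multiplicity=int(info.get("M", 1)),
                    consequence=ConsequenceClass(info.get("CSQ", "nonsynonymous")),
                )
            )
    return snvs
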