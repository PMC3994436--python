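"""Coding-consequence annotation of SNVs against transcript models.

An SNV is classified as silent, nonsynonymous, or stop-gained; stop-gained
calls are split by whether the premature termination codon (PTC) lies in the
transcript's last exon, which is the decision the nonsense-mediated decay
(NMD) machinery makes: a PTC upstream of the last exon marks the transcript
for degradation, a PTC in the last exon escapes surveillance.

The default NMD rule is pure exon membership. The classical refinement —
that a PTC within ~50 nt of the final exon-exon junction also escapes —
is available via ``nmd_rule="50nt"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .core import AnnotationError, ConsequenceClass, SnvRecord

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
START_CODON = "ATG"


@dataclass
class TranscriptModel:
    """One transcript: ordered exons, CDS boundaries, strand.

    ``exons`` are genomic intervals in ascending genomic order regardless of
    strand; ``cds_start``/``cds_end`` are genomic (0-based half-open) bounds
    of the coding region. Exon indices reported by :func:`classify` are in
    transcript (5'->3') orientation.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.transcript_id}: strand must be + or -")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
        if not any(s < self.cds_end and e > self.cds_start for s, e in self.exons):
            raise AnnotationError(f"{self.transcript_id}: CDS outside exons")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def cds_genomic_positions(self) -> list[int]:
        """Genomic positions of CDS bases in transcript (5'->3') order."""
        pos = [
            p
            for s, e in self.exons
            for p in range(max(s, self.cds_start), min(e, self.cds_end))
        ]
        return pos[::-1] if self.strand == "-" else pos

    def exon_index_of(self, pos: int) -> int | None:
        """Exon index in transcript orientation containing ``pos``, or None."""
        for i, (s, e) in enumerate(self.exons):
            if s <= pos < e:
                return i if self.strand == "+" else self.n_exons - 1 - i
        return None


@dataclass
class Consequence:
    """Classified effect of one SNV on one transcript."""

    klass: ConsequenceClass
    codon_ref: str = ""
    codon_alt: str = ""
    aa_ref: str = ""
    aa_alt: str = ""
    exon_index: int = -1
    n_exons: int = 0
    flags: list[str] = field(default_factory=list)


def _fetch(reference: Mapping[str, object], chrom: str, start: int, end: int) -> str:
    """Slice bases from a dict of strings or a pyfaidx.Fasta alike."""
    seq = reference[chrom][start:end]
    return str(seq).upper()


def _translate(codon: str) -> str:
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise AnnotationError(f"non-ACGT codon {codon!r}")
    return str(Seq(codon).translate())


def classify(
    snv: SnvRecord,
    tx: TranscriptModel,
    reference: Mapping[str, object],
    nmd_rule: str = "last_exon",
    nmd_boundary_nt: int = 50,
) -> Consequence:
    """Classify an SNV's coding consequence against one transcript.

    The genomic position is mapped into the CDS reading frame (strand-aware),
    the reference and alternate codons are translated with the standard
    genetic code, and stop-gained calls are split into PTC-in-last-exon
    versus PTC-before-last-exon. Positions inside the transcript span but
    outside the CDS are ``noncoding``.

    Raises :class:`AnnotationError` if the reference base does not match the
    SNV's ref allele, the CDS frame is inconsistent, or a non-ACGT base is
    encountered.
    """
    span = tx.span
    if not (span[0] <= snv.pos < span[1]):
        raise AnnotationError(
            f"{snv.snv_id} at {snv.chrom}:{snv.pos} outside transcript "
            f"{tx.transcript_id} span {span}"
        )
    ref_base = _fetch(reference, snv.chrom, snv.pos, snv.pos + 1)
    if ref_base != snv.ref_base.upper():
        raise AnnotationError(
            f"{snv.snv_id}: reference has {ref_base} at {snv.chrom}:{snv.pos}, "
            f"record says {snv.ref_base}"
        )

    cds_pos = tx.cds_genomic_positions()
    if len(cds_pos) % 3 != 0:
        raise AnnotationError(
            f"{tx.transcript_id}: CDS length {len(cds_pos)} not divisible by 3"
        )
    index_of = {p: i for i, p in enumerate(cds_pos)}
    exon_index = tx.exon_index_of(snv.pos)

    if snv.pos not in index_of:
        return Consequence(
            ConsequenceClass.NONCODING,
            exon_index=-1 if exon_index is None else exon_index,
            n_exons=tx.n_exons,
        )
    if exon_index is None:  # CDS base must lie in an exon
        raise AnnotationError(f"{tx.transcript_id}: CDS position outside exons")

    idx = index_of[snv.pos]
    codon_i, offset = divmod(idx, 3)
    codon_positions = cds_pos[3 * codon_i : 3 * codon_i + 3]
    bases = [_fetch(reference, snv.chrom, p, p + 1) for p in codon_positions]
    if tx.strand == "-":
        bases = [_COMPLEMENT[b] for b in bases]
        alt_cds = _COMPLEMENT[snv.alt_base.upper()]
    else:
        alt_cds = snv.alt_base.upper()
    codon_ref = "".join(bases)
    codon_alt = codon_ref[:offset] + alt_cds + codon_ref[offset + 1 :]

    if codon_i == 0 and codon_ref != START_CODON:
        raise AnnotationError(
            f"{tx.transcript_id}: CDS does not begin with {START_CODON} "
            f"(found {codon_ref})"
        )

    aa_ref, aa_alt = _translate(codon_ref), _translate(codon_alt)
    flags: list[str] = []

    if aa_alt == "*" and aa_ref != "*":
        klass = _ptc_class(tx, cds_pos, codon_i, exon_index, nmd_rule, nmd_boundary_nt)
    elif aa_ref == aa_alt:
        klass = ConsequenceClass.SILENT
    else:
        klass = ConsequenceClass.NONSYNONYMOUS
        if aa_ref == "*":
            flags.append("stop_lost")
        if codon_i == 0:
            flags.append("start_codon")

    return Consequence(
        klass,
        codon_ref=codon_ref,
        codon_alt=codon_alt,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
        exon_index=exon_index,
        n_exons=tx.n_exons,
        flags=flags,
    )


def _ptc_class(
    tx: TranscriptModel,
    cds_pos: list[int],
    codon_i: int,
    exon_index: int,
    nmd_rule: str,
    boundary_nt: int,
) -> ConsequenceClass:
    """NMD-triggering vs escaping PTC under the chosen rule."""
    in_last = exon_index == tx.n_exons - 1
    if nmd_rule == "last_exon" or tx.n_exons == 1:
        return (
            ConsequenceClass.PTC_LAST_EXON if in_last else ConsequenceClass.PTC_NOT_LAST_EXON
        )
    if nmd_rule != "50nt":
        raise ValueError(f"unknown NMD rule {nmd_rule!r}")
    if in_last:
        return ConsequenceClass.PTC_LAST_EXON
    # distance in CDS bases from the new stop to the final exon-exon junction
    last_exon = tx.exons[-1] if tx.strand == "+" else tx.exons[0]
    last_len = sum(
        1
        for s, e in [last_exon]
        for _ in range(max(s, tx.cds_start), min(e, tx.cds_end))
    )
    junction_idx = len(cds_pos) - last_len  # CDS index of first last-exon base
    dist = junction_idx - (3 * codon_i)
    escapes = dist <= boundary_nt
    return ConsequenceClass.PTC_LAST_EXON if escapes else ConsequenceClass.PTC_NOT_LAST_EXON


# --- stratification -------------------------------------------------------

PTC_GROUPS = ("no_PTC", "PTC_not_last_exon", "PTC_last_exon")


def strata(consequences: Sequence[ConsequenceClass | str]) -> pd.DataFrame:
    """Partition classified SNVs into the groups used by the imbalance analysis.

    Returns a DataFrame with two orthogonal labelings: ``ptc_group`` in
    {no_PTC, PTC_not_last_exon, PTC_last_exon} and ``coding_group`` in
    {silent, nonsynonymous, other}.
    """
    classes = [ConsequenceClass(c) for c in consequences]
    ptc = [
        c.value
        if c in (ConsequenceClass.PTC_NOT_LAST_EXON, ConsequenceClass.PTC_LAST_EXON)
        else "no_PTC"
        for c in classes
    ]
    coding = [
        c.value
        if c in (ConsequenceClass.SILENT, ConsequenceClass.NONSYNONYMOUS)
        else "other"
        for c in classes
    ]
    return pd.DataFrame(
        {"consequence": [c.value for c in classes], "ptc_group": ptc, "coding_group": coding}
    )


# --- transcripts.tsv round trip -------------------------------------------

TRANSCRIPT_COLUMNS = [
    "transcript_id",
    "chrom",
    "strand",
    "exon_index",
    "exon_start",
    "exon_end",
    "cds_start",
    "cds_end",
]


def write_transcript_table(transcripts: Sequence[TranscriptModel], path) -> None:
    rows = []
    for tx in transcripts:
        exons = tx.exons if tx.strand == "+" else tx.exons[::-1]
        for i, (s, e) in enumerate(exons):
            rows.append(
                dict(
                    transcript_id=tx.transcript_id,
                    chrom=tx.chrom,
                    strand=tx.strand,
                    exon_index=i,
                    exon_start=s,
                    exon_end=e,
                    cds_start=tx.cds_start,
                    cds_end=tx.cds_end,
                )
            )
    pd.DataFrame(rows, columns=TRANSCRIPT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_transcript_table(path) -> dict[str, TranscriptModel]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, TranscriptModel] = {}
    for tx_id, grp in df.groupby("transcript_id", sort=False):
        first = grp.iloc[0]
        out[str(tx_id)] = TranscriptModel(
            transcript_id=str(tx_id),
            chrom=str(first["chrom"]),
            strand=str(first["strand"]),
            exons=[(int(r.exon_start), int(r.exon_end)) for r in grp.itertuples()],
            cds_start=int(first["cds_start"]),
            cds_end=int(first["cds_end"]),
        )
    return out
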