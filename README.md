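# allelecho

Are somatic point mutations transcribed in proportion to their DNA allele
frequency? `allelecho` is a small analysis pipeline for answering that
question from paired tumor exome and transcriptome read counts: it infers
absolute copy number and mutant multiplicity from the discrete
allele-fraction lattice, estimates DNA and RNA mutation allele fractions
with replicate weighting, annotates premature-termination-codon (PTC)
consequences, and quantifies RNA−DNA allele imbalance — including the
nonsense-mediated decay (NMD) signature, where transcripts carrying a PTC
before their last exon are selectively degraded.

It ships with a first-class synthetic-data generator that emulates
replicate sequencing of a homogeneous tumor cell line over a genome with
large copy-number variations, so the whole analysis is testable end to end
without access to sequencing data.

## The model

A heterozygous single-nucleotide variant (SNV) in a region of absolute
copy number CN, present on m of the CN allelic copies, has a DNA mutation
allele fraction that can only take the discrete lattice values

    f(CN, m) = m·ρ / (CN·ρ + 2·(1 − ρ)),      1 ≤ m ≤ CN,

where ρ is the tumor purity (ρ = 1 for a clean cell line, giving f = m/CN:
50 or 100% in diploid regions; 33, 66 or 100% in triploid regions; 25, 50,
75 or 100% in tetraploid regions). Independently, the tumor:germline depth
ratio r at the locus is proportional to its copy content,
E[r] = (ρ·CN + 2(1 − ρ))/c, with one free scale c per sample. `allelecho`
grid-searches (ρ, c) and assigns each SNV the (CN, m) lattice point
maximizing the binomial log-likelihood of its mutant read count plus a
Gaussian log-likelihood of its log depth ratio.

Allele fractions are estimated per replicate as k/n (mutant over total
reads) and combined by inverse-variance weighting with binomial standard
errors, so replicates with more reads count more. An SNV enters the
analysis only with ≥ 10 DNA and ≥ 10 RNA reads (pooled over replicates)
and a germline deep enough to have excluded a germline variant
(0.5^n_germline < α).

The imbalance score of an SNV is I = 100·(p_RNA − p_DNA) percentage
points. If transcription simply mirrors DNA dosage, I is centred at zero
for every consequence class; NMD drives I negative specifically for
PTC-before-last-exon mutations, since the expected RNA mutant fraction
becomes (1−e)p / ((1−e)p + 1−p) when a fraction e of mutant transcripts
is degraded.

## Worked example

The bundled single-locus example is a highly expressed gene carrying a
heterozygous T>G mutation, sequenced in duplicate: germline depths 141 and
133 with no mutant reads, tumor depths 248 and 247 with mutant fractions
35% and 36%.

```python
from allelecho import AlleleCounts, SampleModel
from allelecho.allelefrac import allele_fraction, combine_replicates
from allelecho.cnfit import assign_cn, coverage_ratio

tumor = [AlleleCounts(87, 248), AlleleCounts(89, 247)]
germ  = [AlleleCounts(0, 141), AlleleCounts(0, 133)]

ratio = coverage_ratio(tumor, germ)                      # 1.807
combined = combine_replicates([allele_fraction(c) for c in tumor])
print(round(combined.p, 4))                              # 0.3555
pooled = allele_fraction(AlleleCounts(176, 495))
fit = assign_cn(pooled, ratio, SampleModel(purity=1.0, psi=2.0, coverage_scale=2.0),
                germline_total=274)
print(fit.cn, fit.m)                                     # 3 1
```

A pooled mutant fraction of 35.5% sits on the triploid lattice point 1/3:
the locus has three copies, with the mutation on one allele and the
wild type on two.

## Full pipeline on synthetic data

```bash
allelecho run --seed 1 --out demo
```

runs simulate → allele fractions → copy number → annotation → imbalance
on the default synthetic study (1000 SNVs over 20 segments of copy number
1–5, duplicate DNA and RNA libraries, NMD efficiency 0.8) and writes
`demo/summary.json`. With seed 1 the summary reports, among others:

| quantity | value | meaning |
|---|---|---|
| `n_snvs` | 964 | SNVs passing the coverage + germline filters |
| `expressed_fraction` | 0.999 | SNVs with ≥ 1 mutant RNA read |
| `r2_all` | 0.949 | Pearson r² of DNA vs RNA allele fractions |
| `rho`, `psi` | 1.0, 2.88 | recovered purity and mean ploidy |
| PTC-not-last mean I | −25.6 (n = 15) | NMD depletes these mutant transcripts |
| PTC-last mean I | +0.1 (n = 11) | last-exon PTCs escape NMD |
| p (no-PTC vs PTC-not-last) | 1.4e−59 | two-sample t-test |
| p (no-PTC vs PTC-last) | 0.98 | no effect |
| sd(I), RNA ≥ 65 / < 15 reads | 5.0 / 13.8 | binomial noise shrinks with coverage |

Mutations are transcribed at their DNA allele frequency; the one genuine
biological exception the analysis is designed to expose — NMD of
PTC-before-last-exon transcripts — shows up exactly where it should.

Each stage is also available separately (`allelecho simulate / af / cn /
annot / imbalance`); see `allelecho --help`.

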