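# Methods

## Problem setting

Given a tumor sample sequenced at the DNA (exome) and RNA (transcriptome)
level in replicate, together with a matched germline DNA sample, the
pipeline asks for every somatic single-nucleotide variant (SNV): what
fraction of DNA copies carry the mutant base, and is the mutant allele
transcribed in that same proportion? Deviations between the RNA and DNA
mutation allele fractions indicate allele-selective transcription or
degradation; the one mechanism modelled explicitly is nonsense-mediated
decay (NMD) of transcripts with a premature termination codon (PTC)
upstream of the last exon.

## Statistical model

**Allele-fraction lattice.** An SNV on m of CN allelic copies in a sample
of purity ρ has expected DNA allele fraction
f(CN, m) = m·ρ/(CN·ρ + 2(1−ρ)); the 2(1−ρ) term is the wild-type
contribution of contaminating diploid normal cells. Observed mutant read
counts are treated as binomial(n, f).

**Coverage ratio.** Under library-size normalization (equal total
sequencing per sample), the tumor:germline depth ratio at a locus is
proportional to its copy content: E[r] = (ρ·CN + 2(1−ρ))/c. The scale c
absorbs the tumor mean ploidy and any residual library-size difference
and is shared by all loci. The log ratio is modelled as Gaussian around
log of that expectation with delta-method variance
1/n_tumor + 1/n_germline.

**Joint fit.** `cnfit.fit_sample_model` grid-searches
ρ ∈ {0.10, 0.15, …, 1.00} and 41 values of c (parameterized so the
median-ratio locus spans copy content 1…cn_max); for each candidate every
SNV is assigned its best lattice point and the per-SNV maxima are summed.
The binomial and coverage terms get equal weight by default
(`coverage_weight`, exposed because no principled relative weight exists
a priori). The purity grid is scanned from high to low so exact
likelihood ties resolve toward the purest explanation; within one SNV,
exact lattice ties resolve toward smaller CN, then smaller m (parsimony —
relevant when the coverage term is disabled and e.g. 1/2 = 2/4).
ψ is reported as the SNV-weighted mean of fitted copy numbers (the
simulator's ground-truth ψ is length-weighted over segments; the two
coincide when SNVs are spread evenly). Identifiability caveats are
surfaced as flags: `rho_unidentifiable` (multiple purity values reach the
maximum, e.g. an all-diploid genome), `degenerate_input`, `few_snvs`.

For a single locus no sample scale can be fitted; the worked example in
the README therefore reads the coverage ratio against a diploid germline
with c = 2. There the allele-fraction term dominates: a pooled fraction
of 0.356 at depth 495 singles out the lattice point 1/3, which exists
only as (CN 3, m 1) for CN ≤ 5 in a pure sample.

**Replicate combination.** Per replicate, p̂ = k/n with standard error
sqrt(p̃(1−p̃)/ñ), using the +2/+4 stabilization p̃ = (k+2)/(n+4),
ñ = n+4 so that k = 0 and k = n retain finite weight. Replicates combine
by inverse-variance weighting, w_i = 1/se_i²; combined se = (Σw_i)^−1/2.
The weighted mean tracks the pooled-count ratio k_Σ/n_Σ closely, but not
identically: when duplicates disagree by several binomial SEs, the
replicate with the less extreme fraction carries slightly less weight, so
the two estimates can differ by more than one percentage point on rare
loci. Copy-number fitting therefore consumes pooled counts (the binomial
likelihood needs integer k, n); the weighted estimates are what the
imbalance analysis reports.

**Filters.** An SNV is analyzed when pooled DNA ≥ 10 and pooled RNA ≥ 10
reads overlap it ("at least ten" is inclusive; the cutoff is applied to
pooled replicate totals, one consistent reading of a per-position
criterion). The germline binomial filter protects against tumor-only
coverage artifacts: a locus is kept only if (i) a heterozygous germline
variant would almost surely have been seen, 0.5^n_germline < α, and
(ii) observed germline mutant reads are consistent with the sequencing
error rate (one-sided exact binomial test vs ε). Defaults α = 0.05,
ε = 10⁻³, both configurable; with α = 0.05 criterion (i) requires at
least 5 germline reads (0.5⁴ = 0.0625, 0.5⁵ = 0.03125).

**Consequence annotation.** Genomic positions are mapped into the CDS
reading frame strand-awarely (codons may straddle exon junctions); ref
and alt codons are translated with the standard genetic code. Stop-gained
calls are split by NMD rule. The default rule is pure exon membership —
PTC before the last exon triggers decay, PTC in the last exon escapes.
The classical refinement (a PTC within 50 nt of the final exon–exon
junction also escapes) is available via `nmd_rule="50nt"`; it is off by
default because exon membership is the decision rule the analysis is
built around. Mutations destroying the reference stop or start codon are
classified nonsynonymous with a `stop_lost`/`start_codon` flag.

**Imbalance statistics.** I = 100·(p_RNA − p_DNA) percentage points.
Group location differences use the classic pooled-variance two-sample
t-test (Welch via `equal_var=False`); correlations are squared Pearson
coefficients. No multiple-testing correction is applied (a handful of
planned contrasts, reported raw). SNVs are stratified by RNA coverage
(≥ 65 vs < 15 reads by default) and |I| > 25 is flagged as an outlier;
all three thresholds are configuration, not code.

## The synthetic-data generator

`sim` emulates replicate exome + transcriptome sequencing of a
homogeneous tumor cell line against an inbred-strain germline:

- **Genome**: `n_segments` = 20 segments (one per chromosome), copy
  number drawn from weights {1: 0.05, 2: 0.30, 3: 0.30, 4: 0.20,
  5: 0.15} — a genome rich in triploid/tetraploid/pentaploid regions,
  CN capped at 5. Germline is diploid everywhere.
- **SNVs**: `n_snvs` = 1000, each in its own gene; multiplicity m uniform
  on 1..CN. Consequences: 30% silent, 2% PTC-not-last-exon, 1% PTC-last-
  exon, remainder nonsynonymous — matching the minority status of PTC
  mutations in real mutation sets.
- **Genes**: every SNV gets a concrete 3-exon transcript (random strand,
  80–160 codons, ATG…stop CDS, 30 nt UTRs, codons allowed to straddle
  junctions) whose sequence realizes the drawn consequence, so the
  annotation module can verify every label. This is a real, testable
  contract, not a convention.
- **Depths**: Poisson. Germline DNA at `dna_depth_mean` = 140 per
  replicate; tumor DNA scaled by (ρ·CN + 2(1−ρ))/ψ_eff (library-size
  normalization); RNA proportional to a per-gene log-normal expression
  level (σ = 1.0, mean-normalized) times `rna_depth_mean` = 60. Optional
  gamma-Poisson over-dispersion, off by default. Defaults mirror the
  worked example's scale (germline ≈ 140 reads/locus) and a transcriptome
  with a realistic spread of coverage; two replicates per library.
- **Reads**: mutant DNA reads ~ binomial(depth, f(CN, m, ρ)); germline
  mutant reads ~ binomial(depth, ε) with ε = 0 by default (inbred
  germline), configurable for filter testing. For NMD targets the mutant
  transcript pool is multiplied by (1 − e), e = `nmd_efficiency` = 0.8 by
  default, giving expected RNA fraction (1−e)p/((1−e)p + 1−p) and a
  correspondingly shrunken RNA depth. Homozygous PTC mutations (m = CN)
  keep fraction 1 while losing depth — NMD changes their expression, not
  their allele fraction, so they contribute no imbalance signal, which is
  biologically correct.
- **Determinism**: one `numpy` generator seeded from `(seed, 0)` for the
  genome and `(seed, 1)` for counts; identical config + seed reproduces
  byte-identical fixture files (VCF/BED/TSV/FASTA/JSON).

What the generator does *not* emulate — and hence what green tests do not
establish about real data: alignment and mapping bias against
mismatch-carrying reads (a major practical concern for RNA allele
fractions), base-quality error structure, subclonality, indels, splice
isoform diversity, GC/capture bias, segment boundaries within genes, and
correlation of expression with copy number. Conclusions from the package
on real data inherit all of those caveats.

## Problem sizes and test design

The built-in analyses run at desk scale: parameter recovery uses 500 SNVs
at mean depth 100 (CN accuracy ≥ 95%, multiplicity ≥ 90% against ground
truth); the direction-of-effect fixtures use 1000 SNVs with deep RNA
(mean 200, σ = 0.5) so that binomial noise does not mask the NMD
contrast; depth-monotonicity of assignment accuracy is averaged over
three seeds at depths 20/50/200. Genome-scale mutation counts are
supported (the generator comfortably produces thousands of SNVs) but add
nothing to the properties under test.

## Numerical choices and degenerate inputs

- Binomial log-likelihoods use `xlogy`, so lattice fractions of exactly
  1 are handled without special-casing (k = n gives 0, k < n gives −∞).
- Zero-coverage replicates are excluded before estimation; an SNV with no
  usable replicates gets NaN estimates and fails the filters.
- `coverage_ratio` refuses division by a zero germline total — such loci
  belong to the germline filter, not the copy-number fit.
- Empty strata are reported with n = 0 and an `empty` flag rather than
  raised, so partial datasets still produce a summary.
- Zero-variance correlation inputs yield NaN with a warning.

## Known limitations

- Purity is estimated on a 0.05 grid; sub-grid precision would require a
  continuous optimizer and is not needed for lattice assignment.
- The equal weighting of allele-fraction and coverage evidence is a
  convention; the `coverage_weight` scalar exposes it.
- One transcript per gene; no isoform-aware annotation.
- Segmentation is taken as given (the simulator provides segments);
  inferring breakpoints from coverage is out of scope.
- X-inactivation and imprinting are not modelled; records can carry
  annotation flags only.
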