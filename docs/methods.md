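# Methods

## The measurement model

A clone grown from a single fibroblast inherits every somatic mutation of
its progenitor cell in every daughter cell. Against the donor's blood
(treated as the germline genotype), clonal somatic SNVs therefore sit at
allele frequency ~0.5 (heterozygous) or >0.9 (homozygous, from 1-copy
regions or LOH), while mutations acquired during culture expansion are
subclonal (<~0.3). The package's analyses all start from this premise.

## Consensus filtering

Candidate calls from three callers are intersected on the exact
(contig, pos, ref, alt) key; read counts come from a designated primary
caller (configurable — the sources never state whose depths were used).
Retained calls need depth ≥ 10 and ≥ 3 alt reads, must not overlap the
dbSNP-like or simple-repeat blacklists (filtered by position-interval
overlap; allele-aware dbSNP matching is a documented alternative), and
must be absent from the blood table — absence of the exact key, with no
read-level re-genotyping (no BAMs in scope). Zygosity windows are closed
at [0.45, 0.55] and strictly open above 0.90, following "between … and"
versus "greater than". Multi-allelic records are split into biallelic
rows before filtering. The filter stages commute and only shrink the
call set; both properties are asserted in tests.

## Signature enrichment

Motifs are trinucleotides with the mutated base in the centre; flank
sets use n (any), y (C/T), r (A/G). The context for each mutation is the
41-nt window centred on the mutated residue, truncated (not discarded)
at contig ends. Both strands are always counted: a motif occurrence is a
forward 3-mer match or a match of the reverse complement.

Enrichment is the ratio of the in-motif mutation fraction to the
in-motif context fraction. Significance is a one-sided Fisher's exact
test on [mutations in/out of motif] vs [context bases in/out of motif]
(scipy), corrected by Benjamini–Hochberg (statsmodels) across samples
within each motif family by default (matching the per-signature
presentation; per-sample families are available). The minimum mutation
load is mutations(motif)·(E−1)/E when E > 1 and q < 0.05, else 0. The
UV-attributable total sums the yCn→yTn and nTt→nCt loads plus 2 SNVs per
tandem CC→TT pair (each pair is two catalog records, keeping load units =
SNV count; the overlap between a pair's 3'C and the yCn motif is not
deduplicated). Tandem pairs are adjacent-position CC→TT on either strand
(GG→AA on the forward strand); in an adjacent run every consecutive pair
counts.

Numerical choices:

- Context bases are counted only at window positions where the full
  trinucleotide is visible (both neighbours inside the window). Counting
  edge centres in context(base) but never in context(motif) inflates
  enrichment by ~5% at 41-nt windows; restricting both counts to
  interior positions removes the bias.
- Enrichment is NaN (undefined, excluded from loads) when the motif
  never occurs in context or the substitution class is empty; it is 0
  (defined) when class mutations exist but none fall in the motif.
- Overlapping motif occurrences all count; N never matches.

A structural property of the minimum-load estimator worth stating: it
equals m_in − m_base·(context fraction), i.e. the in-motif excess over
what a context-blind process of the same class size would have produced.
For a motif whose context fraction is large — yCn covers ~half of all C
contexts, since P(5' pyrimidine) ≈ 0.5 on any strand-symmetric genome —
the estimator recovers at most ~half of a planted in-motif count even
with zero background. This is the intended "minimum estimate" behaviour,
not a defect; tests assert the load stays below the planted count and
matches the analytic expectation.

## Mutation rates

Divisions from telomere attrition: progenitor TRF = measured repeat
length + 1 kb restriction-to-repeat offset + 2 kb culture correction
(≥20 clonal generations × 100 bp); divisions = (11 kb newborn TRF −
progenitor TRF)/attrition, rounded to the nearest integer. The default
attrition of 100 bp/division yields the minimum division count and hence
a maximal per-division rate (prenatal divisions are unknown); 50
bp/division is available as a parameter. Rates: per-division = load /
(divisions × 6×10⁹ diploid nt); yearly = round(load/age); the UV/
endogenous split divides the UV minimum load and the remainder by age.
Donor ages map 62 and 58 to donors 1 and 2 respectively, inferred from
the published per-clone rates (581/62 ≈ 9, 12 743/58 ≈ 220);
configurable. Yearly rates round to integers and donor averages to one
decimal, matching the published display. The published per-clone rows do
not always satisfy UV + endogenous = total; this implementation follows
the stated footnote arithmetic literally, for which the identity holds
to ≤1 post-rounding.

## Covariates and strand bias

Windows tile each contig at a fixed width (1 Mb for real tracks; smaller
for synthetic runs), the last window possibly shorter. Replication
timing is aggregated as the length-weighted mean of the smoothed signal;
DNase peaks are counted by midpoint assignment. "5 equal bins" is read
as equal-population (quantile) bins with stable tie-breaking, sizes
differing by ≤1; equal-width binning is available via a flag. The trend
is the least-squares slope of mean bin density against bin index 1..k
(the sources report "positive slopes" without defining the fit; linear
over bin index is this package's choice).

Strand assignment compares the strand carrying the mutated pyrimidine to
the gene's strands: equal to the coding strand ⇒ the lesion is on the
non-transcribed strand. Overlapping genes of opposite strands make a
position ambiguous, excluded from testing. The test is the exact
one-sided binomial tail P(X ≥ non-transcribed | n, 0.5), BH-corrected
across samples; the control set is every catalog mutation not matching
any UV signature (each record counted once, CC→TT members in the UV set).

## Clonality estimators

SVs: clonal iff supporting/total > 0.30 strictly and blood support = 0;
the junction-total denominator mirrors the insertion formula since the
SV denominator is never defined in the sources; centromere/telomere
exclusion is input-driven (BED), not hard-coded. Insertions: allele
frequency = RAM/(RAM + concordant); in duplicated regions the concordant
count is first scaled by genome-average/local depth (upper bound under
the one-copy assumption). Labels reuse the SNV VAF windows; frequencies
below the het window are subclonal.

## Synthetic data: what it emulates, and what it does not

The generator is the package's test bed and defines its study
conditions:

- Reference: i.i.d. bases at GC 0.41 (human average); 100–400 kb in
  tests. No repeats, no chromatin, no real motif composition — so
  context fractions are their i.i.d. expectations, which is exactly what
  the calibration tests need.
- Processes: UV_YC (yCn→yTn), UV_TT5 (nTt→nCt), UV_CCTT (tandem pairs
  emitted as two adjacent SNV records sharing a pair id), CPG_DEAM
  (nCg→nTg), BACKGROUND (uniform). Motifs are planted on the strand
  carrying the pyrimidine (or 5'T) and recorded on the forward strand;
  per-process counts are multinomial in the mixture weights. The default
  mixture (UV_YC 0.35, UV_TT5 0.15, UV_CCTT 0.05, CPG_DEAM 0.10,
  BACKGROUND 0.35; n = 3000) is forearm-like: UV-dominated with a CpG
  clock component.
- Transcription-coupled repair: inside genes, UV lesions on the template
  strand are accepted with probability tcr_factor, giving a template-
  strand fraction tcr/(1+tcr). The sources give no quantitative repair
  efficiency; tcr_factor = 0.5 is a free simulation parameter chosen to
  give a clear but not overwhelming bias at a few hundred genic
  mutations.
- Zygosity: het/hom/subclonal at 0.85/0.05/0.10 with subclonal cell
  fractions U(0.04, 0.5) (VAF < 0.25). The sources report loads, not
  zygosity proportions; these defaults keep all three filter branches
  exercised.
- Caller tables: one shared sequencing outcome (depth ~ Poisson(50),
  matching 40–60× coverage; alt reads binomial at 0.5/0.97/cf/2), then
  per-caller false-negative dropping and false-positive injection.
  Germline variants (density 1/1000 bp, het) appear in clone tables and
  are the only blood records. exact_vaf=True removes read sampling for
  the fully-noise-off regime, in which the filter chain must recover the
  planted clonal truth exactly.
- Covariates: a latent per-window density multiplier exp(gradient·u),
  u ramping −1..1 across windows, weights all site selection; the
  timing track increases with the multiplier (read as a lateness score)
  plus gaussian noise, and DNase peak counts are Poisson with intensity
  inversely proportional to it.

Passing tests on this generator show the statistics are correctly
implemented and calibrated under known truth; they do not show that real
genomes satisfy the i.i.d.-context or independent-caller-noise
assumptions.

## Problem sizes and determinism

Test and acceptance runs use 100–400 kb genomes, 500–5000 mutations,
10–200 simulation replicates — sizes chosen so the statistical assertions
(4σ bounds, ≥0.8 power, type-I ≤ 0.07) are stable while the full suite
stays fast. All randomness flows from explicit seeds through numpy
generators (SeedSequence spawning in the pipeline); no global state. The
pipeline report excludes timestamps, so identical config + seed gives
byte-identical reports.

## Known limitations

- No read-level simulation (FASTQ/BAM), indels, CNV sequence changes or
  clone phylogenies; callers are emulated at the call-table level.
- Blacklist filtering is positional; allele-aware dbSNP matching is not
  implemented.
- The enrichment context model is the 41-nt local window only; whole-
  genome context and mappability corrections are out of scope.
- Telomere length is an input (no length estimation from reads); the
  prenatal division count is explicitly not modelled.
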