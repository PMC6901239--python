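# Methods

This note documents the models, estimators, parameter choices and known
limitations behind `isodrift`, in the order the pipeline runs.

## Input model and conventions

Cohorts are held as a sample-by-site matrix of diploid genotype codes
(0/1/2 alternate-allele counts, −1 missing) with per-genotype depth
(DP) and quality (GQ), plus per-site QC annotations (QD, MQ, FS, SOR,
MQRankSum, ReadPosRankSum), a consequence class, a CADD score and a
gene id. AC/AN/AF are always derived from the matrix. Variant
positions are 1-based (VCF); intervals 0-based half-open (BED); a
variant at position `pos` overlaps `[start, end)` iff
`start < pos ≤ end`. Strand is ignored — all region assignment is
positional, and gene-structure categories (5'UTR, exon, intron, 3'UTR,
ncRNA) are non-exclusive because genes overlap. `non_coding` is defined
as the mappable genome minus the union of the five gene categories,
computed exactly by interval complement. Panel records failing the
panel's own quality filters are dropped at load time.

## Quality control

**Hard filters.** Cutoffs are derived per cohort (never pooled, to
absorb batch effects) as the boundary to the worst-quality
`tail_fraction` (default 5%) of each annotation: lower bounds for QD,
MQ, MQRankSum, ReadPosRankSum; upper bounds for FS, SOR; SNPs and
INDELs separately. The quantile estimator is linear interpolation
between order statistics (the classical type 7, NumPy's default) so
derived thresholds are exactly reproducible. Filters are strict
inequalities — a value exactly at the cutoff passes — and a missing
annotation is "not evaluated", never a failure. A genotype also fails
below the depth floor (default DP < 10). Sites are kept cohort-wide if
at least one genotype passes (the keep-if-any-unfiltered merge rule).

**GC windows.** The genome is partitioned into fixed consecutive
100 bp blocks from position 1; variants in blocks with GC < 15% or
> 75% are excluded (strict), with ambiguous bases excluded from both
numerator and denominator. An all-ambiguous block excludes nothing
(no evidence of bias is assessable); this case is logged.

**Ultra-rare candidate QC.** A panel-absent variant is retained only
if biallelic with cohort AF ≤ 0.1 and every *carrier* genotype
satisfies DP ∈ [8, 60] and GQ ≥ 30 for SNPs, DP ∈ [12, 60] and
GQ ≥ 40 for INDELs (all bounds inclusive).

## Relatedness

Pairwise pi_hat = P(IBD=2) + ½·P(IBD=1) is estimated by the method of
moments on biallelic SNPs with cohort MAF ≥ 2%: observed IBS0/1/2
counts per pair are equated with their allele-frequency-conditional
expectations summed over markers, solved sequentially for P(IBD=0,1,2),
then clipped to [0,1] and renormalised. This is the per-site-expectation
core of the standard MoM estimator without genome-wide small-sample bin
corrections; the simplification is validated by pedigree simulation
(duplicates ≈ 1, parent-offspring ≈ 0.5, unrelated ≈ 0). The unrelated
subset (threshold pi_hat ≥ 0.0625, first cousins once removed and
closer) is a maximum independent set in the relatedness graph: exact
via complement-graph maximum clique for connected components of ≤ 25
samples, and the better of a minimum-degree greedy sweep and fixed-seed
randomised restarts above that, with deterministic tie-breaks.

## Stratification and drift

Frequency classes use the panel's folded NFE MAF with inclusive upper
bounds; panel-present variants with MAF_NFE = 0 (seen only in other
panel populations) fall in *very rare*. Sharing counts carrier
individuals, not alleles: a sole hom-alt carrier is a singleton. Drift
fold-enrichment divides the cohort AF by max(other-cohort AF, maximum
panel-population AF) for panel-known variants (per-population AF, not
MAF) and by the other-cohort AF alone for panel-absent ones; a
panel-absent variant unseen in the other cohort is cohort-specific.
Aggregate drift fractions (cohort-specific / total, and cohort-specific
plus ≥ 10×-enriched / total) are plain ratios of counts, reported as
percentages.

## Bootstrap load comparison

Per-individual counts are variant *alleles* (het = 1, hom-alt = 2) in
the class/region, divided by region length in Mb for regional analyses
(normalisation before testing; for a fixed region length the test is
unaffected). The comparison fixes the isolate and draws `n_subsets`
(default 10,000) with-replacement subsets of matching size from the
control pool; per subset it records the median, the fixed/subset median
ratio, and a two-sided Wilcoxon rank-sum p-value (exact when both
groups ≤ 12 without ties, otherwise normal approximation with tie and
continuity corrections). The significance verdict demands both
`n_significant ≥ 0.95·n_subsets` at the family's Bonferroni-corrected
alpha (defaults: 5×10⁻³ genome-wide, 8×10⁻⁴ coding regions, 2×10⁻⁴
chromatin states, 0.0125 ROH) and the fixed median falling outside the
[2.5, 97.5] percentile interval of subset medians. The latter
implements "no CI overlap" with the isolate median treated as a point
estimate, since only the resampled cohort has a replicate distribution.
Subsets with zero median produce an infinite ratio and are excluded
from the ratio CI with a logged count.

## SFS, Tajima's D, ROH

The folded SFS subsamples 50 distinct individuals per replicate
(without replacement within, with replacement across 100 replicates),
drops sites with any missing genotype, folds to minor-allele counts and
reports mean and s.d. of bin proportions. Tajima's D uses the standard
constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂) for 2n chromosomes with π
from per-site allele counts; windows are consecutive 1 Mb bins
end-truncated per chromosome, and windows without segregating sites are
undefined and excluded. The isolate aggregate is the median (and 95%
interval) over all windows; the control aggregate is the median over
window medians of repeated size-matched subsets.

ROH calling is a two-state HMM over one sample's markers along a
chromosome: emission P(het | outbred) = 2p(1−p) from the cohort AF,
P(het | autozygous) = 5×10⁻³ (genotype-error allowance), switching
probability 1 − exp(−θd) between markers at distance d with
θ = 5×10⁻⁷ /bp, Viterbi decode, markers with GQ < 30 ignored. The
cited ROH tools do not publish their exact transition parameterisation,
so these defaults are validated by planted-tract recovery (≥ 99% of
planted autozygous length ≥ 1 Mb recovered at 1 marker/kb). Segments
< 0.5 Mb are discarded; [0.5, 2) Mb intermediate; ≥ 2 Mb long; both
kept classes additionally require a per-cohort marker density (per kb)
at or above a cutoff, for which a histogram-antimode helper provides a
suggestion from the characteristic bimodal density distribution.

## Selection statistics

LOF = stop gained, splice donor/acceptor, or missense with CADD ≥ 20;
SYN = synonymous. Cohort-level LOF/SYN is the ratio of summed allele
counts; the singleton scope keeps heterozygous sole-carrier exonic SNPs
only; gene restriction keeps genes with ≥ 1 LOF-or-SYN variant observed
in both cohorts (a monotone filter). Per-individual ratios exclude
individuals with zero SYN alleles rather than adding pseudocounts, and
feed a one-sided rank-sum test across cohorts.

The ASB test takes panel-known SNPs with MAF_NFE ≤ 1%; per replicate a
control subset is resampled, qualifying sites are those carried by both
the isolate and the subset, and each cohort's shift is mean folded
within-cohort AF over qualifying NFIG sites minus the mean over
qualifying test-region sites (exonic non-synonymous; promoter with
CADD ≥ 10; intronic). NFIG — never formally defined by the analyses
this package systematises — is implemented as mappable non-coding space
minus every chromatin-state annotation other than heterochromatin, and
is configurable. Replicates with no qualifying site in either region
are dropped and counted. The final p-value is a one-sided rank-sum over
the two replicate shift collections (alternative: isolate shifts
smaller).

**Limitation.** The replicate-level rank-sum treats bootstrap
replicates as independent observations, but replicates within one
dataset share the underlying cohorts. As the replicate count grows the
test resolves the *dataset-level* difference between cohorts — a single
random quantity — and degenerates toward a sign test of that noise:
p-values concentrate near 0 or 1. Measured on exchangeable synthetic
nulls, the rejection rate at nominal 0.05 is ≈ 0.4–0.6 rather than
0.05. ASB p-values should therefore be read as a directional summary,
not a calibrated error rate; the package reports this operating
behaviour honestly in its acceptance outputs, and the corresponding
calibration test is expected to fail.

Fisher enrichment tests each candidate variant's cohort AC/AN against
the panel POPMAX AC/AN (or AC = 0 with AN = 2 × individuals covered
≥ 30× for panel-absent variants) with a one-sided exact test,
Bonferroni-corrected by the candidate family size. The functional
exonic candidate filter requires enrichment over both the other cohort
and every panel population, a qualifying consequence, CADD ≥ 20 for
missense/inframe, gene pLI ≥ 0.9 for nonsense-class variants and
missense z > 0; sites whose gene lacks constraint data are excluded and
counted.

## The simulator

Forward-time binomial Wright–Fisher on unlinked sites (linkage is
ignored except for autozygosity tracts): ancestral AFs follow a
truncated 1/x density on [10⁻³, 0.5]; both lineages drift
generation-wise at their diploid sizes, the isolate through a founding
bottleneck; deleterious classes transmit with probability ∝ (1 − s),
with s multiplied by the relaxation factor r in the isolate. Defaults:
20,000 sites on a 20 Mb genome, N_cosmo = 10,000, N_iso = 1,000,
60 generations since divergence with a 10-generation bottleneck of 150,
s_del = 0.02 on LOF and CADD ≥ 20 missense (s/4 for other missense,
s/2 for high-CADD promoter sites), r = 1, isolate F = 0.05 in
exponential autozygous tracts of mean 1.5 Mb, cohorts of 80 and 320,
and a 15,000-diploid panel drawn multinomially from the cosmopolitan
lineage so panel absence (ultra-rarity) arises naturally from sampling
zeros. Site QC annotations come from a two-component good/bad mixture
(5% bad, ≥ 3 s.d. separated) so threshold derivation has a planted tail
to find. Annotation layout tiles genes every 20 kb
(5'UTR/exon/intron/exon/intron/exon/3'UTR), adds ncRNA blocks,
chromatin-state tracks for two pseudo cell types, a mappability mask,
and NFIG. Everything is deterministic given the seed, including
emitted files.

What the simulator does *not* emulate: linkage disequilibrium and
recombination, mutation input (the site set is fixed), sequence-context
mutation rates, read-level errors, population structure beyond the
two-lineage split, and realistic genome annotation densities. Passing
recovery tests therefore demonstrates that the estimators respond
correctly to drift, inbreeding and selection-strength signals of known
direction and scale — not that real-data effect sizes are reproduced.

## Study problem sizes and calibration designs

Repeated-dataset studies run at desk scale, chosen once: the bootstrap
load comparison is calibrated on 6,000-site / 6 Mb datasets with 50 vs
200 samples and 2,000 subsets; exchangeable nulls draw both cohorts
from the same simulated lineage. ASB power uses 20,000-site datasets
with 80 vs 320 samples and a *relaxation-only* contrast (identical
demography in both lineages, selection halved in the isolate): under
the strong desk-scale bottleneck, drift conditional on a variant
surviving multiplicatively inflates isolate MAFs, which amplifies the
isolate's baseline-minus-region shift and can mask or reverse the
constraint signal; isolating the factor under test is the appropriate
calibration design, and the study size was set by a pilot power
analysis (~250 eligible exonic sites gives adequate signal-to-noise).
Tajima's D recovery uses one denser dataset (40,000 sites / 20 Mb) so
sparse categories such as 5'UTR retain enough segregating sites per
window.

## Numerical choices and degenerate inputs

Rank-sum tests switch to the exact distribution only for ≤ 12
observations per group without ties; identical constant samples return
p = 1. Bootstrap ratios with zero-median subsets are logged and
excluded from ratio CIs. Tajima's D is undefined (and excluded) at
S = 0; the implementation matches an independently coded oracle to
10⁻⁹ over 1,000 random windows (observed agreement ~10⁻¹⁵). Fisher
p-values match exact hypergeometric enumeration to 10⁻¹² (observed
~10⁻¹⁶). IBD probabilities are clipped and renormalised before pi_hat
is formed; monomorphic marker sets raise an error rather than returning
noise. All randomness flows through explicit NumPy generators seeded by
the caller.
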