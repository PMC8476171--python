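# Methods

This note documents the models behind `strataphase`, the parameter choices
that matter, what the bundled simulator does and does not emulate, and the
numerical conventions adopted where the design was genuinely open.

## Phase by transmission

Each family contributes a father–mother–son–daughter quartet of diploid
genotypes at biallelic SNPs. For an offspring heterozygote the paternal/
maternal assignment is taken as the unique decomposition consistent with
both parental genotypes; homozygous offspring are trivially phased after a
carrier check. Two failure modes are handled conservatively:

- *Triple heterozygotes* (father, mother and the offspring all het) admit
  two decompositions; the affected offspring's two gametes are set missing.
  Masking is per offspring trio, so a homozygous sibling at the same site
  is still phased.
- *Mendelian violations* (an offspring allele absent from both parents)
  mask all four gametes of that family at the site; an optional global
  scope drops the site for every family instead. Half-calls are treated as
  fully missing.

Phasing is strictly family-local; no population-level imputation is ever
performed, because imputation-style phasers systematically impute X alleles
onto degenerate Ys. Site filters default to QUAL ≥ 999, GQ ≥ 20, at most 3
missing sons and 3 missing daughters, and a mean-depth band of
[0.75, 1.5] × the autosomal mean (the lower bound suppresses error-prone
hemizygous sites, the upper bound collapsed paralogs). Within a declared
SDR an extra consistency filter masks the paternal calls of any family
whose son and daughter received the same allele from a heterozygous father
— impossible under strict X/Y transmission and diagnostic of hemizygosity
artifacts.

Coordinates are 1-based inclusive internally (VCF convention); all window
arithmetic is half-open `[start, end)` in bp.

## Differentiation and degeneration statistics

**Read-depth ratio.** Mean son depth over mean daughter depth, computed as
a ratio of means per 10 kb window (and per gene over its SNPs), never a
mean of per-site ratios; it is therefore invariant to uniform depth
rescaling. Genes with a mean ratio strictly below 0.75 are called
hemizygous; genes without SNP coverage are reported uncallable rather than
intact. Windows with zero daughter depth yield a missing value with a
warning.

**Weighted F_ST.** Phased X and Y gametes are haploid samples, so the
Weir–Cockerham estimator is computed from the allele-frequency ANOVA
without heterozygosity terms: per site, θ = (MSP − MSG) / (MSP + (n_c − 1)
MSG) with MSP the among-group and MSG the within-group mean squares of the
allele indicator and n_c the variance-effective size. The "weighted"
window estimate is Σ numerators / Σ denominators. Fixed differences give
exactly 1 for any sample size; identical allele frequencies give the
estimator's small-sample offset −1/(n_c − 1), reported unclipped so users
can see the sampling behaviour. Monomorphic windows are missing, not zero.
Sites with fewer than two called sequences in a group are dropped.

**Consensus sequences.** The alternate allele is substituted into the
reference CDS when at least half of the non-missing sequences in the group
carry it (exact half counts as major; a strict-majority convention is
switchable). Minus-strand CDSs are reverse-complemented before codon
operations; a CDS whose length is not a multiple of 3 is an annotation
error. The premature-stop scan flags any in-frame TAA/TAG/TGA before the
terminal codon.

**Diversity.** N_e = π / 4μ under neutral equilibrium. π and Tajima's D
are not offered as windowed *results*: the stringent phasing filters bias
them strongly, and they exist only as internal simulator calibration
checks.

## Gene trees, monophyly and topology classes

Per-window trees are neighbor joining on pairwise Hamming distances with
pairwise deletion of missing sites; windows with fewer than 5 variable
sites or 4 usable sequences are skipped, and all-identical windows are
flagged uninformative. Tree inference is deliberately replaceable —
externally supplied Newick trees (e.g. maximum likelihood) are accepted
verbatim, because the analysis contribution is the statistic and the
classifier, not the tree builder.

The monophyly fraction of a class (all Ys, or all Xs) is the size of the
largest clade containing only that class divided by the class size,
computed on trees rooted with the outgroup haplotype; m = 1 iff the class
is monophyletic. Ties among equally large clades are irrelevant since only
the fraction is reported. The statistic is invariant to tip-label
permutation within a class and to child rotation.

The multispecies classifier requires tips labelled `<species>_<X|Y>_<i>`
plus an outgroup. A prefilter retains trees with four reciprocally
monophyletic class clades or with monophyletic species clades; everything
else is OTHER (in real data such arrangements are overwhelmingly
genotyping/phasing artifacts). Retained trees are assigned:
ANCESTRAL_SDR when the two species' Ys form a clade and the Xs form a
clade; INDEPENDENT_SDR when each species' X+Y form a clade;
TURNOVER when one species' X+Y clade nests inside the X assemblage with
the other species' Y outside; PAR_BOTH / SDR_A_PAR_B by whether X and Y
intermingle within species clades. Windows where sister relationships are
ambiguous go to OTHER rather than being guessed. Per-stratum calls use a
majority vote with the full class tally reported, on the logic that all
windows of one stratum share a single coalescent history and minority
topologies reflect error.

## Strata: changepoints, divergence, dating

**Changepoints.** The depth-ratio profile is segmented by exact penalized
least squares (change in mean, Gaussian cost) via optimal-partitioning
dynamic programming — identical output to an exhaustive search. The
default penalty is BIC-style, 2σ̂² log n, with σ̂ estimated robustly from
first differences (MAD/0.6745/√2) so that level shifts do not inflate it;
it is user-overridable, which matters on profiles with real gene-scale
deletion dips where a larger penalty yields stratum-scale segments. The
minimum segment length defaults to 5 windows to forbid single-window
strata; the number of strata is a data outcome, never forced. Missing
windows are skipped in the cost but boundaries are reported as indices
into the original series (each the first window of a new segment).

**NG86 divergence.** Synonymous and nonsynonymous site counts use the
standard per-codon thirds, with mutations to stop codons counted as
nonsynonymous; differences in multi-hit codons are averaged over all
mutational pathways, excluding pathways through stop intermediates unless
every pathway is blocked. Proportions are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − (4/3)p); p = 0 maps to 0 and p ≥ 3/4 to +inf
(saturation), and non-finite genes are excluded from all means. Genes with
an internal stop in both sequences are flagged and excluded; a stop in one
sequence skips that codon. Gene-level dN/dS summaries exclude genes below
a minimum SNP count (5 on the ancestral chromosome, 8 on the neo-sex
chromosome, the smallest thresholds that avoid division-by-zero ω).
Hemizygous genes are removed *before* divergence computation, enforced in
pipeline order — their "Y" consensus is really imputed X sequence.

NG86 counting with JC correction substitutes for maximum-likelihood codon
models throughout. The stratum-age estimator uses only the *ratio* of mean
dS values, which is insensitive to this substitution at the reported
precision.

**Dating.** age = T_split · mean dS(X,Y) / mean dS(Y, outgroup X), with
T_split = 14.3 My by default. The Y enters both numerator and denominator
so that faster Y-specific evolution cancels. A zero outgroup divergence
leaves the age undefined (flagged), and a PAR (dS(X,Y) = 0) dates to 0.
Pairwise between-stratum comparisons of per-gene dS, dN, ω and per-window
F_ST use the Mann–Whitney U test; raw p-values are reported alongside a
Holm-adjusted column.

## Shared-duplication Y-homology test

Son-vs-daughter F_ST on paternally inherited autosomal alleles is averaged
over 10 kb windows per species (SNPs with fewer than 8 informative sons or
daughters dropped). Windows in the top q quantile (strict inequality at
the cutoff) in *both* species are shared outliers; the observed count is
tested against the chance expectation q²·N with a 1-df χ² goodness-of-fit
test, plus a hypergeometric tail probability for small expected counts.
Within shared windows, a SNP is a *homologous Y duplicate* when F_ST
exceeds 0.25 in both species and the same allele (by base identity) is
male-restricted in both — frequency zero among daughter-inherited paternal
alleles and positive among son-inherited. Windows with at least two such
SNPs are labelled evidence of Y homology; depth ratio > 1 is reported as a
corroborating column, never a gate.

The outlier quantile defaults to 2%, appropriate to a genome-scale window
count where duplications are numerous. When only a handful of true
duplications segregate among ~10⁴ windows, a 2% cut floods the outlier set
with noise (≈200 windows/species, chance sharing q²N ≈ 4) and the overlap
test loses power regardless of signal strength; the validation suites
therefore use a cut scaled so the outlier set is signal-dominated (top
0.1%), under which all planted duplications are recovered with overlap
p ≪ 10⁻⁵. Choosing the quantile to match the expected signal density is
part of the analysis, and the null calibration (~q² sharing) is always
checked at the 2% default.

## The synthetic-data generator

The generator works at the VCF level and emulates, with known truth:
sex-linked transmission in 15-family quartets; strata with configurable
recombination-stop ages whose X–Y lattice divergence follows a two-state
symmetric model with p_diff = (1 − e^(−2·2μt))/2, exactly invertible to
2μt; a PAR drawing X and Y from one exchangeable pool; X-pool standing
variation from the neutral 1/i frequency spectrum scaled to π; Y gene
deletions fixed on the Y (halved male depth, hemizygous genotypes);
age-dependent Y-read mappability e^(−0.085·age) so male depth declines
across old strata as diverged Y reads fail to map to an X-only reference
(the rate reproduces stratum-mean depth ratios of ≈0.58 at 22 My and
≈0.77 at 7 My); autosome-to-Y duplications as male depth inflation
×(1 + n_copies/2) with male-restricted alleles at alternate-read fraction
n/(2 + n); Poisson(35) depth; and per-genotype error (10⁻³), dropout
(10⁻²), low-GQ (10⁻²) and low-QUAL (5×10⁻³) events, all logged so the
emitted genotypes are exactly reconstructible from truth plus the event
log. Regeneration with the same seed is byte-identical. Two species
analysed against one reference share a `reference_seed` so lattice
alleles — and ancestrally shared duplication alleles — are identical by
descent.

Key defaults and units: μ = 5×10⁻⁸ per site per generation with a
configurable generations-per-year scale (default 1; never stated in the
source literature, so it is a knob, not a claim); mean depth 35×;
π = 0.001/bp; candidate-SNP density 0.01/bp; species splits 14.3 and
2.0 My; default strata mirror a 20.6 Mb chromosome with ages
{22, 13, 12, 7.2} My and deletion probabilities {0.92, 0.83, 0.77, 0.70}.

Coding-sequence divergence is simulated separately, per gene, on the
three-taxon tree (X, Y, outgroup-X) with Poisson mutation, purifying
selection accepting nonsynonymous changes with probability ω = 0.25, and
stop codons rejected. Validation of the dating pipeline uses a clock of
2.5×10⁻³ substitutions/site/My, chosen to match the observed magnitude of
synonymous divergence at a 14.3 My split (dS ≈ 0.06–0.1) — equivalently, a
longer effective generation time — so the NG86 estimator operates in its
accurate range; with 100 genes × 300 codons per stratum (the realistic
per-stratum gene count), median dated ages over 20 replicates fall within
a few percent of truth for t ∈ {1, 5, 10} My.

What the generator does **not** emulate: read-level artifacts (mapping
qualities, indel noise), recombination-map variation and gene conversion,
linkage disequilibrium within the X pool (sites are independent),
selection on the lattice, population structure, and reference-genome
errors. Passing tests therefore demonstrate the correctness and power of
the statistics under idealised genotype-level noise, not robustness to
upstream read-processing pathologies.

## Problem sizes used in validation

The test and acceptance runs use scaled-down problem instances chosen to
keep every check well-powered: 10⁴-SNP chromosomes for phasing exactness,
25 × 100 kb windows for monophyly power, 250 replicate histories for the
topology classifier, 300-window profiles for changepoint/oracle equality,
60 stratum-replicates for age recovery, and ~10⁴ autosomal windows with 5
planted duplications for the homology test. All are configuration, not
hard-coded limits; every routine accepts full-chromosome inputs.

## Known limitations

- The male-depth mappability decay is phenomenological; real mapping loss
  depends on repeat content and read length, not age alone.
- Genotypes at retained hemizygous sites are emitted as confident
  homozygotes (the real artifact), but allele-balance-based QC signals
  (AD skew at true hets) are simplified outside duplication windows.
- The NG86 estimator saturates near p = 3/4; genes at extreme divergence
  are excluded from means rather than rescued by a better model.
- The topology classifier requires all four species-class groups; windows
  missing a group raise an error rather than receiving a partial call.
- Negative F_ST estimates are reported as-is; consumers binning F_ST
  should not assume a [0, 1] support.
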