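# Methods

`awnqtl` reimplements, as a reusable and testable pipeline, the analysis
machinery of a multiparent QTL study: a five-founder recombinant-inbred
barley population (a recurrent elite parent plus four wild donors) mapped
for a quantitative trait (awn length, in mm), a major QTL fine-mapped in
heterogeneous inbred families (HIFs), and candidate genes shortlisted from
NIL transcript variants.  Everything runs on synthetic data generated by
the package itself; no external downloads are involved.

## Breeding-design simulator (`popsim`)

The simulator reproduces the population's pedigree exactly: each wild
donor is crossed to the recipient, the F1 is backcrossed to the recipient
once, the two BC1F1s of a donor pair are intercrossed, and the intercross
F1 is taken through five generations of single seed descent to F6.  All
six unordered donor pairs are represented; line counts per subpopulation
are free parameters with defaults of 152–153 giving 916 lines in total.

Genomes are founder-origin mosaics: per homolog an ordered list of
(segment end in cM, founder index).  Meiosis follows the Haldane model —
crossover count per chromosome is Poisson(length/100) with independent
uniform positions, no interference and no obligate chiasma; there is no
selection or mortality during SSD.  Under this pedigree the expected
genome share is 75% recipient and 12.5% per carried donor, and residual
heterozygosity at F6 is (1/2)^5 of the intercross-F1 level
(0.4375 · 1/32 ≈ 1.4%); both are verified by Monte-Carlo tests against
the closed forms.

SNP genotypes (0/1/2 alternate-allele dosage) are read off the mosaics
through a founder allele panel.  The default synthetic panel gives the
recipient the reference allele everywhere and each donor the alternate
allele at an independent 50% of markers — roughly the informativeness of
a genotyping array on diverse wild material.  Genotyping error is applied
symmetrically per call (a wrong dosage code chosen uniformly), and
missingness is completely at random; both default to 0.

Phenotypes follow the generative counterpart of the mapping model:
line genetic value = cross mean + Σ_QTL Σ_founder dose·effect, where dose
∈ {0, 0.5, 1} is the founder-genome proportion at the QTL and effects are
per-founder deviations from the recipient (the recipient's effect is 0).
Replicates add Normal noise.  When a broad-sense heritability target is
requested, the residual SD is solved from the realised genetic variance
on the plot (single-replicate) basis, the same convention the estimator
in `phenostats` uses, so recovery of the target is well posed.  The
default study conditions are 4 replicates, H² = 0.75, and the published
7HL founder effects (−3.5, −19.0, −1.0, −24.7 mm) at 133.9 cM.

## Founder-origin HMM (`founderprob`)

Because each line descends from the recipient and exactly two donors, the
hidden chain per line and chromosome has three states; posteriors are
embedded into the 5-founder vector with exact zeros for founders outside
the cross.  F6 lines are ≈97% homozygous, so states are homozygous
founder genotypes and residual heterozygosity is absorbed into the
emissions (a `residual_het_rate` mass, default (1/2)^5, carries observed
'1' calls).  Emission of a dosage call given a state compares it with
twice the founder allele, with the error rate placed on the other
homozygous call; missing calls emit 1 in every state, and a line with no
calls at all is returned at the prior with a logged warning.

Transitions use a jump-to-stationary kernel: over d cM the chain stays
with probability exp(−λ·d·expansion), λ = 0.01 per cM, and otherwise
redraws from the stationary prior (0.75 recipient, 0.125 per donor),
which preserves the prior by construction.  Because a redraw lands on the
current state with its prior probability, the kernel's observable
transition rate is λ·expansion·(1 − Σπ²) ≈ 0.41·λ·expansion.  The
simulated RIL genome carries about 2 founder junctions per Morgan per
homolog (one backcross plus intercross plus SSD), so the default
`map_expansion = 5` makes the kernel match that junction intensity.  The
choice is validated, not asserted: a binned-reliability test checks that
posteriors in [0.8, 0.9) are honest to ±0.05, and forward–backward
smoothing is verified against an exhaustive path-sum oracle to 1e−10.
Scan positions between markers are obtained by re-running the smoother
with silent (uniform-emission) loci inserted on a cM grid.

## Mixed-model QTL scan (`qtlscan`)

The response is the per-line replicate mean.  The locus model has fixed
cross means, a random 4-vector of wild-founder effects at the tested
locus with a common variance, further random founder-effect terms for
cofactor QTLs, and cross-specific residual variances.  Significance of a
locus is the likelihood-ratio test of its variance component against the
boundary-corrected ½χ²₀ + ½χ²₁ mixture null; the reported profile is
−log10 p.  The analysis proceeds in three stages: a plain genome
scan; an iterative multi-QTL scan that adds the strongest locus above
−log10 p = 3.2 as a cofactor and rescans, excluding cofactors within
10 cM of the tested locus; and a final joint model reporting shrunken
founder-effect predictions (BLUPs, deviations from the recipient) with
prediction SEs and a per-QTL p from dropping its term.  Pairwise
epistasis adds, per QTL pair, a random term built from products of the
two loci's founder-probability columns and Bonferroni-corrects over
pairs.

Two procedural details are the package's own: (i) because a locus inside
the exclusion window of an existing cofactor is tested with that cofactor
dropped — and therefore re-detects the same QTL — newly selected
cofactors must lie outside the window of every previous one, and a locus
can be selected only once; (ii) peak ties break to the lowest chromosome
label, then lowest cM, for determinism.

REML is maximised by average-information updates with
expectation-maximisation fallback steps, fixed effects profiled
analytically and the diagonal-plus-low-rank covariance handled through
the Woodbury identity; convergence is declared when the restricted
log-likelihood moves by <1e−8 on consecutive iterations (at most 200).
The response is standardised internally, making estimates exactly scale
equivariant.  Variance components are floored at 1e−10 on the
standardised scale; a locus whose probability columns are constant is
assigned p = 1 without fitting.  On balanced one-way data the estimates
match closed-form expected-mean-squares ANOVA to better than 1e−6, the
test suite's independent oracle.

## HIF fine mapping (`finemap`)

HIF parents are lines heterozygous (dosage 1) at the target marker.  A
selfed progeny plant is recombinant when its genotype class (0/1/2)
differs between the two flanking markers — this captures hom↔het as well
as hom↔hom transitions, matching how a breeder screens codominant CAPS
markers; under Haldane linkage the expected recombinant fraction is
1 − (1 − r)².  Two-point linkage is estimated from the 3×3 codominant
count table by EM over the ambiguous double-heterozygote class, with the
inverse Haldane function converting to cM (estimates at or beyond 0.5 are
clamped with a warning).

Interval delimitation works on homozygous recombinant NILs, each carrying
a single breakpoint and an assigned phenotype class (recipient-like or
donor-like).  Each NIL constrains the QTL to the marker region where its
genotype equals its phenotype class; the call is the intersection of
those regions, reported as the closest bounding marker pair, with
interior markers matching every NIL's class listed as co-segregating.
Inconsistent NILs raise an error naming the lines.  Phenotype classes
come from two-sided Welch t-tests against the homozygous reference
groups at α = 0.05: a NIL compatible with exactly one group gets that
class, otherwise it is unclassified.  The α = 0.05 rule necessarily
misclassifies ≈5% of draws, which the power tests account for.

## NIL variant analysis (`nilvariants`)

The hard filter keeps a transcript variant when QUAL ≥ 30, Fisher-strand
FS ≤ 30.0, quality-by-depth QD ≥ 2.0 and read depth DP > 4 ("exceeded
four reads" read strictly, so DP = 5 is the minimum kept).  A missing FS
or QD annotation passes that single criterion and is logged.  Gene origin
is wild when ≥1 passing homozygous-alternate SNP is present (the
reference is the recipient); het-only genes stay recipient-origin with a
flag.  Segregating intervals between two NILs are maximal runs of
consecutive origin-discordant genes along the map, merged across gaps
smaller than `gap_tolerance` (default 1 cM, a package choice exposed as
config); interval bounds are the outermost discordant gene positions.
Candidate shortlisting keeps interval genes with a detected transcript
and either a polymorphism or differential expression, ranked
polymorphic∧DE > polymorphic > DE; DE status itself enters as a
precomputed boolean flag.  The indel-effect annotator reports a
frameshift when the inserted length is not a multiple of 3 and finds a
premature stop by translating the mutated CDS; the test fixture CDS is
synthetic, engineered so that a dinucleotide insertion after base 37
creates an immediate stop, mirroring the causal-gene pattern.

## Phenotype summaries (`phenostats`)

Broad-sense heritability is plot-basis one-way ANOVA:
σ²_G = max(0, (MS_line − MS_error)/r̄) with r̄ the harmonic-mean replicate
count, H² = σ²_G/(σ²_G + MS_error).  Negative component estimates clamp
to zero, keeping H² in [0, 1]; single-replicate lines are excluded with a
warning.  Whether the study's H² was computed on the plot or line-mean
basis is not documented anywhere we could rely on; plot basis is this
package's convention, mirrored by the simulator's calibration.  Relative
trait values are 100·mean/reference-mean, rounded half-up to one decimal
(control = 100.0).

## Problem sizes and determinism

Simulated checks use deliberately chosen sizes: the study-scale fixture
(916 lines, 7×150 cM, 52 markers/chromosome) exercises the pedigree,
heritability and effect-recovery checks, while detection, power and
calibration simulations run on 1–2 chromosome maps with 150–600 lines
and 10–40 replicates per check, sized so each Monte-Carlo bound carries
slack for its own sampling noise.  The acceptance script averages the
recombinant screens over 200 seed replicates.  Every stochastic stage
derives a logged 31-bit sub-seed from the run seed, so identical seeds
and inputs give byte-identical outputs (covered by a CLI determinism
test).

## What the synthetic data does and does not show

The generator reproduces the pedigree, Haldane recombination, array-like
biallelic markers, QTL architectures with founder-specific effects and
replicate noise at a target heritability.  It does not model crossover
interference, segregation distortion, selection during inbreeding,
population-specific marker ascertainment, shared BC1F1 parents within a
subpopulation (lines are simulated with independent pedigrees), or
genotype-by-environment variation.  Passing tests therefore demonstrate
the correctness and calibration of the algorithms under the stated
model, not the biological conclusions of any particular field study.

## Known limitations

- The HMM is a 3-state homozygous-mosaic approximation, not the full
  inheritance-vector construction over ordered genotypes; heterozygous
  stretches are handled only through the emission model.
- No kinship/polygenic background term, dominance, or QTL-support
  intervals beyond flanking markers in the scan.
- Two-point linkage only; no multi-marker map ordering.
- The locus significance is an LRT; software packages that report
  Wald/F-type −log10(P) values will differ in the far tail.
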