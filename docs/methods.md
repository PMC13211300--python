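# Methods

This note documents the models, parameter choices and design decisions
behind `fixmark`, in the order the pipeline runs.

## Study design emulated by the simulator

The panel generator reproduces the statistical structure of a 64-accession
hybrid-swarm validation study: two diverged diploid populations — the
target species and a pool of sympatric relatives — fixed for alternative
alleles at a set of diagnostic loci, plus hybrids. The default scenario
composition is 32 target purebreds, one cryptic F1 whose morphology matches
the purebreds, three atypical "variant" individuals (target-like
inflorescence, relative-like pigmentation), 16 non-target accessions and 12
F1 hybrids; by morphological label that is 33/3/16/12. Optional BC1 classes
(backcrosses to either parent) are available for hybrid-index studies.

Genotypes are drawn allele-wise from per-population alternative-allele
frequencies: background loci take each population's frequency from an
independent Beta(2, 2) per locus; planted diagnostic loci set the
frequencies to 1 and 0. This makes every class correct by construction —
purebreds homozygous for the target allele at all diagnostic loci, F1s
obligate heterozygotes, BC1s heterozygous at each locus independently with
probability 1/2 — while allowing background loci to share variation between
populations. The "variant" individuals draw from the non-target population:
their molecular identity is non-target even though their morphological
label is target-variant, which is what makes the Stage-2 contrast move
meaningful.

### Contamination model

Read depth is negative-binomial per genotype (mean 90, dispersion 5,
matching the deep-coverage regime of the emulated data). Missingness is
**locus-structured** rather than i.i.d.: a fraction (default 0.30) of
"dirty" loci receives a per-locus missing probability drawn uniformly from
[0.05, 0.50] plus low-depth resampling (1% of genotypes resampled to depth
< 3), while clean loci see only a 0.2% baseline. This reflects how
reduced-representation (GBS) dropout actually behaves — restriction-site
polymorphism and repeat content make missingness a property of the locus,
not of random genotype cells — and it is what makes a strict "no missing
data at the locus" mining rule productive: roughly half of all loci are
fully observed across 64 samples, while an i.i.d. model at any realistic
rate would leave almost none. A further 2% of sites receive mapping quality
below 20 (removed by the MAPQ filter). All contamination is applied after
genotype assignment; the generating truth is retained alongside the
observed matrix.

What the simulator does **not** model: linkage between loci, more than one
backcross generation, sequence-level read errors, allele-specific dropout
correlated with genotype, or population structure within each species.
Passing tests therefore demonstrate the pipeline's logic and its behaviour
under locus-level dropout, not robustness to every artefact of real GBS
data.

## QC cascade

Thresholds (defaults): genotype depth ≥ 3; site MAPQ ≥ 20; per-locus
missingness < 0.30 (computed after depth masking, over all samples);
panel-wide folded MAF > 0.05; Hardy–Weinberg exact p ≥ 0.001 within the
target-species population. Depth and MAPQ bounds are inclusive, MAF and
missingness strict, exactly as the thresholds are conventionally printed.
The stage order is fixed — depth masking first (so the missingness rule
sees masked calls), then site-level MAPQ, missingness, MAF, HWE — and the
per-stage report telescopes (each stage's entering count equals the
previous stage's surviving count), split by SNP vs InDel.

The HWE test is the exact conditional test: conditioning on the observed
allele counts, the probability of each heterozygote count of the same
parity is computed from the hypergeometric-type distribution, and the
two-sided p-value sums all configurations no more probable than the
observed one. The exact test is used instead of chi-square because the
within-species sample (n ≈ 32) is small. MAF and missingness are computed
panel-wide; HWE only within the target species (a mixed panel is not
expected to be in equilibrium).

One subtlety: tightening `min_depth` is *not* guaranteed to be monotone in
the surviving-locus count, because masking genotypes changes the downstream
MAF and missingness in either direction. The other four thresholds are
strictly monotone and are property-tested as such.

## Fixed-allele mining

A locus qualifies when (a) every reference-set sample is non-missing and
homozygous for one common allele, and (b) that allele is entirely absent
from the contrast set — no homozygote, no heterozygote, and no missing
genotype at the locus. Missing data disqualify the locus outright: "100%"
and "frequency = 0" are undefined under missingness, and the strict reading
protects assay specificity at the cost of candidate count (which is
abundant).

Two-stage refinement: Stage 1 trains on all morphologically target-labelled
individuals (typical + variant, n = 36). Because the cryptic F1 sits in
this reference set and is heterozygous at every genuinely diagnostic locus,
Stage 1 finds essentially nothing — which is itself the diagnostic signal
that the training set is contaminated. Stage 2 removes the reclassified
samples (the cryptic hybrid, flagged by assay validation, and the excluded
variants) and re-mines with n = 32.

The contrast set contains the non-target *species* individuals. Known
hybrids are deliberately excluded from it: a true hybrid carries the target
allele at half its loci, so a single hybrid in the contrast would veto the
entire genome — the markers exist to detect hybrids, not to mine against
them. Reclassified samples are therefore routed by molecular identity:
genetically non-target samples (the variants) join the contrast, where any
locus at which they carry the target allele is excluded; genetically hybrid
samples join neither set.

SCAR eligibility requires an InDel with allele-length difference ≥ 20 bp
(gel resolution); all SNPs and InDels are KASP-eligible.

## Assay design

Melting temperatures use nearest-neighbor thermodynamics (the unified
Allawi–SantaLucia parameter set as implemented in Biopython's `Tm_NN`, at
its default 50 mM Na⁺ and 25 nM strand concentrations). Constraints are
closed ranges: Tm 58–62 °C, GC 0.40–0.60 inclusive at both ends, length
20–30 nt.

KASP: the two allele-specific primers are windows ending exactly on the
variant (3′-terminal discriminating base for SNPs; spanning the junction
for InDels), paired with a common reverse primer such that the amplicon is
≤ 120 bp (typical KASP practice; configurable). Enumeration covers both
strand orientations, and candidates are ranked by total |Tm − 60 °C|
deviation, then primer length, then lexicographic sequence. The
tie-break is sequence-based rather than positional because a positional
rule ("leftmost") is not invariant under reverse-complementing the input
flank; with this ordering, designing on the reverse-complemented flank with
mirrored coordinates returns the identical physical primer set. Universal
fluorescent tail sequences are proprietary and are not appended; assays
carry a dye map (diagnostic allele → HEX by convention).

SCAR: only simple left-anchored InDels are supported. Codominant mode
places both primers outside the InDel (amplicon size difference = InDel
length, accepted when ≥ 20 bp); dominant mode places the reverse primer
wholly inside the segment deleted from one allele, which then yields no
band. `mode="auto"` prefers codominant.

## Calling

KASP calling is a fixed allele-ratio rule, not clustering: wells with total
intensity below 0.30 are no-calls; otherwise r = HEX/(FAM+HEX) maps to
target homozygote (r ≥ 0.80), alternative homozygote (r ≤ 0.20),
heterozygote (0.35 ≤ r ≤ 0.65), and no-call in the guard bands between.
The simulator's class means — target-hom (FAM 0.10, HEX 1.00), alt-hom
(1.00, 0.10), het (0.55, 0.55), NTC (0.05, 0.05), isotropic Gaussian noise
σ = 0.04 — put every decision boundary ≥ 3σ from the nearest class mean
(the tightest margin is the hom-ratio boundary at ≈ 2.6σ equivalent in
ratio space for σ = 0.05, which is why the default is 0.04), so the caller
recovers ≥ 99% of labels by construction. A deterministic rule was chosen
over k-means-style clustering because it is auditable and the endpoint
clusters are well separated; thresholds are configurable.

Per-sample species calls aggregate the per-assay genotype classes: all
target-homozygous → target; all alternative-homozygous → non-target; any
heterozygous → heterozygous hybrid; conflicting homozygotes → ambiguous;
no-calls are dropped first and flag the result low-confidence.

SCAR bands are matched to expected sizes within ±5 bp (516 vs 537 stay
unambiguous; a band within tolerance of both expected sizes raises an
error). The merged two-locus framework reads the dominant locus (band
present/absent, O/X) together with the codominant pattern:

| dominant | codominant | call |
|---|---|---|
| absent | target size | target |
| absent | both sizes | target |
| present | target size | target |
| present | other size | non-target |
| present | both sizes | heterozygous hybrid |
| anything else | | ambiguous |

The `(present, target-size)` row is encoded as validated even though
dominant-locus presence otherwise indicates non-target; combinations
outside the table return `ambiguous`, never `target` — for a conservation
screen the fail-safe direction is to withhold a purebred certificate.

## Scoring

Both scoring conventions are first-class and must be named: under
`morphological`, a call is concordant when it matches the morphological
pre-classification (variant-labelled samples count toward their validated
non-target expectation; a heterozygous-hybrid call counts as non-target);
under `genetic`, concordance is against molecular ground truth (a plain
non-target call for a hybrid is still a correct exclusion). Sensitivity is
always the concordant fraction among genetically confirmed purebreds,
specificity among genetic non-targets including hybrids. The module
refuses a silent default because headline figures differ materially
between conventions (the cryptic F1 is "wrong" against morphology and
"right" against genetics).

Wilson score intervals are two-sided without continuity correction, with
the exact normal quantile (1.959964 at 95%); the implementation delegates
to statsmodels and is cross-checked in the tests against a numerical
inversion of the score test. Display rounding is one decimal, half away
from zero. Note that for 63/64 the standard Wilson lower bound is 0.91667,
i.e. 91.7% at one decimal; published values of 91.6% for this count pair
presumably reflect a different rounding or CI procedure and are not
reproduced here.

The hybrid index of a sample over a set of diagnostic loci is the fraction
of its non-missing diagnostic alleles that are target-derived: 1 for a
purebred, 0.5 exactly for an F1, 0 for the other parent, expectation
1 − 2^−(k+1) for a k-th backcross toward the target (0.75 for BC1, checked
at simulation scale).

## Scenarios and problem sizes

Scenario S1 ("KASP panel") is the 64-accession composition above; three
KASP assays are read at mined stage-2 loci (two SNPs and one InDel when
available, mirroring a marker set that reuses a large InDel for both assay
chemistries). Scenario S2 ("SCAR panel") is identical except that at the
two SCAR loci one designated purebred additionally yields the heterozygous
combined band pattern — the incomplete-lineage-sorting failure mode that
motivates merging two loci — so the combined framework shows exactly two
morphological discordants (that purebred and the cryptic F1) while
remaining 100% specific against molecular ground truth. The scenario
assays carry the validated marker set's primer sequences and expected
amplicon sizes (null/116 bp dominant; 516/537 bp codominant); de-novo
design is exercised separately on synthetic flanks. In the rare event that
locus dropout removes every SCAR-sized InDel from the mined set, the
pipeline falls back to the planted assay loci with a warning; band
interpretation and scoring are unaffected.

Default sizes — 2000 loci, 200 planted diagnostic loci, 64 samples —
run the full pipeline in about a second and give stage-2 yields of
~110–140 loci under default contamination. Background loci can satisfy the
fixed-allele definition by chance against the 19-individual contrast with
per-panel probability of a few percent; this is sampling realism (a finite
contrast set cannot certify frequency-zero), and the planted loci are
always recovered when fully observed.

## Known limitations

* Mining is strictly intolerant of missing data at a locus; panels with
  pervasive per-genotype missingness will yield few or no candidates even
  when the underlying alleles are fixed.
* The designer checks primer-level constraints only (no hairpin/dimer
  thermodynamics, no genome-wide uniqueness screen) and supports only
  simple left-anchored InDels for SCAR.
* The fluorescence model is class-conditional Gaussian with a shared
  isotropic noise; real endpoint chemistry shows rotation, intensity drift
  and plate effects that a fixed-ratio caller may need re-thresholding for.
* Multi-allelic sites are rejected, not split; the fixed-allele definition
  is inherently biallelic.
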