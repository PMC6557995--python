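# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the numerical conventions a user should know before trusting
a number the pipeline prints.

## Co-segregation model

The genetic model is dominant with complete sharing: a candidate
predisposition variant must be carried (≥1 alternate allele, het or
hom-alt) by *every* sequenced affected member of a pedigree.  Sharing is
evaluated on the decomposed, normalized variant representation
(multi-allelic records split per alt; shared allele suffix trimmed, then
shared prefix trimmed keeping a single anchor base), so the same physical
variant written two ways in two samples still intersects.  A missing
genotype excludes the variant — precision is preferred over recall, since
downstream validation cost dominates; `sharing.missing_as_carrier: true`
relaxes this.

Rarity uses the annotated control allele frequency with threshold
`rarity.af_max = 0.001`; an absent frequency counts as rare, because
unobserved variants are precisely the interesting ones.  Non-silent means
missense, frameshift, stopgain, or splice-site.  The two filters and the
sharing intersection commute, which the suite checks.

Hard filtering is threshold-based (defaults: per-call depth ≥ 8, GQ ≥ 20,
site QUAL ≥ 30, plus optional site-level INFO expressions); the boundary
convention is pass-at-equality (value ≥ threshold), chosen once and
tested.  Model-based recalibration of call quality is out of scope — the
pipeline consumes already-called, already-annotated variants.

## Cancer-germline set by table subtraction

Population releases often publish a full cohort and a complement cohort
(the full release minus a study subset).  Subtracting allele counts
row-wise (AC_subset = AC_full − AC_complement, same for AN; ids absent
from the complement count as 0) recovers the subset's private variants:
those with derived AC > 0.  Subtraction is strict by default — a negative
difference raises a data-inconsistency error naming the variant, because
real release pairs do contain such inconsistencies and silently clamping
them hides data problems; `--clamp` opts into clamping with a logged
warning.  The suite verifies subtract-then-add-back restores the minuend
exactly.

## Gene burden

The latent cancer cohort is derived the same way (general − non-cancer).
For a gene, carriers per cohort are the sum of AC over its non-silent
variants, and the trial count is the cohort's **maximum** AN over those
variants.  The maximum is deliberate: summing AN across sites would count
the same chromosomes once per site.  The resulting 2×2
(carriers / non-carriers × cohort A / cohort B) is an allele-count table,
documented as an approximation of carrier counts that is accurate for
rare variants.  The two-sided Fisher p follows the standard "sum of
hypergeometric probabilities ≤ observed" convention, computed with exact
integer weights C(r1,k)·C(r2,c1−k) and one rational division, so ties are
resolved exactly; tables whose hypergeometric support exceeds 256 values
switch to a log-space summation (gammaln + logsumexp, stable to ~1e-13)
since exact big-integer arithmetic buys nothing at that scale.  Raw p and
BH-adjusted q are both reported across genes.

## ACMG-AMP classification

The engine separates two concerns.  The *combining table* is the published
five-tier rule set over code strengths (very-strong/strong/moderate/
supporting pathogenic; stand-alone/strong/supporting benign).  Because the
published combinations name exact counts ("1 very-strong and 1 moderate")
but extra evidence of a listed class cannot reasonably invalidate a
combination, counts are read as "at least" — this also makes the verdict
monotone under added evidence, which the suite checks exhaustively over
all multisets of size ≤ 4.  Any fired benign-direction rule together with
any pathogenic-direction rule yields uncertain significance (the
conservative reading of conflict handling).  Two stacked very-strong codes
have no dedicated row and combine to uncertain significance on their own;
in practice only one very-strong criterion exists.

The *evidence assignment* is a declared simplification, config-driven:
truncating change in a known loss-of-function gene → very strong;
absent in controls → moderate; co-segregation across affected relatives →
supporting; in-silico damaging → supporting; control AF > 0.05 →
stand-alone benign.  Clinical-grade per-criterion assignment needs
curation that annotation tables alone cannot supply, so the mapping is
kept transparent and overridable rather than pretending to more.  Under
this mapping a shared, control-absent, in-silico-damaging missense variant
scores PM + 2·PP = uncertain significance — the expected tier for a novel
candidate that co-segregates but lacks functional evidence.

## Substitution tolerance (ΔS)

For a missense change at 1-based position *i* with wild type *w* and
mutant *m*, ΔS = S(i, m) − S(i, w) from the PSSM's integer log-odds block;
ΔS(identity) ≡ 0 and adding a constant to a row leaves ΔS unchanged (both
are suite invariants).  Negative ΔS means the profile tolerates the mutant
less than the wild type, so the empirical comparison is lower-tail.

The Monte Carlo null draws sets of k = 3 mutations (the set size of the
original comparison), each mutation independent with replacement: position
uniform on 1..L, mutant uniform over the 19 non-wild-type residues.
Codon structure and CDS weighting are ignored — this *defines* the null
rather than approximating a sequence-level one.  The empirical p uses the
add-one estimator (1 + #{null ≤ observed})/(n + 1), standard Monte Carlo
practice to avoid reporting zero.  The null mean has a closed-form
expectation, Σ<sub>i,a≠w</sub> ΔS(i,a)/(19L), and the 10,000-set sample
mean must sit within 3 standard errors of it.

PSSMs are read in the PSI-BLAST `-out_ascii_pssm` dialect (log-odds block
kept, percentage block and trailing statistics ignored).  A real PSSM from
a live PSI-BLAST search is database-snapshot-dependent, so the shipped
runs use the synthetic generator's matrix; pointing `inputs.pssm` at a
real file is the supported path.

## Somatic recurrence

The hotspot scan is a transparent fixed-halfwidth design: for each residue
the missense count in the window [i−w, i+w] (clipped; default w = 2) is
tested upper-tail against Binomial(N_missense, |window|/L), Bonferroni-
corrected over the L tests.  This deliberately replaces the boundary
heuristics of dedicated hotspot packages with something auditable; the
cost is that residues adjacent to a true hotspot are flagged too (their
windows overlap it), so hotspot output should be read as flagged windows.

The 20/20 rule uses "recurrent residue" = missense count ≥ 2
(configurable; recurrence is not further specified in the literature the
rule comes from), oncogene fraction = recurrent missense / all missense,
TSG fraction = truncating / all non-silent, and a **strict** > 0.20
boundary — exactly 20% classifies as neither.  Fusion events are counted
and reported but excluded from all three statistics.  Per-cancer-type
enrichment is an upper-tail exact binomial against a background rate that
defaults to the pooled mutated fraction across types (a mutation-burden-
adjusted background is not attempted; the pooled rate is exposed as
config), BH-adjusted across types.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the pipeline assumes:

* ten pedigrees, two sequenced affected each, kinship 0.016–0.25 (the
  observed familial range), each sharing `n_planted_shared = 5` planted
  heterozygous rare non-silent variants against `n_background = 2000`
  background variants with Beta(0.2, 20) allele frequencies (a
  rare-variant-heavy site-frequency spectrum; no published AF model exists
  for this step, so the shape was fixed once), 50% silent;
* cohort tables with allele numbers general 24,000 / non-cancer 18,000 /
  control 30,000 and a full/complement release pair 14,000/12,000 —
  desk-scale analogues of a cancer-containing aggregation database
  (thousands of cancer alleles, tens of thousands of controls); the
  planted gene's carrier odds are multiplied by `enrichment_odds = 5` in
  the latent cancer subset, planted variants have control AF 0 and at
  least one subset-private allele in the full/complement pair;
* a 377-position PSSM (the candidate protein's length) with 70% conserved
  positions where the wild type is the strict row maximum;
* 102 somatic mutations with 30% of missense mass on residue 42 and a
  3× cancer-type weight on the first type — mirroring the observed
  spectrum's shape (a dominant hotspot, a handful of truncating events,
  uneven type distribution).

Determinism: every generator is a pure function of (config, seed), and
child streams derive from the one seed by fixed offsets, so adding a
generator never perturbs existing streams; demo bundles are byte-identical
across runs.

Not emulated: read-level errors (the VCFs are post-calling truth),
linkage/haplotype structure between variants, relatedness-driven sharing
of *background* variants (they are independent per sample, so chance
sharing is rarer than in real relatives — the generator therefore records
any background collisions in the truth table rather than assuming there
are none), population stratification, and any planted intolerance of the
candidate mutations (they are drawn like the null, so the ΔS empirical p
on synthetic data is calibrated, not significant).  Passing tests
demonstrate the machinery is correct under these assumptions, not that
real pedigree data would yield the same candidate lists.

## Problem sizes and numerical conventions

The acceptance computations use: the full 2×2 sweep with both row margins
≤ 30 against exact rational enumeration (|Δp| < 1e-10 demanded, 0
observed); 1,000 randomized binomial tails (n ≤ 200) against exact
Fraction summation (< 1e-12); a 10,000-variant background for the
co-segregation recovery; 10,000 null sets for ΔS calibration; 100 seeds
for hotspot recovery, 200 for the family-wise error rate, and 100
end-to-end pipeline runs (three-pedigree layout, 300 background variants)
for burden power, whose analytic power under the Poisson approximation of
carrier counts is ~1.0 at α = 0.001.  Missing values are written as `.`
in all tabular output; all tables are tab-separated UTF-8 with a header
row.  Exit codes: 0 success, 2 configuration error, 3 data inconsistency,
4 parse error.

## Known limitations

* The evidence-assignment mapping is a four-rule simplification of a
  28-criterion clinical framework; its verdicts are tier-plausible, not
  clinical classifications.
* Allele-count burden testing ignores genotype-level information (no
  distinction between one hom-alt and two het carriers) and does no
  covariate or stratification adjustment.
* The hotspot scan's fixed window trades boundary adaptivity for
  auditability and flags neighbourhoods, not single residues.
* Kinship coefficients are consumed as metadata only; no identity-by-
  descent verification is performed.
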