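# Methods

This note documents the models, rules and numerical choices behind each
analysis stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Horizontal-transfer detection

**Model.** A transmissible tumour lineage is clonal, so its nuclear
genealogy is a single rooted tree. Under vertical mtDNA inheritance the
mitochondrial haplotype would be constant along the tree; every transfer of
a host mitochondrial genome introduces one haplotype change on one branch.
Detection therefore reduces to ancestral-state parsimony: we compute a
canonical most-parsimonious labelling of the nuclear tree by mtDNA
haplotype (unit-cost Sankoff dynamic programme, up and down passes) and
define each **HT event** as a change-free connected region of the tree that
contains tumour tips of its state. On cohorts where events form clean
clades this equals grouping tumours into maximal same-haplotype clades; it
additionally keeps a background lineage together when later transfers nest
inside it (the background is then paraphyletic but still one event), and
the number of events equals the minimum change count + 1.

Tie-breaks are deterministic: the root takes the lexicographically smallest
minimal-cost state; a child keeps its parent's state whenever that is
within the minimum, otherwise the lexicographically smallest minimal state.

**Replaced haplotype.** The haplotype an incoming genome displaced is the
ancestral state just above the event. We mask every tip below the event's
region root as missing data (later transfers nested inside the region are
post-transfer states and must not vote) and compute the exact
most-parsimonious-reconstruction state set at the parent node. A singleton
set is reported; the tree root or an ambiguous set yields `Unknown`.

**Heteroplasmy.** A tumour is heteroplasmic when at least two haplotypes
exceed a strict 10% frequency after removing any haplotype identical to the
matched host's germline haplotype (host contamination explains it).
Per-haplotype fractions are estimated from variant allele fractions: a
profile is a candidate when at least half of its defining variants are
observed, its fraction is the median VAF of the variants discriminating it
from the other candidates, and fractions are renormalised to sum to one.

**Haplogroup assignment** minimises the symmetric-difference distance
between a sample's variant set and each haplogroup profile; ties are
flagged ambiguous and resolve to the lexicographically smallest name. This
replaces manual tree-topology assignment and is equivalent when profiles
are distinct.

**Event location** is the unanimous member location when there is one;
otherwise the parsimony ancestral location of the event clade if it is a
singleton state set, else `ambiguous`.

**Group variants.** Within an event, a variant absent from the donor
profile and carried by *all* members is fixed (its somatic/germline status
cannot be determined); one carried by a strict subset is a confident
somatic mutation. Only confident somatic mutations enter dating. A
singleton event has no polymorphism, so all its private variants are fixed.

## Enrichment test

Null model: every haplotype has a horizontal-transfer opportunity
proportional to its host-population frequency. Each of `R = 10,000`
replicates draws `n` donor haplotypes i.i.d. from the frequency table
(seeded, default seed 76); the empirical p is the proportion of replicates
with at least the observed number of target-haplotype draws. Because only
the target's marginal matters, the exact binomial upper tail
`P(X ≥ k), X ~ Bin(n, p_target)` (direct summation with exact integer
coefficients) is reported alongside as an oracle; the Monte-Carlo estimate
should sit within ~3 binomial standard errors of it. The raw proportion can
be exactly 0; a clearly labelled `(hits+1)/(R+1)` estimator is also
reported. A `restricted_to_pairs` flag marks the conservative variant that
restricts events to those with a sampled matched host.

## Clock calibration and dating

The somatic mutation rate is anchored on the divergence of the two major
tumour lineages: `μ = m̄ / T` with mean somatic burden `m̄ = 9.437` and
divergence age `T = 469.28` years, interval from inverting the divergence
HPD (240.34–744.31 years) — `μ = 0.0201 (0.0127–0.0393)` per year. An event
with mean confident somatic count `m` is dated `m/μ` with interval
`(m/μ_high, m/μ_low)`. Uncertainty from the Poisson mutation count itself
is *not* propagated into the interval (matching the anchor-only treatment);
the dating self-consistency test instead checks that simulated counts fall
in the Poisson 95% envelope.

## Copy number

`copies/cell = (mtCOV·φ_mt)/(nuclCOV·φ_nucl) × P` with ploidy `P = 2`.
`φ_nucl` is twice the mode of nuclear somatic VAFs (diploid heterozygous
somatic variants sit at VAF = purity/2), with the mode taken as the
midpoint of the maximal-count histogram bin over (0.05, 0.95] at width
0.02, ties to the lower bin, capped at 1. The binning is a fixed,
reproducible stand-in for an unspecified "mode"; its quantisation limits
purity resolution to ±0.02 — with thousands of somatic sites at ~100×, the
copy-number round trip recovers truth with ~3% mean error. `φ_mt` is the
median VAF of tumour-specific homoplasmic mtDNA variants (choice: median is
robust to the handful of sites involved). Group comparison is a classical
pooled-variance two-tailed t test; its type-I rate is verified at ~5% under
an equal-copy-number null.

## Recombinant-haplotype phasing

Long reads are reduced to allele patterns over the sites that discriminate
the two parental haplotypes. Reads are clustered by exact agreement (sites
a read does not cover wildcard-match), longest reads first; a read
compatible with several clusters is deferred and assigned to the largest,
with ties left unassigned. Noise handling (the read-error policy is a
package choice): a reported haplotype needs ≥ 3 concordant reads; a small
cluster whose disagreement with a larger cluster rests only on sites
covered by a single member read is merged into it as a read-error artefact,
and one strongly covered conflicting site is also forgiven when the larger
cluster has ≥ 20× the support (a recurrent miscall is then more plausible
than a distinct haplotype). Consequence: a genuine haplotype differing from
a 20×-larger one at a single informative site is not distinguishable from
error at this support and will be absorbed. The assign-to-larger rule also
biases frequencies slightly toward the major haplotype when haplotypes
share long identical stretches.

Ancestry segments are the minimal-breakpoint parental tiling of the
circular genome; breakpoints are placed midway between adjacent discordant
informative sites (no finer resolution exists) and their count is always
even on a circle. `fixed_variants` intersects the donor-specific variant
sets of *all* reported haplotypes, including low-level ones.

## Transcript abundance

Counts are normalised by median-of-ratios size factors (computed over genes
expressed in all samples, rescaled to geometric mean 1), transformed as
`log2(normalised + 1)`, and batch-corrected per gene by ordinary least
squares on `abundance ~ group + batch`: the sample-centred fitted batch
terms are subtracted, the log transform reversed, and values rescaled so
each gene's grand mean on the original scale is preserved (the rescaling
convention is a package choice). A single batch is a no-op; a design where
any group is confined to one batch raises an error. The regularised
log-transform and negative-binomial Wald test of dedicated differential
expression packages are deliberately not reimplemented: this package's
claims are about parameter recovery on synthetic cohorts, and a rank test
on corrected abundances carries them.

The group comparison reports `(1 − mean_A/mean_B) × 100` on group means of
per-sample mean mtDNA-gene abundance, with a two-sided Mann–Whitney p on
the pooled per-gene abundances of the two groups (not the per-sample
means). The Mann–Whitney test enumerates all group assignments exactly for
pooled n ≤ 16 (midrank identity `U = R_A − n_A(n_A+1)/2` makes ties exact)
and otherwise uses the normal approximation with tie and continuity
corrections; its type-I rate at n = 10/group is verified within
[0.03, 0.07]. Per-gene testing applies the same rank test with step-up
Benjamini–Hochberg adjustment restricted to the 13 mtDNA + 7 nuclear genes.

## Synthetic cohorts: what they emulate

Defaults are the study conditions: 495 host dogs from 18 haplogroup
frequencies; 539 tumours in 19 HT events with the published donor,
displaced-haplotype, size and heteroplasmy structure (balanced ~55% and
minor ~15% mixtures; one recombinant event); somatic mtDNA mutations
Poisson at 0.0201/year of event age, placed uniformly on the circular
genome outside profile sites; per-tumour matched-host haplotypes drawn from
the population frequencies. The bundled haplogroup profiles are synthetic
stand-ins that preserve the nomenclature's nesting and the target
haplotype's distinguishing structure (8 SNPs + 1 control-region insertion
unique to it or shared only with its parent haplogroup; one control-region
polymorphism shared across several haplogroups); real profiles can be
supplied as TSV. The host-population frequency table is likewise a
synthetic stand-in (target haplotype at 0.22, prevalent but not dominant).

Nuclear trees are built by grafting each later event's clade above a
distinct tip of its host event. Host selection enforces recoverability: a
graft's donor differs from the host's donor and from the host's own
background, per-host same-donor grafts stay at least two below the host's
tip count, and the founding event receives the largest size. These
constraints keep every simulated event an unambiguous parsimony region
(verified exactly on 600 random cohorts); configurations that cannot
satisfy them are rejected with an explanatory error rather than silently
producing ambiguous truth.

Read support is binomial at fixed depth with per-read mapping/base
qualities (95% MQ 60; base qualities ~N(35, 6) clipped); nuclear somatic
VAFs are binomial around purity/2. Expression counts are negative binomial
(dispersion 0.15 — within-group coefficient of variation ~0.4, echoing the
large within-group spread of real tumours) with multiplicative per-gene
per-batch factors (log-SD 0.25) and ~2000 unaffected background genes so
that size-factor estimation sees a transcriptome-scale matrix; without the
background, median-of-ratios normalisation absorbs part of a 13-gene
effect. Long reads span 60–100% of the informative sites (unsheared
genomic long-read libraries on a 16.7 kb circle), with 2% of reads carrying
one miscalled site.

**What passing tests do not show about real data:** the generator has no
alignment or calling artefacts, no index hopping or contamination beyond
the simple host fraction, clean clade-compatible trees (no tree
reconstruction error — the detector's behaviour under paraphyly caused by
tree error is to split events, flagged rather than merged), profile-exact
germline haplotypes, and independent reads. Recovery on these cohorts
demonstrates the correctness of the inference rules, not robustness to
upstream noise.

## Problem sizes used in the checks

Event-recovery checks run 200 random cohorts of 100–600 tumours with 5–20
events; enrichment calibration uses 10,000 replicates (50 random scenarios
at n ≤ 20); dating coverage uses 1000 Poisson replicates; copy-number
recovery spans 50–500 copies/cell at 10 grid points with 3000 nuclear
somatic sites at ~100×; recombination recovery runs 100 seeded simulations
of 300 reads; expression recovery averages 10 cohorts per effect size at
n = 15/group and checks significance over 30 runs. The full test suite
completes in well under five minutes on one core.
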