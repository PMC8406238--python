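# Methods

This note documents the models and procedures `fmtrack` implements, the
choices made where conventions were genuinely open, what the synthetic
generators do and do not emulate, and known limitations.

## Source tracking

A feature's source is decided per patient from presence/absence only.
Presence means count ≥ `min_count` (default 1 read — the literal "observed"
rule; raise it to guard against index hopping / cross-sample bleed).
"Baseline" is strictly the pre-antibiotics phase: a feature seen only during
the antibiotic course is not credited to the patient's baseline community,
because antibiotic-phase communities are already perturbed (this is a
documented, configurable reading; the alternative treats any pre-day-0 sample
as baseline). Donor scope defaults to the induction donor's samples; the
union of induction + alternate donors is available (`donor_scope="union"`)
and is what the multi-donor partition uses. Features never observed in
either scope are excluded from the universe rather than carried as zero
rows.

Source fractions are occurrence-weighted: every present feature counts
equally. The rationale is robustness to marker collisions — conspecific
strains with identical 16S sequences register as a single, often abundant,
ASV whose source call may be wrong; weighting by occurrence caps the damage
at one unit. Abundance-weighted fractions are deliberately not part of the
main outputs.

Colonization calls count presences in distinct samples with day ≥ 0
(follow-up included — "after the initiation of FMT" does not exclude it):
persistent requires ≥ 3 such presences and ≥ 1 follow-up presence; temporary
requires ≥ 3 presences and a clean follow-up; anything else is none.
Patients without follow-up samples yield no calls rather than guesses.

## Flexible-genome strain matching

Windows tile the genome half-open, 0-based, `window = 1000` bp; a trailing
window shorter than half the window size is dropped (a 2,400-bp genome has
two windows), a longer tail is kept with its mean computed over its actual
length. The per-profile median is taken over all retained windows, zeros
included — the conservative choice: absent accessory regions pull the median
down and make the depth gate (default 5) bite sooner.

The match rule is applied symmetrically: a window above sample A's median
with zero depth in B, **or** above B's median with zero depth in A, breaks
the match. The one-directional reading would make verdicts depend on
argument order; the symmetric form is stricter and order-invariant.
"Entirely absent" is depth exactly 0 (configurable in principle via
pre-thresholding of the profile). Consensus across several donor samples is
"match if any donor sample matches", since a single positive identification
of the donor strain suffices.

Pattern classification is a two-stage decision table. Any match anywhere
sends the trajectory to the dominance branch (patterns 1–3), resolved by the
follow-up verdicts: match ⇒ persistent dominance (1), ambiguous ⇒ persistent
colonization with dominance lost (3), insufficient ⇒ temporary (2). With no
match ever, ambiguity anywhere means colonization from an unresolved source:
pattern 4 if ambiguity persists into follow-up, 5 if not; an
all-insufficient series is no colonization (6). With several follow-up
samples the strongest follow-up verdict (match > ambiguous > insufficient)
decides. The classifier is verified exhaustively against an independently
coded table for every verdict string up to length 6.

SNP-haplotype post-processing mirrors standard practice for
strain-deconvolution tools: longitudinal samples pool into five phase bins
(antibiotics pools with baseline — both pre-transplant; exact day boundaries
of the bins are not canonical, so the scheme is an explicit mapping the
caller can replace), and per-bin strain frequencies are multiplied by the
bin's median marker-gene depth to approximate absolute strain abundance.
Genomes must exceed median depth 50 in ≥ 2 bins to be reported.

## Community statistics

Shannon diversity uses the natural log (rescale by 1/ln 2 for bits).
Bray-Curtis requires an explicitly relative table — silent renormalization
hides upstream mistakes. PCoA is classical scaling of −d²/2; negative
eigenvalues (non-Euclidean distances) are discarded without Cailliez
correction and their count reported, with proportion explained computed over
positive eigenvalues only. PERMANOVA uses the standard pseudo-F from
among/within sums of squared distances with label permutation, free or
within strata; Mantel correlates upper triangles (Spearman default) and
permutes one matrix's sample order. Both offer exhaustive enumeration for
small n, where sampled p-values use (1 + hits)/(1 + n_perm) and exhaustive
p-values use hits/arrangements with the identity included.

Trajectory statistics average per subject within half-open 5-day windows
[5k, 5k + 5) anchored at the day-0 transplant (day 5 belongs to window 1).
Arm comparisons use two-sided Mann-Whitney U per window: exact enumeration
when the combined n ≤ 10 with no ties, otherwise the tie-corrected normal
approximation. Function-richness comparisons use Welch's t (arms of an
unbalanced trial rarely share variances or sizes).

## Function tracking

Gene families are classified with literally the same code path as taxa: the
RPKM table is binarized at abundance > 0 (marker-based quantifiers are
already filtered upstream; the threshold is a parameter) and fed to the
taxonomic source assigner — a unit test asserts bitwise identity. The
quinolone response test sums quinolone-class resistance abundance per sample
and compares pooled baseline samples against pooled samples in the window
(abx_end, abx_end + 10] days, two-sided Mann-Whitney; the pooled (rather
than patient-paired) form is the default, and per-patient before/after means
and deltas are emitted alongside. Cumulative category abundance offers a
log10 view with offset = smallest positive value / 10 so empty samples stay
finite.

## IgA-seq

Coating scores add a pseudocount of 1 to each ASV count in each fraction
before converting to relative abundance, then take log2(rel_coated) −
log2(rel_uncoated) (a difference of logs, so swapping fractions negates
scores bit-exactly). An ASV needs ≥ `min_reads` (default 5) raw reads in at
least one fraction of a sample to be scored there. The pseudocount shrinks
scores of low-count ASVs toward 0; at ~50,000 sorted cells per fraction the
bias on a planted score of 2 is ≲ 0.02 and recovery is within 0.1.

Strong classification per sample uses strict inequalities at mean ± 1 SD of
that sample's scored ASVs (zero-SD samples classify everything neutral);
samples with < 3 scored ASVs are skipped. Reliability across samples is a
two-sided one-sample t test per ASV (scored in ≥ `min_samples`, default 5;
the unstated convention — testing across all samples vs per-host means — is
exposed via `groups`, per-sample being the default) with Benjamini-Hochberg
adjustment and class by sign of the mean at FDR < 0.1. The permutation null
shuffles ASV labels independently within every sample — preserving each
sample's score distribution while breaking ASV identity — re-runs the
reliability analysis, and counts reliable ASVs; p = (1 + #{null ≥ obs}) /
(1 + n_perm).

A calibration caveat worth stating: the discovery count is a coarse
statistic. Under a global null, P(≥ 1 discovery) equals the FDR level
exactly (Simes), so the permutation p-value is discrete and the realized
Type-I error at α = 0.05 is ≈ 0.02 — valid (below nominal) but
conservative. Users should read the permutation p as a guard against
spurious "reliable" sets, not as a finely calibrated tail probability.

Sarle's bimodality coefficient uses population moments, (skew² + 1) /
kurtosis, with the usual > 5/9 rule of thumb; a symmetric two-point
distribution attains 1. The transferred-vs-shared contrast computes Pearson
correlations of donor vs patient coating scores within each subset
(transferred = Donor-source features with a non-none colonization call;
shared = Shared-source features; the sets are disjoint by construction) and
bootstraps the difference by resampling ASVs within subsets (percentile CI).

## Synthetic data

The cohort generator emulates the structure of a small randomized FMT trial
in ulcerative colitis: 12 patients (7 transplant, 5 placebo), 2 donors, 4
transplant patients switched to an alternate capsule donor mid-trial,
roughly weekly sampling with 3 baseline days, a 7-day antibiotic course
ending before the day-0 colonoscopic transplant, a 12-week treatment period
and ~18-week follow-up, and 50,000 reads per sample. Communities are
log-normal (σ = 1) subject-by-feature abundances over a randomly carried 55%
of the feature pool; antibiotics suppress a random 80% of a patient's
features 100-fold for the duration of the course; a configurable fraction of
donor-only features transfers at day 0 (default 0.6), of which 70% persist
through follow-up and the rest vanish after the treatment period; unknown
invaders arrive post-antibiotics with a per-sample hazard of 0.05. Counts
are multinomial draws; `multinomial=False` emits expected counts (with
presence floored at one read for active features) so rule-based stages can
be tested for *exact* truth recovery before noise is added. Planted truth
(provenance relative to the union of assigned donors, colonization fates,
multi-donor partition labels) ships with every cohort.

Depth profiles are Poisson per window at mean depth × summed weight of the
strains carrying the window; strains share the first `core_fraction` of
windows and own disjoint accessory windows. IgA fractions draw multinomial
cell counts with coated probabilities ∝ abundance × 2^(s/2) and uncoated
∝ abundance × 2^(−s/2), so the plug-in score estimator converges to the
latent score s as cells grow.

What the generators do **not** emulate: phylogenetic correlation between
features, compositional interactions between taxa abundances, read-level
errors and chimeras, strain-level SNP structure (only accessory content),
within-subject autocorrelated abundance drift, and donor-to-donor community
overlap beyond random carriage. Passing recovery tests therefore
demonstrates correctness of the *procedures* under the stated generative
assumptions, not robustness to every artifact of real sequencing data.

## Numerical and scale choices

Validation experiments run at desk scale on one CPU: 1,000 simulated profile
pairs per strain-call condition; 100 replicates for score recovery and
reliability recovery; 200 datasets × 1,000 shuffles for permutation
calibration; 200 replicates for the specificity contrast; exhaustive
enumeration to series length 10 (colonization) and verdict length 6
(patterns). Exhaustive PERMANOVA/Mantel are O(n!) and intended for n ≤ 8.
The global pipeline seed fans out to stage-specific child seeds via NumPy
SeedSequence spawning, so stages are individually reproducible and changing
one stage's parameters leaves the byte content of unrelated artifacts
unchanged. Ties at decision boundaries are resolved strictly: score exactly
at mean + SD is neutral, median exactly at the depth gate passes (gate is
`median < 5`), a window exactly at the median is not "above" it.

## Limitations

Source assignment inherits the resolution of its markers: conspecific
strains with identical 16S sequences collapse into one feature, so Shared
calls overstate true sharing (the motivation for occurrence weighting and
the flexible-genome module). The flexible-genome rule cannot distinguish "a
different strain" from "a mixture including the donor strain" — both are
ambiguous by design. The six-pattern taxonomy summarizes a trajectory by its
follow-up state and ignores mid-series relapses. The permutation null for
reliable ASVs treats samples as exchangeable labels within a sample, which
ignores between-sample dependence from repeated measures of the same host;
per-host mean scores (`groups=`) are the conservative alternative.
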