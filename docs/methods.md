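# Methods

## The co-occurrence model

The unit of evidence is the *same-subject read pair*: one saliva read
and one feces read drawn from the same individual at the same
timepoint. Over the paired subjects (those with both sites sampled),
the probability that a random same-subject pair falls with both ends in
OTU *k* is compared with the product of the marginal probabilities that
a random saliva read, or a random feces read, falls in *k*:

    llr_k = log2( P(S,F) / (P(S) · P(F)) )

This is the pointwise mutual information between the two site labels
within OTU *k*, in bits. Under independent assembly of the two
communities llr = 0 in expectation; persistent transfer of an organism
between an individual's mouth and gut concentrates its reads in the
same subjects at both sites and drives llr up. Events require
`pair_count ≥ 1` and `llr` **strictly** greater than the threshold
(default 0.5): the margin above the independence point 0 is a
conservative guard against sampling noise, and −∞ scores (OTUs that
never pair) are excluded by the pair-count condition.

Two probability estimators are provided, because the pairing idea does
not by itself fix one:

- `read_pair` (default): frequencies over all same-subject read pairs,
  `P(S,F) = Σ_i c_i^S c_i^F / Σ_i d_i^S d_i^F`, marginals pooled over
  paired subjects. This weights subjects by depth and uses the full
  count information.
- `presence`: the same formulas with counts replaced by per-subject
  presence indicators and depths by 1, i.e. the fraction of subjects
  carrying the OTU in both sites vs in each site. Coarser, but robust
  to abundance outliers.

Both satisfy the defining identity `llr = log2(psf/(ps·pf))` whenever a
pair exists. Useful closed forms under equal depths: a taxon private to
one subject and present in both its sites scores exactly `log2(I)` for
`I` paired subjects (so any such taxon is called at threshold 0.5 once
`I ≥ 2`); a taxon at identical relative abundance in every subject's
saliva and every feces scores exactly 0.

Subjects missing one site at a timepoint cannot form pairs and are
excluded from the probability universe; their reads still participate
in clustering. A paired subject with a zero-depth sample is dropped
with a warning. OTUs absent from every paired subject have no defined
score and are omitted.

## Exact clustering

"100% similarity" is implemented as full-length literal string
equality — same length, same characters, `N` compared literally, after
uppercasing. No terminal-gap tolerance or substring matching is
applied: any length-tolerant identity would require an alignment
convention the method does not otherwise need, and relaxing identity
only inflates chance cross-site matches. All samples of a timepoint
(both sites, all groups) are pooled into one clustering universe, so a
single OTU total per timepoint is meaningful; per-group totals can be
obtained by subsetting the manifest. OTU ids are assigned by first
appearance after sorting reads by (sample, read id), making the
labelling a pure function of the input multiset.

## Group summaries

An event OTU is attributed to every group in which at least one subject
contributes a same-subject pair — the event universe is shared, the
attribution is per contributing subject — and group event counts are
normalised per paired subject because group sizes differ. Group taxon
spectra (relative frequencies of taxa among the group's events) are
clustered with average linkage on Bray–Curtis distance (Pearson
correlation distance available), profiles sorted by label before
linkage so ties break deterministically; the dendrogram is written as
Newick.

## Alpha diversity

Per sample: observed OTUs, Shannon `H = −Σ p_i ln p_i` (natural log,
the convention of the vegan R package; the base is configurable),
Simpson's index of diversity `1 − Σ p_i²`, Chao1 in both the classic
form `S_obs + F1²/(2F2)` (with the `F1(F1−1)/2` fallback at `F2 = 0`)
and the bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))`, and ACE with
the standard rare/abundant cut at 10 reads. ACE is reported as NaN with
a warning when every rare taxon is a singleton (its coverage estimate
is zero). Estimation is delegated to scikit-bio; the test suite checks
it against independently hand-coded formulas. No rarefaction is
applied: the generator uses equal depths, and unequal real depths
should be handled upstream of this package.

## Group statistics

Kruskal–Wallis (mid-ranks, tie correction, chi-square tail) for
multi-group comparisons — note the chi-square p is an approximation
whose small-sample error is a few hundredths; the all-identical
degenerate case is reported as H = 0, p = 1. Wilcoxon rank-sum for
pairwise and F1-vs-F2 comparisons: exact by enumeration when the
combined sample is ≤ 12 without ties (small groups need exact
behaviour), otherwise normal approximation with tie and continuity
correction; a zero tie-corrected variance yields p = 1. All tests
two-sided at α = 0.05. The F1-vs-F2 battery runs per (group, site,
index) and is corrected together with Benjamini–Hochberg; adjusted
values are reported as q-values. BH is the standard step-up procedure
(identical to R's `p.adjust(..., "BH")`); note it is *not* idempotent —
re-adjusting q-values can only push them toward 1.

## Synthetic cohort generator

The generator emulates the target study design: groups Control (14),
INR (9), IR (18), VU (12) — 53 subjects, each with saliva and feces
samples at F1 and F2. Design choices:

- **Disjoint site pools.** Each site's taxon pool has its own reference
  sequences (i.i.d. uniform ACGT, length 250, the V3–V4 scale;
  distinctness is asserted). At zero error rate, cross-site identity
  can therefore arise *only* from planted shared taxa, giving an exact
  false-positive definition.
- **Planted shared taxa.** Each subject carries
  `n_shared_subject_taxa` private taxa (default 2) placed in both its
  sites at `shared_abundance` (default 0.02). Being subject-exclusive,
  their expected score is the `log2(I)` law, well above any threshold
  of interest for realistic cohorts.
- **Abundances and reads.** Pool abundances are log-normal
  (σ = 1 by default) per subject and site, scaled to the non-planted
  mass; reads are one multinomial draw of fixed depth per sample.
  Depth defaults to 500 reads/sample, a deliberately desk-scale setting
  (real MiSeq runs are ~40k reads/sample; the analysis is linear in
  depth and nothing in the test suite depends on the absolute scale).
- **Sequencing error.** Substitutions only, i.i.d. per base, never to
  the same base. Indels are excluded on purpose: exact matching is
  length-sensitive, and substitution-only error probes the 100%
  identity decision cleanly (each errored read becomes a singleton
  OTU).
- **Intervention.** At F2 every relative-abundance vector is raised to
  the power `1/intervention_evenness_factor` and renormalised. A factor
  of 0.5 (default) squares the abundances: dominant taxa gain, rare
  taxa lose, evenness and hence Shannon/Simpson drop — the qualitative
  post-prebiotic direction — without changing the planted richness.
  The transform, rather than taxon dropout, keeps richness and evenness
  effects independently controllable.
- **Determinism.** One `numpy` Generator seeded from the config drives
  every draw in a fixed iteration order; outputs are byte-identical
  across runs.

What the generator does **not** emulate: chimeras, PCR and primer
bias, paired-end merging artefacts, realistic phylogenetic structure
between references, depth variation between samples, subject dropout
between timepoints, and taxonomy (truth labels are synthetic ids).
Passing tests therefore demonstrate the correctness of the statistics
and bookkeeping under the stated model, not robustness to real
sequencing artefacts; on real data the 100%-identity criterion is
sensitive to any residual error, and an upstream denoising step governs
the result scale.

## Numerical conventions

- llr is computed in double precision from the probability ratios;
  `−∞` is represented explicitly and never called an event.
- Thresholding is strict (`>`), so a score exactly at the threshold is
  not an event.
- Event lists are sorted by descending llr with otu_id as tie-break;
  all tables have deterministic row and column orders.
- Scoring tolerances in tests: pair counts are integer-exact, llr
  agrees with brute-force pair enumeration to 1e−9, analytic laws to
  1e−12.

## Problem sizes

Default test and acceptance runs use 53 subjects × 2 sites × 2
timepoints at 500 reads/sample (106k reads per timepoint), with smaller
cohorts (2–10 subjects, 50–300 reads) for oracle-equivalence and law
checks; these sizes exercise every code path while keeping the full
suite in the tens of seconds.
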