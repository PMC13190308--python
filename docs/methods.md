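# Methods

This note documents the models, conventions and design choices behind
`cloneseed`, in the order the pipeline runs.

## Data model and conventions

A patient is a set of *sampling units* (sequenced tumour regions with
tumour of origin, anatomical site, purity ρ ∈ (0,1], ploidy ψ > 0), a set
of *mutation clusters* (per-region CCFs in [0, 1.5], mutation counts), a
ranked ensemble of rooted *clone trees* whose root is the trunk (MRCA),
and allele-specific fractional copy-number *segment profiles* per region.
Conventions that matter downstream:

- Genomic coordinates are 0-based half-open (BED); a `one_based` reader
  flag converts 1-based inclusive input.
- CCF estimates above 1 are tolerated up to 1.5 (noisy estimates), then
  clipped with a warning; the cap is a module constant.
- Dates are integer days since primary surgery (day 0), avoiding calendar
  parsing in a synthetic cohort.
- All tables are tab-separated with `.` for missing values; `segments.tsv`
  carries an optional `major_haplotype` column (A/B) because conserved-LOH
  analysis needs to know *which* parental allele was lost — the major/minor
  decomposition alone cannot distinguish an A-loss from a B-loss, and
  mirrored allelic imbalance would otherwise masquerade as conservation.
- Anatomical sites come from a controlled vocabulary split into
  intrathoracic (mediastinal nodes and soft tissue, lung, lung surgical
  bed, pleura) and extrathoracic (peripheral nodal stations, liver, bone,
  brain, adrenal, and the other distant sites) lists; chest wall and
  diaphragm lesions straddle the pleural boundary and require an
  inside/outside-pleura qualifier, failing loudly without one.

## Subclone architecture

The sum condition (pigeonhole) requires a parent's CCF to cover the sum of
its children's CCFs in every region; the crossing rule forbids a cluster
from descending from one it exceeds in any region (tolerance τ = 0.05 CCF,
configurable, to absorb sampling noise).  `enumerate_trees` generates every
crossing-admissible rooted tree over ≤ 10 clusters (guarded; larger trees
are consumed as input), scores each by the sum condition error and sorts
ascending with a lexicographic edge-list tie-break.  Ties at SCE = 0 are
real — several topologies can satisfy all constraints exactly, which is
precisely why downstream migration probabilities are computed over the
ranked ensemble rather than the single best tree.

Proportions are peeled leaf-to-trunk: a leaf keeps its CCF, an internal
node gets CCF minus the summed child CCFs.  Negative values (sum-condition
violations under noise) are clipped to zero with the residual recorded, so
the identity Σ proportions + Σ residuals = trunk CCF holds exactly per
region.  A subclone at or below 5% in every region is *extinct*; the
comparison carries a 1e-9 float tolerance so exact-boundary inputs behave
as intended.

Presence (for clonality) means detection: more than one mutant read
supporting the cluster in a region, falling back to CCF > 0 with a warning
when no read-support table exists.  Clonality classes aggregate presence
by tumour kind: truncal (the trunk), primary-unique, metastasis-unique,
shared subclonal; driver events, LOH and WGD calls inherit the class of
their assigned cluster.

The biallelic-inactivation test computes the expected VAF of a mutation at
multiplicity m as VAF = m·CCF·ρ / (2(1−ρ) + CN_T·ρ), takes a two-sided
binomial tail (2·CDF or 2·(1−CDF), capped at 1) and applies Holm–Šidák
across all (gene, sample) tests of a patient.  The call direction follows
the source convention — calling "biallelic" where the all-copies-mutated
null is *rejected* at corrected p < 0.05 — which reads as inverted;
`invert_call` flips it, and the default is documented rather than silently
changed.  Dinucleotide variants require a two-proportion z-test that fails
to distinguish the two SNV frequencies (per sample, any sample suffices;
`require_all_samples` available) and ≥ 90% of double-overlapping reads
carrying both alternates in at least one sample.

## Diversity metrics

SNV diversity between two regions is the L1 distance between cluster CCF
vectors, each cluster weighted by its mutation count (equivalent to an
unweighted L1 over per-mutation CCFs; a flag switches to per-cluster
weighting).  The truncal cluster enters only when the MRCA is the seeding
subclone.  SCNA diversity is the segment-length-weighted L1 distance over
the union segmentation of per-allele copy numbers, each divided by the
sample ploidy and rescaled by the diploid reference 2, so that a profile
and its exact whole-genome-doubled counterpart are at distance zero; major
and minor alleles contribute separately (flag to sum).  Both are
pseudometrics and the SCNA metric is invariant to segmentation refinement.
Heterogeneity summaries are means over region pairs: intra-primary,
intra-metastasis, inter-metastasis (multi-region metastases aggregate by
the mean over their region pairs) and primary–metastasis; undefined
summaries are NaN, never zero.

## Migration inference

The refined tree attaches one observation leaf per (cluster, tumour) where
the cluster is *resident* — subclone proportion above the 5% extinction
threshold in at least one region of the tumour, not mere mutation
detection.  The distinction is load-bearing: an ancestor's mutations are
carried by every descendant cell, so its CCF is 1 in tumours its genotype
never inhabited, and detection-based leaves would force one spurious
migration per ancestral cluster along every seeding chain.

Labels are tumours; the root is fixed to the primary and migrations into
the primary are forbidden (the primary is resected before metastatic
relapse).  A Sankoff dynamic program minimises migrations μ; all μ-optimal
labelings are then enumerated (capped at 20,000, deterministic order) and
ranked by γ (distinct ordered source→target pairs — a deliberately coarser
comigration count than the ILP formulation's), then by the number of
cluster vertices labelled with tumours their mutations were never detected
in, then by fewest distinct sources, most primary-labelled vertices, and a
lexicographic label tuple.  The observation-consistency criterion sits
directly after (μ, γ) because the source-count and primary-label
tie-breaks, on their own, collapse genuinely met-to-met chains onto
all-primary labelings that contradict the clusters' own observation
leaves; placing consistency first resolves such chains to the
metastasis-to-metastasis route while leaving genuinely unconstrained
(unobserved) vertices to the later tie-breaks.

Models: `primary_only` restricts sources to the primary; `multi_source` is
unconstrained; `single_source` (each metastasis receives all its
migrations from one source) couples edges globally and is solved exactly
by branch-and-bound over per-metastasis source assignments with the
multi-source Sankoff bound (admissible), exact up to 12 tumours; beyond
that the implementation filters enumerated multi-source optima and reports
infeasibility honestly if none complies.  `select_seeding_model` runs all
three and keeps the smallest μ, breaking ties toward the simpler model.

Polytomy resolution inserts unlabeled intermediate vertices at
multifurcations when that strictly reduces μ: exhaustive over all rooted
binary shapes of the children for degree ≤ 6, greedy best-pairwise-join
beyond; non-contributing intermediates are contracted afterwards so the
output collapses to the input tree when they are removed.  Inserted
vertices carry the polytomy parent's cluster identity, so a migration
through one is attributed to the genotype that actually migrated.

Ensemble probabilities re-run the labeling on each of the ranked trees
(typically the 100 lowest-SCE topologies) and report, per migration, the
fraction of solutions containing it — at (source, target) granularity,
with cluster-level fractions also emitted.  Metastasis-unique clusters the
optimal labeling places in the primary are reclassified as shared
subclonal for downstream analyses.

## Orthogonal validation

Purity adjustment inverts the admixture of one normal copy per allele:
adjusted CN = (observed − (1 − ρ)) / ρ, clipped at zero with a warning
below −0.5.  Clonal LOH is an adjusted allele CN below 0.1; tumour-level
clonal LOH is the intersection over the tumour's regions.  For an inferred
A→B migration, the conserved fraction is |LOH(A) ∩ LOH(B)| / |LOH(A)|
(same allele required) — the denominator is the source's LOH set, since
conservation is a property of what the seeding lineage carried; a source
segment absent from the target is incompatible with the route because LOH
is irreversible.  Detection records assign each tumour its first scan day
(autopsy-only tumours get the midpoint of last scan and death) and a
period class (relapse scan, first/second half of the normalised
post-relapse timeline, autopsy-only).  The validation report compares
conserved fractions along inferred routes against primary-source and
alternative-metastasis-source baselines, and detection-day distributions
of primary- vs metastasis-seeded tumours (Mann–Whitney, one-sided in the
direction the hypotheses specify).

## Seeding statistics

The capacity test statistic is the multinomial log-likelihood ratio
G = 2 Σ oᵢ ln(oᵢ/eᵢ) with eᵢ = n/k; p = (1 + #{G_sim ≥ G_obs}) / (reps + 1)
under an equal-probability multinomial, never exactly zero by the +1
correction, with a 1e-12 slack on the ≥ comparison so maximally even
observed vectors (minimal G) give p = 1.0 on every seed.  The acceptance
script uses 10⁵ replicates; the pipeline uses 10⁴ per patient.

Duration in situ is proxied by the mutations and SCNA breakpoints private
to a metastasis that descend from its seeding subclone(s); SCNA burden per
subclone is the count of copy-number state changes its branch added over
its parent's profile.  The "sufficient duration" threshold is the
per-patient 90th percentile (linear interpolation) of the trunk-to-seeder
mutation path sums over metastasis-to-metastasis seeding subclones — the
source text's "mean of this distribution ... as a patient-specific
threshold" is internally inconsistent (a mean over one number per patient
is the number itself only in the degenerate case), so the percentile is
used directly; a metastasis is sufficient when its total detected mutation
count reaches the threshold (all detected mutations, not private-only; a
flag could restrict this but the inclusive reading matches "total
mutation counts").  Seeder vs non-seeder burden comparisons use
Mann–Whitney within a patient and Wilcoxon signed-rank on per-patient
medians across patients — a stratified nonparametric substitute for the
linear mixed-effects models used in the source analyses, chosen to keep
the package free of random-effects machinery.

## Signature dynamics

Activities are non-negative least-squares coefficients of the normalised
96-channel spectrum on the signature matrix; coefficients sum to ≤ 1 with
the remainder unexplained.  Clusters with ≥ 50 mutations are fitted
directly (bootstrap sd 0); smaller clusters are refitted 1,000 times on
same-size spectra resampled 60/20/20 from the index cluster, a uniform
tree neighbour (parent or children) and a uniform cluster of the same
clonality class, with missing pools reweighted proportionally; mean
activity is reported and clusters with bootstrap sd > 0.1 on ≥ 2
signatures are excluded.  Aetiology groups (clock-like SBS1+SBS5, smoking
SBS4, APOBEC SBS2+SBS13, other SBS17b, platinum SBS31+SBS35 — evaluated
only for platinum-treated patients) are detected at summed activity
≥ 0.06 (inclusive) and called majority above 0.5 (strict).  Episodic
APOBEC on a trunk-to-leaf lineage means trunk-active with ≥ 1 later
emergence, or ≥ 2 emergences, where an emergence is an inactive parent
with an active child.  Cosine distances compare metastasis-unique clusters
among themselves and against ancestral primary clusters.

The signature matrix shipped with the package
(`synthetic_signature_matrix`) is a synthetic stand-in: 96-channel
probability columns drawn once from a sparse Dirichlet with a fixed seed.
It exercises every code path (mixture recovery, resampling, aetiology
calls) but carries no biological content; real analyses must supply a
published SBS catalogue TSV.

## The synthetic cohort generator

The generator's defaults mirror the target cohort's structure: 2–8 primary
regions, 2–37 metastases (capped so each metastasis can own a founding
cluster plus growth), 10–60 clusters, a 0.6 metastasis-to-metastasis
seeding preference, CCF noise sd 0.05 truncated to [0, 1.5].  The tree
grows by uniform attachment — new cluster under a uniform random existing
cluster — producing both linear and branched shapes; seeding events,
spread evenly over the growth steps, create each metastasis's founding
cluster as the child of the migrating subclone.

Design choices that shape what the recovery tests can show:

- **Residency vs detection.** Subclone proportions per region are
  Dirichlet-distributed over the tumour's *resident* clusters (those that
  originated in it); ancestor genotypes have CCF 1 but residency 0 in
  descendant tumours.  Region CCFs are exact mixture sums, so proportions
  and clonality recover exactly at zero noise, and metastasis-level clonal
  LOH reflects the founding lineage rather than collapsing to the trunk.
- **Seeding competence.**  A metastasis becomes a metastasis-to-metastasis
  source only once it carries a private subclone beyond its founder, and
  onward seeding departs from a non-founder subclone.  This mirrors the
  duration-in-situ association and makes the true history identifiable:
  seeding directly from a founder is provably ambiguous under parsimony (a
  primary-source relabeling attains the same μ and γ), so no inference
  method could recover it.  One consequence is that the realised
  metastasis-seeded fraction sits below the nominal 0.6 preference on
  small trees (eligible sources are scarce early); recovery is therefore
  measured against the cohort's realised truth.
- **Monoclonal seeding.**  Each migration carries one subclone; dual-source
  seeding occurs only under the multi-source regime (probability 0.08,
  matching the rarity of dual-seeded metastases); co-migration of several
  subclones into one metastasis is not simulated.  Polyclonal-seeding
  summaries are still computed from inferred histories but the generator
  cannot ground-truth them.
- **Copy number.**  A 10-chromosome, 40-segment diploid template accrues
  per-branch LOH (Poisson, rate 0.5/branch, only on heterozygous segments,
  irreversible by inheritance) and background gains; an optional
  whole-genome doubling doubles a random cluster's profile.  Observed
  region profiles are purity-admixed mixtures (one normal copy per allele),
  so the validation module's purity adjustment inverts them exactly.
- **Detection.**  A tumour's first-detection day is its seeding source's
  day plus an exponential latency (mean 150 days) plus a 30-day floor,
  guaranteeing targets are never detected before their sources and
  reproducing the earlier-detection-of-seeders effect qualitatively,
  without claiming a mechanistic timing model.  Scans run every 90 days
  from relapse to death; tumours past the last scan are autopsy-only.

What passing recovery tests do **not** show: robustness to CCF noise at
realistic depths, to subclone-deconvolution errors upstream, to sampling
bias across anatomical sites, or to polyclonal co-migration — none of
which the generator emulates.

## Problem sizes and numerics

The test suite's recovery cohort is 50 noise-free patients with 10–15
clusters and 2–6 metastases — large enough that migration recovery is
measured over ~190 true edges while the exact branch-and-bound stays
comfortably inside the single-source guard.  The oracle-equivalence check
runs 210 random instances with ≤ 9 refined-tree vertices and ≤ 4 tumours
against full labeling enumeration, cycling the three models.  Type-I
calibration of the capacity test uses 2,000 null datasets (k = 3, n = 30)
at 2,000 Monte Carlo replicates each — resolution 1/2001 is ample at
α = 0.05 — while the headline (2, 2, 1) p-value uses 10⁵ replicates.
Floating-point boundaries carry explicit slack: extinction at 5% + 1e-9,
Monte Carlo tail comparison at G − 1e-12, Fisher small-p enumeration at a
relative 1e-9.

## Known limitations

- The parsimony labeling optimises the same objective as the cited ILP
  approaches but is a different algorithm; γ is counted at (source, target)
  granularity, coarser than the ILP's comigration definition.
- Ensemble probabilities assume the supplied tree ranking is meaningful;
  the generator's perturbation ensemble is a stand-in for a real
  enumeration tool's output.
- Mixed-effects and survival modelling are out of scope; association
  statistics stop at Fisher, chi-squared, rank tests and correlations.
- The single-source branch-and-bound is exponential in the worst case;
  above 12 tumours the implementation degrades gracefully but is no longer
  guaranteed exact.
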