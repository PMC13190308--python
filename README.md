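# cloneseed

Clone-tree analysis of metastatic seeding in multi-tumour cancer cohorts.

Late-stage cancer patients sampled across a multi-region primary tumour and
many metastases (surgical, progression and autopsy specimens) yield, after
variant calling and subclone deconvolution, a compact description of each
patient: mutation clusters with per-region cancer cell fractions (CCFs), a
ranked ensemble of clone trees, and allele-specific copy-number segments.
`cloneseed` turns those tables into the quantities that describe how the
disease spread: which subclones seeded which tumours, whether metastases
seed each other, how strongly anatomy constrains the routes, how long each
metastasis existed before seeding onward, and how mutational processes
shifted along the way.  It is aimed at cancer-genomics analysts working
with multi-region primary and autopsy metastasis cohorts of late-stage NSCLC.

## What it computes

**Subclone architecture.**  A clone tree over mutation clusters must
satisfy the *pigeonhole (sum) condition* — in every region a parent's CCF
is at least the sum of its children's — and the *crossing rule* (a cluster
cannot descend from one it exceeds in any region).  The sum condition error

&nbsp;&nbsp;SCE(T) = Σ_v Σ_r max(0, Σ_{c∈children(v)} CCF(c,r) − CCF(v,r))

ranks candidate topologies; subclone proportions are peeled off the tree
leaf-to-trunk (internal proportion = CCF − Σ children CCF, proportions ≤ 5%
in every region flag an extinct subclone), and clusters classify as
truncal, primary-unique, metastasis-unique or shared subclonal by where
their mutations are detected.

**Migration histories.**  Tumours label the vertices of a *refined* clone
tree (observation leaves pin each cluster to the tumours where it is
resident; inserted vertices resolve polytomies).  A Sankoff-style dynamic
program finds the labeling minimising, lexicographically, migrations μ,
comigrations γ (distinct source→target pairs) and distinct sources, under
three seeding models of increasing complexity — primary-only,
single-source, multi-source — with migrations into the primary forbidden.
The most parsimonious model is selected, and re-running the labeling over
the 100 lowest-SCE trees turns each migration into an ensemble probability.
This is a weighted-parsimony reimplementation of the migration objective of
ILP-based tools, exact for ≤ 12 tumours (branch-and-bound for the
single-source constraint) and verified against exhaustive enumeration.

**Validation and seeding statistics.**  Clonal loss of heterozygosity
(purity-adjusted allele copy number < 0.1) is irreversible, so LOH carried
by a source tumour must be conserved in everything it seeded — an
orthogonal check on every inferred route, alongside radiological
first-detection times.  Seeding subclones are compared with a multinomial
Monte Carlo likelihood-ratio test of equal metastatic capacity; private
mutation/SCNA counts give each metastasis a duration-in-situ surrogate and
a per-patient 90th-percentile "sufficient duration" threshold; migrations
are cross-tabulated by anatomical cavity (intrathoracic vs extrathoracic).

**Signature dynamics.**  Per-cluster trinucleotide spectra are refitted
onto an SBS catalogue by non-negative least squares (clusters under 50
mutations are stabilised by 60/20/20 resampling from the index cluster, a
tree neighbour and a clonality-matched cluster), grouped by aetiology
(clock-like SBS1+5, smoking SBS4, APOBEC SBS2+13, platinum SBS31+35), and
scanned for episodic APOBEC activity — repeated inactive→active
transitions along trunk-to-leaf lineages.

A synthetic cohort generator simulates patients with full ground truth
(tree, proportions, migrations, LOH history, signature exposures,
detection times), so every stage has a recovery test.

## Worked example

Simulate a small noise-free cohort with a 20-tree ensemble per patient and
run the full pipeline:

```bash
cloneseed simulate --out demo_cohort --seed 11 --patients 3 --ensemble 20
cloneseed run --cohort demo_cohort --out demo_out --seed 7
```

(The same cohort is produced in Python with
`SimulationConfig(seed=11, n_clusters=(10, 16), n_metastases=(3, 6),
ccf_noise_sd=0.0, fraction_met_to_met=0.6)`.)  The cohort summary prints:

```
patient_id         model  n_metastases  n_p2m_seeders  n_m2m_seeders  pct_seeded_by_metastasis  capacity_p
    SIM001 single_source             5              2              3                      60.0         1.0
    SIM002 single_source             3              2              1                      33.3         1.0
    SIM003 single_source             5              4              1                      20.0         1.0
```

Per patient: the selected seeding model, the number of primary-to-metastasis
and metastasis-to-metastasis seeding subclones, the share of metastases
seeded by other metastases, and the Monte Carlo p-value for equal seeding
capacity across primary subclones (p = 1.0: seeded counts are compatible
with equal capacity).  `demo_out/SIM001/migrations.tsv` lists each inferred
migration with its ensemble probability:

```
source  target  cluster  probability
M1      M2      C04      0.95
M1      M3      C07      0.95
M2      M4      C09      0.75
P       M1      C02      0.95
P       M5      C12      0.9
```

so metastasis M2 was seeded from metastasis M1 by subclone C04 in 95% of
migration solutions across the tree ensemble.  `threshold_sweep.tsv`
recomputes the metastasis- vs primary-seeded proportions as the
probability threshold rises.

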