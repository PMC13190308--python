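"""Seeding subclones and what distinguishes them.

Subclones inferred to migrate are *seeding* subclones, classified
primary-to-metastasis or metastasis-to-metastasis by their migration's
source; truncal clones are excluded from seeder/non-seeder comparisons.
This module houses the multinomial Monte Carlo test of equal per-subclone
metastatic capacity, the duration-in-situ surrogate (private mutations and
SCNAs accrued after seeding) with its per-patient 'sufficient duration'
threshold, cavity-structured seeding summaries, and per-subclone SCNA-burden
comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort_model import CloneTree, MutationCluster, Segment
from .migration_inference import MigrationHistory

log = logging.getLogger("cloneseed")


# --------------------------------------------------------------------------
# Seeding annotation
# --------------------------------------------------------------------------

@dataclass
class SeedingAnnotation:
    #: cluster -> primary_to_met_seeder | met_to_met_seeder | non_seeding
    cluster_role: dict[str, str]
    #: metastasis -> primary | metastasis | both
    seeded_by: dict[str, str]
    #: metastasis -> does it seed other tumours
    seeds_others: dict[str, bool]
    #: metastasis -> number of distinct incoming migrations
    n_incoming: dict[str, int] = field(default_factory=dict)


def annotate_seeding(
    history: MigrationHistory,
    tree: CloneTree,
    primary: str,
    tumour_kind: dict[str, str],
) -> SeedingAnnotation:
    """Classify clusters and metastases by their role in the inferred
    history.  A cluster that migrates from the primary is a
    primary-to-metastasis seeder; from a metastasis, a
    metastasis-to-metastasis seeder (a cluster doing both is counted with
    its primary role first)."""
    role = {c: "non_seeding" for c in tree.nodes}
    for src, _tgt, cluster in history.migrations:
        if cluster not in role:
            continue
        kind = "primary_to_met_seeder" if src == primary else "met_to_met_seeder"
        if role[cluster] == "non_seeding" or kind == "primary_to_met_seeder":
            role[cluster] = kind

    mets = sorted(t for t, k in tumour_kind.items() if k == "metastasis")
    seeds_others = {m: False for m in mets}
    n_incoming = {m: 0 for m in mets}
    for src, tgt, _ in history.migrations:
        if src in seeds_others:
            seeds_others[src] = True
        if tgt in n_incoming:
            n_incoming[tgt] += 1
    return SeedingAnnotation(
        cluster_role=role,
        seeded_by=dict(history.seeded_by),
        seeds_others=seeds_others,
        n_incoming=n_incoming,
    )


# --------------------------------------------------------------------------
# Metastatic capacity (multinomial Monte Carlo)
# --------------------------------------------------------------------------

def _multinomial_g(counts: np.ndarray) -> float:
    """Log-likelihood-ratio statistic against the equal-probability
    multinomial: G = 2 * sum o_i ln(o_i / e_i), e_i = n / k."""
    n = counts.sum()
    k = len(counts)
    e = n / k
    nz = counts[counts > 0]
    return float(2.0 * np.sum(nz * np.log(nz / e)))


def monte_carlo_capacity_test(
    counts: list[int] | np.ndarray,
    reps: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte Carlo p-value for whether subclones seeded comparable numbers
    of metastases.

    The observed statistic is the multinomial likelihood ratio G against an
    equal-probability null; p = (1 + #{G_sim >= G_obs}) / (reps + 1) over
    simulated equal-probability multinomials.  p > 0.05 indicates
    compatibility with equal seeding probabilities.  Returns NaN for fewer
    than two subclones.
    """
    counts = np.asarray(counts, dtype=float)
    k = len(counts)
    n = int(counts.sum())
    if k < 2:
        return math.nan
    if n < 1:
        raise ValueError("at least one seeded metastasis required")
    if reps < 1:
        raise ValueError("reps must be positive")
    g_obs = _multinomial_g(counts)
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(n, np.full(k, 1.0 / k), size=reps).astype(float)
    e = n / k
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(sims > 0, sims * np.log(sims / e), 0.0)
    g_sim = 2.0 * terms.sum(axis=1)
    hits = int(np.count_nonzero(g_sim >= g_obs - 1e-12))
    return (1 + hits) / (reps + 1)


# --------------------------------------------------------------------------
# Duration in situ
# --------------------------------------------------------------------------

def _breakpoint_count(segments: list[Segment]) -> int:
    """Copy-number state changes between adjacent segments per chromosome."""
    count = 0
    by_chrom: dict[str, list[Segment]] = {}
    for s in sorted(segments, key=lambda s: (s.chrom, s.start)):
        by_chrom.setdefault(s.chrom, []).append(s)
    for segs in by_chrom.values():
        for a, b in zip(segs, segs[1:]):
            if (a.cn_major, a.cn_minor) != (b.cn_major, b.cn_minor):
                count += 1
    return count


def private_breakpoints(
    cluster: str, tree: CloneTree, subclone_profiles: dict[str, list[Segment]]
) -> int:
    """SCNA breakpoints a cluster acquired on its own branch: breakpoints
    of its profile not present in its parent's profile."""
    if cluster not in subclone_profiles:
        return 0
    own = _breakpoint_count(subclone_profiles[cluster])
    par = tree.parent.get(cluster)
    if par is None or par not in subclone_profiles:
        return own
    return max(0, own - _breakpoint_count(subclone_profiles[par]))


def duration_in_situ(
    metastasis: str,
    history: MigrationHistory,
    tree: CloneTree,
    clusters: dict[str, MutationCluster],
    presence_by_tumour: dict[str, set[str]],
    subclone_profiles: dict[str, list[Segment]] | None = None,
) -> tuple[int, int] | None:
    """Mutations and SCNA breakpoints accrued after seeding: counts on
    clusters private to the metastasis that descend from its seeding
    subclone(s).  None when the seeder is unknown."""
    seeders = [c for s, t, c in history.migrations if t == metastasis]
    if not seeders:
        return None
    eligible: set[str] = set()
    for s in seeders:
        if s in tree.nodes:
            eligible |= tree.descendants(s)
    private = {
        c for c in eligible
        if presence_by_tumour.get(c) == {metastasis}
    }
    n_mut = sum(clusters[c].n_mutations for c in private)
    n_scna = sum(
        private_breakpoints(c, tree, subclone_profiles or {}) for c in private
    )
    return n_mut, n_scna


@dataclass
class DurationSurrogate:
    emergence_counts: list[int]          # per met-to-met seeder
    threshold: float | None              # patient-specific mutation threshold
    total_mutations: dict[str, int]      # metastasis -> detected mutations
    sufficient: dict[str, bool | None]   # metastasis -> has 'sufficient' time


def sufficiency_threshold(
    history: MigrationHistory,
    tree: CloneTree,
    clusters: dict[str, MutationCluster],
    presence_by_tumour: dict[str, set[str]],
    tumour_kind: dict[str, str],
    primary: str,
) -> DurationSurrogate:
    """Patient-specific 'sufficient duration in situ' threshold.

    For each metastasis-to-metastasis seeding subclone, the emergence count
    is the mutations accumulated from the trunk to that subclone (inclusive
    path sum); the threshold is the 90th percentile (linear interpolation)
    of these counts.  A metastasis has sufficient time when its total
    detected mutation count reaches the threshold.
    """
    m2m_seeders = sorted(
        {c for s, _t, c in history.migrations if s != primary and c in tree.nodes}
    )
    emergence = []
    for c in m2m_seeders:
        path = [c] + tree.ancestors(c)
        emergence.append(sum(clusters[p].n_mutations for p in path))
    threshold = (
        float(np.percentile(emergence, 90)) if emergence else None
    )
    total = {}
    sufficient: dict[str, bool | None] = {}
    for t, kind in sorted(tumour_kind.items()):
        if kind != "metastasis":
            continue
        detected = [
            c for c, tums in presence_by_tumour.items() if t in tums
        ]
        total[t] = sum(clusters[c].n_mutations for c in detected)
        sufficient[t] = None if threshold is None else total[t] >= threshold
    return DurationSurrogate(
        emergence_counts=emergence,
        threshold=threshold,
        total_mutations=total,
        sufficient=sufficient,
    )


# --------------------------------------------------------------------------
# Cavity structure
# --------------------------------------------------------------------------

@dataclass
class CavitySummary:
    cross_tab: dict[tuple[str, str], int]   # (source cavity, target cavity)
    within_cavity_fraction: float | None
    within_organ_fraction: float | None     # of within-cavity migrations
    per_site_seeding: dict[str, tuple[int, int]]  # site -> (seeding, total mets)


def cavity_summary(
    history: MigrationHistory,
    cavity: dict[str, str],
    site: dict[str, str],
    tumour_kind: dict[str, str],
) -> CavitySummary:
    """Cross-tabulate metastasis-to-metastasis migrations by anatomical
    cavity and summarise per-site seeding prevalence."""
    m2m = sorted(
        {(s, t) for s, t, _ in history.migrations
         if tumour_kind.get(s) == "metastasis"}
    )
    tab: dict[tuple[str, str], int] = {}
    within = within_organ = 0
    for s, t in m2m:
        key = (cavity[s], cavity[t])
        tab[key] = tab.get(key, 0) + 1
        if cavity[s] == cavity[t]:
            within += 1
            if site[s] == site[t]:
                within_organ += 1
    n = len(m2m)
    seeds = {s for s, _ in m2m}
    per_site: dict[str, list[int]] = {}
    for t, kind in tumour_kind.items():
        if kind != "metastasis":
            continue
        rec = per_site.setdefault(site[t], [0, 0])
        rec[1] += 1
        if t in seeds:
            rec[0] += 1
    return CavitySummary(
        cross_tab=tab,
        within_cavity_fraction=(within / n) if n else None,
        within_organ_fraction=(within_organ / within) if within else None,
        per_site_seeding={k: (v[0], v[1]) for k, v in sorted(per_site.items())},
    )


# --------------------------------------------------------------------------
# SCNA burden
# --------------------------------------------------------------------------

@dataclass
class BurdenReport:
    burden: dict[str, int]                  # cluster -> breakpoints
    scna_snv_ratio: dict[str, float]        # cluster -> breakpoints / mutations
    median_by_role: dict[str, float]        # seeder/non-seeder medians
    p_seeder_vs_non: float


def scna_burden_comparison(
    annotation: SeedingAnnotation,
    tree: CloneTree,
    clusters: dict[str, MutationCluster],
    subclone_profiles: dict[str, list[Segment]],
) -> BurdenReport:
    """Per-subclone SCNA burden (branch breakpoints) and acquisition rate
    (SCNA/SNV ratio), compared between seeding and non-seeding subclones
    (truncal clusters excluded) with a Mann-Whitney test."""
    burden = {}
    ratio = {}
    for c in sorted(tree.nodes):
        b = private_breakpoints(c, tree, subclone_profiles)
        burden[c] = b
        ratio[c] = b / max(1, clusters[c].n_mutations)
    non_truncal = [c for c in tree.nodes if c != tree.root]
    seeders = [
        c for c in non_truncal
        if annotation.cluster_role.get(c, "non_seeding") != "non_seeding"
    ]
    non_seeders = [
        c for c in non_truncal
        if annotation.cluster_role.get(c) == "non_seeding"
    ]
    medians = {}
    if seeders:
        medians["seeder"] = float(np.median([burden[c] for c in seeders]))
    if non_seeders:
        medians["non_seeding"] = float(
            np.median([burden[c] for c in non_seeders])
        )
    p = math.nan
    if seeders and non_seeders:
        a = [burden[c] for c in seeders]
        b = [burden[c] for c in non_seeders]
        if len(set(a + b)) > 1:
            p = float(stats.mannwhitneyu(a, b).pvalue)
        else:
            p = 1.0
    return BurdenReport(
        burden=burden,
        scna_snv_ratio=ratio,
        median_by_role=medians,
        p_seeder_vs_non=p,
    )


def paired_burden_test(
    per_patient_medians: list[tuple[float, float]]
) -> float:
    """Wilcoxon signed-rank test on per-patient (seeder, non-seeder) median
    pairs; a stratified nonparametric substitute for mixed-effects
    modelling."""
    diffs = [a - b for a, b in per_patient_medians]
    if not diffs or all(d == 0 for d in diffs):
        return math.nan
    return float(stats.wilcoxon([a for a, _ in per_patient_medians],
                                [b for _, b in per_patient_medians]).pvalue)
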