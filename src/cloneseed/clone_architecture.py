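"""Subclone architecture: tree scoring and enumeration, proportions,
clonality classes, presence, double-nucleotide variants, event timing and
biallelic-inactivation testing.

The clone tree is constrained by two rules.  The *pigeonhole / sum
condition*: in every region a parent's CCF must be at least the sum of its
children's CCFs.  The *crossing rule*: a cluster whose CCF exceeds another's
in one region but is lower in a second region cannot be its descendant.  The
*sum condition error* (SCE) of a topology totals the magnitude of
sum-condition violations across internal nodes and regions; the lowest-SCE
topology is preferred and the ranked ensemble quantifies uncertainty.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .cohort_model import CloneTree, MutationCluster

log = logging.getLogger("cloneseed")

#: Crossing-rule tolerance (CCF units) absorbing sampling noise.
CROSSING_TOLERANCE = 0.05
#: Subclone proportion at or below which a subclone counts as extinct.
EXTINCTION_THRESHOLD = 0.05
#: Minimum mutant reads for a cluster to be called present in a region.
MIN_MUTANT_READS = 2


# --------------------------------------------------------------------------
# Presence
# --------------------------------------------------------------------------

def detect_presence(
    cluster: MutationCluster,
    region_id: str,
    mutant_reads: dict[tuple[str, str], int] | None,
) -> bool:
    """A cluster is present in a region when more than one mutant read
    supports any of its mutations; without read support, fall back to
    CCF > 0 (with a warning, once)."""
    if mutant_reads is not None and (cluster.cluster_id, region_id) in mutant_reads:
        return mutant_reads[(cluster.cluster_id, region_id)] >= MIN_MUTANT_READS
    if mutant_reads is None:
        log.warning(
            "no read-support table; falling back to CCF > 0 for presence"
        )
    return cluster.ccf.get(region_id, 0.0) > 0.0


def presence_table(
    clusters: dict[str, MutationCluster],
    regions: list[str],
    mutant_reads: dict[tuple[str, str], int] | None,
) -> dict[tuple[str, str], bool]:
    return {
        (cid, rid): detect_presence(clusters[cid], rid, mutant_reads)
        for cid in clusters
        for rid in regions
    }


# --------------------------------------------------------------------------
# Tree scoring and enumeration
# --------------------------------------------------------------------------

def score_tree_sce(
    tree: CloneTree, clusters: dict[str, MutationCluster]
) -> float:
    """Sum condition error: sum over internal nodes and regions of the
    excess of summed child CCFs over the parent CCF."""
    kids = tree.children()
    sce = 0.0
    for node, children in kids.items():
        if not children:
            continue
        regions = clusters[node].ccf.keys()
        for r in regions:
            child_sum = sum(clusters[c].ccf.get(r, 0.0) for c in children)
            sce += max(0.0, child_sum - clusters[node].ccf.get(r, 0.0))
    return sce


def _admissible_parents(
    clusters: dict[str, MutationCluster], trunk: str, tol: float
) -> dict[str, list[str]]:
    """For each non-trunk cluster, the nodes that could be its parent
    under the crossing rule (parent CCF >= child CCF - tol in every region)."""
    ids = sorted(clusters)
    out: dict[str, list[str]] = {}
    for child in ids:
        if child == trunk:
            continue
        cands = []
        for parent in ids:
            if parent == child:
                continue
            ok = all(
                clusters[parent].ccf.get(r, 0.0) >= ccf - tol
                for r, ccf in clusters[child].ccf.items()
            )
            if ok:
                cands.append(parent)
        out[child] = cands
    return out


def enumerate_trees(
    clusters: dict[str, MutationCluster],
    max_clusters: int = 10,
    tolerance: float = CROSSING_TOLERANCE,
    max_trees: int = 500_000,
) -> list[CloneTree]:
    """Enumerate every rooted tree over the clusters admissible under the
    crossing rule, scored by SCE and sorted ascending (ties broken by the
    lexicographic edge list).

    Enumeration is exhaustive and guarded: more than ``max_clusters``
    clusters is refused (supply an externally built tree instead).
    """
    if len(clusters) > max_clusters:
        raise ValueError(
            f"{len(clusters)} clusters exceeds the enumeration guard "
            f"({max_clusters}); provide an external tree"
        )
    trunk = next(c.cluster_id for c in clusters.values() if c.is_trunk)
    admissible = _admissible_parents(clusters, trunk, tolerance)
    free = sorted(admissible)
    if any(not admissible[c] for c in free):
        bad = [c for c in free if not admissible[c]]
        log.warning("no admissible parent for clusters %s; no tree exists", bad)
        return []

    results: list[CloneTree] = []
    parent: dict[str, str] = {}

    def creates_cycle(child: str, par: str) -> bool:
        cur = par
        while cur in parent:
            if cur == child:
                return True
            cur = parent[cur]
        return cur == child

    def assign(i: int) -> None:
        if len(results) >= max_trees:
            raise RuntimeError(
                f"admissible tree count exceeds {max_trees}; tighten the "
                f"tolerance or supply an external tree"
            )
        if i == len(free):
            results.append(
                CloneTree(
                    nodes=set(clusters), parent=dict(parent), sce=0.0, rank=0
                )
            )
            return
        child = free[i]
        for par in admissible[child]:
            if creates_cycle(child, par):
                continue
            parent[child] = par
            assign(i + 1)
            del parent[child]

    assign(0)
    for t in results:
        t.sce = score_tree_sce(t, clusters)
    results.sort(key=lambda t: (t.sce, t.edges()))
    for rank, t in enumerate(results, start=1):
        t.rank = rank
    return results


# --------------------------------------------------------------------------
# Subclone proportions
# --------------------------------------------------------------------------

@dataclass
class SubcloneProportions:
    proportion: dict[tuple[str, str], float]  # (cluster, region) -> fraction
    extinct: dict[str, bool]
    residual: dict[tuple[str, str], float] = field(default_factory=dict)


def infer_subclone_proportions(
    tree: CloneTree,
    clusters: dict[str, MutationCluster],
    extinction_threshold: float = EXTINCTION_THRESHOLD,
) -> SubcloneProportions:
    """Peel subclone proportions off the tree, leaves to trunk.

    A leaf's proportion equals its CCF; an internal node's proportion is its
    CCF minus the summed CCFs of its children.  Negative values (sum
    condition violations under noise) are clipped to zero and the residual
    recorded.  A subclone is extinct when its proportion is at or below the
    threshold in every region.
    """
    kids = tree.children()
    regions = sorted({r for c in clusters.values() for r in c.ccf})
    proportion: dict[tuple[str, str], float] = {}
    residual: dict[tuple[str, str], float] = {}
    for node in tree.nodes:
        for r in regions:
            ccf = clusters[node].ccf.get(r, 0.0)
            child_sum = sum(clusters[c].ccf.get(r, 0.0) for c in kids[node])
            raw = ccf - child_sum
            if raw < 0:
                residual[(node, r)] = raw
                raw = 0.0
            proportion[(node, r)] = raw
    extinct = {
        node: all(
            proportion[(node, r)] <= extinction_threshold + 1e-9
            for r in regions
        )
        for node in tree.nodes
    }
    if residual:
        total = sum(residual.values())
        log.info(
            "clipped %d negative proportions (total residual %.4f)",
            len(residual), total,
        )
    return SubcloneProportions(
        proportion=proportion, extinct=extinct, residual=residual
    )


# --------------------------------------------------------------------------
# Clonality
# --------------------------------------------------------------------------

CLONALITY_CLASSES = (
    "truncal", "primary_unique", "metastasis_unique", "shared_subclonal"
)


def classify_clonality(
    tree: CloneTree,
    presence: dict[tuple[str, str], bool],
    region_kinds: dict[str, str],  # region_id -> primary | metastasis
) -> dict[str, str]:
    """Classify every cluster by where it is detected.

    Trunk -> truncal.  Otherwise presence is aggregated to tumour kind:
    detected only in primary regions -> primary_unique; only in metastasis
    regions -> metastasis_unique; in both -> shared_subclonal.  Clusters
    detected nowhere are flagged ``undetected`` and excluded from class
    counts.
    """
    out: dict[str, str] = {}
    for node in sorted(tree.nodes):
        if node == tree.root:
            out[node] = "truncal"
            continue
        in_primary = any(
            flag and region_kinds[r] == "primary"
            for (c, r), flag in presence.items()
            if c == node
        )
        in_met = any(
            flag and region_kinds[r] == "metastasis"
            for (c, r), flag in presence.items()
            if c == node
        )
        if in_primary and in_met:
            out[node] = "shared_subclonal"
        elif in_primary:
            out[node] = "primary_unique"
        elif in_met:
            out[node] = "metastasis_unique"
        else:
            log.warning("cluster %s detected in no region", node)
            out[node] = "undetected"
    return out


def classify_event_timing(
    event_cluster: str, clonality: dict[str, str]
) -> str:
    """An event (driver mutation, LOH, amplification or WGD) inherits the
    clonality class of the cluster it is assigned to."""
    if event_cluster not in clonality:
        raise KeyError(f"event assigned to unknown cluster {event_cluster}")
    return clonality[event_cluster]


# --------------------------------------------------------------------------
# Double nucleotide variants
# --------------------------------------------------------------------------

def call_dnv(
    snv1_counts: list[tuple[int, int]],
    snv2_counts: list[tuple[int, int]],
    both_variant_reads: list[int],
    overlapping_reads: list[int],
    alpha: float = 0.05,
    require_all_samples: bool = False,
) -> bool:
    """Call a dinucleotide variant from two adjacent SNVs.

    Two criteria: (i) a two-sided two-proportion z-test finds the per-sample
    variant frequencies of the two SNVs not significantly different at
    ``alpha`` (any sample suffices by default); and (ii) at least 90% of
    reads overlapping both positions carry both variants in at least one
    sample.
    """
    if len(snv1_counts) != len(snv2_counts):
        raise ValueError("per-sample count lists must align")
    if all(n == 0 for n in overlapping_reads):
        log.warning("no overlapping reads in any sample; not a DNV")
        return False

    similar = []
    for (a1, n1), (a2, n2) in zip(snv1_counts, snv2_counts):
        if n1 == 0 or n2 == 0:
            continue
        if a1 == a2 and n1 == n2:
            similar.append(True)
            continue
        _, p = proportions_ztest([a1, a2], [n1, n2])
        similar.append(bool(np.isnan(p)) or p >= alpha)
    if not similar:
        return False
    freq_ok = all(similar) if require_all_samples else any(similar)

    phase_ok = any(
        n > 0 and b / n >= 0.9
        for b, n in zip(both_variant_reads, overlapping_reads)
    )
    return bool(freq_ok and phase_ok)


# --------------------------------------------------------------------------
# Biallelic inactivation of tumour suppressors
# --------------------------------------------------------------------------

@dataclass
class BiallelicTestInput:
    """One sample-level test of whether all remaining copies of a tumour
    suppressor carry the mutation (null hypothesis: m = CN_T in LOH
    regions)."""

    rho: float           # tumour purity
    ccf: float           # cancer cell fraction of the mutation
    cn_t: float          # tumour copy number at the locus
    m: float             # mutation multiplicity
    alt_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if not (0 < self.rho <= 1):
            raise ValueError(f"purity {self.rho} outside (0, 1]")
        if self.alt_reads > self.total_reads:
            raise ValueError("alt_reads exceeds total_reads")


def expected_vaf(rho: float, ccf: float, cn_t: float, m: float) -> float:
    """Expected variant allele frequency of a mutation at multiplicity m."""
    return (m * ccf * rho) / (2 * (1 - rho) + cn_t * rho)


def test_biallelic(inp: BiallelicTestInput) -> float:
    """Two-sided binomial p-value against the all-copies-mutated null.

    p = 2*CDF when CDF < 0.5, else 2*(1-CDF), capped at 1, where the CDF is
    the binomial CDF at ``alt_reads`` with n = ``total_reads`` and success
    probability the expected VAF.
    """
    p_exp = expected_vaf(inp.rho, inp.ccf, inp.cn_t, inp.m)
    if not (0.0 < p_exp < 1.0):
        raise ValueError(
            f"expected VAF {p_exp:.4f} outside (0, 1); "
            f"inputs rho={inp.rho} ccf={inp.ccf} cn_t={inp.cn_t} m={inp.m}"
        )
    cdf = stats.binom.cdf(inp.alt_reads, inp.total_reads, p_exp)
    p = 2 * cdf if cdf < 0.5 else 2 * (1 - cdf)
    return float(min(1.0, p))


def test_biallelic_family(
    inputs: dict[str, BiallelicTestInput],
    alpha: float = 0.05,
    invert_call: bool = False,
) -> dict[str, tuple[float, bool]]:
    """Apply the biallelic test across a family of (gene, sample) inputs with
    Holm-Sidak correction; a gene/sample is called biallelic when the
    corrected p is below ``alpha``.

    Note the call direction follows the source convention of calling at
    P < 0.05, i.e. rejecting the all-copies-mutated null; ``invert_call``
    flips it so that *compatibility* with the null is called instead.
    """
    keys = sorted(inputs)
    raw = [test_biallelic(inputs[k]) for k in keys]
    if not raw:
        return {}
    reject, corrected, _, _ = multipletests(raw, alpha=alpha, method="holm-sidak")
    out = {}
    for k, p, rej in zip(keys, corrected, reject):
        call = (not rej) if invert_call else bool(rej)
        out[k] = (float(p), call)
    return out


# --------------------------------------------------------------------------
# Brute-force oracle (testing aid): all labelled rooted trees
# --------------------------------------------------------------------------

def brute_force_admissible_trees(
    clusters: dict[str, MutationCluster],
    tolerance: float = CROSSING_TOLERANCE,
) -> list[frozenset[tuple[str, str]]]:
    """Independent generator of all labelled rooted trees over the clusters
    (trunk-rooted), filtered by the crossing rule.  Exponential; intended
    for cross-checking :func:`enumerate_trees` on <= 6 clusters."""
    trunk = next(c.cluster_id for c in clusters.values() if c.is_trunk)
    others = sorted(set(clusters) - {trunk})
    all_nodes = [trunk] + others
    out = []
    for parents in itertools.product(all_nodes, repeat=len(others)):
        mapping = dict(zip(others, parents))
        if any(child == par for child, par in mapping.items()):
            continue
        # rootedness: every node must reach trunk
        ok = True
        for n in others:
            seen = set()
            cur = n
            while cur != trunk:
                if cur in seen or cur not in mapping:
                    ok = False
                    break
                seen.add(cur)
                cur = mapping[cur]
            if not ok:
                break
        if not ok:
            continue
        # crossing rule
        for child, par in mapping.items():
            for r, ccf in clusters[child].ccf.items():
                if clusters[par].ccf.get(r, 0.0) < ccf - tolerance:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            out.append(frozenset((p, c) for c, p in mapping.items()))
    return out
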