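"""Pairwise genomic diversity between tumour regions.

Two pseudometrics: an SNV distance (mutation-count-weighted L1 norm between
cluster CCF vectors) and an SCNA distance (segment-length-weighted L1 norm
between ploidy-normalised allele-specific copy numbers over the union
segmentation).  Four per-patient heterogeneity summaries average these over
region pairs: intra-primary, intra-metastasis, inter-metastasis and
primary-metastasis.
"""

from __future__ import annotations

import itertools
import math

from .cohort_model import MutationCluster, Patient, Segment, SegmentProfile


def snv_diversity(
    region_a: str,
    region_b: str,
    clusters: dict[str, MutationCluster],
    mrca_seeds: bool = False,
    weight_by_mutations: bool = True,
) -> float:
    """Weighted L1 distance between the CCF vectors of two regions.

    Each cluster contributes |CCF_a - CCF_b|, weighted by its mutation count
    (equivalent to an unweighted L1 over per-mutation CCFs; set
    ``weight_by_mutations=False`` for the per-cluster variant).  The truncal
    cluster is included only when ``mrca_seeds`` is set — truncal events are
    shared by construction and only discriminate when the MRCA itself is the
    seeding subclone.
    """
    total = 0.0
    for c in clusters.values():
        if c.is_trunk and not mrca_seeds:
            continue
        w = c.n_mutations if weight_by_mutations else 1.0
        total += w * abs(c.ccf.get(region_a, 0.0) - c.ccf.get(region_b, 0.0))
    return total


def _union_breakpoints(segs_a: list[Segment], segs_b: list[Segment]):
    """Per chromosome, the joint breakpoint grid of two profiles restricted
    to positions covered by both."""
    chroms_a = {s.chrom for s in segs_a}
    chroms_b = {s.chrom for s in segs_b}
    chroms = chroms_a & chroms_b
    if not chroms:
        raise ValueError("profiles share no chromosomes")
    by_a = {c: [s for s in segs_a if s.chrom == c] for c in chroms}
    by_b = {c: [s for s in segs_b if s.chrom == c] for c in chroms}
    out = []
    for chrom in sorted(chroms):
        points = sorted(
            {s.start for s in by_a[chrom]} | {s.end for s in by_a[chrom]}
            | {s.start for s in by_b[chrom]} | {s.end for s in by_b[chrom]}
        )
        for lo, hi in zip(points, points[1:]):
            sa = next((s for s in by_a[chrom] if s.start <= lo and s.end >= hi), None)
            sb = next((s for s in by_b[chrom] if s.start <= lo and s.end >= hi), None)
            if sa is not None and sb is not None:
                out.append((hi - lo, sa, sb))
    return out


def scna_diversity(
    profile_a: SegmentProfile,
    profile_b: SegmentProfile,
    ploidy_a: float,
    ploidy_b: float,
    sum_alleles: bool = False,
) -> float:
    """Segment-length-weighted L1 distance between allele-specific copy
    numbers, normalised by sample ploidy.

    Copy numbers are divided by the sample ploidy and rescaled by the
    diploid reference (2), so a profile and its exact whole-genome-doubled
    counterpart are at distance zero.  Major and minor alleles contribute
    separately unless ``sum_alleles`` is set.
    """
    pieces = _union_breakpoints(profile_a.segments, profile_b.segments)
    total_len = sum(length for length, _, _ in pieces)
    if total_len == 0:
        return 0.0
    dist = 0.0
    for length, sa, sb in pieces:
        w = length / total_len
        da = sa.cn_major / ploidy_a - sb.cn_major / ploidy_b
        db = sa.cn_minor / ploidy_a - sb.cn_minor / ploidy_b
        if sum_alleles:
            dist += w * abs(da + db) * 2.0
        else:
            dist += w * (abs(da) + abs(db)) * 2.0
    return dist


def heterogeneity_summary(
    patient: Patient,
    pair_values: dict[frozenset[str], float],
) -> dict[str, float]:
    """Per-patient heterogeneity means from a region-pair distance table.

    Returns ``intra_primary``, ``intra_metastasis``, ``inter_metastasis``
    and ``primary_metastasis``; undefined summaries (too few regions or
    metastases) come back as NaN, never zero.  Multi-region metastases enter
    the inter-metastasis mean through the mean over their region pairs.
    """
    tumours = patient.tumours()
    primary = patient.primary_tumour
    kinds = {t: patient.tumour_kind(t) for t in tumours}
    mets = sorted(t for t in tumours if kinds[t] == "metastasis")

    def get(a: str, b: str) -> float:
        return pair_values[frozenset((a, b))]

    def mean(values: list[float]) -> float:
        return sum(values) / len(values) if values else math.nan

    primary_regions = tumours.get(primary, [])
    intra_primary = mean(
        [get(a, b) for a, b in itertools.combinations(primary_regions, 2)]
    )

    intra_met_values = []
    for m in mets:
        for a, b in itertools.combinations(tumours[m], 2):
            intra_met_values.append(get(a, b))
    intra_metastasis = mean(intra_met_values)

    inter_values = []
    for m1, m2 in itertools.combinations(mets, 2):
        cross = [get(a, b) for a in tumours[m1] for b in tumours[m2]]
        inter_values.append(mean(cross))
    inter_metastasis = mean(inter_values)

    pm_values = [
        get(a, b)
        for a in primary_regions
        for m in mets
        for b in tumours[m]
    ]
    primary_metastasis = mean(pm_values)

    return {
        "intra_primary": intra_primary,
        "intra_metastasis": intra_metastasis,
        "inter_metastasis": inter_metastasis,
        "primary_metastasis": primary_metastasis,
    }


def diversity_matrices(
    patient: Patient, mrca_seeds: bool = False
) -> dict[str, dict[frozenset[str], float]]:
    """All pairwise SNV and (where segment profiles exist) SCNA distances."""
    regions = sorted(patient.sampling_units)
    snv = {
        frozenset((a, b)): snv_diversity(a, b, patient.clusters, mrca_seeds)
        for a, b in itertools.combinations(regions, 2)
    }
    out = {"snv": snv}
    if patient.segment_profiles:
        covered = [r for r in regions if r in patient.segment_profiles]
        scna = {}
        for a, b in itertools.combinations(covered, 2):
            scna[frozenset((a, b))] = scna_diversity(
                patient.segment_profiles[a],
                patient.segment_profiles[b],
                patient.sampling_units[a].ploidy,
                patient.sampling_units[b].ploidy,
            )
        out["scna"] = scna
    return out
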