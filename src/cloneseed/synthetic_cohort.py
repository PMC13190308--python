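"""Synthetic multi-tumour cohorts with known ground truth.

The generator emulates the data structure of a late-stage NSCLC autopsy
cohort: a multi-region primary tumour plus anatomically labelled metastases,
a clone tree over mutation clusters obeying the pigeonhole and crossing
constraints, per-region CCFs (exact mixtures of true subclone proportions,
optionally with truncated-normal noise), irreversible clonal LOH accumulating
along branches, ground-truth migrations under three seeding regimes,
per-cluster mutational-signature activity with optional episodic APOBEC, and
radiological first-detection times with an exponential post-seeding latency.

Two modelling choices shape migration identifiability: a metastasis becomes
a competent metastasis-to-metastasis source only once it carries at least
one private subclone beyond its founder, and onward seeding departs from a
non-founder subclone.  Without them, seeding straight from a founder is
provably ambiguous under parsimony (a primary-source relabeling attains the
same migration count), so no method could recover it; with them the true
history is the unique parsimony optimum in the noise-free limit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .clone_architecture import score_tree_sce
from .cohort_model import (
    CloneTree,
    EXTRATHORACIC_SITES,
    INTRATHORACIC_SITES,
    MutationCluster,
    Patient,
    SamplingUnit,
    Segment,
    SegmentProfile,
    validate_patient,
    write_patient,
)

log = logging.getLogger("cloneseed")

#: Default NSCLC signature set.
NSCLC_SIGNATURES = (
    "SBS1", "SBS2", "SBS4", "SBS5", "SBS13", "SBS17b", "SBS31", "SBS35"
)

#: Genome template: (chromosome, number of segments, segment length in bp).
GENOME_TEMPLATE = [(str(c), 4, 10_000_000) for c in range(1, 11)]

#: Trinucleotide contexts are represented positionally (96 channels).
N_CONTEXTS = 96

#: Probability that a metastasis is seeded by a second source under the
#: multi-source regime (the study observed 4/258 dual-seeded metastases).
P_DUAL_SOURCE = 0.08


@dataclass
class SimulationConfig:
    """Knobs of the generative model; defaults mirror the cohort structure
    the pipeline targets (2-8 primary regions, 2-37 metastases, 10-60
    mutation clusters)."""

    seed: int = 0
    n_primary_regions: tuple[int, int] = (2, 8)
    n_metastases: tuple[int, int] = (2, 37)
    n_clusters: tuple[int, int] = (10, 60)
    seeding_model: str = "multi_source"
    fraction_met_to_met: float = 0.6
    ccf_noise_sd: float = 0.05
    mean_mutations_per_cluster: float = 40.0
    loh_rate_per_branch: float = 0.5
    gain_rate_per_branch: float = 0.5
    p_extrathoracic_exit: float = 0.25
    signature_set: tuple[str, ...] = NSCLC_SIGNATURES
    episodic_apobec: bool = True

    def __post_init__(self) -> None:
        for name in ("n_primary_regions", "n_metastases", "n_clusters"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name}: empty range ({lo}, {hi})")
        for name in ("fraction_met_to_met", "ccf_noise_sd",
                     "p_extrathoracic_exit"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.seeding_model not in ("primary_only", "single_source",
                                      "multi_source"):
            raise ValueError(f"unknown seeding model {self.seeding_model!r}")
        if self.seeding_model == "primary_only" and self.fraction_met_to_met > 0:
            raise ValueError(
                "fraction_met_to_met > 0 is infeasible under primary_only"
            )


@dataclass
class GroundTruth:
    true_tree: CloneTree
    true_origin: dict[str, str]                     # cluster -> tumour
    true_proportions: dict[tuple[str, str], float]  # (cluster, region)
    true_migrations: list[tuple[str, str, str]]     # (source, target, cluster)
    true_loh_history: dict[tuple[str, int, str], str]  # (chrom, start, hap) -> cluster
    true_signature_activity: dict[str, dict[str, float]]
    true_detection_day: dict[str, float]
    seeding_model: str = "multi_source"

    def met_to_met_fraction(self) -> float | None:
        """Fraction of metastases whose seeding involves a metastasis
        source (dual-seeded metastases count toward the metastasis side).

        Every migration target is a metastasis, so a source is itself a
        metastasis exactly when it appears among the targets."""
        targets: dict[str, set[str]] = {}
        for src, tgt, _ in self.true_migrations:
            targets.setdefault(tgt, set()).add(src)
        if not targets:
            return None
        met_seeded = sum(
            1 for srcs in targets.values() if any(s in targets for s in srcs)
        )
        return met_seeded / len(targets)


# --------------------------------------------------------------------------
# Signature matrix (synthetic stand-in for a COSMIC-style SBS catalogue)
# --------------------------------------------------------------------------

def synthetic_signature_matrix(
    signatures: tuple[str, ...] = NSCLC_SIGNATURES, seed: int = 2024
) -> pd.DataFrame:
    """A synthetic 96-context x signature probability matrix.

    Columns are probability vectors over the 96 trinucleotide channels,
    drawn once from a sparse Dirichlet with a fixed seed so the matrix is
    reproducible.  This is a stand-in catalogue for testing and simulation;
    real analyses should load a published SBS matrix TSV instead.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    for sig in signatures:
        w = rng.dirichlet(np.full(N_CONTEXTS, 0.3))
        cols[sig] = w
    idx = [f"ctx{i:02d}" for i in range(N_CONTEXTS)]
    return pd.DataFrame(cols, index=idx)


# --------------------------------------------------------------------------
# Patient simulation
# --------------------------------------------------------------------------

def _rand_range(rng, pair):
    lo, hi = pair
    return int(rng.integers(lo, hi + 1))


def _sample_site(rng, cavity: str) -> str:
    pool = sorted(
        INTRATHORACIC_SITES if cavity == "intrathoracic"
        else EXTRATHORACIC_SITES
    )
    return str(rng.choice(pool))


def simulate_patient(
    config: SimulationConfig, patient_id: str = "SIM001"
) -> tuple[Patient, GroundTruth]:
    """Simulate one patient and its ground truth.

    The clone tree grows by uniform attachment (new cluster under a uniform
    random existing cluster), interleaved with seeding events that each
    create a metastasis's founding cluster as the child of the migrating
    subclone.  Per-region CCFs are exact mixtures of Dirichlet-distributed
    subclone proportions, with optional truncated-normal noise.
    """
    rng = np.random.default_rng(config.seed)
    n_primary_regions = _rand_range(rng, config.n_primary_regions)
    n_clusters = _rand_range(rng, config.n_clusters)
    n_mets = _rand_range(rng, config.n_metastases)
    # every metastasis consumes a founding cluster and met-to-met sources
    # need room for a private subclone, so cap the metastasis count
    n_mets = max(1, min(n_mets, (n_clusters - 2) // 2))

    primary = "P"
    mets = [f"M{i + 1}" for i in range(n_mets)]

    # --- grow the clone tree and the migration history together ----------
    trunk = "C01"
    clusters_order = [trunk]
    parent: dict[str, str] = {}
    origin: dict[str, str] = {trunk: primary}
    migrations: list[tuple[str, str, str]] = []
    founder: dict[str, str] = {}   # tumour -> founding cluster
    own: dict[str, list[str]] = {primary: [trunk]}  # tumour -> origin clusters

    # choose the creation steps at which metastases are seeded (spread out
    # so early metastases can accrue private subclones before seeding on)
    seed_steps = set(
        np.linspace(1, n_clusters - 1, n_mets, dtype=int).tolist()
    )

    def new_id() -> str:
        return f"C{len(clusters_order) + 1:02d}"

    met_queue = list(mets)
    for step in range(1, n_clusters):
        seeding = bool(seed_steps & {step}) and met_queue
        if seeding:
            target = met_queue.pop(0)
            eligible = [
                m for m in mets
                if m in founder and len(own[m]) >= 2
            ]
            use_met = (
                config.seeding_model != "primary_only"
                and eligible
                and rng.random() < config.fraction_met_to_met
            )
            if use_met:
                source = str(rng.choice(eligible))
                non_founders = [c for c in own[source] if c != founder[source]]
                src_cluster = str(rng.choice(non_founders))
            else:
                source = primary
                src_cluster = str(rng.choice(own[primary]))
            child = new_id()
            clusters_order.append(child)
            parent[child] = src_cluster
            origin[child] = target
            founder[target] = child
            own[target] = [child]
            migrations.append((source, target, src_cluster))
            # occasional dual-source seeding under the multi-source regime
            if (
                config.seeding_model == "multi_source"
                and rng.random() < P_DUAL_SOURCE
                and len(clusters_order) < n_clusters
            ):
                others = [
                    m for m in eligible if m != source
                ] or ([primary] if source != primary else [])
                if others:
                    source2 = str(rng.choice(others))
                    if source2 == primary:
                        src2 = str(rng.choice(own[primary]))
                    else:
                        nf = [c for c in own[source2] if c != founder[source2]]
                        src2 = str(rng.choice(nf))
                    child2 = new_id()
                    clusters_order.append(child2)
                    parent[child2] = src2
                    origin[child2] = target
                    own[target].append(child2)
                    migrations.append((source2, target, src2))
        else:
            attach = str(rng.choice(clusters_order))
            child = new_id()
            clusters_order.append(child)
            parent[child] = attach
            origin[child] = origin[attach]
            own[origin[attach]].append(child)

    tree = CloneTree(
        nodes=set(clusters_order), parent=dict(parent), sce=0.0, rank=1
    )
    seeded_mets = sorted(founder)
    tumours = [primary] + seeded_mets

    # --- sampling units ---------------------------------------------------
    units: dict[str, SamplingUnit] = {}
    region_of_tumour: dict[str, list[str]] = {}
    primary_site = "lung"
    for i in range(n_primary_regions):
        rid = f"P_R{i + 1}"
        units[rid] = SamplingUnit(
            region_id=rid, tumour_id=primary, tumour_kind="primary",
            anatomical_site=primary_site,
            purity=float(rng.uniform(0.4, 0.95)), ploidy=2.0,
            collection="surgery",
        )
        region_of_tumour.setdefault(primary, []).append(rid)
    met_cavity: dict[str, str] = {}
    for m in seeded_mets:
        src = next(s for s, t, _ in migrations if t == m)
        src_cavity = met_cavity.get(src, "intrathoracic")
        crosses = rng.random() < config.p_extrathoracic_exit
        cavity = (
            ("extrathoracic" if src_cavity == "intrathoracic"
             else "intrathoracic")
            if crosses else src_cavity
        )
        met_cavity[m] = cavity
        site = _sample_site(rng, cavity)
        for i in range(int(rng.integers(1, 4))):
            rid = f"{m}_R{i + 1}"
            units[rid] = SamplingUnit(
                region_id=rid, tumour_id=m, tumour_kind="metastasis",
                anatomical_site=site,
                purity=float(rng.uniform(0.4, 0.95)), ploidy=2.0,
                collection="autopsy",
            )
            region_of_tumour.setdefault(m, []).append(rid)

    # --- subclone membership and per-region proportions -------------------
    def path_to_root(c: str) -> list[str]:
        out = [c]
        while out[-1] in parent:
            out.append(parent[out[-1]])
        return out

    in_tumour: dict[str, list[str]] = {}
    for t in tumours:
        members: set[str] = set()
        for c in own[t]:
            members.update(path_to_root(c))
        in_tumour[t] = [c for c in clusters_order if c in members]

    n_mut = {
        c: max(1, int(rng.poisson(config.mean_mutations_per_cluster)))
        for c in clusters_order
    }
    n_mut[trunk] = max(n_mut[trunk], int(config.mean_mutations_per_cluster * 3))

    # Cell populations of a tumour are the clusters that originated in it:
    # ancestor genotypes reside in the tumours where they arose, so their
    # CCF is 1 in descendant-bearing regions while their resident
    # proportion there is 0.  This keeps metastasis-level clonal LOH
    # informative (it reflects the founding lineage, not the trunk alone).
    proportions: dict[tuple[str, str], float] = {}
    ccf_true: dict[tuple[str, str], float] = {}
    subtree_cache: dict[str, set[str]] = {
        c: {c} | tree.descendants(c) for c in clusters_order
    }
    for t in tumours:
        residents = own[t]
        for rid in region_of_tumour[t]:
            props = rng.dirichlet(np.full(len(residents), 1.0))
            weight = dict(zip(residents, props))
            for c in in_tumour[t]:
                proportions[(c, rid)] = float(weight.get(c, 0.0))
            for c in clusters_order:
                sub = subtree_cache[c]
                ccf_true[(c, rid)] = float(
                    sum(p for m, p in zip(residents, props) if m in sub)
                )

    all_regions = sorted(units)
    clusters: dict[str, MutationCluster] = {}
    for c in clusters_order:
        ccf_obs = {}
        for rid in all_regions:
            v = ccf_true.get((c, rid), 0.0)
            if config.ccf_noise_sd > 0 and v > 0:
                v = float(
                    np.clip(rng.normal(v, config.ccf_noise_sd), 0.0, 1.5)
                )
            ccf_obs[rid] = v
        clusters[c] = MutationCluster(
            cluster_id=c, ccf=ccf_obs, n_mutations=n_mut[c],
            is_trunk=(c == trunk),
        )

    # mutant read support reflects true presence (CCF > 0 <=> >= 2 reads)
    mutant_reads = {
        (c, rid): (
            0 if ccf_true.get((c, rid), 0.0) <= 0
            else max(2, int(round(50 * ccf_true[(c, rid)])))
        )
        for c in clusters_order
        for rid in all_regions
    }

    # --- copy number: irreversible LOH plus background gains ---------------
    seg_keys = [
        (chrom, i * seg_len, (i + 1) * seg_len)
        for chrom, n_segs, seg_len in GENOME_TEMPLATE
        for i in range(n_segs)
    ]
    base_profile = {key: {"A": 1.0, "B": 1.0} for key in seg_keys}
    cn: dict[str, dict] = {}
    loh_history: dict[tuple[str, int, str], str] = {}
    wgd_calls: list[str] = []
    wgd_cluster = (
        str(rng.choice(clusters_order)) if rng.random() < 0.3 else None
    )
    for c in clusters_order:  # creation order = parents before children
        prof = (
            {k: dict(v) for k, v in base_profile.items()}
            if c == trunk
            else {k: dict(v) for k, v in cn[parent[c]].items()}
        )
        if c == wgd_cluster:
            for v in prof.values():
                v["A"] *= 2
                v["B"] *= 2
            wgd_calls.append(c)
        for _ in range(int(rng.poisson(config.loh_rate_per_branch))):
            candidates = [
                (k, hap)
                for k in seg_keys
                for hap in ("A", "B")
                if prof[k][hap] > 0 and prof[k]["A" if hap == "B" else "B"] > 0
            ]
            if not candidates:
                break
            k, hap = candidates[int(rng.integers(len(candidates)))]
            prof[k][hap] = 0.0
            loh_history[(k[0], k[1], hap)] = c
        for _ in range(int(rng.poisson(config.gain_rate_per_branch))):
            k = seg_keys[int(rng.integers(len(seg_keys)))]
            hap = str(rng.choice(["A", "B"]))
            if prof[k][hap] > 0:
                prof[k][hap] += 1
        cn[c] = prof

    subclone_profiles: dict[str, list[Segment]] = {}
    for c in clusters_order:
        segs = []
        for (chrom, start, end) in seg_keys:
            a, b = cn[c][(chrom, start, end)]["A"], cn[c][(chrom, start, end)]["B"]
            segs.append(
                Segment(
                    chrom=chrom, start=start, end=end,
                    cn_major=max(a, b), cn_minor=min(a, b),
                    major_haplotype="A" if a >= b else "B",
                )
            )
        subclone_profiles[c] = segs

    profiles: dict[str, SegmentProfile] = {}
    total_len = sum(e - s for _, s, e in seg_keys)
    for t in tumours:
        for rid in region_of_tumour[t]:
            rho = units[rid].purity
            segs = []
            ploidy_num = 0.0
            for (chrom, start, end) in seg_keys:
                a = sum(
                    proportions[(c, rid)] * cn[c][(chrom, start, end)]["A"]
                    for c in in_tumour[t]
                )
                b = sum(
                    proportions[(c, rid)] * cn[c][(chrom, start, end)]["B"]
                    for c in in_tumour[t]
                )
                ploidy_num += (a + b) * (end - start)
                obs_a = rho * a + (1 - rho) * 1.0
                obs_b = rho * b + (1 - rho) * 1.0
                segs.append(
                    Segment(
                        chrom=chrom, start=start, end=end,
                        cn_major=max(obs_a, obs_b), cn_minor=min(obs_a, obs_b),
                        major_haplotype="A" if obs_a >= obs_b else "B",
                    )
                )
            units[rid].ploidy = float(ploidy_num / total_len)
            profiles[rid] = SegmentProfile(region_id=rid, segments=segs)

    # --- mutational signatures --------------------------------------------
    sig_matrix = synthetic_signature_matrix(tuple(config.signature_set))
    platinum_treated = bool(rng.random() < 0.5)
    activity = _simulate_signature_activity(
        rng, tree, clusters_order, origin, primary,
        list(config.signature_set), config.episodic_apobec, platinum_treated,
    )
    ctx_rows = {}
    for c in clusters_order:
        mix = np.zeros(N_CONTEXTS)
        for sig, a in activity[c].items():
            mix += a * sig_matrix[sig].to_numpy()
        mix = mix / mix.sum()
        ctx_rows[c] = rng.multinomial(n_mut[c], mix)
    context_counts = pd.DataFrame.from_dict(
        ctx_rows, orient="index", columns=list(sig_matrix.index)
    )
    context_counts.index.name = "cluster_id"

    # --- detection times and scans -----------------------------------------
    detection: dict[str, float] = {primary: 0.0}
    for src, tgt, _ in migrations:
        if tgt in detection:
            continue
        base = detection.get(src, 0.0)
        detection[tgt] = base + float(rng.exponential(150.0)) + 30.0
    relapse_day = int(min(detection[m] for m in seeded_mets)) if seeded_mets else 360
    death_day = int(max(detection.values())) + int(rng.integers(90, 240))
    scan_days = list(range(relapse_day, death_day, 90))
    scan_records = [
        (
            day,
            tuple(
                m for m in seeded_mets if detection[m] <= day
            ),
        )
        for day in scan_days
    ]

    # --- driver events (plumbing for timing classification) ----------------
    driver_events = []
    driver_pool = ["TP53", "KRAS", "EGFR", "STK11", "KEAP1", "SMARCA4"]
    for gene in driver_pool[: int(rng.integers(2, 5))]:
        cid = str(rng.choice(clusters_order))
        kind = str(rng.choice(["mutation", "amplification", "loh"]))
        driver_events.append((gene, kind, cid))

    patient = Patient(
        patient_id=patient_id,
        sampling_units=units,
        clusters=clusters,
        trees=[tree],
        segment_profiles=profiles,
        subclone_profiles=subclone_profiles,
        wgd_calls=wgd_calls,
        driver_events=driver_events,
        scan_records=scan_records,
        mutant_reads=mutant_reads,
        context_counts=context_counts,
        surgery_day=0,
        relapse_day=relapse_day,
        death_day=death_day,
        platinum_treated=platinum_treated,
    )
    validate_patient(patient)

    truth = GroundTruth(
        true_tree=tree,
        true_origin=origin,
        true_proportions=proportions,
        true_migrations=sorted(migrations),
        true_loh_history=loh_history,
        true_signature_activity=activity,
        true_detection_day=detection,
        seeding_model=config.seeding_model,
    )
    return patient, truth


def _simulate_signature_activity(
    rng, tree, clusters_order, origin, primary, signatures,
    episodic_apobec, platinum_treated,
):
    """Exposures evolve along the tree: clock-like plus smoking at the
    trunk, APOBEC toggling on and off along branches when episodic activity
    is enabled, platinum signatures added to metastasis clusters of treated
    patients."""
    has = set(signatures)
    activity: dict[str, dict[str, float]] = {}
    apobec_state: dict[str, bool] = {}
    for c in clusters_order:
        if c not in tree.parent:  # trunk
            exp = {}
            if "SBS1" in has:
                exp["SBS1"] = 0.15
            if "SBS5" in has:
                exp["SBS5"] = 0.35
            if "SBS4" in has:
                exp["SBS4"] = 0.5
            apobec_state[c] = bool(
                episodic_apobec and rng.random() < 0.3
            )
        else:
            par = tree.parent[c]
            exp = dict(activity[par])
            exp.pop("SBS2", None)
            exp.pop("SBS13", None)
            exp.pop("SBS31", None)
            exp.pop("SBS35", None)
            state = apobec_state[par]
            if episodic_apobec:
                if state and rng.random() < 0.35:
                    state = False
                elif not state and rng.random() < 0.2:
                    state = True
            apobec_state[c] = state
        if apobec_state[c] and "SBS2" in has and "SBS13" in has:
            exp["SBS2"] = 0.2
            exp["SBS13"] = 0.2
        if (
            platinum_treated
            and origin[c] != primary
            and "SBS31" in has
        ):
            exp["SBS31"] = 0.25
        total = sum(exp.values())
        activity[c] = {s: v / total for s, v in exp.items()}
    return activity


# --------------------------------------------------------------------------
# Tree ensembles
# --------------------------------------------------------------------------

def simulate_tree_ensemble(
    truth: GroundTruth,
    k: int,
    clusters: dict[str, MutationCluster],
    seed: int = 0,
) -> list[CloneTree]:
    """The true tree plus ``k - 1`` perturbed topologies, each scored by SCE
    on the supplied (possibly noisy) CCFs and sorted ascending.

    Perturbations reattach a random non-trunk cluster below a random
    non-descendant; candidates whose SCE does not exceed the true tree's are
    retried a bounded number of times so the ensemble represents strictly
    worse alternatives where possible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    true_tree = truth.true_tree
    true_sce = score_tree_sce(true_tree, clusters)
    ensemble = [
        CloneTree(
            nodes=set(true_tree.nodes), parent=dict(true_tree.parent),
            sce=true_sce, rank=1,
        )
    ]
    seen = {frozenset(true_tree.edges())}
    non_trunk = sorted(true_tree.nodes - {true_tree.root})
    attempts = 0
    while len(ensemble) < k and attempts < 60 * k:
        attempts += 1
        cand_parent = dict(true_tree.parent)
        c = str(rng.choice(non_trunk))
        forbidden = true_tree.descendants(c) | {c, cand_parent[c]}
        options = sorted(true_tree.nodes - forbidden)
        if not options:
            continue
        cand_parent[c] = str(rng.choice(options))
        key = frozenset((p, ch) for ch, p in cand_parent.items())
        if key in seen:
            continue
        tree = CloneTree(
            nodes=set(true_tree.nodes), parent=cand_parent, sce=0.0, rank=0
        )
        tree.sce = score_tree_sce(tree, clusters)
        if tree.sce <= true_sce and attempts < 30 * k:
            continue  # prefer strictly worse topologies while budget allows
        seen.add(key)
        ensemble.append(tree)
    ensemble.sort(key=lambda t: (t.sce, t.rank != 1, t.edges()))
    for rank, t in enumerate(ensemble, start=1):
        t.rank = rank
    return ensemble


# --------------------------------------------------------------------------
# Cohort emission
# --------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    doc = {
        "seeding_model": truth.seeding_model,
        "tree_edges": truth.true_tree.edges(),
        "origin": truth.true_origin,
        "proportions": {
            f"{c}|{r}": v for (c, r), v in sorted(truth.true_proportions.items())
        },
        "migrations": truth.true_migrations,
        "loh_history": {
            f"{chrom}|{start}|{hap}": c
            for (chrom, start, hap), c in sorted(truth.true_loh_history.items())
        },
        "signature_activity": truth.true_signature_activity,
        "detection_day": truth.true_detection_day,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def simulate_cohort(
    config: SimulationConfig,
    n_patients: int,
    out_dir: str | Path | None = None,
    ensemble_size: int = 1,
) -> list[tuple[Patient, GroundTruth]]:
    """Simulate a cohort; patient seeds derive deterministically from the
    config seed.  When ``out_dir`` is given the full file set (plus
    ground_truth.json) is written per patient."""
    out = []
    for i in range(n_patients):
        cfg = dataclasses.replace(config, seed=(config.seed * 10_007 + i) % (2**31))
        pid = f"SIM{i + 1:03d}"
        patient, truth = simulate_patient(cfg, patient_id=pid)
        if ensemble_size > 1:
            patient.trees = simulate_tree_ensemble(
                truth, ensemble_size, patient.clusters, seed=cfg.seed + 1
            )
        if out_dir is not None:
            pdir = Path(out_dir) / pid
            write_patient(patient, pdir)
            write_ground_truth(truth, pdir / "ground_truth.json")
        out.append((patient, truth))
    return out
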