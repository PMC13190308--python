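"""Per-subclone mutational-signature activity and its dynamics.

Signature activities are estimated by constrained least squares: the
96-channel trinucleotide spectrum of a cluster's mutations is fitted onto a
signature catalogue by non-negative least squares and rescaled to fractions
of mutations.  Clusters with at least 50 mutations are fitted directly;
smaller clusters are stabilised by resampling their mutations (1,000
iterations) from the index cluster (60%), a tree neighbour (20%) and a
clonality-class-matched cluster (20%), reporting the mean activity and its
bootstrap standard deviation; clusters whose sd exceeds 0.1 on two or more
signatures are excluded.

Aetiology groups: clock-like (SBS1+SBS5), smoking (SBS4), APOBEC
(SBS2+SBS13), other (SBS17b), platinum (SBS31+SBS35, evaluated only in
platinum-treated patients).  An aetiology is detected at group activity
>= 0.06 and is the majority aetiology when it exceeds 0.5.  Episodic APOBEC
requires repeated inactive-to-active transitions along trunk-to-leaf
lineages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.spatial.distance import cosine as cosine_distance

from .cohort_model import CloneTree

log = logging.getLogger("cloneseed")

DIRECT_FIT_MIN_MUTATIONS = 50
DETECTION_THRESHOLD = 0.06
MAJORITY_THRESHOLD = 0.5
EXCLUSION_SD = 0.1
RESAMPLE_WEIGHTS = (0.6, 0.2, 0.2)  # index, tree neighbour, class-matched

AETIOLOGY_GROUPS = {
    "clock_like": ("SBS1", "SBS5"),
    "smoking": ("SBS4",),
    "apobec": ("SBS2", "SBS13"),
    "other": ("SBS17b",),
    "platinum": ("SBS31", "SBS35"),
}


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

def fit_activity(
    counts: np.ndarray, signature_matrix: pd.DataFrame
) -> pd.Series | None:
    """Non-negative least-squares fit of a 96-channel spectrum onto the
    signature catalogue, rescaled to activity fractions.

    Returns None for an all-zero spectrum.  The unexplained remainder is
    1 - sum(activities).
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        return None
    target = counts / total
    coef, _ = nnls(signature_matrix.to_numpy(), target)
    # the target is a probability vector, so coefficients are activity
    # fractions up to the fit residual; clip numerical excess above 1
    exposure = coef / coef.sum() if coef.sum() > 1.0 else coef
    return pd.Series(exposure, index=signature_matrix.columns)


@dataclass
class SignatureActivity:
    activity: dict[str, pd.Series]       # cluster -> activity vector
    sd: dict[str, pd.Series] = field(default_factory=dict)
    excluded: dict[str, bool] = field(default_factory=dict)


def resample_fit(
    cluster: str,
    tree: CloneTree,
    clonality: dict[str, str],
    context_counts: pd.DataFrame,
    signature_matrix: pd.DataFrame,
    iterations: int = 1000,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series]:
    """Bootstrap-stabilised activity of a small cluster.

    Per iteration, a same-size spectrum is drawn with mutation sources
    chosen 60/20/20 from the index cluster, a uniform tree neighbour
    (parent or child) and a uniform cluster of the same clonality class;
    missing source pools reweight the remaining ones.  Returns (mean, sd)
    across iterations.
    """
    rng = np.random.default_rng(seed)
    idx_counts = context_counts.loc[cluster].to_numpy(dtype=float)
    n = int(idx_counts.sum())
    if n == 0:
        raise ValueError(f"cluster {cluster} has no mutations to resample")

    kids = tree.children()
    neighbours = [c for c in kids.get(cluster, [])]
    if cluster in tree.parent:
        neighbours.append(tree.parent[cluster])
    neighbours = [c for c in sorted(neighbours) if c in context_counts.index]
    matched = [
        c for c in sorted(clonality)
        if c != cluster
        and clonality.get(c) == clonality.get(cluster)
        and c in context_counts.index
    ]

    pools = [[cluster], neighbours, matched]
    weights = np.array(RESAMPLE_WEIGHTS, dtype=float)
    available = np.array([bool(p) for p in pools])
    if not available.all():
        log.info(
            "cluster %s: missing resampling pools %s; reweighting",
            cluster,
            [i for i, a in enumerate(available) if not a],
        )
    weights = weights * available
    weights = weights / weights.sum()

    dists = {}
    for pool in pools:
        for c in pool:
            if c not in dists:
                v = context_counts.loc[c].to_numpy(dtype=float)
                dists[c] = v / v.sum() if v.sum() > 0 else None

    draws = []
    for _ in range(iterations):
        source_n = rng.multinomial(n, weights)
        spectrum = np.zeros(len(idx_counts))
        for pool, k in zip(pools, source_n):
            if k == 0 or not pool:
                continue
            src = pool[int(rng.integers(len(pool)))]
            if dists[src] is None:
                continue
            spectrum += rng.multinomial(k, dists[src])
        act = fit_activity(spectrum, signature_matrix)
        if act is not None:
            draws.append(act)
    stacked = pd.DataFrame(draws)
    return stacked.mean(axis=0), stacked.std(axis=0, ddof=1)


def cluster_activities(
    tree: CloneTree,
    clonality: dict[str, str],
    context_counts: pd.DataFrame,
    signature_matrix: pd.DataFrame,
    iterations: int = 1000,
    seed: int = 0,
) -> SignatureActivity:
    """Fit every cluster: direct NNLS at >= 50 mutations, resampled below."""
    out = SignatureActivity(activity={})
    rng = np.random.default_rng(seed)
    for i, cluster in enumerate(sorted(tree.nodes)):
        if cluster not in context_counts.index:
            continue
        counts = context_counts.loc[cluster].to_numpy(dtype=float)
        if counts.sum() >= DIRECT_FIT_MIN_MUTATIONS:
            act = fit_activity(counts, signature_matrix)
            sd = pd.Series(0.0, index=signature_matrix.columns)
        else:
            act, sd = resample_fit(
                cluster, tree, clonality, context_counts, signature_matrix,
                iterations=iterations, seed=int(rng.integers(2**31)),
            )
        if act is None:
            continue
        out.activity[cluster] = act
        out.sd[cluster] = sd
        out.excluded[cluster] = bool((sd > EXCLUSION_SD).sum() >= 2)
    return out


# --------------------------------------------------------------------------
# Aetiologies
# --------------------------------------------------------------------------

@dataclass
class AetiologyProfile:
    group_activity: dict[str, dict[str, float]]  # cluster -> group -> activity
    detected: dict[str, dict[str, bool]]
    majority: dict[str, str | None]


def aetiology_summary(
    activities: SignatureActivity,
    platinum_treated: bool,
    clonality: dict[str, str] | None = None,
) -> tuple[AetiologyProfile, pd.DataFrame]:
    """Group activities by aetiology, call detection (>= 0.06) and majority
    (> 0.5), and tabulate prevalence (fraction of subclones with detection),
    stratified by clonality class when given.  Platinum signatures are
    masked for patients never treated with platinum chemotherapy."""
    group_activity: dict[str, dict[str, float]] = {}
    detected: dict[str, dict[str, bool]] = {}
    majority: dict[str, str | None] = {}
    for cluster, act in activities.activity.items():
        if activities.excluded.get(cluster):
            continue
        groups = {}
        for group, members in AETIOLOGY_GROUPS.items():
            if group == "platinum" and not platinum_treated:
                continue
            groups[group] = float(
                sum(act.get(m, 0.0) for m in members)
            )
        group_activity[cluster] = groups
        detected[cluster] = {
            g: v >= DETECTION_THRESHOLD for g, v in groups.items()
        }
        top = max(groups, key=lambda g: groups[g]) if groups else None
        majority[cluster] = (
            top if top is not None and groups[top] > MAJORITY_THRESHOLD
            else None
        )

    rows = []
    for group in AETIOLOGY_GROUPS:
        if group == "platinum" and not platinum_treated:
            continue
        strata: dict[str, list[bool]] = {"all": []}
        for cluster, det in detected.items():
            strata["all"].append(det[group])
            if clonality is not None:
                strata.setdefault(clonality.get(cluster, "?"), []).append(
                    det[group]
                )
        for stratum, flags in strata.items():
            if flags:
                rows.append(
                    {
                        "aetiology": group,
                        "stratum": stratum,
                        "prevalence": sum(flags) / len(flags),
                        "n_subclones": len(flags),
                    }
                )
    prevalence = pd.DataFrame(rows)
    return (
        AetiologyProfile(
            group_activity=group_activity, detected=detected, majority=majority
        ),
        prevalence,
    )


# --------------------------------------------------------------------------
# Episodic APOBEC
# --------------------------------------------------------------------------

def detect_episodic_apobec(
    tree: CloneTree,
    active: dict[str, bool],
) -> tuple[bool, dict[tuple[str, ...], bool]]:
    """Episodic APOBEC activity along trunk-to-leaf lineages.

    An *emergence* is a parent inactive / child active transition.  A
    lineage is episodic when (i) the trunk is active and at least one later
    emergence occurs, or (ii) two or more emergences occur.  The patient
    flag is true when any lineage is episodic.  Clusters without an
    activity call break the lineage (treated as inactive).
    """
    kids = tree.children()
    leaves = [n for n in sorted(tree.nodes) if not kids[n]]
    lineages: dict[tuple[str, ...], bool] = {}
    any_episodic = False
    for leaf in leaves:
        path = [leaf] + tree.ancestors(leaf)
        path.reverse()  # trunk first
        states = [bool(active.get(c, False)) for c in path]
        emergences = sum(
            1 for a, b in zip(states, states[1:]) if (not a) and b
        )
        episodic = (states[0] and emergences >= 1) or emergences >= 2
        lineages[tuple(path)] = episodic
        any_episodic = any_episodic or episodic
    return any_episodic, lineages


# --------------------------------------------------------------------------
# Signature distances
# --------------------------------------------------------------------------

def signature_distance_report(
    activities: SignatureActivity,
    clonality: dict[str, str],
) -> dict[str, float]:
    """Mean pairwise cosine distances: among metastasis-unique subclones,
    and between metastasis-unique and ancestral-primary subclones (truncal,
    shared subclonal, primary-unique).  NaN when a stratum is degenerate."""
    met_unique = [
        c for c in sorted(activities.activity)
        if clonality.get(c) == "metastasis_unique"
        and not activities.excluded.get(c)
    ]
    ancestral = [
        c for c in sorted(activities.activity)
        if clonality.get(c) in ("truncal", "shared_subclonal", "primary_unique")
        and not activities.excluded.get(c)
    ]

    def dist(a: str, b: str) -> float:
        va = activities.activity[a].to_numpy()
        vb = activities.activity[b].to_numpy()
        if va.sum() == 0 or vb.sum() == 0:
            return math.nan
        return float(cosine_distance(va, vb))

    mm = [
        dist(a, b)
        for i, a in enumerate(met_unique)
        for b in met_unique[i + 1:]
    ]
    mp = [dist(a, b) for a in met_unique for b in ancestral]
    mm = [d for d in mm if not math.isnan(d)]
    mp = [d for d in mp if not math.isnan(d)]
    return {
        "met_met_mean": float(np.mean(mm)) if mm else math.nan,
        "met_primary_mean": float(np.mean(mp)) if mp else math.nan,
    }
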