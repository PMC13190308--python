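"""End-to-end orchestration over a cohort directory.

Stages run in method order — architecture (presence, proportions,
clonality), diversity, migration inference (+ ensemble probabilities),
orthogonal validation, seeding analysis and signature dynamics — and write
per-patient TSVs plus a cohort summary.  All randomness derives from one
root seed.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clone_architecture as arch
from . import diversity_metrics as div
from . import migration_inference as mig
from . import migration_validation as valid
from . import seeding_analysis as seed_mod
from . import signature_dynamics as sig
from .cohort_model import Patient, read_patient
from .synthetic_cohort import synthetic_signature_matrix

log = logging.getLogger("cloneseed")

DEFAULT_THRESHOLDS = (0.0, 0.25, 0.5, 0.75, 0.9, 1.0)


@dataclass
class PatientResult:
    patient_id: str
    primary: str
    proportions: arch.SubcloneProportions
    #: detection-based clonality classes (classify_clonality output)
    clonality_detected: dict[str, str]
    #: classes after the parsimony reclassification rule; used downstream
    clonality: dict[str, str]
    history: mig.MigrationHistory
    annotation: seed_mod.SeedingAnnotation
    heterogeneity: dict[str, float]
    presence_by_tumour: dict[str, set[str]]
    capacity_p: float
    duration: seed_mod.DurationSurrogate
    cavity: seed_mod.CavitySummary
    pair_probs: dict[tuple[str, str], float] = field(default_factory=dict)
    cluster_probs: dict[tuple[str, str, str], float] = field(default_factory=dict)
    validation: valid.ValidationReport | None = None
    episodic_apobec: bool | None = None
    signature_distances: dict[str, float] | None = None


def extant_presence_by_tumour(
    patient: Patient,
    proportions: arch.SubcloneProportions,
    include_extinct: bool = False,
) -> dict[str, set[str]]:
    """Tumour-level residency for migration inference.

    A cluster is resident in a tumour when cells of that exact genotype are
    there: its subclone *proportion* exceeds the extinction threshold in at
    least one of the tumour's regions.  This is deliberately stricter than
    mutation detection (an ancestor's mutations are carried by every
    descendant cell, so its CCF is 1 in tumours it never inhabited) —
    observation leaves built from detection would manufacture spurious
    migrations for every ancestral cluster along a seeding chain.
    """
    floor = 0.0 if include_extinct else arch.EXTINCTION_THRESHOLD
    by_tumour: dict[str, set[str]] = {}
    tumour_of = {
        rid: u.tumour_id for rid, u in patient.sampling_units.items()
    }
    for (cid, rid), value in proportions.proportion.items():
        if value > floor:
            by_tumour.setdefault(cid, set()).add(tumour_of[rid])
    return by_tumour


def analyse_patient(
    patient: Patient,
    seed: int = 0,
    run_signatures: bool = True,
    signature_iterations: int = 200,
    model: str = "auto",
) -> PatientResult:
    """Run every analysis stage on one patient (rank-1 tree for the point
    estimates; the full ensemble for migration probabilities)."""
    tree = patient.tree
    regions = sorted(patient.sampling_units)
    region_kinds = {
        rid: u.tumour_kind for rid, u in patient.sampling_units.items()
    }
    primary = patient.primary_tumour
    tumour_kind = {t: patient.tumour_kind(t) for t in patient.tumours()}

    presence = arch.presence_table(
        patient.clusters, regions, patient.mutant_reads
    )
    proportions = arch.infer_subclone_proportions(tree, patient.clusters)
    clonality_detected = arch.classify_clonality(tree, presence, region_kinds)
    by_tumour = extant_presence_by_tumour(patient, proportions)

    if model == "auto":
        history = mig.select_seeding_model(tree, by_tumour, primary)
    else:
        history = mig.infer_history(tree, by_tumour, primary, model)
    clonality = mig.reclassify_shared(history, clonality_detected, primary)

    pair_probs: dict[tuple[str, str], float] = {}
    cluster_probs: dict[tuple[str, str, str], float] = {}
    if len(patient.trees) > 1:
        pair_probs, cluster_probs = mig.migration_probabilities(
            patient.trees, by_tumour, primary, model=model
        )
    else:
        pair_probs = {
            (a, b): 1.0 for a, b in {(a, b) for a, b, _ in history.migrations}
        }
        cluster_probs = {m: 1.0 for m in set(history.migrations)}

    matrices = div.diversity_matrices(patient)
    heterogeneity = div.heterogeneity_summary(patient, matrices["snv"])

    annotation = seed_mod.annotate_seeding(history, tree, primary, tumour_kind)

    p2m_counts: dict[str, set[str]] = {}
    for src, tgt, cluster in history.migrations:
        if src == primary:
            p2m_counts.setdefault(cluster, set()).add(tgt)
    capacity_p = (
        seed_mod.monte_carlo_capacity_test(
            [len(v) for _, v in sorted(p2m_counts.items())],
            reps=10_000,
            seed=seed,
        )
        if len(p2m_counts) >= 2
        else math.nan
    )

    duration = seed_mod.sufficiency_threshold(
        history, tree, patient.clusters, by_tumour, tumour_kind, primary
    )
    cavity = seed_mod.cavity_summary(
        history,
        {t: patient.tumour_cavity(t) for t in tumour_kind},
        {t: patient.tumour_site(t) for t in tumour_kind},
        tumour_kind,
    )

    validation = None
    if patient.segment_profiles:
        validation = valid.validate_history(
            patient, history.migrations, history.seeded_by
        )

    episodic = None
    distances = None
    if run_signatures and patient.context_counts is not None:
        matrix = synthetic_signature_matrix()
        activities = sig.cluster_activities(
            tree, clonality, patient.context_counts, matrix,
            iterations=signature_iterations, seed=seed + 1,
        )
        profile, _prev = sig.aetiology_summary(
            activities, patient.platinum_treated, clonality
        )
        active = {
            c: det.get("apobec", False) for c, det in profile.detected.items()
        }
        episodic, _ = sig.detect_episodic_apobec(tree, active)
        distances = sig.signature_distance_report(activities, clonality)

    return PatientResult(
        patient_id=patient.patient_id,
        primary=primary,
        proportions=proportions,
        clonality_detected=clonality_detected,
        clonality=clonality,
        history=history,
        annotation=annotation,
        heterogeneity=heterogeneity,
        presence_by_tumour=by_tumour,
        capacity_p=capacity_p,
        duration=duration,
        cavity=cavity,
        pair_probs=pair_probs,
        cluster_probs=cluster_probs,
        validation=validation,
        episodic_apobec=episodic,
        signature_distances=distances,
    )


# --------------------------------------------------------------------------
# Cohort summary
# --------------------------------------------------------------------------

def summarise_cohort(results: list[PatientResult]) -> pd.DataFrame:
    """One row per patient plus the roll-ups the per-patient rows imply."""
    rows = []
    for r in results:
        mets = sorted(r.annotation.seeds_others)
        seeded = {m: r.annotation.seeded_by.get(m) for m in mets}
        seeded_known = [m for m in mets if seeded[m] is not None]
        n_seeded = len(seeded_known)
        pct = lambda kind: (
            100.0
            * sum(1 for m in seeded_known if seeded[m] == kind)
            / n_seeded
            if n_seeded
            else math.nan
        )
        mono = [
            m for m in mets if r.annotation.n_incoming.get(m, 0) == 1
        ]
        roles = r.annotation.cluster_role
        rows.append(
            {
                "patient_id": r.patient_id,
                "model": r.history.model,
                "n_metastases": len(mets),
                "n_p2m_seeders": sum(
                    1 for v in roles.values() if v == "primary_to_met_seeder"
                ),
                "n_m2m_seeders": sum(
                    1 for v in roles.values() if v == "met_to_met_seeder"
                ),
                "pct_seeded_by_primary": pct("primary"),
                "pct_seeded_by_metastasis": pct("metastasis"),
                "pct_seeded_by_both": pct("both"),
                "pct_single_subclone_seeded": (
                    100.0 * len(mono) / n_seeded if n_seeded else math.nan
                ),
                "within_cavity_fraction": r.cavity.within_cavity_fraction,
                "capacity_p": r.capacity_p,
                "episodic_apobec": r.episodic_apobec,
                **{f"het_{k}": v for k, v in r.heterogeneity.items()},
            }
        )
    return pd.DataFrame(rows)


def threshold_sweep(
    results: list[PatientResult],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Cohort proportions of metastases seeded by metastasis vs primary as
    the migration-probability threshold increases."""
    rows = []
    for thr in thresholds:
        counts = {"primary": 0, "metastasis": 0, "both": 0}
        retained = 0
        for r in results:
            seeded = mig.seeded_by_at_threshold(r.pair_probs, r.primary, thr)
            for m, kind in seeded.items():
                counts[kind] += 1
            retained += sum(1 for p in r.pair_probs.values() if p >= thr)
        total = sum(counts.values())
        rows.append(
            {
                "threshold": thr,
                "n_migrations_retained": retained,
                "n_seeded_metastases": total,
                **{
                    f"pct_{k}": (100.0 * v / total if total else math.nan)
                    for k, v in counts.items()
                },
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Disk pipeline
# --------------------------------------------------------------------------

def _write_patient_outputs(result: PatientResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"cluster_id": c, "region_id": r, "proportion": v,
             "extinct": result.proportions.extinct[c]}
            for (c, r), v in sorted(result.proportions.proportion.items())
        ]
    ).to_csv(out_dir / "proportions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"cluster_id": c, "clonality": v}
            for c, v in sorted(result.clonality.items())
        ]
    ).to_csv(out_dir / "clonality.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "source": a, "target": b, "cluster": c,
                "probability": result.cluster_probs.get((a, b, c), math.nan),
            }
            for a, b, c in result.history.migrations
        ]
    ).to_csv(out_dir / "migrations.tsv", sep="\t", index=False)
    (out_dir / "model_report.json").write_text(
        json.dumps(
            {
                "model": result.history.model,
                "n_migrations": result.history.n_migrations,
                "n_comigrations": result.history.n_comigrations,
                "mu_by_model": result.history.mu_by_model,
                "seeded_by": result.history.seeded_by,
                "capacity_p": (
                    None if math.isnan(result.capacity_p)
                    else result.capacity_p
                ),
            },
            indent=1,
        )
    )
    if result.validation is not None:
        pd.DataFrame(result.validation.loh_rows).to_csv(
            out_dir / "loh_validation.tsv", sep="\t", index=False
        )


def run_pipeline(
    cohort_dir: str | Path,
    out_dir: str | Path,
    seed: int = 0,
    run_signatures: bool = True,
    model: str = "auto",
) -> pd.DataFrame:
    """Analyse every patient directory under ``cohort_dir``; write
    per-patient artefacts, ``summary.tsv``/``summary.json`` and the
    migration-probability threshold sweep.  Deterministic given the seed."""
    cohort_dir = Path(cohort_dir)
    out_dir = Path(out_dir)
    patient_dirs = sorted(
        d for d in cohort_dir.iterdir()
        if d.is_dir() and (d / "samples.tsv").exists()
    )
    if not patient_dirs:
        raise FileNotFoundError(f"no patient directories under {cohort_dir}")
    results = []
    rng = np.random.default_rng(seed)
    for pdir in patient_dirs:
        t0 = time.time()
        patient = read_patient(pdir)
        result = analyse_patient(
            patient,
            seed=int(rng.integers(2**31)),
            run_signatures=run_signatures,
            model=model,
        )
        _write_patient_outputs(result, out_dir / patient.patient_id)
        log.info(
            "patient %s analysed in %.1fs (model %s, %d migrations)",
            patient.patient_id, time.time() - t0,
            result.history.model, result.history.n_migrations,
        )
        results.append(result)
    summary = summarise_cohort(results)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
    sweep = threshold_sweep(results)
    sweep.to_csv(out_dir / "threshold_sweep.tsv", sep="\t", index=False)
    roll_up = {
        "n_patients": len(results),
        "pct_metastases_met_seeded": _cohort_seeded_pct(results, "metastasis"),
        "pct_metastases_primary_seeded": _cohort_seeded_pct(results, "primary"),
        "pct_metastases_both_seeded": _cohort_seeded_pct(results, "both"),
    }
    (out_dir / "summary.json").write_text(json.dumps(roll_up, indent=1))
    return summary


def _cohort_seeded_pct(results: list[PatientResult], kind: str) -> float:
    num = den = 0
    for r in results:
        for m, k in r.annotation.seeded_by.items():
            den += 1
            if k == kind:
                num += 1
    return 100.0 * num / den if den else math.nan
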