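"""Orthogonal validation of inferred migrations.

Two independent lines of evidence check the parsimony histories.  First,
clonal loss of heterozygosity: LOH is irreversible, so clonal LOH present in
a source sample should be conserved in any tumour it seeded, and a target
carrying LOH its putative source lacks is incompatible with that route.
Second, radiology: a tumour cannot be detected before the tumour that
seeded it, so detection-time distributions should separate primary-seeded
from metastasis-seeded tumours.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort_model import Patient, SegmentProfile

log = logging.getLogger("cloneseed")

#: Purity-adjusted allele copy number below which an allele counts as lost
#: in (essentially) all cancer cells.
CLONAL_LOH_THRESHOLD = 0.1


# --------------------------------------------------------------------------
# Clonal LOH
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LOHSegment:
    chrom: str
    start: int
    end: int
    allele: str  # haplotype identity ('A'/'B') or 'minor' when unphased


def adjusted_allele_cn(observed: float, purity: float) -> float:
    """Invert the admixture of one normal copy per allele from
    contaminating cells: adjusted = (observed - (1 - purity)) / purity.
    Values below -0.5 indicate an inconsistent purity estimate and are
    clipped to zero with a warning."""
    adj = (observed - (1.0 - purity)) / purity
    if adj < -0.5:
        log.warning(
            "adjusted allele CN %.3f < -0.5; purity %.2f inconsistent, "
            "clipping to 0", adj, purity,
        )
        return 0.0
    return max(0.0, adj)


def clonal_loh_segments(
    profile: SegmentProfile,
    purity: float,
    threshold: float = CLONAL_LOH_THRESHOLD,
) -> set[LOHSegment]:
    """Segments with clonal LOH in a region: purity-adjusted allele copy
    number below the threshold.  Allele identity is the lost haplotype when
    the profile is phased, else the generic 'minor' label."""
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity {purity} outside (0, 1]")
    out: set[LOHSegment] = set()
    for seg in profile.segments:
        adj_minor = adjusted_allele_cn(seg.cn_minor, purity)
        adj_major = adjusted_allele_cn(seg.cn_major, purity)
        if seg.major_haplotype in ("A", "B"):
            minor_hap = "B" if seg.major_haplotype == "A" else "A"
            if adj_minor < threshold:
                out.add(LOHSegment(seg.chrom, seg.start, seg.end, minor_hap))
            if adj_major < threshold:
                out.add(
                    LOHSegment(seg.chrom, seg.start, seg.end,
                               seg.major_haplotype)
                )
        else:
            if adj_minor < threshold:
                out.add(LOHSegment(seg.chrom, seg.start, seg.end, "minor"))
    return out


def conserved_loh_fraction(
    source_set: set[LOHSegment], target_set: set[LOHSegment]
) -> float:
    """Fraction of the source's clonal-LOH segments also lost (same allele)
    in the target; NaN when the source has none.

    The denominator is the source's LOH segment count — conservation is a
    property of what the seeding lineage carried.
    """
    if not source_set:
        return math.nan
    return len(source_set & target_set) / len(source_set)


# --------------------------------------------------------------------------
# Radiological detection
# --------------------------------------------------------------------------

DETECTION_PERIODS = ("relapse_scan", "first_half", "second_half", "autopsy_only")


@dataclass
class DetectionRecord:
    tumour_id: str
    first_detection_day: float  # days since primary surgery
    period: str


def assign_detection(
    tumour_id: str,
    scans: list[tuple[int, tuple[str, ...]]],
    death_day: int | None,
) -> DetectionRecord | None:
    """First-detection day and scan-period class for one tumour.

    The detection day is the first scan listing the tumour; tumours only
    sampled at autopsy get the midpoint of the last scan and death.  Periods
    normalise the scan timeline between the relapse scan and death:
    detections on the relapse scan are their own class, later scans split at
    the 50% point, and autopsy-only detections close the scale.
    """
    if not scans:
        return None
    scans = sorted(scans)
    relapse_day = scans[0][0]
    last_scan_day = scans[-1][0]
    detected_on = next(
        (day for day, detected in scans if tumour_id in detected), None
    )
    if detected_on is None:
        if death_day is None:
            return None
        day = (last_scan_day + death_day) / 2.0
        return DetectionRecord(tumour_id, day, "autopsy_only")
    if detected_on == relapse_day:
        return DetectionRecord(tumour_id, float(detected_on), "relapse_scan")
    end = death_day if death_day is not None else last_scan_day
    span = max(1, end - relapse_day)
    fraction = (detected_on - relapse_day) / span
    period = "first_half" if fraction <= 0.5 else "second_half"
    return DetectionRecord(tumour_id, float(detected_on), period)


# --------------------------------------------------------------------------
# History validation report
# --------------------------------------------------------------------------

@dataclass
class ValidationReport:
    #: per inferred met->met pair: conserved fraction along the inferred
    #: route, the primary-as-source alternative, and the mean over all
    #: alternative metastasis sources
    loh_rows: list[dict]
    #: migrations whose target carries clonal LOH absent from the source
    non_conserved_pairs: list[tuple[str, str]]
    #: Mann-Whitney p: inferred-route fractions vs alternative-source fractions
    loh_route_p: float
    #: detection-day distributions by seeding source kind
    detection_days: dict[str, list[float]]
    #: Mann-Whitney p: primary-seeded vs metastasis-seeded detection days
    detection_p: float


def _tumour_loh(patient: Patient, tumour: str) -> set[LOHSegment]:
    """Clonal LOH of a tumour: the intersection over its regions (clonal
    means present in all cancer cells of every sample of the tumour)."""
    regions = patient.tumours()[tumour]
    sets = []
    for rid in regions:
        if rid not in patient.segment_profiles:
            continue
        sets.append(
            clonal_loh_segments(
                patient.segment_profiles[rid],
                patient.sampling_units[rid].purity,
            )
        )
    if not sets:
        return set()
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def validate_history(
    patient: Patient,
    migrations: list[tuple[str, str, str]],
    seeded_by: dict[str, str],
) -> ValidationReport:
    """Check a migration history against conserved LOH and detection times."""
    if not patient.segment_profiles:
        raise ValueError(
            "no segment profiles available; LOH validation impossible"
        )
    tumours = sorted(patient.tumours())
    primary = patient.primary_tumour
    loh = {t: _tumour_loh(patient, t) for t in tumours}

    pairs = sorted({(a, b) for a, b, _ in migrations if a != primary})
    rows = []
    non_conserved = []
    route_fracs, alt_fracs = [], []
    for src, tgt in pairs:
        f_route = conserved_loh_fraction(loh[src], loh[tgt])
        f_primary = conserved_loh_fraction(loh[primary], loh[tgt])
        alt_sources = [
            t for t in tumours
            if t not in (src, tgt, primary)
            and patient.tumour_kind(t) == "metastasis"
        ]
        alt_values = [
            conserved_loh_fraction(loh[t], loh[tgt]) for t in alt_sources
        ]
        alt_values = [v for v in alt_values if not math.isnan(v)]
        f_alt = float(np.mean(alt_values)) if alt_values else math.nan
        rows.append(
            {
                "source": src,
                "target": tgt,
                "conserved_route": f_route,
                "conserved_primary_source": f_primary,
                "conserved_alt_met_mean": f_alt,
            }
        )
        if not math.isnan(f_route):
            route_fracs.append(f_route)
            alt_fracs.extend(alt_values)
        # LOH is irreversible: clonal LOH in the source must be carried by
        # every cell of a tumour it seeded, so source LOH absent from the
        # target is incompatible with the route
        if loh[src] - loh[tgt]:
            non_conserved.append((src, tgt))

    loh_route_p = math.nan
    if route_fracs and alt_fracs:
        try:
            loh_route_p = float(
                stats.mannwhitneyu(
                    route_fracs, alt_fracs, alternative="greater"
                ).pvalue
            )
        except ValueError:
            pass

    detection_days: dict[str, list[float]] = {"primary": [], "metastasis": []}
    for tumour, source_kind in seeded_by.items():
        rec = assign_detection(tumour, patient.scan_records, patient.death_day)
        if rec is None:
            continue
        if source_kind in ("primary", "metastasis"):
            detection_days[source_kind].append(rec.first_detection_day)
    detection_p = math.nan
    if detection_days["primary"] and detection_days["metastasis"]:
        try:
            detection_p = float(
                stats.mannwhitneyu(
                    detection_days["primary"],
                    detection_days["metastasis"],
                    alternative="less",
                ).pvalue
            )
        except ValueError:
            pass

    return ValidationReport(
        loh_rows=rows,
        non_conserved_pairs=non_conserved,
        loh_route_p=loh_route_p,
        detection_days=detection_days,
        detection_p=detection_p,
    )
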