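"""Domain types, validation and on-disk formats for multi-tumour clone-tree cohorts.

A *patient* bundles everything the downstream stages consume: sequenced
regions (with tumour of origin, anatomical site, purity and ploidy), mutation
clusters with per-region cancer cell fractions (CCFs), a ranked ensemble of
clone trees, allele-specific fractional copy-number segments per region,
optional per-subclone copy-number profiles, driver/WGD event assignments and
the radiological scan timeline.

All tables are tab-separated with a mandatory header row and ``.`` for
missing values.  Genomic coordinates are 0-based half-open (BED convention);
a ``one_based`` flag on the readers converts 1-based inclusive input.
Dates are integer days since primary surgery (day 0).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

log = logging.getLogger("cloneseed")

# --------------------------------------------------------------------------
# Anatomical-site vocabulary and cavity classification
# --------------------------------------------------------------------------

#: Sites that lie within the thoracic cavity.
INTRATHORACIC_SITES = frozenset(
    {
        "mediastinal lymph node",
        "mediastinal soft tissue",
        "lung",
        "lung surgical bed",
        "pleura",
    }
)

#: Sites outside the thoracic cavity.
EXTRATHORACIC_SITES = frozenset(
    {
        "axillary lymph node",
        "cervical lymph node",
        "supraclavicular lymph node",
        "abdominopelvic lymph node",
        "soft tissue",
        "cardiac",
        "bone",
        "liver",
        "brain",
        "gastric",
        "adrenal",
        "kidney",
        "peritoneum",
        "bladder",
    }
)

#: Sites straddling the pleural boundary: classification needs a qualifier
#: stating whether the lesion arose inside or outside the pleura.
AMBIGUOUS_SITES = frozenset({"chest wall", "diaphragm"})

SITE_VOCABULARY = INTRATHORACIC_SITES | EXTRATHORACIC_SITES | AMBIGUOUS_SITES

#: Free-text aliases resolved onto the controlled vocabulary.
SITE_ALIASES = {
    "mediastinal ln": "mediastinal lymph node",
    "mediastinum": "mediastinal soft tissue",
    "axillary ln": "axillary lymph node",
    "cervical ln": "cervical lymph node",
    "supraclavicular ln": "supraclavicular lymph node",
    "abdominal lymph node": "abdominopelvic lymph node",
    "pelvic lymph node": "abdominopelvic lymph node",
    "adrenal gland": "adrenal",
    "stomach": "gastric",
    "pericardium": "cardiac",
    "myocardium": "cardiac",
    "hepatic": "liver",
    "osseous": "bone",
    "skin": "soft tissue",
    "subcutaneous": "soft tissue",
}

VALID_QUALIFIERS = ("inside_pleura", "outside_pleura")


class CohortValidationError(ValueError):
    """Raised when an on-disk table or a Patient violates an invariant."""


def normalise_site(site: str) -> str:
    s = site.strip().lower()
    s = SITE_ALIASES.get(s, s)
    if s not in SITE_VOCABULARY:
        raise CohortValidationError(f"unknown anatomical site: {site!r}")
    return s


def classify_cavity(anatomical_site: str, qualifier: str | None = None) -> str:
    """Deterministically map an anatomical site to its cavity class.

    ``chest wall`` and ``diaphragm`` lesions can arise on either side of the
    pleural boundary and require ``qualifier`` (``inside_pleura`` /
    ``outside_pleura``); all other sites classify unconditionally.
    """
    site = normalise_site(anatomical_site)
    if site in AMBIGUOUS_SITES:
        if qualifier is None:
            raise CohortValidationError(
                f"site {site!r} needs a pleural-boundary qualifier "
                f"({' or '.join(VALID_QUALIFIERS)})"
            )
        if qualifier not in VALID_QUALIFIERS:
            raise CohortValidationError(f"unknown qualifier {qualifier!r}")
        return "intrathoracic" if qualifier == "inside_pleura" else "extrathoracic"
    if site in INTRATHORACIC_SITES:
        return "intrathoracic"
    return "extrathoracic"


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

TUMOUR_KINDS = ("primary", "metastasis")
COLLECTIONS = ("surgery", "relapse", "progression", "autopsy")

#: CCF estimates above 1 are tolerated up to this cap, then clipped.
CCF_CAP = 1.5


@dataclass
class SamplingUnit:
    """A sequenced tumour region."""

    region_id: str
    tumour_id: str
    tumour_kind: str  # primary | metastasis
    anatomical_site: str
    purity: float
    ploidy: float
    collection: str = "autopsy"
    cavity_qualifier: str | None = None

    def __post_init__(self) -> None:
        if self.tumour_kind not in TUMOUR_KINDS:
            raise CohortValidationError(
                f"{self.region_id}: bad tumour_kind {self.tumour_kind!r}"
            )
        if not (0.0 < self.purity <= 1.0):
            raise CohortValidationError(
                f"{self.region_id}: purity {self.purity} outside (0, 1]"
            )
        if not self.ploidy > 0:
            raise CohortValidationError(f"{self.region_id}: ploidy must be > 0")
        if self.collection not in COLLECTIONS:
            raise CohortValidationError(
                f"{self.region_id}: bad collection {self.collection!r}"
            )
        self.anatomical_site = normalise_site(self.anatomical_site)

    @property
    def cavity(self) -> str:
        """Cavity class; the primary tumour forms its own class."""
        if self.tumour_kind == "primary":
            return "primary"
        return classify_cavity(self.anatomical_site, self.cavity_qualifier)


@dataclass
class MutationCluster:
    """A subclone's mutation set with per-region CCFs."""

    cluster_id: str
    ccf: dict[str, float]  # region_id -> CCF in [0, CCF_CAP]
    n_mutations: int
    is_trunk: bool = False
    mutation_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_mutations < 0:
            raise CohortValidationError(
                f"cluster {self.cluster_id}: negative mutation count"
            )
        for region, value in list(self.ccf.items()):
            if not math.isfinite(value) or value < 0:
                raise CohortValidationError(
                    f"cluster {self.cluster_id}: bad CCF {value} in {region}"
                )
            if value > CCF_CAP:
                log.warning(
                    "cluster %s region %s: CCF %.3f clipped to %.2f",
                    self.cluster_id, region, value, CCF_CAP,
                )
                self.ccf[region] = CCF_CAP


@dataclass
class CloneTree:
    """Rooted tree over mutation clusters; root is the trunk (MRCA)."""

    nodes: set[str]
    parent: dict[str, str]  # child -> parent; root absent
    sce: float = 0.0
    rank: int = 1

    def __post_init__(self) -> None:
        roots = [n for n in self.nodes if n not in self.parent]
        if len(roots) != 1:
            raise CohortValidationError(
                f"tree must have exactly one root, found {sorted(roots)}"
            )
        for child, par in self.parent.items():
            if child not in self.nodes or par not in self.nodes:
                raise CohortValidationError(
                    f"edge {par}->{child} references unknown node"
                )
        # connectivity + acyclicity: every node must reach the root
        root = roots[0]
        for n in self.nodes:
            seen = set()
            cur = n
            while cur != root:
                if cur in seen:
                    raise CohortValidationError(f"cycle through {cur}")
                seen.add(cur)
                cur = self.parent[cur]

    @property
    def root(self) -> str:
        return next(n for n in self.nodes if n not in self.parent)

    def children(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {n: [] for n in self.nodes}
        for child, par in self.parent.items():
            out[par].append(child)
        for kids in out.values():
            kids.sort()
        return out

    def edges(self) -> list[tuple[str, str]]:
        return sorted((p, c) for c, p in self.parent.items())

    def descendants(self, node: str) -> set[str]:
        kids = self.children()
        out: set[str] = set()
        stack = list(kids[node])
        while stack:
            n = stack.pop()
            out.add(n)
            stack.extend(kids[n])
        return out

    def ancestors(self, node: str) -> list[str]:
        out = []
        cur = node
        while cur in self.parent:
            cur = self.parent[cur]
            out.append(cur)
        return out


@dataclass
class Segment:
    chrom: str
    start: int
    end: int
    cn_major: float
    cn_minor: float
    major_haplotype: str | None = None  # 'A' or 'B' when phased

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise CohortValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: end <= start"
            )
        if self.cn_minor < 0 or self.cn_major < self.cn_minor:
            raise CohortValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: "
                f"need cn_major >= cn_minor >= 0"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentProfile:
    """Allele-specific fractional copy numbers over genomic segments."""

    region_id: str
    segments: list[Segment]

    def __post_init__(self) -> None:
        self.segments.sort(key=lambda s: (s.chrom, s.start))
        by_chrom: dict[str, list[Segment]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise CohortValidationError(
                        f"{self.region_id}: overlapping segments on {chrom} "
                        f"at {b.start}"
                    )


@dataclass
class Patient:
    patient_id: str
    sampling_units: dict[str, SamplingUnit]
    clusters: dict[str, MutationCluster]
    trees: list[CloneTree]
    segment_profiles: dict[str, SegmentProfile] = field(default_factory=dict)
    subclone_profiles: dict[str, list[Segment]] = field(default_factory=dict)
    wgd_calls: list[str] = field(default_factory=list)
    driver_events: list[tuple[str, str, str]] = field(default_factory=list)
    scan_records: list[tuple[int, tuple[str, ...]]] = field(default_factory=list)
    mutant_reads: dict[tuple[str, str], int] = field(default_factory=dict)
    context_counts: pd.DataFrame | None = None  # clusters x 96 contexts
    surgery_day: int = 0
    relapse_day: int | None = None
    death_day: int | None = None
    platinum_treated: bool = False

    # -- convenience views ------------------------------------------------
    @property
    def tree(self) -> CloneTree:
        """Rank-1 (lowest-SCE) tree."""
        return self.trees[0]

    @property
    def trunk(self) -> str:
        return next(c for c in self.clusters.values() if c.is_trunk).cluster_id

    @property
    def primary_tumour(self) -> str:
        return next(
            u.tumour_id
            for u in self.sampling_units.values()
            if u.tumour_kind == "primary"
        )

    def tumours(self) -> dict[str, list[str]]:
        """tumour_id -> sorted region_ids."""
        out: dict[str, list[str]] = {}
        for u in self.sampling_units.values():
            out.setdefault(u.tumour_id, []).append(u.region_id)
        for regions in out.values():
            regions.sort()
        return out

    def tumour_kind(self, tumour_id: str) -> str:
        for u in self.sampling_units.values():
            if u.tumour_id == tumour_id:
                return u.tumour_kind
        raise KeyError(tumour_id)

    def tumour_cavity(self, tumour_id: str) -> str:
        for u in self.sampling_units.values():
            if u.tumour_id == tumour_id:
                return u.cavity
        raise KeyError(tumour_id)

    def tumour_site(self, tumour_id: str) -> str:
        for u in self.sampling_units.values():
            if u.tumour_id == tumour_id:
                return u.anatomical_site
        raise KeyError(tumour_id)


def validate_patient(patient: Patient) -> None:
    """Cross-validate all invariants; raise CohortValidationError on failure."""
    regions = set(patient.sampling_units)
    primaries = {
        u.tumour_id
        for u in patient.sampling_units.values()
        if u.tumour_kind == "primary"
    }
    if len(primaries) != 1:
        raise CohortValidationError(
            f"{patient.patient_id}: exactly one primary tumour required, "
            f"found {sorted(primaries)}"
        )
    trunks = [c.cluster_id for c in patient.clusters.values() if c.is_trunk]
    if len(trunks) != 1:
        raise CohortValidationError(
            f"{patient.patient_id}: exactly one trunk cluster required, "
            f"found {trunks}"
        )
    for c in patient.clusters.values():
        dangling = set(c.ccf) - regions
        if dangling:
            raise CohortValidationError(
                f"cluster {c.cluster_id} references unknown regions: "
                f"{sorted(dangling)}"
            )
    cluster_ids = set(patient.clusters)
    for tree in patient.trees:
        if tree.nodes != cluster_ids:
            raise CohortValidationError(
                f"{patient.patient_id}: tree rank {tree.rank} nodes do not "
                f"match the cluster table"
            )
        if tree.root != trunks[0]:
            raise CohortValidationError(
                f"{patient.patient_id}: tree root {tree.root} is not the trunk"
            )
    for rid in patient.segment_profiles:
        if rid not in regions:
            raise CohortValidationError(f"segments reference unknown region {rid}")
    for cid in patient.wgd_calls:
        if cid not in cluster_ids:
            raise CohortValidationError(f"WGD call on unknown cluster {cid}")
    for gene, kind, cid in patient.driver_events:
        if cid not in cluster_ids:
            raise CohortValidationError(
                f"driver event {gene}/{kind} on unknown cluster {cid}"
            )
    for (cid, rid) in patient.mutant_reads:
        if cid not in cluster_ids or rid not in regions:
            raise CohortValidationError(
                f"read-support entry ({cid}, {rid}) does not resolve"
            )
    tumour_ids = {u.tumour_id for u in patient.sampling_units.values()}
    for day, detected in patient.scan_records:
        unknown = set(detected) - tumour_ids
        if unknown:
            raise CohortValidationError(
                f"scan at day {day} lists unknown tumours {sorted(unknown)}"
            )
    days = [
        d
        for d in (patient.surgery_day, patient.relapse_day, patient.death_day)
        if d is not None
    ]
    if days != sorted(days):
        raise CohortValidationError(
            f"{patient.patient_id}: surgery <= relapse <= death violated"
        )


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------

def _read_tsv(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise CohortValidationError(f"missing file: {path}")
    df = pd.read_csv(path, sep="\t", na_values=["."], dtype={"chrom": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing columns {missing}")
    return df


def read_patient(directory: str | Path, one_based: bool = False) -> Patient:
    """Load and cross-validate a patient directory.

    Required files: ``samples.tsv``, ``clusters.tsv``, ``tree.json``.
    Optional: ``segments.tsv``, ``subclone_segments.tsv``, ``events.tsv``,
    ``scans.tsv``, ``reads.tsv``, ``contexts.tsv``, ``patient.json``.
    """
    directory = Path(directory)

    samples = _read_tsv(
        directory / "samples.tsv",
        ["region_id", "tumour_id", "tumour_kind", "anatomical_site",
         "purity", "ploidy"],
    )
    units: dict[str, SamplingUnit] = {}
    for i, row in samples.iterrows():
        try:
            qual = row.get("cavity_qualifier")
            units[str(row.region_id)] = SamplingUnit(
                region_id=str(row.region_id),
                tumour_id=str(row.tumour_id),
                tumour_kind=str(row.tumour_kind),
                anatomical_site=str(row.anatomical_site),
                purity=float(row.purity),
                ploidy=float(row.ploidy),
                collection=str(row.get("collection", "autopsy")),
                cavity_qualifier=None if pd.isna(qual) else str(qual),
            )
        except (TypeError, ValueError) as exc:
            raise CohortValidationError(
                f"samples.tsv line {i + 2}: {exc}"
            ) from exc

    cdf = _read_tsv(
        directory / "clusters.tsv",
        ["cluster_id", "region_id", "ccf", "n_mutations"],
    )
    clusters: dict[str, MutationCluster] = {}
    for cid, grp in cdf.groupby("cluster_id", sort=True):
        n_mut = int(grp.n_mutations.iloc[0])
        ccf = {}
        for i, row in grp.iterrows():
            try:
                ccf[str(row.region_id)] = float(row.ccf)
            except (TypeError, ValueError) as exc:
                raise CohortValidationError(
                    f"clusters.tsv line {i + 2}: malformed CCF {row.ccf!r}"
                ) from exc
        is_trunk = bool(grp.get("is_trunk", pd.Series([0])).iloc[0])
        clusters[str(cid)] = MutationCluster(
            cluster_id=str(cid), ccf=ccf, n_mutations=n_mut, is_trunk=is_trunk
        )

    tree_path = directory / "tree.json"
    if not tree_path.exists():
        raise CohortValidationError(f"missing file: {tree_path}")
    tree_doc = json.loads(tree_path.read_text())
    trees = []
    for entry in tree_doc["trees"]:
        parent = {str(c): str(p) for p, c in entry["edges"]}
        nodes = set(parent) | set(parent.values())
        if not nodes:  # single-cluster patient
            nodes = set(clusters)
        trees.append(
            CloneTree(
                nodes=nodes,
                parent=parent,
                sce=float(entry.get("sce", 0.0)),
                rank=int(entry.get("rank", 1)),
            )
        )
    trees.sort(key=lambda t: t.rank)

    profiles: dict[str, SegmentProfile] = {}
    seg_path = directory / "segments.tsv"
    if seg_path.exists():
        sdf = _read_tsv(
            seg_path,
            ["region_id", "chrom", "start", "end", "cn_major", "cn_minor"],
        )
        shift = 1 if one_based else 0
        for rid, grp in sdf.groupby("region_id", sort=True):
            segs = []
            for i, row in grp.iterrows():
                hap = row.get("major_haplotype")
                segs.append(
                    Segment(
                        chrom=str(row.chrom),
                        start=int(row.start) - shift,
                        end=int(row.end),
                        cn_major=float(row.cn_major),
                        cn_minor=float(row.cn_minor),
                        major_haplotype=None if pd.isna(hap) else str(hap),
                    )
                )
            profiles[str(rid)] = SegmentProfile(region_id=str(rid), segments=segs)

    subclone_profiles: dict[str, list[Segment]] = {}
    sub_path = directory / "subclone_segments.tsv"
    if sub_path.exists():
        sub = _read_tsv(
            sub_path,
            ["cluster_id", "chrom", "start", "end", "cn_major", "cn_minor"],
        )
        shift = 1 if one_based else 0
        for cid, grp in sub.groupby("cluster_id", sort=True):
            subclone_profiles[str(cid)] = [
                Segment(
                    chrom=str(r.chrom),
                    start=int(r.start) - shift,
                    end=int(r.end),
                    cn_major=float(r.cn_major),
                    cn_minor=float(r.cn_minor),
                    major_haplotype=(
                        None if pd.isna(r.get("major_haplotype"))
                        else str(r.get("major_haplotype"))
                    ),
                )
                for _, r in grp.iterrows()
            ]

    wgd_calls: list[str] = []
    driver_events: list[tuple[str, str, str]] = []
    ev_path = directory / "events.tsv"
    if ev_path.exists():
        edf = _read_tsv(ev_path, ["gene", "kind", "cluster_id"])
        for _, row in edf.iterrows():
            kind = str(row.kind)
            if kind == "wgd":
                wgd_calls.append(str(row.cluster_id))
            else:
                driver_events.append((str(row.gene), kind, str(row.cluster_id)))

    scan_records: list[tuple[int, tuple[str, ...]]] = []
    scan_path = directory / "scans.tsv"
    if scan_path.exists():
        sdf = _read_tsv(scan_path, ["scan_day", "detected_tumours"])
        for _, row in sdf.iterrows():
            detected: tuple[str, ...] = ()
            if not pd.isna(row.detected_tumours):
                detected = tuple(
                    t for t in str(row.detected_tumours).split(",") if t
                )
            scan_records.append((int(row.scan_day), detected))
        scan_records.sort()

    mutant_reads: dict[tuple[str, str], int] = {}
    reads_path = directory / "reads.tsv"
    if reads_path.exists():
        rdf = _read_tsv(reads_path, ["cluster_id", "region_id", "mutant_reads"])
        for _, row in rdf.iterrows():
            mutant_reads[(str(row.cluster_id), str(row.region_id))] = int(
                row.mutant_reads
            )

    context_counts = None
    ctx_path = directory / "contexts.tsv"
    if ctx_path.exists():
        context_counts = pd.read_csv(ctx_path, sep="\t", index_col=0)
        context_counts.index = context_counts.index.astype(str)

    meta = {}
    meta_path = directory / "patient.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())

    patient = Patient(
        patient_id=str(meta.get("patient_id", directory.name)),
        sampling_units=units,
        clusters=clusters,
        trees=trees,
        segment_profiles=profiles,
        subclone_profiles=subclone_profiles,
        wgd_calls=wgd_calls,
        driver_events=driver_events,
        scan_records=scan_records,
        mutant_reads=mutant_reads,
        context_counts=context_counts,
        surgery_day=int(meta.get("surgery_day", 0)),
        relapse_day=meta.get("relapse_day"),
        death_day=meta.get("death_day"),
        platinum_treated=bool(meta.get("platinum_treated", False)),
    )
    validate_patient(patient)
    return patient


def write_patient(patient: Patient, directory: str | Path) -> None:
    """Emit the full patient file set (inverse of :func:`read_patient`)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    rows = [
        {
            "region_id": u.region_id,
            "tumour_id": u.tumour_id,
            "tumour_kind": u.tumour_kind,
            "anatomical_site": u.anatomical_site,
            "cavity_qualifier": u.cavity_qualifier or ".",
            "purity": u.purity,
            "ploidy": u.ploidy,
            "collection": u.collection,
        }
        for u in sorted(patient.sampling_units.values(), key=lambda u: u.region_id)
    ]
    pd.DataFrame(rows).to_csv(directory / "samples.tsv", sep="\t", index=False)

    crows = []
    for c in sorted(patient.clusters.values(), key=lambda c: c.cluster_id):
        for rid in sorted(c.ccf):
            crows.append(
                {
                    "cluster_id": c.cluster_id,
                    "region_id": rid,
                    "ccf": c.ccf[rid],
                    "n_mutations": c.n_mutations,
                    "is_trunk": int(c.is_trunk),
                }
            )
    pd.DataFrame(crows).to_csv(directory / "clusters.tsv", sep="\t", index=False)

    tree_doc = {
        "trees": [
            {"rank": t.rank, "sce": t.sce, "edges": t.edges()}
            for t in patient.trees
        ]
    }
    (directory / "tree.json").write_text(json.dumps(tree_doc, indent=1))

    if patient.segment_profiles:
        srows = []
        for rid in sorted(patient.segment_profiles):
            for s in patient.segment_profiles[rid].segments:
                srows.append(
                    {
                        "region_id": rid,
                        "chrom": s.chrom,
                        "start": s.start,
                        "end": s.end,
                        "cn_major": s.cn_major,
                        "cn_minor": s.cn_minor,
                        "major_haplotype": s.major_haplotype or ".",
                    }
                )
        pd.DataFrame(srows).to_csv(
            directory / "segments.tsv", sep="\t", index=False
        )

    if patient.subclone_profiles:
        srows = []
        for cid in sorted(patient.subclone_profiles):
            for s in patient.subclone_profiles[cid]:
                srows.append(
                    {
                        "cluster_id": cid,
                        "chrom": s.chrom,
                        "start": s.start,
                        "end": s.end,
                        "cn_major": s.cn_major,
                        "cn_minor": s.cn_minor,
                        "major_haplotype": s.major_haplotype or ".",
                    }
                )
        pd.DataFrame(srows).to_csv(
            directory / "subclone_segments.tsv", sep="\t", index=False
        )

    events = [
        {"gene": g, "kind": k, "cluster_id": cid}
        for g, k, cid in patient.driver_events
    ] + [{"gene": ".", "kind": "wgd", "cluster_id": cid} for cid in patient.wgd_calls]
    if events:
        pd.DataFrame(events).to_csv(
            directory / "events.tsv", sep="\t", index=False
        )

    if patient.scan_records:
        pd.DataFrame(
            [
                {
                    "scan_day": day,
                    "detected_tumours": ",".join(detected) if detected else ".",
                }
                for day, detected in sorted(patient.scan_records)
            ]
        ).to_csv(directory / "scans.tsv", sep="\t", index=False)

    if patient.mutant_reads:
        pd.DataFrame(
            [
                {"cluster_id": cid, "region_id": rid, "mutant_reads": n}
                for (cid, rid), n in sorted(patient.mutant_reads.items())
            ]
        ).to_csv(directory / "reads.tsv", sep="\t", index=False)

    if patient.context_counts is not None:
        patient.context_counts.sort_index().to_csv(
            directory / "contexts.tsv", sep="\t"
        )

    meta = {
        "patient_id": patient.patient_id,
        "surgery_day": patient.surgery_day,
        "relapse_day": patient.relapse_day,
        "death_day": patient.death_day,
        "platinum_treated": patient.platinum_treated,
    }
    (directory / "patient.json").write_text(json.dumps(meta, indent=1))


# --------------------------------------------------------------------------
# Newick export
# --------------------------------------------------------------------------

def write_tree_newick(
    tree: CloneTree,
    clusters: dict[str, MutationCluster],
    out: str | Path | None = None,
) -> str:
    """Serialise a clone tree to Newick.

    Cluster ids become labels and branch lengths are the child cluster's
    mutation count; children are emitted in lexicographic order.
    """
    kids = tree.children()

    def render(node: str) -> str:
        length = clusters[node].n_mutations if node in clusters else 0
        if kids[node]:
            inner = ",".join(render(c) for c in kids[node])
            return f"({inner}){node}:{length}"
        return f"{node}:{length}"

    text = render(tree.root) + ";"
    if out is not None:
        Path(out).write_text(text + "\n")
    return text
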