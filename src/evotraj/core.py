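"""Core domain types for tumour cohorts and their tabular input schemas.

The in-memory model mirrors the outputs of allele-specific copy-number
callers (Battenberg-style segment tables with up to two subclonal states)
and SNV subclonal clustering (DPClust-style cluster CCFs), plus a per-sample
metadata sheet.  Coordinates are held internally as 0-based half-open;
input tables default to 1-based inclusive as produced by the upstream
callers.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

FRACTION_TOL = 1e-6

SHEET_COLUMNS = [
    "sample_id", "purity", "nrpcc", "wgd", "smoking", "ancestry", "sex",
    "age_dx", "sbs4", "sv_count", "kataegis", "snv_total", "survival_weeks",
]
SEGMENT_COLUMNS = [
    "sample_id", "chrom", "start", "end",
    "major1", "minor1", "frac1", "major2", "minor2", "frac2",
]
SNV_COLUMNS = ["sample_id", "gene", "cluster_id", "multiplicity"]
CLUSTER_COLUMNS = ["sample_id", "cluster_id", "ccf", "n_mutations"]


class SchemaError(ValueError):
    """An input table does not match the documented schema."""


class ValidationError(ValueError):
    """An input record violates a domain invariant."""


def normalize_chrom(chrom: str) -> str:
    """Normalize chromosome names to the "chr"-prefixed convention."""
    chrom = str(chrom)
    return chrom if chrom.startswith("chr") else "chr" + chrom


@dataclass(frozen=True)
class CNState:
    """One cellular copy-number state: allele-specific copies and the
    fraction of tumour cells in which it is found."""

    major: int
    minor: int
    fraction: float

    def __post_init__(self):
        if self.major < 0 or self.minor < 0:
            raise ValidationError(
                f"negative copy number: {self.major}+{self.minor}")
        if self.minor > self.major:
            raise ValidationError(
                f"minor > major copy number: {self.major}+{self.minor}")
        if not (0.0 < self.fraction <= 1.0 + FRACTION_TOL):
            raise ValidationError(f"state fraction {self.fraction} not in (0,1]")


@dataclass(frozen=True)
class CopyNumberSegment:
    """An allele-specific copy-number interval with 1 or 2 cellular states.

    A segment is clonal iff it carries exactly one state; a subclonal
    segment has two states whose cell fractions sum to 1.
    """

    chrom: str
    start: int
    end: int
    states: tuple

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError(
                f"segment end {self.end} <= start {self.start} on {self.chrom}")
        if not 1 <= len(self.states) <= 2:
            raise ValidationError(
                f"segment must have 1-2 states, got {len(self.states)}")
        total = sum(s.fraction for s in self.states)
        if abs(total - 1.0) > FRACTION_TOL:
            raise ValidationError(
                f"state fractions sum to {total}, expected 1")

    @property
    def clonal(self) -> bool:
        return len(self.states) == 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SubcloneCluster:
    """A mutation cluster with its cancer cell fraction."""

    cluster_id: str
    ccf: float
    n_mutations: int = 0

    def __post_init__(self):
        if not (0.0 < self.ccf <= 1.0):
            raise ValidationError(f"cluster CCF {self.ccf} not in (0,1]")
        if self.n_mutations < 0:
            raise ValidationError("n_mutations must be >= 0")


@dataclass(frozen=True)
class SnvCall:
    """A driver-gene SNV with its cluster assignment and mutant multiplicity."""

    gene: str
    cluster_id: str
    multiplicity: int = 1

    def __post_init__(self):
        if self.multiplicity < 1:
            raise ValidationError("SNV multiplicity must be >= 1")


@dataclass
class TumourSample:
    sample_id: str
    purity: float
    nrpcc: float
    wgd: bool
    smoking: str = "never"            # {ever, never}
    ancestry: str = "OTHER"           # {EUR, EAS, OTHER}
    sex: str = "F"                    # {M, F}
    age_dx: float = 65.0
    sbs4_positive: bool = False
    segments: list = field(default_factory=list)
    snvs: list = field(default_factory=list)
    clusters: list = field(default_factory=list)
    sv_count: int = 0
    kataegis_count: int = 0
    snv_total: int = 0
    survival_weeks: float | None = None
    signature_activities: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.purity <= 1.0):
            raise ValidationError(
                f"{self.sample_id}: purity {self.purity} not in (0,1]")
        for count in (self.sv_count, self.kataegis_count, self.snv_total):
            if count < 0:
                raise ValidationError(f"{self.sample_id}: negative count")
        self.validate_segments()
        cluster_ids = {c.cluster_id for c in self.clusters}
        for snv in self.snvs:
            if snv.cluster_id not in cluster_ids:
                raise ValidationError(
                    f"{self.sample_id}: SNV in {snv.gene} references unknown "
                    f"cluster {snv.cluster_id!r}")

    def validate_segments(self):
        by_chrom: dict[str, list] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for prev, cur in zip(segs, segs[1:]):
                if cur.start < prev.end:
                    raise ValidationError(
                        f"{self.sample_id}: overlapping segments on {chrom} "
                        f"at {prev.start}-{prev.end} and {cur.start}-{cur.end}")

    @property
    def clonal_cluster(self) -> SubcloneCluster | None:
        if not self.clusters:
            return None
        return max(self.clusters, key=lambda c: c.ccf)

    def cluster(self, cluster_id: str) -> SubcloneCluster:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise ValidationError(
            f"{self.sample_id}: unknown cluster {cluster_id!r}")


@dataclass
class Cohort:
    samples: list
    driver_list: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample_ids: {dupes}")

    def __len__(self):
        return len(self.samples)

    def sample(self, sample_id: str) -> TumourSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


# ---------------------------------------------------------------------------
# Readers / writers


def _require_columns(df: pd.DataFrame, required: list, path: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"1", "true", "t", "yes"}:
        return True
    if text in {"0", "false", "f", "no"}:
        return False
    raise SchemaError(f"cannot parse boolean value {value!r}")


def read_driver_list(path: str) -> list:
    with open(path) as handle:
        genes = [line.strip() for line in handle if line.strip()
                 and not line.startswith("#")]
    return genes


def read_cohort(sample_sheet_path, segments_path, snv_path, clusters_path,
                driver_list_path=None, *, coords: str = "1-inclusive",
                signature_path=None) -> Cohort:
    """Assemble a :class:`Cohort` from the five tabular inputs.

    ``coords`` declares the coordinate dialect of the segment table:
    ``"1-inclusive"`` (the Battenberg-style default) or ``"0-half-open"``.
    Internally everything is 0-based half-open.
    """
    if coords not in {"1-inclusive", "0-half-open"}:
        raise SchemaError(f"unknown coordinate dialect {coords!r}")
    offset = 1 if coords == "1-inclusive" else 0

    read_kw = {"sep": "\t", "float_precision": "round_trip"}
    sheet = pd.read_csv(sample_sheet_path, dtype={"sample_id": str}, **read_kw)
    _require_columns(sheet, SHEET_COLUMNS, str(sample_sheet_path))
    segs = pd.read_csv(segments_path, dtype={"sample_id": str}, **read_kw)
    _require_columns(segs, SEGMENT_COLUMNS, str(segments_path))
    snvs = pd.read_csv(snv_path, dtype={"sample_id": str, "cluster_id": str},
                       **read_kw)
    _require_columns(snvs, SNV_COLUMNS, str(snv_path))
    clusters = pd.read_csv(clusters_path,
                           dtype={"sample_id": str, "cluster_id": str},
                           **read_kw)
    _require_columns(clusters, CLUSTER_COLUMNS, str(clusters_path))

    driver_list = read_driver_list(driver_list_path) if driver_list_path else []
    driver_set = set(driver_list)

    activities: dict[str, dict] = {}
    if signature_path is not None:
        acts = pd.read_csv(signature_path, sep="\t", dtype={"sample_id": str},
                           float_precision="round_trip")
        _require_columns(acts, ["sample_id"], str(signature_path))
        for _, row in acts.iterrows():
            activities[row["sample_id"]] = {
                c: float(row[c]) for c in acts.columns if c != "sample_id"}

    seg_groups = {k: v for k, v in segs.groupby("sample_id")}
    snv_groups = {k: v for k, v in snvs.groupby("sample_id")}
    cluster_groups = {k: v for k, v in clusters.groupby("sample_id")}

    samples = []
    for _, row in sheet.iterrows():
        sid = row["sample_id"]
        sample_segments = []
        for idx, seg in seg_groups.get(sid, pd.DataFrame()).iterrows():
            states = [CNState(int(seg["major1"]), int(seg["minor1"]),
                              float(seg["frac1"]))]
            if not pd.isna(seg.get("major2")) and str(seg.get("major2")) != "":
                states.append(CNState(int(seg["major2"]), int(seg["minor2"]),
                                      float(seg["frac2"])))
            try:
                sample_segments.append(CopyNumberSegment(
                    chrom=normalize_chrom(seg["chrom"]),
                    start=int(seg["start"]) - offset,
                    end=int(seg["end"]),
                    states=tuple(states)))
            except ValidationError as exc:
                raise ValidationError(
                    f"sample {sid}, segment row {idx}: {exc}") from exc

        sample_clusters = [
            SubcloneCluster(str(c["cluster_id"]), float(c["ccf"]),
                            int(c["n_mutations"]))
            for _, c in cluster_groups.get(sid, pd.DataFrame()).iterrows()]

        sample_snvs = []
        for _, s in snv_groups.get(sid, pd.DataFrame()).iterrows():
            gene = str(s["gene"])
            if driver_set and gene not in driver_set:
                raise ValidationError(
                    f"sample {sid}: SNV gene {gene!r} not in driver list")
            sample_snvs.append(SnvCall(gene, str(s["cluster_id"]),
                                       int(s["multiplicity"])))

        survival = row["survival_weeks"]
        samples.append(TumourSample(
            sample_id=sid,
            purity=float(row["purity"]),
            nrpcc=float(row["nrpcc"]),
            wgd=_parse_bool(row["wgd"]),
            smoking=str(row["smoking"]),
            ancestry=str(row["ancestry"]),
            sex=str(row["sex"]),
            age_dx=float(row["age_dx"]),
            sbs4_positive=_parse_bool(row["sbs4"]),
            segments=sample_segments,
            snvs=sample_snvs,
            clusters=sample_clusters,
            sv_count=int(row["sv_count"]),
            kataegis_count=int(row["kataegis"]),
            snv_total=int(row["snv_total"]),
            survival_weeks=None if pd.isna(survival) else float(survival),
            signature_activities=activities.get(sid, {}),
        ))

    return Cohort(samples=samples, driver_list=driver_list,
                  provenance={"coords": coords})


def write_cohort(cohort: Cohort, out_dir: str) -> dict:
    """Write the cohort as the TSV file set that :func:`read_cohort`
    round-trips (coordinates written 1-based inclusive)."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {name: os.path.join(out_dir, name + ".tsv")
             for name in ("sample_sheet", "segments", "snvs", "clusters")}
    paths["driver_list"] = os.path.join(out_dir, "driver_list.txt")

    sheet_rows, seg_rows, snv_rows, cluster_rows = [], [], [], []
    signature_names: list[str] = []
    for s in cohort.samples:
        sheet_rows.append({
            "sample_id": s.sample_id, "purity": repr(s.purity),
            "nrpcc": repr(s.nrpcc), "wgd": int(s.wgd), "smoking": s.smoking,
            "ancestry": s.ancestry, "sex": s.sex, "age_dx": repr(s.age_dx),
            "sbs4": int(s.sbs4_positive), "sv_count": s.sv_count,
            "kataegis": s.kataegis_count, "snv_total": s.snv_total,
            "survival_weeks": "" if s.survival_weeks is None
            else repr(s.survival_weeks)})
        for seg in s.segments:
            row = {"sample_id": s.sample_id, "chrom": seg.chrom,
                   "start": seg.start + 1, "end": seg.end,
                   "major1": seg.states[0].major, "minor1": seg.states[0].minor,
                   "frac1": repr(seg.states[0].fraction),
                   "major2": "", "minor2": "", "frac2": ""}
            if len(seg.states) == 2:
                row.update(major2=seg.states[1].major,
                           minor2=seg.states[1].minor,
                           frac2=repr(seg.states[1].fraction))
            seg_rows.append(row)
        for snv in s.snvs:
            snv_rows.append({"sample_id": s.sample_id, "gene": snv.gene,
                             "cluster_id": snv.cluster_id,
                             "multiplicity": snv.multiplicity})
        for c in s.clusters:
            cluster_rows.append({"sample_id": s.sample_id,
                                 "cluster_id": c.cluster_id,
                                 "ccf": repr(c.ccf),
                                 "n_mutations": c.n_mutations})
        for name in s.signature_activities:
            if name not in signature_names:
                signature_names.append(name)

    pd.DataFrame(sheet_rows, columns=SHEET_COLUMNS).to_csv(
        paths["sample_sheet"], sep="\t", index=False)
    pd.DataFrame(seg_rows, columns=SEGMENT_COLUMNS).to_csv(
        paths["segments"], sep="\t", index=False)
    pd.DataFrame(snv_rows, columns=SNV_COLUMNS).to_csv(
        paths["snvs"], sep="\t", index=False)
    pd.DataFrame(cluster_rows, columns=CLUSTER_COLUMNS).to_csv(
        paths["clusters"], sep="\t", index=False)
    with open(paths["driver_list"], "w") as handle:
        for gene in cohort.driver_list:
            handle.write(gene + "\n")

    if signature_names:
        paths["signatures"] = os.path.join(out_dir, "signatures.tsv")
        rows = []
        for s in cohort.samples:
            row = {"sample_id": s.sample_id}
            row.update({name: repr(float(s.signature_activities.get(name, 0.0)))
                        for name in signature_names})
            rows.append(row)
        pd.DataFrame(rows, columns=["sample_id"] + signature_names).to_csv(
            paths["signatures"], sep="\t", index=False)
    return paths


def read_cohort_dir(in_dir: str, *, coords: str = "1-inclusive") -> Cohort:
    """Read a cohort from a directory written by :func:`write_cohort`."""
    sig = os.path.join(in_dir, "signatures.tsv")
    return read_cohort(
        os.path.join(in_dir, "sample_sheet.tsv"),
        os.path.join(in_dir, "segments.tsv"),
        os.path.join(in_dir, "snvs.tsv"),
        os.path.join(in_dir, "clusters.tsv"),
        os.path.join(in_dir, "driver_list.txt"),
        coords=coords,
        signature_path=sig if os.path.exists(sig) else None)


# ---------------------------------------------------------------------------
# Quality control


def qc_filter(cohort: Cohort, min_nrpcc: float = 10.0,
              min_purity: float = 0.30) -> Cohort:
    """Retain samples with nrpcc >= min_nrpcc and purity >= min_purity.

    Thresholds are inclusive ("a minimum of" reads the boundary as passing).
    Idempotent and order-preserving; excluded sample ids are logged.
    """
    if min_nrpcc < 0 or min_purity < 0:
        raise ValidationError("QC thresholds must be >= 0")
    kept, excluded = [], []
    for s in cohort.samples:
        if s.nrpcc >= min_nrpcc and s.purity >= min_purity:
            kept.append(s)
        else:
            excluded.append(s.sample_id)
    if excluded:
        logger.info("qc_filter excluded %d samples: %s",
                    len(excluded), ", ".join(excluded))
    if not kept:
        logger.warning("qc_filter removed every sample")
    return Cohort(samples=kept, driver_list=list(cohort.driver_list),
                  provenance=dict(cohort.provenance,
                                  qc={"min_nrpcc": min_nrpcc,
                                      "min_purity": min_purity}))


def cohorts_equal(a: Cohort, b: Cohort, tol: float = 0.0) -> bool:
    """Structural equality of two cohorts (numeric fields exact by default)."""
    if len(a) != len(b) or a.driver_list != b.driver_list:
        return False

    def close(x, y):
        if x is None or y is None:
            return x is y
        return math.isclose(x, y, rel_tol=tol, abs_tol=tol)

    for sa, sb in zip(a.samples, b.samples):
        if (sa.sample_id != sb.sample_id or sa.wgd != sb.wgd
                or sa.smoking != sb.smoking or sa.ancestry != sb.ancestry
                or sa.sex != sb.sex or sa.sbs4_positive != sb.sbs4_positive
                or sa.sv_count != sb.sv_count
                or sa.kataegis_count != sb.kataegis_count
                or sa.snv_total != sb.snv_total):
            return False
        if not (close(sa.purity, sb.purity) and close(sa.nrpcc, sb.nrpcc)
                and close(sa.age_dx, sb.age_dx)
                and close(sa.survival_weeks, sb.survival_weeks)):
            return False
        if sorted(sa.snvs, key=lambda x: (x.gene, x.cluster_id)) != \
                sorted(sb.snvs, key=lambda x: (x.gene, x.cluster_id)):
            return False
        ca = sorted(sa.clusters, key=lambda c: c.cluster_id)
        cb = sorted(sb.clusters, key=lambda c: c.cluster_id)
        if len(ca) != len(cb):
            return False
        for x, y in zip(ca, cb):
            if x.cluster_id != y.cluster_id or x.n_mutations != y.n_mutations \
                    or not close(x.ccf, y.ccf):
                return False
        ga = sorted(sa.segments, key=lambda g: (g.chrom, g.start))
        gb = sorted(sb.segments, key=lambda g: (g.chrom, g.start))
        if len(ga) != len(gb):
            return False
        for x, y in zip(ga, gb):
            if (x.chrom, x.start, x.end) != (y.chrom, y.start, y.end):
                return False
            if len(x.states) != len(y.states):
                return False
            for u, v in zip(x.states, y.states):
                if (u.major, u.minor) != (v.major, v.minor) \
                        or not close(u.fraction, v.fraction):
                    return False
        keys = set(sa.signature_activities) | set(sb.signature_activities)
        for k in keys:
            if not close(sa.signature_activities.get(k, 0.0),
                         sb.signature_activities.get(k, 0.0)):
                return False
    return True
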