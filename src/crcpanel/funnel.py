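"""The variant filter funnel.

Two cascades are implemented as ordered, individually reportable stages:

* the candidate-pathogenic (PGV) funnel — upstream PASS status, functional
  class and location, population frequency, ClinVar category, a
  recurrent-indel artifact screen, and depth of coverage, followed by
  deduplication into unique variants with their carrier lists;
* the uncertain-significance (VUS) funnel — ClinVar "uncertain" calls put
  through depth, exonic/non-synonymous and frequency filters and
  deduplicated the same way.

Every stage only removes records, so retained counts are monotone
non-increasing along the cascade; this is asserted on every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .hgvs import VariantKey, VariantKind
from .io import AnnotationRecord, ClinVar, CohortTable, Location, PATHOGENIC_TIER
from .panel import Panel

__all__ = [
    "FilterConfig", "StageCount", "FunnelReport", "UniqueVariant",
    "stage_pass", "stage_functional", "stage_maf", "stage_depth",
    "stage_clinvar", "flag_artifacts", "dedupe",
    "run_pgv_funnel", "run_vus_funnel",
]

#: ClinVar categories that count as pathogenic-tier for the synonymous rescue.
CLINVAR_PATH_TIER = frozenset({
    ClinVar.PATHOGENIC, ClinVar.LIKELY_PATHOGENIC, ClinVar.PATH_OR_LP})

DEFAULT_CLINVAR_KEEP = frozenset({
    ClinVar.PATHOGENIC, ClinVar.LIKELY_PATHOGENIC, ClinVar.PATH_OR_LP,
    ClinVar.UNCERTAIN, ClinVar.CONFLICTING, ClinVar.NO_ENTRY})


@dataclass(frozen=True)
class FilterConfig:
    """Tunable thresholds of both funnels.

    ``maf_max`` — retain minor allele frequency strictly below this (or
    unknown); ``depth_min`` — retain depth strictly above this;
    ``flank_bp`` — how far into an intron a variant still counts as
    "flanking" an exon; ``artifact_sample_fraction`` — an indel key seen in
    more than this fraction of cohort samples is treated as a recurrent
    calling artifact; ``splice_flank_bp`` — exonic distance from an
    annotated exon boundary within which a variant is a splice candidate.
    """

    maf_max: float = 0.05
    depth_min: int = 30
    flank_bp: int = 20
    clinvar_keep: frozenset = DEFAULT_CLINVAR_KEEP
    artifact_sample_fraction: float = 0.2
    synonymous_rescue: bool = True
    splice_flank_bp: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_max <= 1.0:
            raise ValueError("maf_max must be in (0, 1]")
        if self.depth_min < 0 or self.flank_bp < 0:
            raise ValueError("depth_min and flank_bp must be non-negative")


@dataclass(frozen=True)
class StageCount:
    name: str
    n_records: int
    n_unique: int


@dataclass
class UniqueVariant:
    """One unique variant after dedup, with carrier provenance."""

    key: VariantKey
    records: list[AnnotationRecord]

    @property
    def carriers(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.sample_id, None)
        return list(seen)

    @property
    def representative(self) -> AnnotationRecord:
        return self.records[0]


@dataclass
class FunnelReport:
    """Per-stage retained counts plus the final retained material."""

    stages: list[StageCount]
    records: list[AnnotationRecord]
    unique: list[UniqueVariant]
    flagged_artifacts: list[AnnotationRecord] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = [s.n_records for s in self.stages]
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise AssertionError(
                f"funnel stage counts must be non-increasing: {counts}")
        if self.stages and self.stages[-1].n_records != len(self.records):
            raise AssertionError("final stage count != retained record count")

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"stage": s.name, "records": s.n_records, "unique": s.n_unique}
                for s in self.stages],
            "n_final_records": len(self.records),
            "n_unique_variants": len(self.unique),
            "n_flagged_artifacts": len(self.flagged_artifacts),
            **self.extras,
        }


def _n_unique(records) -> int:
    return len({r.key for r in records})


def stage_pass(records) -> list[AnnotationRecord]:
    """Retain only calls the upstream caller labelled PASS."""
    return [r for r in records if r.filter_status == "PASS"]


def _is_splice_candidate(r: AnnotationRecord, panel: Panel | None,
                         cfg: FilterConfig) -> bool:
    if panel is None:
        v = r.hgvs
        offs = [o for o in (v.intron_offset, v.end_offset) if o is not None]
        return any(abs(o) <= 2 for o in offs) or v.splice_candidate
    return panel.is_splice_candidate(r.hgvs, flank_bp=cfg.splice_flank_bp)


def stage_functional(records, cfg: FilterConfig = FilterConfig(),
                     panel: Panel | None = None) -> list[AnnotationRecord]:
    """Drop synonymous calls and restrict to exonic/flanking locations.

    A synonymous call survives only under the rescue rule: a
    pathogenic-tier ClinVar entry or splice candidacy (an exonic base at an
    annotated exon boundary) keeps it in play — the guard against writing
    off a splice-disrupting "silent" change.
    """
    out = []
    for r in records:
        v = r.hgvs
        if v.kind == VariantKind.SYNONYMOUS:
            if not (cfg.synonymous_rescue
                    and (r.clinvar in CLINVAR_PATH_TIER
                         or _is_splice_candidate(r, panel, cfg))):
                continue
        if r.location in (Location.UTR, Location.INTERGENIC):
            continue
        if r.location == Location.INTRONIC or v.intron_offset is not None:
            offs = [o for o in (v.intron_offset, v.end_offset) if o is not None]
            if not offs or min(abs(o) for o in offs) > cfg.flank_bp:
                continue
        out.append(r)
    return out


def stage_maf(records, cfg: FilterConfig = FilterConfig()) -> list[AnnotationRecord]:
    """Retain rare variants: MAF unknown or strictly below the cutoff."""
    return [r for r in records if r.maf is None or r.maf < cfg.maf_max]


def stage_depth(records, cfg: FilterConfig = FilterConfig()) -> list[AnnotationRecord]:
    """Retain calls covered by strictly more than ``depth_min`` reads."""
    return [r for r in records if r.depth > cfg.depth_min]


def stage_clinvar(records, cfg: FilterConfig = FilterConfig()) -> list[AnnotationRecord]:
    """Retain ClinVar categories of interest (benign tiers drop out)."""
    return [r for r in records if r.clinvar in cfg.clinvar_keep]


def flag_artifacts(records, n_samples: int,
                   cfg: FilterConfig = FilterConfig()):
    """Flag recurrent indel calls as likely alignment artifacts.

    Small insertions/deletions called at the same position in an
    implausibly large fraction of samples are a known signature of
    homopolymer miscalls on amplicon sequencing; they are removed from the
    prioritized list but preserved (flagged) for the report.  Substitutions
    are never flagged.  Returns ``(kept, flagged)``.
    """
    if n_samples <= 0:
        n_samples = len({r.sample_id for r in records}) or 1
    carriers: dict[VariantKey, set] = {}
    for r in records:
        if r.hgvs.is_indel:
            carriers.setdefault(r.key, set()).add(r.sample_id)
    bad = {k for k, s in carriers.items()
           if len(s) > cfg.artifact_sample_fraction * n_samples}
    kept, flagged = [], []
    for r in records:
        if r.key in bad:
            flagged.append(replace(r, artifact=True))
        else:
            kept.append(r)
    return kept, flagged


def dedupe(records) -> list[UniqueVariant]:
    """Collapse records to unique variants (first-seen order) with carriers."""
    grouped: dict[VariantKey, UniqueVariant] = {}
    for r in records:
        uv = grouped.get(r.key)
        if uv is None:
            grouped[r.key] = UniqueVariant(key=r.key, records=[r])
        else:
            uv.records.append(r)
    return list(grouped.values())


def run_pgv_funnel(cohort: CohortTable, cfg: FilterConfig = FilterConfig(),
                   panel: Panel | None = None) -> FunnelReport:
    """Run the candidate-pathogenic cascade and report per-stage counts.

    Stage order: PASS -> functional/location -> MAF -> ClinVar ->
    artifact screen -> depth -> dedupe.
    """
    records = list(cohort.records)
    stages = [StageCount("input", len(records), _n_unique(records))]

    def push(name, recs):
        stages.append(StageCount(name, len(recs), _n_unique(recs)))
        return recs

    records = push("pass", stage_pass(records))
    records = push("functional", stage_functional(records, cfg, panel))
    records = push("maf", stage_maf(records, cfg))
    records = push("clinvar", stage_clinvar(records, cfg))
    records, flagged = flag_artifacts(records, cohort.n_patients, cfg)
    push("artifact", records)
    records = push("depth", stage_depth(records, cfg))
    unique = dedupe(records)
    return FunnelReport(stages=stages, records=records, unique=unique,
                        flagged_artifacts=flagged,
                        extras={"n_samples": cohort.n_patients})


def run_vus_funnel(cohort: CohortTable, cfg: FilterConfig = FilterConfig(),
                   panel: Panel | None = None,
                   pgv_carriers=None) -> FunnelReport:
    """Run the uncertain-significance cascade.

    Stage order: ClinVar uncertain -> depth -> exonic & non-synonymous ->
    dedupe -> MAF.  The report carries the unique VUS count, the patients
    with at least one retained VUS, and — when the candidate-pathogenic
    carrier set is supplied — the overlap partition between VUS carriers
    and PGV carriers.
    """
    records = list(cohort.records)
    stages = [StageCount("input", len(records), _n_unique(records))]

    def push(name, recs):
        stages.append(StageCount(name, len(recs), _n_unique(recs)))
        return recs

    records = push("clinvar_uncertain",
                   [r for r in records if r.clinvar == ClinVar.UNCERTAIN])
    records = push("depth", stage_depth(records, cfg))
    records = push("exonic_nonsynonymous",
                   [r for r in records
                    if r.location == Location.EXONIC
                    and r.hgvs.kind != VariantKind.SYNONYMOUS])
    unique = dedupe(records)
    unique = [uv for uv in unique
              if uv.representative.maf is None
              or uv.representative.maf < cfg.maf_max]
    records = [r for uv in unique for r in uv.records]
    stages.append(StageCount("dedupe_maf", len(records), len(unique)))

    vus_carriers = sorted({r.sample_id for r in records})
    extras = {
        "n_unique_vus": len(unique),
        "vus_carriers": vus_carriers,
        "n_vus_carriers": len(vus_carriers),
    }
    if pgv_carriers is not None:
        pgv_carriers = set(pgv_carriers)
        overlap = sorted(set(vus_carriers) & pgv_carriers)
        extras["vus_carriers_with_pgv"] = overlap
        extras["n_vus_carriers_with_pgv"] = len(overlap)
        extras["n_vus_only_carriers"] = len(vus_carriers) - len(overlap)
    return FunnelReport(stages=stages, records=records, unique=unique,
                        extras=extras)
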