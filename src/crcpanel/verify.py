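"""Orthogonal verification of candidate pathogenic calls.

Short-read panel calls in the 3' exons of PMS2 cannot be attributed to a
locus with confidence: the pseudogene PMS2CL is near-identical over that
region, and a call may originate from either copy.  Such calls require
gene-specific confirmation (long-range PCR anchored outside the homology,
followed by sequencing); all other calls are confirmed by conventional
re-sequencing.  The wet-lab outcome enters the pipeline as a per-variant,
per-sample ledger of confirmed/failed/unverified statuses, and patient
resolution is recomputed from the verified call set.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .hgvs import HgvsVariant, VariantKey
from .funnel import UniqueVariant

log = logging.getLogger(__name__)

__all__ = [
    "HomologyRegion", "VerificationStatus", "VerificationLedger",
    "PgvCall", "needs_gene_specific_verification", "apply_ledger",
    "resolve_patients", "default_homology_regions", "read_homology_regions",
    "read_ledger",
]


@dataclass(frozen=True)
class HomologyRegion:
    """A coding-coordinate interval sharing high identity with a pseudogene."""

    gene: str
    cdna_start: int
    cdna_end: int
    pseudogene: str = ""

    def __post_init__(self) -> None:
        if self.cdna_start > self.cdna_end:
            raise ValueError("cdna_start must be <= cdna_end")


class VerificationStatus(str, enum.Enum):
    CONFIRMED_PRESENT = "confirmed_present"
    CONFIRMED_ABSENT = "confirmed_absent"
    UNVERIFIED = "unverified"


@dataclass
class VerificationLedger:
    """Mapping ``(VariantKey, sample_id) -> status``; one status per pair."""

    entries: dict = field(default_factory=dict)

    def status(self, key: VariantKey, sample_id: str) -> VerificationStatus:
        return self.entries.get((key, sample_id), VerificationStatus.UNVERIFIED)

    def set(self, key: VariantKey, sample_id: str,
            status: VerificationStatus) -> None:
        self.entries[(key, str(sample_id))] = VerificationStatus(status)


@dataclass(frozen=True)
class PgvCall:
    """One pathogenic/likely pathogenic call in one patient."""

    key: VariantKey
    sample_id: str
    tier: str = "pathogenic"


def needs_gene_specific_verification(v: HgvsVariant | VariantKey,
                                     regions) -> bool:
    """True iff the variant's coding span intersects a homology region.

    Intronic-offset ends use their anchor exonic coordinate, so a canonical
    splice variant next to a homologous exon is (conservatively) included.
    """
    if isinstance(v, VariantKey):
        from .hgvs import parse_cdna
        v = parse_cdna(v.cdna, gene=v.gene)
    start, end = v.cdna_position, max(v.cdna_end, v.cdna_position)
    for region in regions:
        if region.gene != v.gene:
            continue
        if start <= region.cdna_end and end >= region.cdna_start:
            return True
    return False


def apply_ledger(pgv_calls, ledger: VerificationLedger, regions=()):
    """Split candidate calls into verified and excluded sets.

    A call confirmed absent is excluded.  A call inside a pseudogene
    homology region is excluded unless explicitly confirmed present (its
    locus of origin is otherwise unknowable from short reads).  Everything
    else is retained.  Returns ``(verified, excluded, unverified_homology)``
    where the two excluded lists preserve the input calls for reporting.
    """
    calls = list(pgv_calls)
    known = {(c.key, c.sample_id) for c in calls}
    for key, sid in ledger.entries:
        if (key, sid) not in known:
            log.warning("ledger entry for a call never made: %s in %s", key, sid)

    verified, excluded, unverified = [], [], []
    for call in calls:
        status = ledger.status(call.key, call.sample_id)
        if status == VerificationStatus.CONFIRMED_ABSENT:
            excluded.append(call)
        elif (status == VerificationStatus.UNVERIFIED
              and needs_gene_specific_verification(call.key, regions)):
            unverified.append(call)
        else:
            verified.append(call)
    return verified, excluded, unverified


def resolve_patients(patient_ids, verified_calls) -> dict[str, str]:
    """A patient is resolved iff at least one verified PGV remains."""
    carriers = {c.sample_id for c in verified_calls}
    return {pid: ("resolved" if pid in carriers else "unresolved")
            for pid in patient_ids}


def calls_from_unique(unique_variants, classifications,
                      pgv_tiers=("pathogenic", "likely_pathogenic")):
    """Expand classified unique variants into per-patient PGV calls."""
    calls = []
    for uv in unique_variants:
        cls = classifications.get(uv.key)
        if cls is None:
            continue
        tier = getattr(cls.tier, "value", cls.tier)
        if tier not in pgv_tiers:
            continue
        for sid in uv.carriers:
            calls.append(PgvCall(key=uv.key, sample_id=sid, tier=tier))
    return calls


def read_homology_regions(path: str | Path) -> list[HomologyRegion]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [HomologyRegion(gene=row["gene"].strip().upper(),
                           cdna_start=int(row["cdna_start"]),
                           cdna_end=int(row["cdna_end"]),
                           pseudogene=row.get("pseudogene", ""))
            for _, row in df.iterrows()]


def default_homology_regions() -> list[HomologyRegion]:
    """The shipped default: the 3' portion of PMS2 mirrored in PMS2CL."""
    with resources.as_file(
            resources.files("crcpanel").joinpath("data/pms2_homology.tsv")) as p:
        return read_homology_regions(p)


def read_ledger(path: str | Path) -> VerificationLedger:
    """Read a verification ledger TSV (gene, cdna, sample_id, status)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    ledger = VerificationLedger()
    for _, row in df.iterrows():
        pair = (VariantKey(row["gene"], row["cdna"]), str(row["sample_id"]).strip())
        if pair in ledger.entries:
            raise ValueError(f"duplicate ledger entry for {pair}")
        ledger.entries[pair] = VerificationStatus(row["status"].strip().lower())
    return ledger
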