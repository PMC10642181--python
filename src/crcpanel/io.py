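"""Reading and writing the formats the triage pipeline touches.

Annotated variant tables arrive as one TSV per sample (the per-patient
export of the upstream annotation software); they are merged into a single
in-memory cohort table.  A minimal VCF representation is provided for
interchange of synthetic cohorts, and the patient registry holds the
clinical covariates used by the cohort statistics.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd
import pysam

from .hgvs import HgvsVariant, VariantKey, parse_cdna

log = logging.getLogger(__name__)

__all__ = [
    "Location", "ClinVar", "AnnotationRecord", "PatientRecord", "CohortTable",
    "SchemaError", "DEFAULT_DIALECT", "PREDICTORS",
    "read_annotation_tsv", "write_annotation_tsv",
    "read_vcf", "write_vcf", "read_registry", "write_registry",
    "load_fixture",
]

#: The four in-silico impact estimators carried on each record.
PREDICTORS = ("sift", "polyphen", "grantham", "fathmm")

PATHOGENIC_TIER = frozenset({"pathogenic", "likely_pathogenic", "path_or_lp"})


class SchemaError(ValueError):
    """A mandatory column is missing or a closed enumeration is violated."""


class Location(str, enum.Enum):
    EXONIC = "exonic"
    FLANKING = "flanking"
    INTRONIC = "intronic"
    UTR = "utr"
    INTERGENIC = "intergenic"


class ClinVar(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    PATH_OR_LP = "path_or_lp"
    UNCERTAIN = "uncertain"
    CONFLICTING = "conflicting"
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    NO_ENTRY = "no_entry"


_CLINVAR_ALIASES = {
    "pathogenic": ClinVar.PATHOGENIC,
    "likely pathogenic": ClinVar.LIKELY_PATHOGENIC,
    "likely_pathogenic": ClinVar.LIKELY_PATHOGENIC,
    "pathogenic/likely pathogenic": ClinVar.PATH_OR_LP,
    "pathogenic/likely_pathogenic": ClinVar.PATH_OR_LP,
    "path_or_lp": ClinVar.PATH_OR_LP,
    "uncertain significance": ClinVar.UNCERTAIN,
    "uncertain": ClinVar.UNCERTAIN,
    "vus": ClinVar.UNCERTAIN,
    "conflicting interpretation of pathogenicity": ClinVar.CONFLICTING,
    "conflicting interpretations of pathogenicity": ClinVar.CONFLICTING,
    "conflicting": ClinVar.CONFLICTING,
    "benign": ClinVar.BENIGN,
    "likely benign": ClinVar.LIKELY_BENIGN,
    "likely_benign": ClinVar.LIKELY_BENIGN,
    "benign/likely benign": ClinVar.LIKELY_BENIGN,
    "no entry": ClinVar.NO_ENTRY,
    "no_entry": ClinVar.NO_ENTRY,
    "": ClinVar.NO_ENTRY,
    ".": ClinVar.NO_ENTRY,
    "na": ClinVar.NO_ENTRY,
}


def parse_clinvar(text: str) -> ClinVar:
    """Map a free-text ClinVar significance to the closed enumeration.

    Unknown strings map to ``no_entry`` with a logged warning, so an
    unexpected archive label never silently drops a record.
    """
    key = str(text).strip().lower()
    if key in _CLINVAR_ALIASES:
        return _CLINVAR_ALIASES[key]
    log.warning("unrecognised ClinVar significance %r mapped to no_entry", text)
    return ClinVar.NO_ENTRY


def parse_maf(text) -> float | None:
    """Parse a minor-allele-frequency cell; NA/blank means unknown, not 0."""
    if text is None:
        return None
    s = str(text).strip()
    if s == "" or s.upper() in ("NA", "N/A", "NONE", "."):
        return None
    value = float(s)
    if isinstance(text, float) and math.isnan(value):
        return None
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"MAF {value} outside [0, 1]")
    return value


@dataclass
class AnnotationRecord:
    """One annotated variant call in one sample — the funnel's atom."""

    sample_id: str
    gene: str
    transcript: str
    hgvs: HgvsVariant
    location: Location
    filter_status: str = "PASS"  # 'PASS' or 'other'
    depth: int = 0
    maf: float | None = None
    clinvar: ClinVar = ClinVar.NO_ENTRY
    predictions: dict = field(default_factory=dict)
    artifact: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.maf is not None and not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"MAF {self.maf} outside [0, 1]")

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.gene, self.hgvs.cdna)


class Gender(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Localization(str, enum.Enum):
    COLON = "colon"
    RECTUM = "rectum"
    BOTH = "both"
    NA = "na"


class Sidedness(str, enum.Enum):
    RIGHT = "right"
    LEFT = "left"
    BOTH = "both"
    NA = "na"


@dataclass
class PatientRecord:
    """Clinical covariates for one patient.

    ``ihc`` is ``None`` when no immunohistochemistry result is on file, the
    string ``"all_positive"`` for normal staining, or a list of mismatch
    repair proteins lost on staining.
    """

    patient_id: str
    age_dx: int
    gender: Gender
    localization: Localization = Localization.NA
    sidedness: Sidedness = Sidedness.NA
    ihc: list[str] | str | None = None
    family_history: bool | None = None
    deceased: bool | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.age_dx <= 120:
            raise ValueError(f"age_dx {self.age_dx} outside [0, 120]")
        self.gender = Gender(self.gender)
        self.localization = Localization(self.localization)
        self.sidedness = Sidedness(self.sidedness)


@dataclass
class CohortTable:
    """All annotation records of a cohort plus the patient registry."""

    records: list[AnnotationRecord]
    registry: dict[str, PatientRecord]

    def __post_init__(self) -> None:
        if self.registry:
            orphans = {r.sample_id for r in self.records} - set(self.registry)
            if orphans:
                raise ValueError(
                    f"records reference samples missing from the registry: "
                    f"{sorted(orphans)[:5]}")

    @property
    def n_patients(self) -> int:
        return len(self.registry)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.registry)


#: Default mapping of our field names to source column headers.
DEFAULT_DIALECT = {
    "sample_id": "sample",
    "gene": "gene",
    "transcript": "transcript",
    "cdna": "cdna",
    "protein": "protein",
    "location": "location",
    "filter_status": "filter",
    "depth": "depth",
    "maf": "maf",
    "clinvar": "clinvar",
    "sift": "sift",
    "polyphen": "polyphen",
    "grantham": "grantham",
    "fathmm": "fathmm",
}

_MANDATORY = ("sample_id", "gene", "cdna", "location", "filter_status",
              "depth", "maf", "clinvar")


def _record_from_row(row: dict, dialect: dict, path) -> AnnotationRecord:
    def cell(field, default=""):
        col = dialect.get(field, field)
        return row.get(col, default)

    predictions = {}
    for p in PREDICTORS:
        val = str(cell(p, "")).strip().lower()
        if val in ("deleterious", "damaging", "d"):
            predictions[p] = "deleterious"
        elif val in ("tolerated", "benign", "t", "b"):
            predictions[p] = "tolerated"
    loc_raw = str(cell("location")).strip().lower()
    try:
        location = Location(loc_raw)
    except ValueError as exc:
        raise SchemaError(
            f"{path}: unknown location {loc_raw!r}") from exc
    filt = str(cell("filter_status")).strip()
    return AnnotationRecord(
        sample_id=str(cell("sample_id")).strip(),
        gene=str(cell("gene")).strip().upper(),
        transcript=str(cell("transcript")).strip(),
        hgvs=parse_cdna(str(cell("cdna")), gene=str(cell("gene")).strip().upper(),
                        protein=str(cell("protein")).strip()),
        location=location,
        filter_status="PASS" if filt.upper() == "PASS" else "other",
        depth=int(float(cell("depth", 0) or 0)),
        maf=parse_maf(cell("maf")),
        clinvar=parse_clinvar(cell("clinvar")),
        predictions=predictions,
    )


def read_annotation_tsv(paths, registry=None, dialect=None) -> CohortTable:
    """Read and merge per-sample annotation TSVs in file order.

    ``dialect`` maps our field names to the source column headers
    (:data:`DEFAULT_DIALECT` mirrors the shipped export layout).  A missing
    mandatory column raises :class:`SchemaError` naming column and file.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    records: list[AnnotationRecord] = []
    for path in paths:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        for fld in _MANDATORY:
            if dialect[fld] not in df.columns:
                raise SchemaError(
                    f"file {path} lacks mandatory column "
                    f"{dialect[fld]!r} (field {fld})")
        for row in df.to_dict("records"):
            records.append(_record_from_row(row, dialect, path))
    if registry is None:
        registry = {}
    return CohortTable(records=records, registry=registry)


def write_annotation_tsv(records, path, dialect=None) -> None:
    """Write records back out in the default dialect (round-trip safe)."""
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    rows = []
    for r in records:
        row = {
            dialect["sample_id"]: r.sample_id,
            dialect["gene"]: r.gene,
            dialect["transcript"]: r.transcript,
            dialect["cdna"]: r.hgvs.cdna,
            dialect["protein"]: r.hgvs.protein,
            dialect["location"]: r.location.value,
            dialect["filter_status"]: r.filter_status if r.filter_status == "PASS" else "other",
            dialect["depth"]: r.depth,
            dialect["maf"]: "NA" if r.maf is None else repr(r.maf),
            dialect["clinvar"]: r.clinvar.value,
        }
        for p in PREDICTORS:
            row[dialect[p]] = r.predictions.get(p, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# minimal VCF interchange (synthetic cohorts)

_VCF_INFO = [
    ("SID", "String", "Sample identifier of the call"),
    ("GENE", "String", "Panel gene symbol"),
    ("TRANSCRIPT", "String", "Transcript accession"),
    ("CDNA", "String", "cDNA HGVS description"),
    ("PROTEIN", "String", "Protein HGVS description"),
    ("LOC", "String", "Location class"),
    ("DP", "Integer", "Depth of coverage"),
    ("MAF", "String", "Minor allele frequency (string to keep full precision)"),
    ("CLNSIG", "String", "ClinVar significance category"),
    ("PRED", "String", "Prediction calls predictor:call,..."),
]


def write_vcf(records, path) -> None:
    """Write one VCF line per annotation record.

    Coding cDNA coordinates stand in for genomic positions (one contig per
    gene); all cohort fields ride in INFO so the file round-trips
    losslessly against :func:`read_vcf`.
    """
    header = pysam.VariantHeader()
    for key, typ, desc in _VCF_INFO:
        header.info.add(key, 1, typ, desc)
    header.filters.add("other", None, None, "Non-PASS upstream filter status")
    for contig in sorted({r.gene for r in records}):
        header.contigs.add(contig, length=100000)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in records:
            v = r.hgvs
            rec = vcf.new_record(
                contig=r.gene,
                start=max(v.cdna_position, 1) - 1,
                # placeholder alleles for non-substitutions: the authoritative
                # description is INFO/CDNA (coding coordinates, no genome)
                alleles=(v.ref or "N", v.alt or "NN"),
            )
            if r.filter_status == "PASS":
                rec.filter.add("PASS")
            else:
                rec.filter.add("other")
            rec.info["SID"] = r.sample_id
            rec.info["GENE"] = r.gene
            rec.info["TRANSCRIPT"] = r.transcript or "."
            rec.info["CDNA"] = v.cdna
            rec.info["PROTEIN"] = v.protein or "."
            rec.info["LOC"] = r.location.value
            rec.info["DP"] = r.depth
            if r.maf is not None:
                rec.info["MAF"] = repr(r.maf)
            rec.info["CLNSIG"] = r.clinvar.value
            if r.predictions:
                rec.info["PRED"] = ",".join(
                    f"{k}:{v_}" for k, v_ in sorted(r.predictions.items()))
            vcf.write(rec)


def read_vcf(path) -> list[AnnotationRecord]:
    """Read a minimal VCF written by :func:`write_vcf`."""
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf, start=1):
            info = rec.info
            if "DP" not in info:
                raise ValueError(f"{path}: record {i} ({rec.contig}:{rec.pos}) "
                                 f"is missing DP")
            filters = list(rec.filter.keys())
            preds = {}
            for item in str(info.get("PRED", "") or "").split(","):
                if ":" in item:
                    k, _, v = item.partition(":")
                    preds[k] = v
            protein = str(info.get("PROTEIN", "") or "")
            records.append(AnnotationRecord(
                sample_id=str(info["SID"]),
                gene=str(info["GENE"]),
                transcript="" if str(info.get("TRANSCRIPT")) == "." else str(info.get("TRANSCRIPT")),
                hgvs=parse_cdna(str(info["CDNA"]), gene=str(info["GENE"]),
                                protein="" if protein == "." else protein),
                location=Location(str(info["LOC"])),
                filter_status="PASS" if filters == ["PASS"] else "other",
                depth=int(info["DP"]),
                maf=float(str(info["MAF"])) if "MAF" in info else None,
                clinvar=ClinVar(str(info["CLNSIG"])),
                predictions=preds,
            ))
    return records


# ---------------------------------------------------------------------------
# patient registry

def _parse_optional_bool(x) -> bool | None:
    s = str(x).strip().lower()
    if s in ("", "na", "none", "nan"):
        return None
    return s in ("1", "true", "yes", "y")


def read_registry(path) -> dict[str, PatientRecord]:
    """Read the patient registry (TSV or CSV, one row per patient)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    registry: dict[str, PatientRecord] = {}
    for _, row in df.iterrows():
        pid = str(row["patient_id"]).strip()
        if pid in registry:
            raise ValueError(f"duplicate patient_id {pid!r} in {path}")
        ihc_raw = str(row.get("ihc", "")).strip()
        ihc: list[str] | str | None
        if not ihc_raw or ihc_raw.lower() in ("na", "none"):
            ihc = None
        elif ihc_raw.lower() == "all_positive":
            ihc = "all_positive"
        else:
            ihc = [g.strip().upper() for g in ihc_raw.split(";") if g.strip()]
        registry[pid] = PatientRecord(
            patient_id=pid,
            age_dx=int(float(row["age_dx"])),
            gender=Gender(str(row["gender"]).strip().lower()),
            localization=Localization(str(row.get("localization", "na")).strip().lower() or "na"),
            sidedness=Sidedness(str(row.get("sidedness", "na")).strip().lower() or "na"),
            ihc=ihc,
            family_history=_parse_optional_bool(row.get("family_history", "")),
            deceased=_parse_optional_bool(row.get("deceased", "")),
        )
    return registry


def write_registry(registry: dict[str, PatientRecord], path) -> None:
    rows = []
    for p in registry.values():
        if p.ihc is None:
            ihc = ""
        elif isinstance(p.ihc, str):
            ihc = p.ihc
        else:
            ihc = ";".join(p.ihc)
        rows.append({
            "patient_id": p.patient_id,
            "age_dx": p.age_dx,
            "gender": p.gender.value,
            "localization": p.localization.value,
            "sidedness": p.sidedness.value,
            "ihc": ihc,
            "family_history": "" if p.family_history is None else str(p.family_history).lower(),
            "deceased": "" if p.deceased is None else str(p.deceased).lower(),
        })
    sep = "," if str(path).endswith(".csv") else "\t"
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# packaged fixtures

_FIXTURES = {
    "table2_aggregates": "table2_aggregates.tsv",
    "table3_pgv": "table3_pgv.tsv",
    "table4_ihc": "table4_ihc.tsv",
    "table5_vus": "table5_vus.tsv",
    "pms2_homology": "pms2_homology.tsv",
    "paper_ledger": "paper_ledger.tsv",
    "panel_genes": "panel_genes.tsv",
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged reference tables as a DataFrame."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"available: {sorted(_FIXTURES)}")
    with resources.as_file(
            resources.files("crcpanel").joinpath("data", _FIXTURES[name])) as p:
        return pd.read_csv(p, sep="\t", dtype=str).fillna("")
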