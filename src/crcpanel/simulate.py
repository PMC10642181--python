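"""Synthetic annotated cohorts with known ground truth.

Two entry points:

* :func:`generate_cohort` draws a randomised cohort from a
  :class:`SimulationConfig` — planted pathogenic variants, planted VUSs,
  pseudogene-shadow variants, recurrent-indel artifacts, and a background
  of benign/common calls each constructed to fail one specific funnel
  stage, so per-stage retained counts are exactly checkable against the
  returned truth table rather than only statistically.

* :func:`paper_scenario` deterministically rebuilds the published study
  cohort from the packaged reference tables: 107 patients, the 28
  candidate-pathogenic carrier rows, the 21 uncertain-significance
  variants with synthetic carrier assignments constrained by the printed
  totals, one recurrent-indel artifact, per-patient benign background, and
  the verification ledger that removes the pseudogene-shadowed PMS2 call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .acmg import EvidenceSet, Tier, parse_tier
from .hgvs import VariantKey, parse_cdna
from .io import (AnnotationRecord, ClinVar, CohortTable, Gender, Localization,
                 PatientRecord, Sidedness, load_fixture)
from .panel import Panel, default_panel
from .verify import VerificationLedger, VerificationStatus

__all__ = [
    "PlantedVariant", "SimulationConfig", "TruthTable", "Scenario",
    "generate_registry", "generate_cohort", "paper_scenario",
    "random_simulation_config", "expected_retained_counts",
]

#: Funnel stage order used to turn per-variant failure modes into fates.
STAGE_ORDER = ("pass", "functional", "maf", "clinvar", "artifact", "depth")


@dataclass(frozen=True)
class PlantedVariant:
    """One variant planted with full knowledge of its expected fate."""

    gene: str
    cdna: str
    protein: str
    carriers: tuple
    tier: str = "pathogenic"
    clinvar: str = "pathogenic"
    maf: float | None = None
    reported_before: str = "No"

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.gene, self.cdna)


@dataclass
class SimulationConfig:
    """Study-scale defaults: 107 patients, 100-200 annotated calls each,
    mean depth 604x, ages 18-58 around a median of ~37."""

    n_patients: int = 107
    variants_per_patient: tuple = (100, 200)
    planted_pgvs: tuple = ()
    planted_vus: tuple = ()
    shadow_variants: tuple = ()       # PlantedVariant in pseudogene homology
    artifact_indels: tuple = ()       # (gene, cdna, sample_fraction)
    depth_mean: float = 604.0
    depth_dispersion: float = 10.0
    age_mean: float = 36.0
    age_sd: float = 9.0
    age_bounds: tuple = (18, 58)
    seed: int = 0

    def __post_init__(self) -> None:
        keys = [p.key for group in (self.planted_pgvs, self.planted_vus,
                                    self.shadow_variants) for p in group]
        if len(keys) != len(set(keys)):
            raise ValueError("planted variant keys must be unique")


@dataclass
class TruthTable:
    """Per planted/background variant: the expected funnel fate
    (stage at which it is removed, or ``prioritized``), expected tier and
    verification status; plus per-patient expected positivity."""

    rows: list = field(default_factory=list)
    expected_pre_carriers: set = field(default_factory=set)
    expected_post_carriers: set = field(default_factory=set)

    def add(self, sample_id, gene, cdna, origin, fate,
            tier=None, verification=None) -> None:
        self.rows.append({
            "sample_id": sample_id, "gene": gene, "cdna": cdna,
            "origin": origin, "expected_fate": fate,
            "expected_tier": tier, "expected_verification": verification,
        })

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.rows)


def expected_retained_counts(truth: TruthTable) -> dict[str, int]:
    """Retained record count after each stage implied by the truth table."""
    idx = {s: i for i, s in enumerate(STAGE_ORDER)}
    out = {}
    for i, stage in enumerate(STAGE_ORDER):
        out[stage] = sum(
            1 for row in truth.rows
            if row["expected_fate"] == "prioritized"
            or idx[row["expected_fate"]] > i)
    return out


def generate_registry(cfg: SimulationConfig,
                      rng: np.random.Generator | None = None):
    """Draw a patient registry from the demographic model.

    Ages are a discretised truncated normal (rejection sampling inside the
    bounds); gender is balanced; tumour site favours the colon ~3:1.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.age_bounds
    registry = {}
    for i in range(1, cfg.n_patients + 1):
        while True:
            age = int(round(rng.normal(cfg.age_mean, cfg.age_sd)))
            if lo <= age <= hi:
                break
        registry[str(i)] = PatientRecord(
            patient_id=str(i),
            age_dx=age,
            gender=Gender.MALE if rng.random() < 0.5 else Gender.FEMALE,
            localization=Localization(
                rng.choice(["colon", "rectum", "both", "na"],
                           p=[0.735, 0.235, 0.02, 0.01])),
            sidedness=Sidedness(
                rng.choice(["right", "left", "both", "na"],
                           p=[0.44, 0.43, 0.065, 0.065])),
        )
    return registry


_BASES = np.array(list("ACGT"))
_AA3 = ["Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
        "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val"]


def _draw_depth(cfg, rng) -> int:
    p = cfg.depth_dispersion / (cfg.depth_dispersion + cfg.depth_mean)
    return int(rng.negative_binomial(cfg.depth_dispersion, p))


def _planted_record(pv: PlantedVariant, sid: str, panel: Panel, cfg,
                    rng, clinvar: ClinVar) -> AnnotationRecord:
    gene = panel.get(pv.gene)
    v = parse_cdna(pv.cdna, gene=pv.gene, protein=pv.protein)
    from .io import Location
    location = Location.FLANKING if v.intron_offset is not None else Location.EXONIC
    return AnnotationRecord(
        sample_id=str(sid), gene=pv.gene,
        transcript=gene.refseq if gene else "",
        hgvs=v, location=location, filter_status="PASS",
        depth=max(31, _draw_depth(cfg, rng)), maf=pv.maf, clinvar=clinvar,
    )


def _background_record(sid: str, panel: Panel, cfg, rng):
    """One background call constructed to fail a chosen stage (or survive
    as an uncertain-significance call).  Returns (record, fate, origin)."""
    category = rng.choice(
        ["non_pass", "synonymous", "deep_intronic", "utr",
         "common_benign", "rare_benign", "low_depth", "rare_vus"],
        p=[0.05, 0.15, 0.10, 0.05, 0.40, 0.10, 0.05, 0.10])
    from .io import Location
    gene = str(rng.choice(panel.symbols))
    pos = int(rng.integers(3000, 9999))
    ref, alt = rng.choice(_BASES, size=2, replace=False)
    aa_from, aa_to = (str(_AA3[i]) for i in rng.integers(0, len(_AA3), 2))
    res = int(math.ceil(pos / 3))
    depth = max(31, _draw_depth(cfg, rng))
    cdna = f"c.{pos}{ref}>{alt}"
    protein = f"p.{aa_from}{res}{aa_to}"
    location = Location.EXONIC
    filt = "PASS"
    maf: float | None = float(rng.uniform(0, 0.0001))
    clinvar = ClinVar.NO_ENTRY

    if category == "non_pass":
        filt, fate = "other", "pass"
    elif category == "synonymous":
        protein = f"p.{aa_from}{res}="
        fate = "functional"
    elif category == "deep_intronic":
        off = int(rng.integers(30, 500))
        cdna = f"c.{pos}+{off}{ref}>{alt}"
        protein = "p.?"
        location = Location.INTRONIC
        fate = "functional"
    elif category == "utr":
        location = Location.UTR
        protein = "p.?"
        fate = "functional"
    elif category == "common_benign":
        maf = float(rng.uniform(0.05, 0.5))
        clinvar = ClinVar.BENIGN
        fate = "maf"
    elif category == "rare_benign":
        maf = float(rng.uniform(0.0, 0.049))
        clinvar = ClinVar.BENIGN
        fate = "clinvar"
    elif category == "low_depth":
        depth = int(rng.integers(1, 31))
        fate = "depth"
    else:  # rare_vus: survives the cascade, expected tier VUS
        maf = None if rng.random() < 0.7 else float(rng.uniform(0, 0.0005))
        clinvar = ClinVar.UNCERTAIN
        fate = "prioritized"

    rec = AnnotationRecord(
        sample_id=str(sid), gene=gene,
        transcript=panel[gene].refseq if gene in panel else "",
        hgvs=parse_cdna(cdna, gene=gene, protein=protein),
        location=location, filter_status=filt, depth=depth,
        maf=maf, clinvar=clinvar,
    )
    return rec, fate, f"background_{category}"


def generate_cohort(cfg: SimulationConfig, panel: Panel | None = None):
    """Generate a cohort, its truth table, and curated evidence.

    Deterministic for a fixed seed.  Shadow variants are annotated
    identically to true calls — they are distinguishable only through the
    homology-region flag and the verification ledger.  Returns
    ``(CohortTable, TruthTable, curated_evidence)``.
    """
    panel = panel or default_panel()
    rng = np.random.default_rng(cfg.seed)
    registry = generate_registry(cfg, rng)
    ids = list(registry)
    id_set = set(ids)
    for group in (cfg.planted_pgvs, cfg.planted_vus, cfg.shadow_variants):
        for pv in group:
            stray = set(map(str, pv.carriers)) - id_set
            if stray:
                raise ValueError(
                    f"planted carriers {sorted(stray)} outside the registry")

    records: list[AnnotationRecord] = []
    truth = TruthTable()

    for pv in cfg.planted_pgvs:
        for sid in pv.carriers:
            records.append(_planted_record(pv, sid, panel, cfg, rng,
                                           ClinVar(pv.clinvar)))
            truth.add(str(sid), pv.gene, pv.key.cdna, "pgv", "prioritized",
                      tier=pv.tier, verification="verified")
            truth.expected_pre_carriers.add(str(sid))
            truth.expected_post_carriers.add(str(sid))

    for pv in cfg.planted_vus:
        for sid in pv.carriers:
            records.append(_planted_record(pv, sid, panel, cfg, rng,
                                           ClinVar.UNCERTAIN))
            truth.add(str(sid), pv.gene, pv.key.cdna, "vus", "prioritized",
                      tier="vus")

    for pv in cfg.shadow_variants:
        for sid in pv.carriers:
            records.append(_planted_record(pv, sid, panel, cfg, rng,
                                           ClinVar(pv.clinvar)))
            truth.add(str(sid), pv.gene, pv.key.cdna, "shadow", "prioritized",
                      tier=pv.tier, verification="excluded_unverified")
            truth.expected_pre_carriers.add(str(sid))

    for gene, cdna, fraction in cfg.artifact_indels:
        n_carriers = int(math.floor(fraction * cfg.n_patients)) + 1
        for sid in ids[:n_carriers]:
            v = parse_cdna(cdna, gene=gene, protein="p.?")
            from .io import Location
            records.append(AnnotationRecord(
                sample_id=sid, gene=gene,
                transcript=panel[gene].refseq if gene in panel else "",
                hgvs=v, location=Location.EXONIC, filter_status="PASS",
                depth=max(31, _draw_depth(cfg, rng)), maf=None,
                clinvar=ClinVar.NO_ENTRY))
            truth.add(sid, gene, v.cdna, "artifact", "artifact")

    planted_per_patient: dict[str, int] = {sid: 0 for sid in ids}
    for row in truth.rows:
        planted_per_patient[row["sample_id"]] += 1
    lo, hi = cfg.variants_per_patient
    for sid in ids:
        n_total = int(rng.integers(lo, hi + 1))
        for _ in range(max(0, n_total - planted_per_patient[sid])):
            rec, fate, origin = _background_record(sid, panel, cfg, rng)
            records.append(rec)
            truth.add(sid, rec.gene, rec.hgvs.cdna, origin, fate,
                      tier="vus" if fate == "prioritized" else None)

    curated = {}
    for pv in list(cfg.planted_pgvs) + list(cfg.shadow_variants):
        curated[pv.key] = EvidenceSet(variant=pv.key,
                                      tier_override=parse_tier(pv.tier))

    cohort = CohortTable(records=records, registry=registry)
    return cohort, truth, curated


def random_simulation_config(seed: int, n_patients: int = 30,
                             n_pgvs: int = 5, n_shadow: int = 1,
                             variants_per_patient: tuple = (20, 40),
                             ) -> SimulationConfig:
    """A randomised planted-variant configuration for recovery studies."""
    rng = np.random.default_rng(seed)
    panel = default_panel()
    lof_genes = [g.symbol for g in panel if g.lof_mechanism]
    ids = [str(i) for i in range(1, n_patients + 1)]

    planted = []
    used_pos: set[tuple] = set()
    for k in range(n_pgvs):
        gene = str(rng.choice(lof_genes))
        while True:
            pos = int(rng.integers(100, 1100))
            if (gene, pos) not in used_pos:
                used_pos.add((gene, pos))
                break
        n_car = int(rng.integers(1, 3))
        carriers = tuple(str(x) for x in rng.choice(ids, n_car, replace=False))
        planted.append(PlantedVariant(
            gene=gene, cdna=f"c.{pos}C>T",
            protein=f"p.Gln{int(math.ceil(pos / 3))}Ter",
            carriers=carriers, tier="pathogenic", clinvar="pathogenic"))

    shadows = []
    for k in range(n_shadow):
        pos = int(rng.integers(1200, 2580))
        carriers = tuple(str(x) for x in rng.choice(ids, 1))
        shadows.append(PlantedVariant(
            gene="PMS2", cdna=f"c.{pos}_{pos + 1}delAG",
            protein=f"p.Arg{int(math.ceil(pos / 3))}GlyfsTer14",
            carriers=carriers, tier="pathogenic", clinvar="pathogenic"))

    return SimulationConfig(
        n_patients=n_patients, variants_per_patient=variants_per_patient,
        planted_pgvs=tuple(planted), shadow_variants=tuple(shadows),
        artifact_indels=(("MSH6", "c.3261dupC", 0.3),),
        seed=int(rng.integers(0, 2**31 - 1)))


# ---------------------------------------------------------------------------
# the deterministic published-study scenario

# Carrier assignments for the uncertain-significance variants are synthetic:
# the source tables print only the variants and cohort-level totals (35
# carriers, 19 with an MMR-gene VUS, 9 overlapping the PGV-positive set,
# 5 carrying an MSH6 VUS), so patients are assigned here to satisfy exactly
# those totals.  BMPR1A c.185A>G is carried by patient 9, whose candidate-
# pathogenic record (ClinVar "uncertain significance") doubles as the VUS
# call, mirroring the variant's presence in both published lists.
_VUS_CARRIERS = {
    ("MLH1", "c.1013A>G"): ("28", "29"),
    ("MLH1", "c.1772A>G"): ("30", "42"),
    ("MSH2", "c.508C>G"): ("31", "32"),
    ("MSH2", "c.157G>T"): ("33", "43"),
    ("MSH6", "c.560A>G"): ("34", "35"),
    ("MSH6", "c.2347T>A"): ("36", "37"),
    ("MSH6", "c.3489A>C"): ("38",),
    ("PMS2", "c.924G>C"): ("39", "40"),
    ("PMS2", "c.1555T>C"): ("41", "44"),
    ("PMS2", "c.2186_2187delTC"): ("19", "20"),
    ("APC", "c.5038C>G"): ("45",),
    ("BMPR1A", "c.185A>G"): (),          # via patient 9's candidate record
    ("POLE", "c.73G>A"): ("24", "46"),
    ("POLE", "c.4759G>A"): ("24", "47"),
    ("POLE", "c.4144C>T"): ("48", "27"),
    ("POLE", "c.3901G>A"): ("24", "49"),
    ("POLE", "c.1004T>G"): ("50", "26"),
    ("POLE", "c.4124C>T"): ("51",),
    ("POLE", "c.1337G>A"): ("52",),
    ("POLE", "c.3311C>T"): ("53", "21"),
    ("POLE", "c.3970C>T"): ("22", "25"),
}

_AGE_CYCLE = (26, 30, 33, 35, 37, 37, 38, 41, 44, 48)


def _scenario_registry() -> dict[str, PatientRecord]:
    """107 patients whose marginals reproduce the published demographics
    (3 patients aged >=50 of whom 2 are mutation-positive; 54 males;
    colon:rectum ~3:1)."""
    age_overrides = {"16": 52, "18": 58, "100": 50}
    fam = {"1", "12", "17"}
    dead = {"2", "5", "6", "8", "20"}
    ihc: dict[str, list | str] = {
        "1": ["MLH1"], "8": "all_positive", "14": "all_positive",
        "16": ["MSH2", "MSH6"], "17": ["MSH2"], "19": ["MLH1"],
        "20": ["MLH1", "PMS2"], "26": "all_positive",
    }
    for i in range(28, 37):       # mutation-negative with an MMR loss on IHC
        ihc[str(i)] = ["MLH1"]
    for i in range(37, 43):       # mutation-negative with normal staining
        ihc[str(i)] = "all_positive"

    registry = {}
    for i in range(1, 108):
        pid = str(i)
        age = age_overrides.get(pid, _AGE_CYCLE[(i - 1) % len(_AGE_CYCLE)])
        if i <= 27:
            gender = "male" if i <= 15 else "female"
            localization = ("colon" if i <= 18 else
                            "rectum" if i <= 25 else "both")
            sidedness = ("right" if i <= 12 else "left" if i <= 22 else
                         "both" if i <= 26 else "na")
        else:
            gender = "male" if i <= 66 else "female"
            localization = ("colon" if i <= 88 else
                            "rectum" if i <= 106 else "na")
            sidedness = ("right" if i <= 62 else "left" if i <= 99 else
                         "both" if i <= 102 else "na")
        registry[pid] = PatientRecord(
            patient_id=pid, age_dx=age, gender=Gender(gender),
            localization=Localization(localization),
            sidedness=Sidedness(sidedness),
            ihc=ihc.get(pid),
            family_history=pid in fam or None,
            deceased=pid in dead or None,
        )
    return registry


@dataclass
class Scenario:
    """The end-to-end acceptance input: cohort, ledger, curated evidence."""

    cohort: CohortTable
    ledger: VerificationLedger
    curated: dict
    reported_flags: dict


def paper_scenario(panel: Panel | None = None,
                   include_background: bool = True) -> Scenario:
    """Rebuild the study cohort deterministically from the fixtures."""
    from .io import Location
    from .verify import read_ledger
    from importlib import resources

    panel = panel or default_panel()
    registry = _scenario_registry()
    records: list[AnnotationRecord] = []

    t3 = load_fixture("table3_pgv")
    curated: dict[VariantKey, EvidenceSet] = {}
    reported: dict[VariantKey, str] = {}
    from .io import parse_clinvar, parse_maf
    for _, row in t3.iterrows():
        gene = row["gene"]
        v = parse_cdna(row["cdna"], gene=gene, protein=row["protein"])
        location = (Location.FLANKING if v.intron_offset is not None
                    else Location.EXONIC)
        records.append(AnnotationRecord(
            sample_id=str(row["patient_id"]), gene=gene,
            transcript=panel[gene].refseq,
            hgvs=v, location=location, filter_status="PASS", depth=604,
            maf=parse_maf(row["maf"]), clinvar=parse_clinvar(row["clinvar"])))
        key = VariantKey(gene, row["cdna"])
        curated.setdefault(key, EvidenceSet(
            variant=key, tier_override=parse_tier(row["acmg"])))
        reported.setdefault(key, row["reported_before"])

    t5 = load_fixture("table5_vus")
    for _, row in t5.iterrows():
        gene = row["gene"]
        carriers = _VUS_CARRIERS[(gene, row["cdna"])]
        v_maf = parse_maf(row["maf"])
        for sid in carriers:
            records.append(AnnotationRecord(
                sample_id=sid, gene=gene, transcript=row["transcript"],
                hgvs=parse_cdna(row["cdna"], gene=gene, protein=row["protein"]),
                location=Location.EXONIC, filter_status="PASS", depth=604,
                maf=v_maf, clinvar=ClinVar.UNCERTAIN))

    if include_background:
        # recurrent single-base deletion seen in 30/107 samples: the
        # deterministic stand-in for the manually-inspected indel artifact
        for i in range(1, 31):
            records.append(AnnotationRecord(
                sample_id=str(i), gene="PMS2",
                transcript=panel["PMS2"].refseq,
                hgvs=parse_cdna("c.1105delA", gene="PMS2", protein="p.?"),
                location=Location.EXONIC, filter_status="PASS", depth=604,
                maf=None, clinvar=ClinVar.NO_ENTRY))
        # common benign + benign synonymous background per patient
        for pid in registry:
            records.append(AnnotationRecord(
                sample_id=pid, gene="APC", transcript=panel["APC"].refseq,
                hgvs=parse_cdna("c.5465T>A", gene="APC",
                                protein="p.Val1822Asp"),
                location=Location.EXONIC, filter_status="PASS", depth=604,
                maf=0.4, clinvar=ClinVar.BENIGN))
            records.append(AnnotationRecord(
                sample_id=pid, gene="TP53", transcript=panel["TP53"].refseq,
                hgvs=parse_cdna("c.639A>G", gene="TP53", protein="p.Arg213="),
                location=Location.EXONIC, filter_status="PASS", depth=604,
                maf=0.7, clinvar=ClinVar.BENIGN))

    with resources.as_file(
            resources.files("crcpanel").joinpath("data/paper_ledger.tsv")) as p:
        ledger = read_ledger(p)

    cohort = CohortTable(records=records, registry=registry)
    return Scenario(cohort=cohort, ledger=ledger, curated=curated,
                    reported_flags=reported)
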