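"""ACMG/AMP evidence combination and a conservative auto-assigner.

The 28 evidence codes (PVS1, PS1-4, PM1-6, PP1-5, BA1, BS1-4, BP1-7) are
combined into the five-tier verdict by the fixed rule table.  Counts use
*effective* strengths, so a curator may downgrade PVS1 to strong or promote
a moderate criterion, and the combination follows the adjusted weights.

Only criteria computable from the annotation record itself are
auto-assigned (loss-of-function, frequency, in-frame change, in-silico
concordance); everything requiring literature, segregation or functional
data enters through the curated-evidence channel, which wins per code.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .hgvs import VariantKey, VariantKind
from .io import AnnotationRecord, ClinVar, PREDICTORS
from .panel import Panel, PanelGene

__all__ = [
    "Strength", "Tier", "AcmgCriterion", "EvidenceSet", "Classification",
    "CRITERION_CODES", "combine", "auto_assign", "classify_cohort",
    "AutoAssignConfig", "read_curated_evidence",
]


class Strength(str, enum.Enum):
    STAND_ALONE = "stand_alone"
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


class Tier(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


#: Tier order used by the monotonicity property (benign lowest).
TIER_ORDER = {Tier.BENIGN: 0, Tier.LIKELY_BENIGN: 1, Tier.VUS: 2,
              Tier.LIKELY_PATHOGENIC: 3, Tier.PATHOGENIC: 4}

CRITERION_CODES: tuple[str, ...] = (
    "PVS1",
    "PS1", "PS2", "PS3", "PS4",
    "PM1", "PM2", "PM3", "PM4", "PM5", "PM6",
    "PP1", "PP2", "PP3", "PP4", "PP5",
    "BA1",
    "BS1", "BS2", "BS3", "BS4",
    "BP1", "BP2", "BP3", "BP4", "BP5", "BP6", "BP7",
)

_NATIVE_STRENGTH = {
    "PVS": Strength.VERY_STRONG,
    "PS": Strength.STRONG,
    "PM": Strength.MODERATE,
    "PP": Strength.SUPPORTING,
    "BA": Strength.STAND_ALONE,
    "BS": Strength.STRONG,
    "BP": Strength.SUPPORTING,
}


def native_strength(code: str) -> Strength:
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if code.startswith(prefix):
            return _NATIVE_STRENGTH[prefix]
    raise ValueError(f"unknown criterion code {code!r}")


@dataclass(frozen=True)
class AcmgCriterion:
    """One evidence code with its effective (possibly overridden) strength."""

    code: str
    strength: Strength | None = None

    def __post_init__(self) -> None:
        if self.code not in CRITERION_CODES:
            raise ValueError(f"unknown criterion code {self.code!r}")
        if self.strength is None:
            object.__setattr__(self, "strength", native_strength(self.code))

    @property
    def benign_side(self) -> bool:
        return self.code.startswith("B")


@dataclass
class EvidenceSet:
    """The criteria assigned to one variant, with per-code provenance."""

    variant: VariantKey
    criteria: set[AcmgCriterion] = field(default_factory=set)
    provenance: dict[str, str] = field(default_factory=dict)  # code -> auto|curated
    tier_override: Tier | None = None

    def __post_init__(self) -> None:
        codes = [c.code for c in self.criteria]
        if len(codes) != len(set(codes)):
            raise ValueError(f"duplicate criterion codes for {self.variant}")

    def merge_curated(self, other: "EvidenceSet") -> "EvidenceSet":
        """Overlay curated evidence: curated wins per code."""
        merged = {c.code: c for c in self.criteria}
        prov = dict(self.provenance)
        for c in other.criteria:
            merged[c.code] = c
            prov[c.code] = "curated"
        return EvidenceSet(variant=self.variant,
                           criteria=set(merged.values()),
                           provenance=prov,
                           tier_override=other.tier_override or self.tier_override)


@dataclass
class Classification:
    tier: Tier
    fired_rule: str
    conflict: bool = False

    def __post_init__(self) -> None:
        if self.conflict and self.tier != Tier.VUS:
            raise ValueError("conflicting evidence must resolve to VUS")


def _counts(e: EvidenceSet):
    """Effective-strength tallies on each side."""
    pvs = ps = pm = pp = ba = bs = bp = 0
    for c in e.criteria:
        if c.benign_side:
            if c.strength == Strength.STAND_ALONE:
                ba += 1
            elif c.strength in (Strength.VERY_STRONG, Strength.STRONG):
                bs += 1
            else:
                bp += 1
        else:
            if c.strength == Strength.VERY_STRONG:
                pvs += 1
            elif c.strength == Strength.STRONG:
                ps += 1
            elif c.strength == Strength.MODERATE:
                pm += 1
            else:
                pp += 1
    return pvs, ps, pm, pp, ba, bs, bp


def _pathogenic_rule(pvs, ps, pm, pp) -> str | None:
    if pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2):
        return "P: PVS1 + supporting combination"
    if ps >= 2:
        return "P: >=2 strong"
    if ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)):
        return "P: 1 strong + moderate/supporting combination"
    return None


def _likely_pathogenic_rule(pvs, ps, pm, pp) -> str | None:
    if pvs >= 1 and pm == 1:
        return "LP: PVS1 + 1 moderate"
    if ps == 1 and 1 <= pm <= 2:
        return "LP: 1 strong + 1-2 moderate"
    if ps == 1 and pp >= 2:
        return "LP: 1 strong + >=2 supporting"
    if pm >= 3:
        return "LP: >=3 moderate"
    if pm == 2 and pp >= 2:
        return "LP: 2 moderate + >=2 supporting"
    if pm == 1 and pp >= 4:
        return "LP: 1 moderate + >=4 supporting"
    return None


def _benign_rule(ba, bs, bp) -> str | None:
    if ba >= 1:
        return "B: stand-alone"
    if bs >= 2:
        return "B: >=2 strong benign"
    return None


def _likely_benign_rule(ba, bs, bp) -> str | None:
    if bs >= 1 and bp >= 1:
        return "LB: 1 strong + 1 supporting benign"
    if bp >= 2:
        return "LB: >=2 supporting benign"
    return None


def combine(e: EvidenceSet) -> Classification:
    """Apply the combining rules to an evidence set.

    When rules fire on both the pathogenic and the benign side the
    verdict is uncertain significance with ``conflict=True`` — the stated
    convention for contradictory evidence.  A curated tier override, when
    present, short-circuits the table.
    """
    if e.tier_override is not None:
        return Classification(tier=e.tier_override, fired_rule="curated override")
    pvs, ps, pm, pp, ba, bs, bp = _counts(e)
    path_rule = _pathogenic_rule(pvs, ps, pm, pp) or \
        _likely_pathogenic_rule(pvs, ps, pm, pp)
    benign_rule = _benign_rule(ba, bs, bp) or _likely_benign_rule(ba, bs, bp)
    if path_rule and benign_rule:
        return Classification(tier=Tier.VUS,
                              fired_rule=f"conflict({path_rule} vs {benign_rule})",
                              conflict=True)
    if path_rule:
        tier = Tier.PATHOGENIC if path_rule.startswith("P:") else Tier.LIKELY_PATHOGENIC
        return Classification(tier=tier, fired_rule=path_rule)
    if benign_rule:
        tier = Tier.BENIGN if benign_rule.startswith("B:") else Tier.LIKELY_BENIGN
        return Classification(tier=tier, fired_rule=benign_rule)
    return Classification(tier=Tier.VUS, fired_rule="no rule fired")


@dataclass(frozen=True)
class AutoAssignConfig:
    """Frequency cutoffs for the computable criteria.

    ``pm2_max`` — absent/ultra-rare in population databases;
    ``bs1_max`` — frequency greater than expected for the disorder;
    ``ba1_min`` — stand-alone common-variant threshold.
    """

    pm2_max: float = 1e-4
    bs1_max: float = 1e-3
    ba1_min: float = 0.05
    min_concordant_predictions: int = 3


NULL_KINDS = {VariantKind.NONSENSE, VariantKind.FRAMESHIFT, VariantKind.SPLICE_SITE}


def auto_assign(record: AnnotationRecord, gene: PanelGene | None,
                cfg: AutoAssignConfig = AutoAssignConfig(),
                panel: Panel | None = None) -> EvidenceSet:
    """Assign the transparent computable subset of criteria.

    PVS1 (null variant in a gene with a loss-of-function disease
    mechanism), PM2/BS1/BA1 (frequency), PM4 (in-frame indel), BP7
    (silent, no splice candidacy, benign predictions), PP3/BP4 (in-silico
    concordance).  Everything else is left to curated input.
    """
    v = record.hgvs
    crit: set[AcmgCriterion] = set()

    is_null = v.kind in NULL_KINDS
    if v.kind == VariantKind.SPLICE_SITE:
        offs = [o for o in (v.intron_offset, v.end_offset) if o is not None]
        is_null = bool(offs) and min(abs(o) for o in offs) <= 2
    if is_null and gene is not None and gene.lof_mechanism:
        crit.add(AcmgCriterion("PVS1"))

    maf = record.maf
    if maf is None or maf < cfg.pm2_max:
        crit.add(AcmgCriterion("PM2"))
    elif maf > cfg.ba1_min:
        crit.add(AcmgCriterion("BA1"))
    elif maf > cfg.bs1_max:
        crit.add(AcmgCriterion("BS1"))

    if v.kind == VariantKind.INFRAME_INDEL:
        crit.add(AcmgCriterion("PM4"))

    calls = [record.predictions.get(p) for p in PREDICTORS]
    n_del = sum(1 for c in calls if c == "deleterious")
    n_ben = sum(1 for c in calls if c == "tolerated")
    if n_del >= cfg.min_concordant_predictions:
        crit.add(AcmgCriterion("PP3"))
    elif n_ben >= cfg.min_concordant_predictions:
        crit.add(AcmgCriterion("BP4"))
        if v.kind == VariantKind.SYNONYMOUS and not (
                panel is not None and panel.is_splice_candidate(v)):
            crit.add(AcmgCriterion("BP7"))

    return EvidenceSet(variant=record.key, criteria=crit,
                       provenance={c.code: "auto" for c in crit})


PGV_TIERS = frozenset({Tier.PATHOGENIC, Tier.LIKELY_PATHOGENIC})


def classify_cohort(unique_variants, curated_evidence=None,
                    panel: Panel | None = None,
                    cfg: AutoAssignConfig = AutoAssignConfig()):
    """Classify unique variants; curated evidence overlays auto evidence.

    ``unique_variants`` is the dedup output of the funnel
    (:class:`~crcpanel.funnel.UniqueVariant`); ``curated_evidence`` maps
    :class:`VariantKey` to :class:`EvidenceSet`.  Returns a mapping
    ``VariantKey -> Classification``.
    """
    import logging
    log = logging.getLogger(__name__)
    curated_evidence = dict(curated_evidence or {})
    known = {uv.key for uv in unique_variants}
    for key in curated_evidence:
        if key not in known:
            log.warning("curated evidence for unobserved variant %s ignored", key)

    result = {}
    for uv in unique_variants:
        rec = uv.representative
        gene = panel.get(rec.gene) if panel is not None else None
        evidence = auto_assign(rec, gene, cfg=cfg, panel=panel)
        cur = curated_evidence.get(uv.key)
        if cur is not None:
            evidence = evidence.merge_curated(cur)
        result[uv.key] = combine(evidence)
    return result


_TIER_ALIASES = {
    "pathogenic": Tier.PATHOGENIC,
    "likely pathogenic": Tier.LIKELY_PATHOGENIC,
    "likely_pathogenic": Tier.LIKELY_PATHOGENIC,
    "vus": Tier.VUS,
    "uncertain significance": Tier.VUS,
    "likely benign": Tier.LIKELY_BENIGN,
    "likely_benign": Tier.LIKELY_BENIGN,
    "benign": Tier.BENIGN,
}


def parse_tier(text: str) -> Tier:
    return _TIER_ALIASES[str(text).strip().lower()]


def read_curated_evidence(path: str | Path) -> dict[VariantKey, EvidenceSet]:
    """Read a curated-evidence TSV.

    Columns: gene, cdna, criteria (semicolon-separated codes, each with an
    optional ``:strength`` override), optional tier (final override).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[VariantKey, EvidenceSet] = {}
    for _, row in df.iterrows():
        key = VariantKey(row["gene"], row["cdna"])
        criteria = set()
        for item in str(row.get("criteria", "")).split(";"):
            item = item.strip()
            if not item:
                continue
            code, _, strength = item.partition(":")
            criteria.add(AcmgCriterion(
                code.strip().upper(),
                Strength(strength.strip().lower()) if strength else None))
        tier = parse_tier(row["tier"]) if str(row.get("tier", "")).strip() else None
        out[key] = EvidenceSet(variant=key, criteria=criteria,
                               provenance={c.code: "curated" for c in criteria},
                               tier_override=tier)
    return out
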