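"""Evidence combination rules, auto-assignment, and the rule-table oracle."""

import itertools

import pytest

from crcpanel.acmg import (AcmgCriterion, AutoAssignConfig, EvidenceSet,
                           Strength, TIER_ORDER, Tier, auto_assign,
                           classify_cohort, combine, CRITERION_CODES,
                           native_strength)
from crcpanel.funnel import dedupe
from crcpanel.hgvs import VariantKey
from tests.conftest import make_record

KEY = VariantKey("MSH2", "c.1C>T")


def ev(*codes, **overrides):
    crit = {AcmgCriterion(c) for c in codes}
    for code, strength in overrides.items():
        crit = {c for c in crit if c.code != code}
        crit.add(AcmgCriterion(code, Strength(strength)))
    return EvidenceSet(variant=KEY, criteria=crit)


# Independently coded rule table: tier from raw evidence-class counts.
def oracle_tier(pvs, ps, pm, pp, ba, bs, bp):
    pathogenic = ((pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1)
                                 or pp >= 2))
                  or ps >= 2
                  or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2)
                                   or (pm == 1 and pp >= 4))))
    likely_path = ((pvs >= 1 and pm == 1)
                   or (ps == 1 and 1 <= pm <= 2)
                   or (ps == 1 and pp >= 2)
                   or pm >= 3
                   or (pm == 2 and pp >= 2)
                   or (pm == 1 and pp >= 4))
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2
    if (pathogenic or likely_path) and (benign or likely_benign):
        return Tier.VUS, True
    if pathogenic:
        return Tier.PATHOGENIC, False
    if likely_path:
        return Tier.LIKELY_PATHOGENIC, False
    if benign:
        return Tier.BENIGN, False
    if likely_benign:
        return Tier.LIKELY_BENIGN, False
    return Tier.VUS, False


PS_CODES = ("PS1", "PS2", "PS3")
PM_CODES = ("PM1", "PM2", "PM3", "PM4", "PM5")
PP_CODES = ("PP1", "PP2", "PP3", "PP4", "PP5")
BS_CODES = ("BS1", "BS2", "BS3")
BP_CODES = ("BP1", "BP2", "BP3")


def lattice_evidence(pvs, ps, pm, pp, ba, bs, bp):
    codes = (("PVS1",) * pvs + PS_CODES[:ps] + PM_CODES[:pm] + PP_CODES[:pp]
             + ("BA1",) * ba + BS_CODES[:bs] + BP_CODES[:bp])
    return ev(*codes)


LATTICE = list(itertools.product(range(2), range(4), range(6), range(6),
                                 range(2), range(4), range(4)))


class TestCombine:
    @pytest.mark.parametrize("codes,tier", [
        (("PVS1", "PS1"), Tier.PATHOGENIC),
        (("PVS1", "PM2"), Tier.LIKELY_PATHOGENIC),
        (("PVS1", "PM2", "PM4"), Tier.PATHOGENIC),
        (("PVS1",), Tier.VUS),            # strict table: no clause matches
        (("PM2",), Tier.VUS),
        (("PS1", "PM1", "PM2"), Tier.LIKELY_PATHOGENIC),
        (("PS1", "PM1", "PM2", "PM3"), Tier.PATHOGENIC),
        (("PM1", "PM2", "PM3"), Tier.LIKELY_PATHOGENIC),
        (("BA1",), Tier.BENIGN),
        (("BS1", "BS2"), Tier.BENIGN),
        (("BS1", "BP1"), Tier.LIKELY_BENIGN),
        (("BP1", "BP4"), Tier.LIKELY_BENIGN),
        ((), Tier.VUS),
    ])
    def test_rule_table_examples(self, codes, tier):
        assert combine(ev(*codes)).tier == tier

    def test_conflict_resolves_to_vus(self):
        cls = combine(ev("PVS1", "PS1", "BS1", "BS2"))
        assert cls.tier == Tier.VUS
        assert cls.conflict
        assert not combine(ev("PVS1", "PS1")).conflict

    def test_benign_evidence_without_rule_is_not_conflict(self):
        # one BS alone fires no benign rule, so pathogenic side stands
        assert combine(ev("PVS1", "PS1", "BS1")).tier == Tier.PATHOGENIC

    def test_strength_override_changes_counts(self):
        # PM2 promoted to strong acts as a second strong criterion
        assert combine(ev("PS1", "PM2")).tier == Tier.LIKELY_PATHOGENIC
        assert combine(ev("PS1", "PM2", PM2="strong")).tier == Tier.PATHOGENIC
        # PVS1 downgraded to strong no longer triggers the very-strong clause
        assert combine(ev("PVS1", "PM2", PVS1="strong")).tier \
            == Tier.LIKELY_PATHOGENIC

    def test_exhaustive_lattice_against_oracle(self):
        for pvs, ps, pm, pp, ba, bs, bp in LATTICE:
            cls = combine(lattice_evidence(pvs, ps, pm, pp, ba, bs, bp))
            tier, conflict = oracle_tier(pvs, ps, pm, pp, ba, bs, bp)
            assert (cls.tier, cls.conflict) == (tier, conflict), \
                (pvs, ps, pm, pp, ba, bs, bp)

    def test_pathogenic_monotonicity(self):
        """Absent benign evidence, adding pathogenic evidence never
        lowers the verdict."""
        for pvs, ps, pm, pp in itertools.product(range(2), range(3),
                                                 range(5), range(5)):
            base = combine(lattice_evidence(pvs, ps, pm, pp, 0, 0, 0)).tier
            for dpvs, dps, dpm, dpp in ((1, 0, 0, 0), (0, 1, 0, 0),
                                        (0, 0, 1, 0), (0, 0, 0, 1)):
                bumped = combine(lattice_evidence(
                    min(pvs + dpvs, 1), ps + dps, pm + dpm, pp + dpp,
                    0, 0, 0)).tier
                assert TIER_ORDER[bumped] >= TIER_ORDER[base]

    def test_symmetry_under_evidence_order(self):
        codes = ["PM2", "PVS1", "PP3", "BS1"]
        for perm in itertools.permutations(codes):
            assert combine(ev(*perm)).tier == combine(ev(*codes)).tier

    def test_all_codes_have_native_strengths(self):
        assert len(CRITERION_CODES) == 28
        for code in CRITERION_CODES:
            AcmgCriterion(code)  # does not raise
        assert native_strength("PVS1") == Strength.VERY_STRONG
        assert native_strength("BA1") == Strength.STAND_ALONE


class TestAutoAssign:
    def test_null_variant_in_lof_gene(self, panel):
        rec = make_record(gene="MSH2", cdna="c.187delG", protein="p.Val63Ter")
        codes = {c.code for c in auto_assign(rec, panel["MSH2"]).criteria}
        assert {"PVS1", "PM2"} <= codes

    def test_null_variant_in_non_lof_gene_gets_no_pvs1(self, panel):
        rec = make_record(gene="POLE", cdna="c.100C>T", protein="p.Gln34Ter")
        codes = {c.code for c in auto_assign(rec, panel["POLE"]).criteria}
        assert "PVS1" not in codes

    def test_common_variant_ba1(self, panel):
        rec = make_record(maf=0.12, protein="p.Val100Met", cdna="c.298G>A")
        codes = {c.code for c in auto_assign(rec, panel["MSH2"]).criteria}
        assert codes == {"BA1"}

    def test_bs1_band(self, panel):
        rec = make_record(maf=0.004, protein="p.Val100Met", cdna="c.298G>A")
        codes = {c.code for c in auto_assign(rec, panel["MSH2"]).criteria}
        assert "BS1" in codes and "BA1" not in codes

    def test_inframe_indel_pm4(self, panel):
        rec = make_record(cdna="c.300_302delTGA", protein="p.Asp101del")
        codes = {c.code for c in auto_assign(rec, panel["MSH2"]).criteria}
        assert "PM4" in codes

    def test_silent_benign_predictions(self, panel):
        rec = make_record(cdna="c.300G>A", protein="p.Lys100=", maf=0.004,
                          predictions={p: "tolerated" for p in
                                       ("sift", "polyphen", "grantham",
                                        "fathmm")})
        codes = {c.code for c in auto_assign(rec, panel["MSH2"]).criteria}
        assert {"BP4", "BP7"} <= codes

    def test_pp3_concordant_deleterious(self, panel):
        rec = make_record(cdna="c.298G>A", protein="p.Val100Met",
                          predictions={"sift": "deleterious",
                                       "polyphen": "deleterious",
                                       "fathmm": "deleterious"})
        codes = {c.code for c in auto_assign(rec, panel["MSH2"]).criteria}
        assert "PP3" in codes


class TestClassifyCohort:
    def test_curated_tiers_reproduce_pgv_set(self, table3_records, scenario,
                                             panel):
        unique = dedupe(table3_records)
        classifications = classify_cohort(unique, scenario.curated,
                                          panel=panel)
        pgv = {k for k, c in classifications.items()
               if c.tier in (Tier.PATHOGENIC, Tier.LIKELY_PATHOGENIC)}
        assert len(pgv) == 24

    def test_vus_excluded_from_pgv_set(self, panel):
        rec = make_record(cdna="c.298G>A", protein="p.Val100Met", maf=0.004)
        unique = dedupe([rec])
        cls = classify_cohort(unique, panel=panel)
        assert cls[rec.key].tier == Tier.VUS

    def test_empty_cohort(self, panel):
        assert classify_cohort([], panel=panel) == {}

    def test_unknown_curated_key_warned_and_ignored(self, panel, caplog):
        import logging
        ghost = VariantKey("APC", "c.9999G>A")
        curated = {ghost: EvidenceSet(variant=ghost,
                                      tier_override=Tier.PATHOGENIC)}
        rec = make_record()
        with caplog.at_level(logging.WARNING, logger="crcpanel.acmg"):
            cls = classify_cohort(dedupe([rec]), curated, panel=panel)
        assert ghost not in cls
        assert "unobserved" in caplog.text
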