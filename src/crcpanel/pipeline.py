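"""End-to-end orchestration: funnel -> classification -> verification ->
uncertain-significance accounting -> cohort summary."""

from __future__ import annotations

from dataclasses import dataclass, field

from .acmg import PGV_TIERS, classify_cohort
from .funnel import FilterConfig, FunnelReport, run_pgv_funnel, run_vus_funnel
from .io import CohortTable
from .panel import Panel, default_panel
from .stats import CohortSummary, build_summary
from .verify import (VerificationLedger, apply_ledger, calls_from_unique,
                     default_homology_regions, resolve_patients)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    funnel: FunnelReport
    vus: FunnelReport
    classifications: dict
    pgv_unique: list
    verified_calls: list
    excluded_calls: list
    unverified_calls: list
    resolution: dict
    summary: CohortSummary

    @property
    def pre_carriers(self) -> set:
        return {c.sample_id for calls in
                (self.verified_calls, self.excluded_calls,
                 self.unverified_calls) for c in calls}

    @property
    def post_carriers(self) -> set:
        return {c.sample_id for c in self.verified_calls}


def run_pipeline(cohort: CohortTable, cfg: FilterConfig = FilterConfig(),
                 panel: Panel | None = None, curated=None,
                 ledger: VerificationLedger | None = None,
                 regions=None, reported_flags=None,
                 verify: bool = True, run_tests: bool = True) -> PipelineResult:
    """Run the whole triage on a cohort table.

    With ``verify=False`` the ledger and homology regions are ignored and
    the post-verification surfaces equal the pre-verification ones.
    """
    panel = panel or default_panel()
    funnel = run_pgv_funnel(cohort, cfg, panel)
    classifications = classify_cohort(funnel.unique, curated, panel=panel)
    pgv_unique = [uv for uv in funnel.unique
                  if classifications[uv.key].tier in PGV_TIERS]
    calls = calls_from_unique(pgv_unique, classifications)

    if verify:
        if regions is None:
            regions = default_homology_regions()
        ledger = ledger or VerificationLedger()
        verified, excluded, unverified = apply_ledger(calls, ledger, regions)
    else:
        verified, excluded, unverified = list(calls), [], []

    pre_carriers = {c.sample_id for c in calls}
    vus = run_vus_funnel(cohort, cfg, panel, pgv_carriers=pre_carriers)
    resolution = resolve_patients(cohort.registry or
                                  sorted({r.sample_id for r in cohort.records}),
                                  verified)
    summary = build_summary(cohort, pgv_unique, classifications,
                            verified, excluded, unverified,
                            vus_report=vus, reported_flags=reported_flags,
                            run_tests=run_tests)
    return PipelineResult(
        funnel=funnel, vus=vus, classifications=classifications,
        pgv_unique=pgv_unique, verified_calls=verified,
        excluded_calls=excluded, unverified_calls=unverified,
        resolution=resolution, summary=summary)
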