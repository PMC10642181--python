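"""Cohort-level summary surfaces and association statistics.

Carrier yields, per-gene distributions, novelty and immunohistochemistry
concordance are straight tabulations of the verified call set.  The
association tests mirror standard clinical-genetics practice on small
cohorts: Fisher's exact test (two-sided, minimum-likelihood convention)
for sparse categorical tables, Pearson's chi-squared with Yates continuity
correction for the balanced 2x2, and the Wilcoxon rank-sum test for age.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .hgvs import VariantKey
from .io import CohortTable, PatientRecord
from .panel import MMR_GENES

__all__ = [
    "ContingencyTable", "CohortSummary", "TestResult",
    "fisher_exact", "chi_squared_yates", "wilcoxon_rank_sum",
    "pgv_yield", "mmr_carrier_count", "per_gene_distribution",
    "novelty_count", "ihc_concordance", "association_tests", "build_summary",
]

SIGNIFICANCE_LEVEL = 0.05


class DegenerateTableError(ValueError):
    """A margin of the contingency table is zero (test undefined)."""


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of non-negative integer counts with labels."""

    counts: tuple
    row_labels: tuple = ()
    col_labels: tuple = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=int)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", tuple(map(tuple, arr.tolist())))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)


@dataclass(frozen=True)
class TestResult:
    method: str
    p_value: float
    statistic: float | None = None
    significant: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "significant",
                           bool(self.p_value < SIGNIFICANCE_LEVEL))


def _as_array(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.array
    return np.asarray(table, dtype=int)


def fisher_exact(table, tol: float = 1e-12) -> float:
    """Two-sided Fisher's exact p by full hypergeometric enumeration.

    The two-sided p is the sum of the probabilities, under fixed margins,
    of every table whose point probability does not exceed that of the
    observed table (to within a relative tolerance) — the
    minimum-likelihood convention.  2x2 tables are enumerated directly;
    general r x c tables are enumerated recursively for totals up to 200.
    """
    arr = _as_array(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError(f"zero margin in table {arr.tolist()}")

    if arr.shape == (2, 2):
        a, b = arr[0]
        c, d = arr[1]
        r1, c1, n = a + b, a + c, arr.sum()
        support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
        pmf = sps.hypergeom.pmf(support, n, r1, c1)
        p_obs = sps.hypergeom.pmf(a, n, r1, c1)
        p = float(pmf[pmf <= p_obs * (1 + tol)].sum())
        return min(p, 1.0)

    n = int(arr.sum())
    if n > 200:
        raise ValueError("r x c enumeration supported for totals up to 200")
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)

    from math import lgamma

    def lfact(k):
        return lgamma(k + 1)

    log_const = (sum(lfact(r) for r in row_sums)
                 + sum(lfact(c) for c in col_sums) - lfact(n))

    def log_prob(cells) -> float:
        return log_const - sum(lfact(x) for x in cells)

    p_obs = log_prob(arr.ravel().tolist())
    total = 0.0
    r, c = arr.shape

    def recurse(row: int, cols_left: np.ndarray, cells: list):
        nonlocal total
        if row == r - 1:
            final = cells + cols_left.tolist()
            lp = log_prob(final)
            if lp <= p_obs + math.log1p(tol):
                total += math.exp(lp)
            return
        # enumerate compositions of row_sums[row] into c parts bounded by cols_left
        target = row_sums[row]

        def fill(j: int, remaining: int, row_cells: list):
            if j == c - 1:
                if remaining <= cols_left[j]:
                    new_cols = cols_left - np.array(row_cells + [remaining])
                    recurse(row + 1, new_cols, cells + row_cells + [remaining])
                return
            for x in range(min(remaining, cols_left[j]) + 1):
                fill(j + 1, remaining - x, row_cells + [x])

        fill(0, int(target), [])

    recurse(0, col_sums.copy(), [])
    return min(float(total), 1.0)


def chi_squared_yates(table) -> TestResult:
    """Pearson's chi-squared on a 2x2 with Yates continuity correction."""
    arr = _as_array(table)
    if arr.shape != (2, 2):
        raise ValueError("chi-squared with Yates correction requires a 2x2 table")
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if (expected == 0).any():
        raise DegenerateTableError(f"zero expected count in table {arr.tolist()}")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=True)
    return TestResult(method="chi_squared_yates", p_value=float(p),
                      statistic=float(stat))


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when both groups have at most 10 untied values;
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    if np.ptp(combined) == 0:
        return TestResult(method="wilcoxon_rank_sum", p_value=1.0,
                          statistic=float(len(x) * len(y) / 2))
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(method="wilcoxon_rank_sum", p_value=float(res.pvalue),
                      statistic=float(res.statistic))


# ---------------------------------------------------------------------------
# tabulations

def pgv_yield(n_patients: int, calls) -> tuple[int, float]:
    """Distinct patients with >=1 call, as count and proportion."""
    if n_patients == 0:
        raise ZeroDivisionError("proportion undefined for an empty cohort")
    count = len({c.sample_id for c in calls})
    return count, count / n_patients


def mmr_carrier_count(calls) -> int:
    """Distinct patients with >=1 call in a mismatch-repair gene.

    EPCAM is excluded from the MMR set: its mechanism (MSH2 silencing by
    3' deletion) is not detectable as a small coding variant here.
    """
    return len({c.sample_id for c in calls if c.key.gene in MMR_GENES})


def per_gene_distribution(unique_pgvs, classifications, genes=None) -> dict:
    """Unique-variant counts per gene split by tier; absent genes are zero."""
    out: dict[str, dict[str, int]] = {}
    if genes is not None:
        for g in genes:
            out[g] = {"pathogenic": 0, "likely_pathogenic": 0}
    for uv in unique_pgvs:
        cls = classifications[uv.key]
        tier = getattr(cls.tier, "value", cls.tier)
        bucket = out.setdefault(uv.key.gene,
                                {"pathogenic": 0, "likely_pathogenic": 0})
        if tier in bucket:
            bucket[tier] += 1
    return out


def novelty_count(unique_pgvs, reported_flags) -> tuple[int, int]:
    """Count unique variants not reported before, and the MMR subset.

    ``reported_flags`` maps :class:`VariantKey` to the report-column string;
    a flag starting with "no" (including qualified entries such as
    "No (G>T only)") marks the variant novel.
    """
    novel = set()
    for uv in unique_pgvs:
        flag = str(reported_flags.get(uv.key, "")).strip().lower()
        if flag.startswith("no"):
            novel.add(uv.key)
    n_mmr = sum(1 for k in novel if k.gene in MMR_GENES)
    return len(novel), n_mmr


def ihc_concordance(entries) -> list[dict]:
    """Assess IHC staining against the variant found per patient.

    ``entries`` iterates ``(patient_id, ihc, variant_gene)`` where ``ihc``
    is a list of MMR proteins lost or the string ``"all_positive"``.
    Concordant iff a lost protein's gene matches the variant's gene, or
    staining was normal and the variant is in a non-MMR gene.
    """
    out = []
    for patient_id, ihc, variant_gene in entries:
        gene = str(variant_gene).strip().upper()
        if isinstance(ihc, str) and ihc.strip().lower() == "all_positive":
            concordant = gene not in MMR_GENES
        else:
            lost = {str(g).strip().upper() for g in ihc}
            concordant = gene in lost
        out.append({"patient_id": str(patient_id), "gene": gene,
                    "concordant": concordant})
    return out


def association_tests(registry: dict[str, PatientRecord],
                      positive_ids, include_na: bool = False) -> dict:
    """Clinical covariates versus mutation status.

    Age is compared by rank-sum; dichotomised age (<50 / >=50) by Fisher's
    exact test; gender by Yates-corrected chi-squared; tumor localization
    and sidedness by Fisher's exact test on the r x c table ("not
    applicable" rows excluded unless requested).
    """
    positive = set(positive_ids)
    pos = [p for p in registry.values() if p.patient_id in positive]
    neg = [p for p in registry.values() if p.patient_id not in positive]
    out: dict[str, TestResult] = {}

    out["age"] = wilcoxon_rank_sum([p.age_dx for p in pos],
                                   [p.age_dx for p in neg])

    age_table = [[sum(1 for p in pos if p.age_dx < 50),
                  sum(1 for p in neg if p.age_dx < 50)],
                 [sum(1 for p in pos if p.age_dx >= 50),
                  sum(1 for p in neg if p.age_dx >= 50)]]
    out["categorical_age"] = TestResult(
        method="fisher_exact", p_value=fisher_exact(age_table))

    gender_table = [[sum(1 for p in pos if p.gender.value == "male"),
                     sum(1 for p in neg if p.gender.value == "male")],
                    [sum(1 for p in pos if p.gender.value == "female"),
                     sum(1 for p in neg if p.gender.value == "female")]]
    out["gender"] = chi_squared_yates(gender_table)

    for name, attr in (("localization", "localization"),
                       ("sidedness", "sidedness")):
        levels = []
        for p in registry.values():
            v = getattr(p, attr).value
            if v == "na" and not include_na:
                continue
            if v not in levels:
                levels.append(v)
        tbl = [[sum(1 for p in pos if getattr(p, attr).value == lv),
                sum(1 for p in neg if getattr(p, attr).value == lv)]
               for lv in levels]
        tbl = [row for row in tbl if sum(row) > 0]
        if len(tbl) >= 2:
            out[name] = TestResult(method="fisher_exact",
                                   p_value=fisher_exact(tbl))
    return out


# ---------------------------------------------------------------------------
# the full summary

@dataclass
class CohortSummary:
    """Everything the cohort report prints, in one serialisable object."""

    n_patients: int
    n_pgv_patients_pre: int
    pgv_proportion_pre: float
    n_pgv_patients_post: int
    pgv_proportion_post: float
    n_unique_pgvs: int
    n_novel_unique_pgvs: int
    n_novel_mmr: int
    n_mmr_carriers_verified: int
    mmr_proportion: float
    per_gene: dict
    n_unique_vus: int
    vus_per_gene: dict
    n_vus_carriers: int
    n_vus_carriers_with_pgv: int
    n_unresolved: int
    unresolved_patients: list
    excluded_calls: list
    tests: dict = field(default_factory=dict)
    significance_level: float = SIGNIFICANCE_LEVEL

    def __post_init__(self) -> None:
        assert self.n_mmr_carriers_verified <= self.n_pgv_patients_post
        assert round(self.pgv_proportion_pre, 4) == round(
            self.n_pgv_patients_pre / self.n_patients, 4)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["tests"] = {
            name: {"method": t.method, "p_value": t.p_value,
                   "statistic": t.statistic, "significant": t.significant}
            for name, t in self.tests.items()}
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def build_summary(cohort: CohortTable, pgv_unique, classifications,
                  verified_calls, excluded_calls, unverified_calls,
                  vus_report=None, reported_flags=None,
                  run_tests: bool = True) -> CohortSummary:
    """Assemble the cohort summary from the pipeline products.

    ``pgv_unique`` holds the unique variants classified into the top two
    tiers, ``verified_calls``/``excluded_calls``/``unverified_calls`` the
    per-patient split after the verification ledger, and ``vus_report``
    the uncertain-significance funnel output.
    """
    n = cohort.n_patients
    pre_calls = [c for calls in
                 ([verified_calls, excluded_calls, unverified_calls])
                 for c in calls]
    n_pre, prop_pre = pgv_yield(n, pre_calls)
    n_post, prop_post = pgv_yield(n, verified_calls)
    novel, novel_mmr = novelty_count(pgv_unique, reported_flags or {})
    mmr_verified = mmr_carrier_count(verified_calls)

    vus_per_gene: dict[str, int] = {}
    n_unique_vus = n_vus_carriers = n_vus_with_pgv = 0
    if vus_report is not None:
        for uv in vus_report.unique:
            vus_per_gene[uv.key.gene] = vus_per_gene.get(uv.key.gene, 0) + 1
        n_unique_vus = vus_report.extras.get("n_unique_vus", len(vus_report.unique))
        n_vus_carriers = vus_report.extras.get("n_vus_carriers", 0)
        n_vus_with_pgv = vus_report.extras.get("n_vus_carriers_with_pgv", 0)

    pre_carriers = {c.sample_id for c in pre_calls}
    post_carriers = {c.sample_id for c in verified_calls}
    unresolved = sorted(pre_carriers - post_carriers, key=str)

    tests = {}
    if run_tests and cohort.registry:
        tests = association_tests(cohort.registry, pre_carriers)

    return CohortSummary(
        n_patients=n,
        n_pgv_patients_pre=n_pre,
        pgv_proportion_pre=prop_pre,
        n_pgv_patients_post=n_post,
        pgv_proportion_post=prop_post,
        n_unique_pgvs=len(pgv_unique),
        n_novel_unique_pgvs=novel,
        n_novel_mmr=novel_mmr,
        n_mmr_carriers_verified=mmr_verified,
        mmr_proportion=mmr_verified / n if n else 0.0,
        per_gene=per_gene_distribution(pgv_unique, classifications),
        n_unique_vus=n_unique_vus,
        vus_per_gene=vus_per_gene,
        n_vus_carriers=n_vus_carriers,
        n_vus_carriers_with_pgv=n_vus_with_pgv,
        n_unresolved=len(unresolved),
        unresolved_patients=unresolved,
        excluded_calls=[{"gene": c.key.gene, "cdna": c.key.cdna,
                         "sample_id": c.sample_id} for c in excluded_calls],
        tests=tests,
    )
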