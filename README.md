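# crcpanel

Germline variant triage for a 14-gene hereditary colorectal cancer (CRC)
panel: the filter funnel, ACMG/AMP classification, pseudogene-aware
verification, and cohort statistics behind a multigene panel screen —
with a synthetic-cohort generator so every stage is testable offline.

## The problem

Panel sequencing of a CRC cohort yields 100–200 annotated small-variant
calls per patient. A clinical screen narrows these to the handful of
pathogenic/likely pathogenic germline variants (PGVs) through an ordered
cascade of filters — caller PASS status, functional class and location,
population frequency (MAF < 0.05 or unknown), ClinVar category, a
recurrent-indel artifact screen, and depth of coverage (> 30×) — then
deduplicates to unique variants, combines ACMG evidence codes
(PVS1, PS1–4, PM1–6, PP1–5, BA1, BS1–4, BP1–7) into the five-tier verdict,
and confirms calls orthogonally. Calls in the 3' exons of *PMS2* need
gene-specific confirmation because the pseudogene *PMS2CL* is
near-identical there; a verification ledger records per-variant,
per-sample outcomes, and patient resolution is recomputed from the
verified call set. The package is aimed at groups running or auditing
such screens who want the desk-side arithmetic reproducible and testable.

The ACMG combining rules are implemented in full: e.g. *Pathogenic* iff
PVS1 ∧ (≥1 PS ∨ ≥2 PM ∨ (1 PM ∧ 1 PP) ∨ ≥2 PP), or ≥2 PS, or
1 PS ∧ (≥3 PM ∨ (2 PM ∧ ≥2 PP) ∨ (1 PM ∧ ≥4 PP)); contradictory evidence
resolves to uncertain significance with a conflict flag. Two-sided
Fisher's exact p-values use the minimum-likelihood convention by full
hypergeometric enumeration (2×2 and r×c up to N = 200).

## Worked example

The packaged reference scenario rebuilds a 107-patient early-onset CRC
cohort from the shipped tables (28 candidate-pathogenic carrier rows, 21
uncertain-significance variants, benign background, one recurrent-indel
artifact, and the verification ledger for the *PMS2* calls):

```
$ crcpanel report --scenario paper --out out/
25/107 patients (23.4%) with a verified pathogenic/likely pathogenic variant; 24 unique; 21 unique VUS
```

`out/summary.json` then contains, among others:

```json
{
  "n_patients": 107,
  "n_pgv_patients_pre": 27,
  "n_pgv_patients_post": 25,
  "n_unique_pgvs": 24,
  "n_novel_unique_pgvs": 10,
  "n_mmr_carriers_verified": 14,
  "n_unique_vus": 21,
  "n_vus_carriers": 35
}
```

Reading: 27 patients carried a candidate PGV before verification (24
unique variants); long-range PCR showed the recurrent
*PMS2*:c.2192_2196delTAACT call absent in its three carriers, leaving 25
verified carriers (23.4%), of whom 14 carry a mismatch-repair-gene
variant (Lynch syndrome, 13.1%); two patients whose only call failed
verification remain unresolved. The same objects are available from
Python:

```python
from crcpanel import run_pipeline
from crcpanel.simulate import paper_scenario

sc = paper_scenario()
result = run_pipeline(sc.cohort, curated=sc.curated, ledger=sc.ledger,
                      reported_flags=sc.reported_flags)
print(result.summary.n_pgv_patients_post)   # 25
print(result.summary.tests["gender"].p_value)  # 0.697...
```

Synthetic cohorts with exact ground truth:

```
crcpanel simulate --seed 1 --n-patients 50 --out sim/
crcpanel triage --annotations sim/annotations.tsv --registry sim/registry.tsv --out sim/triage/
```

`sim/truth.tsv` records, for every generated call, the funnel stage at
which it must be removed (or "prioritized"), its expected tier and its
expected verification status.

## Layout

- `crcpanel.panel` / `crcpanel.hgvs` — panel definition, cDNA HGVS
  parsing, variant identity
- `crcpanel.io` — annotation TSV / minimal VCF / registry / packaged
  reference tables
- `crcpanel.funnel` — the PGV and VUS filter cascades with per-stage
  reports
- `crcpanel.acmg` — evidence combination, auto-assignment, curated
  evidence
- `crcpanel.verify` — homology regions, verification ledger, patient
  resolution
- `crcpanel.stats` — yields, distributions, concordance, exact tests
- `crcpanel.simulate` — synthetic cohorts with truth tables; the
  reference scenario
- `crcpanel.cli` / `crcpanel.pipeline` — orchestration

See `docs/methods.md` for the model, parameter defaults and the
assumptions behind the synthetic generator.
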