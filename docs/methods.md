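# Methods

## Problem and scope

Multigene panel screening for hereditary colorectal cancer produces, per
patient, 100–200 annotated small-variant calls of which at most a handful
are clinically meaningful. `crcpanel` implements the desk side of that
screen for a 14-gene panel (the Lynch-syndrome mismatch-repair genes MLH1,
MSH2, MSH6, PMS2 plus EPCAM; the polyposis genes APC, BMPR1A, MUTYH,
SMAD4, PTEN, STK11; the proofreading polymerases POLD1, POLE; and TP53):
merging per-sample annotation exports, narrowing them through an ordered
filter funnel, combining ACMG/AMP evidence into the five-tier verdict,
applying orthogonal-verification results with explicit handling of the
PMS2/PMS2CL pseudogene problem, and producing the cohort yield and
association surfaces. Read alignment, variant calling and annotation are
upstream of this package: inputs arrive as annotated tables (TSV with a
configurable column dialect, or a minimal VCF for synthetic interchange).

## The filter funnel

The candidate-pathogenic cascade applies, in order:

1. **PASS** — only calls the upstream caller marked PASS.
2. **Functional/location** — synonymous calls removed; retained locations
   are exonic and near-exonic ("flanking": intronic offset within
   `flank_bp` of an exon edge). A synonymous call survives only under the
   *rescue rule*: a pathogenic-tier ClinVar entry or splice candidacy.
   Splice candidacy of an exonic base means lying within `splice_flank_bp`
   coding bases of an annotated exon boundary; boundaries are part of the
   panel configuration, not hard-coded biology, because transcript exon
   tables change with annotation releases.
3. **Frequency** — retain minor allele frequency strictly below `maf_max`,
   or unknown. Unknown is retained deliberately: in understudied
   populations most true pathogenic variants have no population-database
   entry, and treating missing as zero would be equivalent, while treating
   it as common would discard exactly the variants of interest.
4. **ClinVar category** — benign and likely-benign archive entries are
   removed; pathogenic, likely pathogenic, uncertain, conflicting and
   absent entries continue.
5. **Artifact screen** — an indel key called in more than
   `artifact_sample_fraction` of cohort samples is flagged as a recurrent
   alignment/homopolymer artifact, removed from the prioritized list and
   preserved in the report. This deterministic rule stands in for manual
   inspection of pileups; substitutions are never flagged. The fraction
   (default 0.2) is a judgement call — recurrence across unrelated samples
   at panel scale is the signature being captured, and the threshold is
   configurable.
6. **Depth** — retain calls covered by strictly more than `depth_min`
   reads (default 30, i.e. "30× or less" is excluded; the stricter of the
   two readings the source protocols admit, applied to both cascades).
7. **Dedup** — records collapse to unique variants keyed by
   (gene, whitespace-normalised cDNA HGVS), keeping carrier lists and
   record-level provenance.

Retained counts are non-increasing along the cascade and this is asserted
on every run. The uncertain-significance cascade mirrors the same
thresholds in the order: ClinVar uncertain → depth → exonic and
non-synonymous → dedup → frequency, and reports the unique VUS count, VUS
carriers, and their overlap with the candidate-pathogenic carrier set.
Filter predicates commute at the record level (verified by a one-pass
oracle in the tests), so stage order affects intermediate counts only.

## ACMG/AMP combination

The 28 evidence codes are combined by the 2015 rule table. Counts use
*effective* strengths, so curated overrides (e.g. PVS1 downgraded to
strong) flow through the arithmetic. Contradictory evidence — any
pathogenic-side rule and any benign-side rule firing together — resolves
to uncertain significance with a conflict flag. PVS1 alone is uncertain
significance under the strict table (no likely-pathogenic clause matches);
some commercial tools emit likely pathogenic there, and the difference is
visible in the `fired_rule` field.

The auto-assigner covers only criteria computable from the record itself:
PVS1 (null variant — nonsense, frameshift, canonical ±1/2 splice — in a
gene with a loss-of-function mechanism; POLD1/POLE are excluded since
their mechanism is proofreading-domain missense), PM2 (frequency below
1e-4 or absent), BA1 (>0.05), BS1 (>1e-3), PM4 (in-frame indel), PP3/BP4
(at least 3 of the 4 in-silico predictors concordant), BP7 (silent, no
splice candidacy, benign predictions). The frequency cutoffs are artifact
configuration, not published facts. Everything requiring literature,
segregation or functional evidence enters through the curated-evidence
channel (TSV of codes with optional strength overrides and an optional
final-tier override), which wins per code. Published per-variant tiers are
supplied to the reference scenario this way, because the full evidence
behind them is not recomputable offline.

## Verification and the PMS2/PMS2CL problem

Short reads cannot distinguish the 3' exons of PMS2 from the pseudogene
PMS2CL; a call there may originate from either locus. Calls whose coding
span intersects a configured homology region (shipped default:
PMS2 c.1145–c.2589, the 3' exon block mirrored in PMS2CL; the exact
boundary is configuration) require gene-specific confirmation. The wet-lab
outcome enters as a ledger of (variant, sample) → confirmed_present /
confirmed_absent / unverified. `apply_ledger` removes confirmed-absent
calls, removes homology-region calls that remain unverified (conservative:
an unverifiable call never contributes to the verified yield), and keeps
everything else; it never adds calls and is idempotent. Patients are
resolved iff at least one verified pathogenic/likely pathogenic call
remains.

## Cohort statistics

Yields are distinct-carrier counts over the registry denominator. The MMR
(Lynch-syndrome) carrier count uses {MLH1, MSH2, MSH6, PMS2}; EPCAM is
excluded because its mechanism (3' deletions silencing MSH2) is not a
small coding variant detectable here. Association tests follow small-cohort
practice: two-sided Fisher's exact test in the minimum-likelihood
convention (sum of the probabilities of all margin-fixed tables whose
point probability does not exceed the observed, within 1e-12 relative
tolerance; 2×2 via direct hypergeometric enumeration, r×c by recursive
enumeration for totals up to 200), Pearson's chi-squared with Yates
continuity correction for the balanced 2×2, and the Wilcoxon rank-sum test
(exact for two untied groups of ≤10, otherwise normal approximation with
tie and continuity correction). "Not applicable" levels are excluded from
association tables by default. The significance threshold is 0.05 and no
multiple-testing correction is applied, matching the descriptive intent of
the surface. The mid-p Fisher variant was rejected because it does not
reproduce the reference value for the age table; Yates correction was kept
because the uncorrected chi-squared gives ≈0.54 where the corrected test
gives 0.697.

## Synthetic cohorts and the reference scenario

`generate_cohort` is truth-table-driven rather than a free simulation:
every planted and background variant is constructed to fail one chosen
funnel stage (or survive), so per-stage retained counts are exactly
checkable, not just statistically. Defaults emulate the study conditions:
107 patients, 100–200 calls each, negative-binomial depth with mean 604×
(dispersion 10), background frequency mixture of a common clump
(MAF ~ U(0.05, 0.5), ClinVar benign) and rare noise (MAF ~ U(0, 0.05) or
absent), registry ages from a discretised truncated normal
(mean 36, SD 9, bounds [18, 58]; no distribution family is published, so
this is a stand-in matching the reported mean/SD/range), balanced gender,
colon:rectum ≈ 3:1. All randomness flows from a single `numpy` generator
seeded once; outputs are byte-identical for a fixed seed.

Shadow variants (planted in the PMS2 homology region with annotations
indistinguishable from real calls) test that unverified homology calls
never reach verified yields. Artifact indels are planted above the
flagging fraction. Planted pathogenic variants come with curated tiers, so
at the funnel+classifier level recovery is exact (sensitivity =
specificity = 1 over seeded configurations) — a check of plumbing
correctness, not of classification power.

`paper_scenario` deterministically rebuilds the study cohort from the
packaged tables: the 28 candidate-pathogenic carrier rows, the 21 VUSs,
one recurrent-indel artifact in 30/107 samples, two benign background
calls per patient, and the verification ledger marking
PMS2 c.2192_2196delTAACT absent in its three carriers (and
c.1579_1580delAG present in its one). VUS carrier assignments are
synthetic — the source prints only variants and cohort totals — chosen to
satisfy exactly the published constraints (35 carriers, 19 with an
MMR-gene VUS, 9 overlapping the PGV-positive set, 5 MSH6 carriers). The
registry is likewise synthetic but reproduces the published cross-tabs
cell-for-cell. What passing tests on this scenario show is that the
pipeline arithmetic reproduces the published surfaces from the published
per-variant inputs; they do not re-derive the upstream funnel from raw
reads (the raw-cohort counts 15,063 → 1,092 → 360 → 305 and 231 → 226 → 39
require the archived sequencing data and the upstream caller, and are out
of scope).

## Numerical and degenerate-input choices

Frequency and depth comparisons are strict inequalities (`maf < 0.05`,
`depth > 30`). Missing MAF is "rare, unknown", never 0. Zero-margin
contingency tables raise a degenerate-table error rather than returning
NaN. HGVS support is deliberately partial — substitutions, del, ins,
delins, dup, intronic offsets — covering panel reports; unparseable
descriptions are preserved verbatim with kind `unknown` and are never
silently dropped. Variant identity is whitespace/case-normalised
(gene, cDNA); no genome liftover or transcript projection is attempted.
Tie-break in dedup is first-seen order, making reports stable under
re-runs and input order changes (asserted by property tests).

## Known limitations

- Exon boundaries ship only for MLH1 (needed for the silent splice-site
  rescue); other genes fall back to canonical ±1/2 intronic detection
  until boundaries are configured.
- The auto-assigner is deliberately conservative; without curated
  evidence most true pathogenic missense variants classify as uncertain.
- A combination-dependent rule (a proofreading-gene missense treated as
  likely pathogenic only in the presence of a second heterozygous
  pathogenic variant) is not expressible in the rule table and is left to
  curated evidence.
- The artifact screen needs cohort-level recurrence; it cannot flag an
  artifact seen in a single sample.
- The synthetic background does not model annotation errors, multi-allelic
  sites, or correlated depth across amplicons.
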