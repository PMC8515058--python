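# Methods

## The analysis

`ctdna-concord` implements a tumor-informed liquid-biopsy analysis for
targeted-panel sequencing of ovarian cancer. Each patient contributes an
FFPE tumor sample and a matched plasma sample, both sequenced with the same
27-gene panel and UMI consensus calling. The package consumes *annotated
variant call tables* (it performs no alignment, variant calling or
annotation lookups) and answers three questions:

1. Which called variants are credible, potentially pathogenic somatic
   events (triage + germline resolution)?
2. In what fraction of patients is at least one tumor somatic variant also
   detectable in plasma, overall and by treatment group, FIGO stage and
   sampling timing (concordance)?
3. What do plasma-only variants say about inter-/intra-tumor heterogeneity
   (reverse analysis and clonality calls)?

## Triage cascade

Per sample, each variant passes through ordered gates; the first failing
gate is recorded, and every decision carries its full gate trace.

Prefilter (in order):

| gate       | rule                                                        | default |
|------------|-------------------------------------------------------------|---------|
| population | max available AF over 1000G/gnomAD/ExAC (MMAF) > `max_pop_af` → discard `common_maf` | 1% |
| synonymous | synonymous consequence → discard                             | — |
| VAF        | VAF < floor → discard `low_vaf`; no VAF evidence → `no_vaf` | tumor 5%; plasma 0.5% (GeneGlobe caller) / 0.2% (CLC caller) |

The VAF floor is inclusive (a call exactly at the floor passes); lowering
the plasma floor therefore retains a superset of variants — the
monotonicity property the mode-contrast analysis relies on.

Classification (first match wins):

1. ClinVar pathogenic / likely pathogenic → retained (`clinvar_pathogenic`);
2. ClinVar benign / likely benign → discarded (`clinvar_benign`) — the
   ClinVar classification outranks consequence in both directions, so a
   ClinVar-benign nonsense call is discarded;
3. nonsense, frameshift or canonical ±1/2 splice-site → retained
   (`truncating_or_splice`);
4. unclassified inframe indel → retained (`inframe_indel`);
5. missense → retained only on unanimous in-silico consensus: MetaLR
   damaging AND MetaSVM damaging AND CADD phred ≥ `cadd_phred_cutoff`
   (default 20, the conventional CADD cutoff; configurable because
   annotators differ). A missing predictor breaks the consensus and is
   named in the trace;
6. anything else → discarded (`unclassifiable`).

ClinVar VUS and conflicting-interpretation records are treated as "not
classified" and routed to the consequence rules. The MMAF is reported in
the audit trail but is not an additional retention gate beyond the 1%
prefilter: retention of missense VUS hinges on the three predictors only.

## Germline resolution

In plasma, nearly all cfDNA is non-tumor, so a heterozygous germline
variant sits near 50% VAF while ctDNA-diluted somatic variants sit far
below. Retained plasma variants with VAF inside a closed window (default
[0.40, 0.60]; the width is configurable because "near 50%" is a judgment
call and sensitivity to it should be testable) are flagged *suspected
germline*. A suspect excludes nothing by itself: exclusion requires either
membership on the patient's prior-study germline list or an orthogonal
confirmation flag (e.g. Sanger on blood), supplied as input. Confirmed
evidence removes the variant from both the tumor and plasma retained sets;
unconfirmed suspects are written to a pending-confirmation report and stay
somatic. Evidence is keyed per (patient, normalized variant key), so the
same allele in two patients is independent evidence, and exclusion is
idempotent.

## Variant identity

Tumor/plasma matching is exact on normalized keys (same panel, same
target regions — no fuzzy windows). Internally a key is the minimal
spelling of the event: shared trailing then leading bases are trimmed, and
for pure indels one allele may become empty. This collapses left- and
right-padded spellings of the same indel without needing a reference
genome, which keeps the package download-free. Spellings that differ by
position inside a repeat run are inherently ambiguous without sequence
context; when a reference window is available, `left_align` shifts the key
to the leftmost equivalent position (shift-then-trim). Stored records keep
VCF-style anchored alleles; only comparison keys use the minimal form
(serialized with `-` for an empty allele).

## Concordance

A patient is *eligible* if the tumor yielded ≥ 1 somatic variant after
triage and germline exclusion — concordance is undefined without a
tumor-informed target set, so variant-free and QC-failed tumors leave the
denominator. A patient is *concordant* if the key intersection of tumor
and plasma somatic sets is non-empty. Percentages are reported to one
decimal, half-up, always beside their raw counts so every stratum is
auditable; empty strata report NA. Stratum counts sum to the overall
counts by construction.

For patients with ≥ 2 shared variants, VAF-hierarchy concordance asks
whether tumor and plasma rank the shared variants identically (strict
order, ties break it); Kendall's tau (scipy) is reported as the
quantitative companion since rank agreement alone has no magnitude.

The gene spectrum counts each tumor sample once per gene, over the
QC-passing tumor denominator, with exact fractions. The post-surgery
outcome table is a pure cross-tabulation of ctDNA detection (≥ 1 shared
variant) against outcome; no survival model is fitted.

## Reverse analysis

Plasma-only somatic keys (plasma minus index tumor) are attributed to any
additional anatomic-site profiles that contain them. Two site profiles are
called `clonally_related` when they share ≥ `min_shared` somatic variants
(default 2 — a single shared hotspot can recur independently, so one match
is `indeterminate`); non-empty profiles sharing nothing are `independent`.
Rarity of the shared combination is *not* computed (that would need
external cohort frequencies); the verdict is purely count-based and
documented as such. Sanger-targeted profiles contribute presence/absence
only for queried keys; absence of an unqueried key is unknown, not
negative.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the called-variant level (no reads). Defaults encode the study conditions
the pipeline is designed for; none of the distributional choices is a
claim about any real cohort.

* **Cohort composition** — 96 patients; 24% treatment-naive / 76%
  post-treatment; FIGO stages 14.6/7.3/57.3/20.8%; histology mix headed by
  high-grade serous (71.9%). Counts are allocated by largest remainder and
  shuffled, so the default cohort hits 23/73, stages 14/7/55/20 and 69
  high-grade serous exactly. Post-treatment timings split 7:12:6:48
  (post-surgery : recurrence : progression : on-chemo). Two tumor samples
  fail QC (`qc_fail_rate = 2/96`).
* **Tumor variants** — independent Bernoulli per panel gene (TP53 0.78,
  BRCA1/ARID1A/KRAS 0.096, PIK3CA 0.085, PTEN/RB1 0.064,
  BRCA2/ATM/ATR/MSH6 0.053, remaining genes 0.02). True tumor VAF ~
  Beta(2, 2) truncated to [0.05, 0.95]; observed via Binomial at UMI depth
  1276. Retention category mix 0.47/0.20/0.04/0.29 (ClinVar-P/LP,
  truncating, inframe, missense-consensus), mirroring the benchmark tumor
  accounting proportions.
* **Shedding model** — per-patient ctDNA fraction = stage median ×
  exp(σ·Z), σ(log) = 1.0, capped at 1. Stage medians 0.001 / 0.003 / 0.01 /
  0.03 for I–IV (stage II is the geometric interpolation of its
  neighbours, as no separate anchor exists); post-treatment plasma is
  attenuated ×0.1. True plasma VAF = tumor VAF × fraction; observed via
  Binomial at depth 513. A call enters the plasma table iff ≥ 1 consensus
  read supports it and the implied VAF clears the caller noise floor
  (0.001) — deliberately below both analysis floors, so sensitivity is
  governed by the triage thresholds, which is what the 0.5%-vs-0.2%
  contrast measures.
* **Germline** — 37 variants across the cohort (multinomial over
  patients), 26 on the prior-study list and 11 discoverable only through
  the plasma VAF window; both-sample VAF ~ Normal(0.5, 0.03) clipped to
  [0.3, 0.7]; ClinVar P/LP annotations (germline pathogenic alleles in
  BRCA-pathway genes).
* **Decoys** — per-sample Poisson counts of annotation classes the cascade
  must discard: common polymorphisms (mean 12), synonymous (6), ClinVar
  benign (2), non-consensus missense (5). These rates are desk-scale
  stand-ins, far below a raw annotator's output volume; they exercise
  every discard path without dominating runtime.
* **Calibration override** — `patient_detection_probability` replaces the
  shedding model with a patient-level coin: with probability p, one
  tumor-retained somatic variant is copied into plasma at VAF 15/513.
  Used to verify that measured concordance recovers a known p; not part of
  the default conditions.

A fixed seed makes cohorts bit-reproducible. What the simulation does
*not* model: co-mutation structure (genes are independent), FFPE artifact
chemistry, UMI family-size error profiles, panel footprint differences
between callers, and CHIP (clonal hematopoiesis) contamination of plasma —
so green tests demonstrate pipeline correctness under the assumed
generative structure, not caller accuracy on real reads.

## Benchmark fixture

`build_reference_fixture()` constructs, deterministically and without an
RNG, a 96-patient cohort whose annotation-category composition matches a
published variant-accounting benchmark exactly: 7255 annotated tumor calls
(94 QC-passing samples) of which 335 survive the prefilter — 99 ClinVar
P/LP, 41 truncating/splice, 8 inframe, 187 missense with exactly 61
three-way-damaging — giving 209 retained; 37 germline (patient, key) pairs
(26 prior-study + 11 window-confirmed) recur in tumor and both plasma call
sets, giving 172 tumor somatic. The 0.5%-floor plasma set has 237
survivors (43/39/5/150, 43 consensus) → 130 retained → 93 somatic; the
0.2%-floor set has 14280 survivors (1328/2794/1544/8614, 2104 consensus) →
7770 retained → 7733 somatic. Decoy calls (common-MAF, synonymous,
below-floor) pad each table to the published annotated totals. The lowest
fixture VAFs are chosen so the implied integer read counts still clear
their floor (e.g. 2/513 ≥ 0.2%). `scripts/acceptance.py` recomputes the
retained totals from this fixture by running the full pipeline.

## Numerical and interface choices

* Coordinates are 1-based (VCF convention) throughout.
* Percentages: exact `Decimal` division, quantized half-up to one decimal.
* Records without VAF evidence are kept and fail the VAF gate with reason
  `no_vaf` — an explicit audit row beats a silent drop.
* The canonical interchange is the documented TSV sidecar (bit-exact float
  round-trip via `repr`); VCF INFO parsing is a convenience layer, since
  annotations typically come from a third-party annotator rather than the
  caller's VCF.
* Problem sizes in the test suite: the exhaustive classifier check covers
  all 2205 annotation-state combinations; threshold monotonicity runs 50
  default cohorts; parameter recovery runs 200 replicates at each p ∈
  {0.2, 0.5, 0.8} with decoys and germline off (they do not enter
  tumor-informed concordance); generator calibration pools 200 cohorts for
  the TP53 marginal and 30 for the shedding-recovery rank test. These
  sizes give stable verdicts at desk scale.

## Known limitations

* Germline recall depends on the plasma VAF window: a true germline
  variant drawn outside [0.40, 0.60] and absent from the prior list stays
  somatic until confirmed — the confirm-then-exclude order is intentional.
* Clonality verdicts ignore VAF and rarity; they are shared-count
  heuristics, not phylogenetic inference.
* Indel identity inside repeat runs requires a reference window; without
  one, equivalent in-run spellings remain distinct keys.
* The published plasma accounting under the 0.5%-floor caller is
  internally inconsistent by two variants (43+39+5+150 = 237); the fixture
  realizes the component counts, and the retained/somatic totals follow
  from them.
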