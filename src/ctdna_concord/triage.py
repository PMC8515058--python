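"""The variant filtering and retention cascade.

Two stages, applied per sample:

1. **Prefilter** — population-frequency, synonymous and VAF gates, in that
   order, first failure recorded: variants common in 1000G/gnomAD/ExAC
   (any available AF above 1%) are presumed polymorphisms and excluded;
   synonymous variants are excluded; calls below the VAF floor of the
   sample type are excluded (tumor 5%; plasma 0.5% under the GeneGlobe
   caller, 0.2% under CLC).  The floor is inclusive (a call exactly at the
   floor passes).

2. **Classification** — first match wins: ClinVar pathogenic/likely
   pathogenic is retained; ClinVar benign/likely benign is discarded
   (outranking consequence); truncating or canonical-splice variants are
   retained; unclassified inframe indels are retained; missense variants
   are retained only on a unanimous in-silico consensus (MetaLR damaging,
   MetaSVM damaging and CADD phred at or above the cutoff); anything else
   is unclassifiable and discarded.  ClinVar VUS and conflicting
   interpretations route to the consequence-based rules.

Every input variant receives exactly one audited decision with the ordered
trace of gates evaluated.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import ConfigError
from .variant_io import (
    TRUNCATING,
    AnnotatedVariant,
    CallerMode,
    ClinVarClass,
    Consequence,
    PredictorCall,
    SampleTable,
    SampleType,
    VariantKey,
    normalize_key,
)

__all__ = [
    "TriageThresholds",
    "TriageDecision",
    "Category",
    "DiscardReason",
    "prefilter",
    "classify",
    "triage_sample",
    "TriageResult",
]


class Category(str, enum.Enum):
    CLINVAR_PATHOGENIC = "clinvar_pathogenic"
    TRUNCATING_OR_SPLICE = "truncating_or_splice"
    INFRAME_INDEL = "inframe_indel"
    MISSENSE_CONSENSUS_DAMAGING = "missense_consensus_damaging"
    NONE = "none"


class DiscardReason(str, enum.Enum):
    COMMON_MAF = "common_maf"
    SYNONYMOUS = "synonymous"
    LOW_VAF = "low_vaf"
    NO_VAF = "no_vaf"
    CLINVAR_BENIGN = "clinvar_benign"
    MISSENSE_NOT_CONSENSUS = "missense_not_consensus"
    UNCLASSIFIABLE = "unclassifiable"


RETAINED_CATEGORIES = (
    Category.CLINVAR_PATHOGENIC,
    Category.TRUNCATING_OR_SPLICE,
    Category.INFRAME_INDEL,
    Category.MISSENSE_CONSENSUS_DAMAGING,
)


@dataclass(frozen=True)
class TriageThresholds:
    """Tunable gates of the cascade (fractions in (0,1))."""

    max_pop_af: float = 0.01
    min_tumor_vaf: float = 0.05
    min_plasma_vaf_geneglobe: float = 0.005
    min_plasma_vaf_clc: float = 0.002
    cadd_phred_cutoff: float = 20.0

    def __post_init__(self) -> None:
        for name in (
            "max_pop_af",
            "min_tumor_vaf",
            "min_plasma_vaf_geneglobe",
            "min_plasma_vaf_clc",
        ):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ConfigError(f"{name} must be in (0,1), got {value}")
        if self.min_plasma_vaf_clc >= self.min_plasma_vaf_geneglobe:
            raise ConfigError(
                "min_plasma_vaf_clc must be below min_plasma_vaf_geneglobe"
            )
        if self.cadd_phred_cutoff < 0:
            raise ConfigError("cadd_phred_cutoff must be non-negative")

    def vaf_floor(self, sample_type: SampleType, caller_mode: Optional[CallerMode]) -> float:
        if sample_type == SampleType.TUMOR_FFPE:
            return self.min_tumor_vaf
        if caller_mode == CallerMode.CLC:
            return self.min_plasma_vaf_clc
        return self.min_plasma_vaf_geneglobe


@dataclass
class TriageDecision:
    """Audited verdict for one variant: retained XOR discard_reason."""

    key: VariantKey
    retained: bool
    category: Category = Category.NONE
    discard_reason: Optional[DiscardReason] = None
    stage_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.retained == (self.discard_reason is None)
        assert not self.retained or self.category != Category.NONE


def prefilter(
    variant: AnnotatedVariant,
    sample_type: SampleType,
    caller_mode: Optional[CallerMode] = None,
    thresholds: TriageThresholds = TriageThresholds(),
) -> tuple:
    """Evaluate the MAF → synonymous → VAF gates.

    Returns ``(passed, reason_or_None, trace)``.  Absent population
    frequencies never fail the MAF gate; a variant with no VAF evidence
    fails the VAF gate with its own reason (``no_vaf``).
    """
    trace = []
    mmaf = variant.mmaf
    if mmaf is not None and mmaf > thresholds.max_pop_af:
        trace.append(f"maf:fail({mmaf:g}>{thresholds.max_pop_af:g})")
        return False, DiscardReason.COMMON_MAF, trace
    trace.append("maf:pass" if mmaf is not None else "maf:pass(absent)")
    if variant.consequence == Consequence.SYNONYMOUS:
        trace.append("synonymous:fail")
        return False, DiscardReason.SYNONYMOUS, trace
    trace.append("synonymous:pass")
    floor = thresholds.vaf_floor(sample_type, caller_mode)
    if variant.vaf is None:
        trace.append("vaf:fail(absent)")
        return False, DiscardReason.NO_VAF, trace
    if variant.vaf < floor:
        trace.append(f"vaf:fail({variant.vaf:g}<{floor:g})")
        return False, DiscardReason.LOW_VAF, trace
    trace.append(f"vaf:pass(>={floor:g})")
    return True, None, trace


def classify(
    variant: AnnotatedVariant,
    thresholds: TriageThresholds = TriageThresholds(),
    trace: Optional[list] = None,
) -> TriageDecision:
    """Classify a prefilter survivor; first matching rule wins."""
    key = normalize_key(variant)
    trace = list(trace) if trace else []
    cv = variant.clinvar
    if cv in (ClinVarClass.PATHOGENIC, ClinVarClass.LIKELY_PATHOGENIC):
        trace.append("clinvar:pathogenic")
        return TriageDecision(key, True, Category.CLINVAR_PATHOGENIC, None, trace)
    if cv in (ClinVarClass.BENIGN, ClinVarClass.LIKELY_BENIGN):
        trace.append("clinvar:benign")
        return TriageDecision(
            key, False, Category.NONE, DiscardReason.CLINVAR_BENIGN, trace
        )
    trace.append("clinvar:not_classified")
    if variant.consequence in TRUNCATING:
        trace.append(f"consequence:{variant.consequence.value}")
        return TriageDecision(key, True, Category.TRUNCATING_OR_SPLICE, None, trace)
    if variant.consequence == Consequence.INFRAME_INDEL:
        trace.append("consequence:inframe_indel")
        return TriageDecision(key, True, Category.INFRAME_INDEL, None, trace)
    if variant.consequence == Consequence.MISSENSE:
        absent = [
            name
            for name, call in (("metalr", variant.metalr), ("metasvm", variant.metasvm))
            if call == PredictorCall.ABSENT
        ]
        if variant.cadd_phred is None:
            absent.append("cadd")
        if absent:
            trace.append("missense:predictor_absent(" + ",".join(absent) + ")")
            return TriageDecision(
                key, False, Category.NONE, DiscardReason.MISSENSE_NOT_CONSENSUS, trace
            )
        consensus = (
            variant.metalr == PredictorCall.DAMAGING
            and variant.metasvm == PredictorCall.DAMAGING
            and variant.cadd_phred >= thresholds.cadd_phred_cutoff
        )
        trace.append(
            "missense:consensus_damaging" if consensus else "missense:not_consensus"
        )
        if consensus:
            return TriageDecision(
                key, True, Category.MISSENSE_CONSENSUS_DAMAGING, None, trace
            )
        return TriageDecision(
            key, False, Category.NONE, DiscardReason.MISSENSE_NOT_CONSENSUS, trace
        )
    trace.append(f"consequence:{variant.consequence.value}:unclassifiable")
    return TriageDecision(key, False, Category.NONE, DiscardReason.UNCLASSIFIABLE, trace)


def decide(
    variant: AnnotatedVariant,
    sample_type: SampleType,
    caller_mode: Optional[CallerMode] = None,
    thresholds: TriageThresholds = TriageThresholds(),
) -> TriageDecision:
    """Full per-variant decision: prefilter then classification."""
    passed, reason, trace = prefilter(variant, sample_type, caller_mode, thresholds)
    if not passed:
        return TriageDecision(
            normalize_key(variant), False, Category.NONE, reason, trace
        )
    return classify(variant, thresholds, trace)


@dataclass
class TriageResult:
    """Per-sample triage output: retained calls, counts and the audit trail."""

    sample_id: str
    patient_id: str
    sample_type: SampleType
    caller_mode: Optional[CallerMode]
    qc_fail: bool
    decisions: list  # (AnnotatedVariant, TriageDecision) per input row
    retained: list  # AnnotatedVariant

    @property
    def category_counts(self) -> Counter:
        return Counter(
            d.category for _, d in self.decisions if d.retained
        )

    @property
    def discard_counts(self) -> Counter:
        return Counter(
            d.discard_reason for _, d in self.decisions if not d.retained
        )

    @property
    def n_prefilter_pass(self) -> int:
        prefilter_reasons = {
            DiscardReason.COMMON_MAF,
            DiscardReason.SYNONYMOUS,
            DiscardReason.LOW_VAF,
            DiscardReason.NO_VAF,
        }
        return sum(
            1
            for _, d in self.decisions
            if d.retained or d.discard_reason not in prefilter_reasons
        )


def triage_sample(
    table: SampleTable, thresholds: TriageThresholds = TriageThresholds()
) -> TriageResult:
    """Run the cascade on one sample.

    A QC-failing table yields an empty, flagged result.  Category counts
    always sum to the retained count and, with the discard counts, account
    for every input row.
    """
    if not table.qc_pass:
        return TriageResult(
            table.sample_id,
            table.patient_id,
            table.sample_type,
            table.caller_mode,
            qc_fail=True,
            decisions=[],
            retained=[],
        )
    decisions = []
    retained = []
    for variant in table.variants:
        decision = decide(variant, table.sample_type, table.caller_mode, thresholds)
        decisions.append((variant, decision))
        if decision.retained:
            retained.append(variant)
    return TriageResult(
        table.sample_id,
        table.patient_id,
        table.sample_type,
        table.caller_mode,
        qc_fail=False,
        decisions=decisions,
        retained=retained,
    )


def audit_rows(result: TriageResult) -> list:
    """Flatten a triage result into audit-table rows (dicts)."""
    rows = []
    for variant, decision in result.decisions:
        rows.append(
            {
                "patient_id": result.patient_id,
                "sample_id": result.sample_id,
                "sample_type": result.sample_type.value,
                "caller_mode": result.caller_mode.value if result.caller_mode else "",
                "chrom": decision.key.chrom,
                "pos": decision.key.pos,
                "ref": decision.key.ref or "-",
                "alt": decision.key.alt or "-",
                "gene": variant.gene or "",
                "consequence": variant.consequence.value,
                "vaf": "" if variant.vaf is None else repr(variant.vaf),
                "decision": "retained" if decision.retained else "discarded",
                "category": decision.category.value,
                "reason": decision.discard_reason.value if decision.discard_reason else "",
                "trace": "|".join(decision.stage_trace),
            }
        )
    return rows
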