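"""Tumor-plasma concordance, VAF hierarchy, gene spectrum, outcome split.

Tumor-informed concordance asks, per patient: was at least one somatic
variant retained in the tumor sample also detected in the matched plasma?
Patients without any tumor somatic variant have no target set and are
excluded from denominators.  Percentages are reported to one decimal
(half-up) and every percentage is recomputable from its printed counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd
from scipy import stats

from .variant_io import (
    FigoStage,
    Group,
    Histology,
    Outcome,
    Timing,
    VariantKey,
)

__all__ = [
    "SomaticCall",
    "PatientRecord",
    "ConcordanceSummary",
    "SharedVariant",
    "shared_variants",
    "concordance_by",
    "vaf_hierarchy_concordant",
    "gene_spectrum",
    "outcome_split",
    "round_pct",
]

STRATIFIERS = ("overall", "group", "figo_stage", "timing")


class SomaticCall(NamedTuple):
    key: VariantKey
    vaf: Optional[float]
    gene: Optional[str] = None


class SharedVariant(NamedTuple):
    key: VariantKey
    vaf_tumor: Optional[float]
    vaf_plasma: Optional[float]
    gene: Optional[str] = None


@dataclass
class PatientRecord:
    """Paired tumor/plasma somatic variant sets plus clinical strata."""

    patient_id: str
    group: Group
    timing: Timing
    figo_stage: FigoStage
    histology: Histology
    tumor_somatic: list  # SomaticCall
    plasma_somatic: list  # SomaticCall
    outcome: Outcome = Outcome.UNKNOWN
    tumor_qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.group == Group.TREATMENT_NAIVE and self.timing != Timing.DIAGNOSIS:
            raise ValueError(
                f"patient {self.patient_id}: treatment-naive implies sampling "
                "at diagnosis"
            )

    @property
    def eligible(self) -> bool:
        """Has a tumor-informed target set (>= 1 tumor somatic variant)."""
        return len(self.tumor_somatic) > 0


@dataclass
class ConcordanceSummary:
    stratifier: str
    stratum: str
    n_eligible: int
    n_concordant: int
    percentage: Optional[float]  # None when n_eligible == 0 (reported NA)
    shared_sets: dict = field(default_factory=dict)  # patient_id -> [SharedVariant]


def round_pct(n: int, d: int) -> Optional[float]:
    """100*n/d to one decimal, half-up; None for an empty denominator."""
    if d == 0:
        return None
    return float(
        (Decimal(100 * n) / Decimal(d)).quantize(Decimal("0.1"), ROUND_HALF_UP)
    )


def shared_variants(patient: PatientRecord) -> list:
    """Exact key intersection of tumor and plasma somatic sets.

    Ordered by descending tumor VAF; each entry pairs the tumor and plasma
    VAFs of the shared variant.
    """
    plasma = {c.key: c for c in patient.plasma_somatic}
    out = []
    seen = set()
    for call in patient.tumor_somatic:
        if call.key in plasma and call.key not in seen:
            seen.add(call.key)
            out.append(
                SharedVariant(
                    call.key, call.vaf, plasma[call.key].vaf, call.gene
                )
            )
    out.sort(key=lambda s: (-(s.vaf_tumor if s.vaf_tumor is not None else -1.0),
                            s.key))
    return out


def _stratum_of(patient: PatientRecord, stratifier: str) -> str:
    if stratifier == "overall":
        return "overall"
    if stratifier == "group":
        return patient.group.value
    if stratifier == "figo_stage":
        return patient.figo_stage.value
    if stratifier == "timing":
        return patient.timing.value
    raise ValueError(f"unknown stratifier {stratifier!r}; use one of {STRATIFIERS}")


def _levels(stratifier: str) -> list:
    try:
        return {
            "overall": ["overall"],
            "group": [g.value for g in Group],
            "figo_stage": [s.value for s in FigoStage],
            "timing": [t.value for t in Timing],
        }[stratifier]
    except KeyError:
        raise ValueError(
            f"unknown stratifier {stratifier!r}; use one of {STRATIFIERS}"
        ) from None


def concordance_by(
    cohort: Sequence[PatientRecord], stratifier: str = "overall"
) -> list:
    """Stratified tumor-informed concordance summaries.

    One summary per stratum level (empty strata included with NA
    percentage); denominators are eligible patients only, so stratum counts
    always sum to the overall counts.
    """
    summaries = []
    for level in _levels(stratifier):
        members = [
            p for p in cohort if p.eligible and _stratum_of(p, stratifier) == level
        ]
        shared_sets = {p.patient_id: shared_variants(p) for p in members}
        n_conc = sum(1 for s in shared_sets.values() if s)
        summaries.append(
            ConcordanceSummary(
                stratifier=stratifier,
                stratum=level,
                n_eligible=len(members),
                n_concordant=n_conc,
                percentage=round_pct(n_conc, len(members)),
                shared_sets=shared_sets,
            )
        )
    return summaries


@dataclass
class HierarchyResult:
    applicable: bool
    concordant: Optional[bool] = None
    tau: Optional[float] = None


def vaf_hierarchy_concordant(shared: Sequence[SharedVariant]) -> HierarchyResult:
    """Do tumor and plasma rank the shared variants identically?

    Requires >= 2 shared variants with both VAFs present; concordance is
    strict rank-order agreement (ties break it), with Kendall's tau as the
    quantitative companion.
    """
    pairs = [
        (s.vaf_tumor, s.vaf_plasma)
        for s in shared
        if s.vaf_tumor is not None and s.vaf_plasma is not None
    ]
    if len(pairs) < 2:
        return HierarchyResult(applicable=False)
    tumor = [p[0] for p in pairs]
    plasma = [p[1] for p in pairs]
    order_t = sorted(range(len(pairs)), key=lambda i: -tumor[i])
    order_p = sorted(range(len(pairs)), key=lambda i: -plasma[i])
    no_ties = len(set(tumor)) == len(tumor) and len(set(plasma)) == len(plasma)
    concordant = no_ties and order_t == order_p
    tau = float(stats.kendalltau(tumor, plasma).statistic)
    return HierarchyResult(applicable=True, concordant=concordant, tau=tau)


def gene_spectrum(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Per-gene tumor mutation spectrum over QC-passing tumor samples.

    A sample counts once per gene regardless of variant multiplicity; the
    fraction's denominator is the QC-passing tumor sample count and is
    reported exactly (no rounding).
    """
    denom = sum(1 for p in cohort if p.tumor_qc_pass)
    counts: dict = {}
    for p in cohort:
        if not p.tumor_qc_pass:
            continue
        for gene in {c.gene for c in p.tumor_somatic if c.gene}:
            counts[gene] = counts.get(gene, 0) + 1
    rows = [
        {
            "gene": gene,
            "n_mutated_samples": n,
            "fraction": (n / denom) if denom else float("nan"),
        }
        for gene, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["gene", "n_mutated_samples", "fraction"])


def outcome_split(
    cohort: Sequence[PatientRecord], timing: Timing = Timing.POST_SURGERY_PRE_CHEMO
) -> pd.DataFrame:
    """Cross-tabulate ctDNA detection against clinical outcome.

    Within the given sampling-timing subgroup, a patient is ctDNA-positive
    when at least one tumor somatic variant was shared with plasma.  Pure
    cross-tabulation — no survival model is fitted.
    """
    rows = []
    for p in cohort:
        if p.timing != timing or not p.eligible:
            continue
        positive = bool(shared_variants(p))
        rows.append(
            {
                "ctdna": "positive" if positive else "negative",
                "outcome": p.outcome.value,
            }
        )
    index = pd.CategoricalIndex(
        ["positive", "negative"], categories=["positive", "negative"]
    )
    columns = [o.value for o in Outcome]
    table = pd.DataFrame(0, index=index, columns=columns)
    for row in rows:
        table.loc[row["ctdna"], row["outcome"]] += 1
    table.index.name = "ctdna"
    return table


def concordance_frame(summaries: Iterable[ConcordanceSummary]) -> pd.DataFrame:
    """Tabular view of summaries (stratifier, stratum, counts, pct)."""
    return pd.DataFrame(
        [
            {
                "stratifier": s.stratifier,
                "stratum": s.stratum,
                "n_eligible": s.n_eligible,
                "n_concordant": s.n_concordant,
                "percentage": "NA" if s.percentage is None else s.percentage,
            }
            for s in summaries
        ]
    )
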