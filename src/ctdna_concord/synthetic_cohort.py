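"""Synthetic paired tumor/plasma cohorts with ground-truth labels.

The generator emulates the statistical structure the analysis assumes, at
the called-variant level (no reads are simulated):

* a cohort of ovarian-cancer patients split into treatment-naive and
  post-treatment groups, with FIGO stage and histology mixes allocated
  exactly to the configured fractions (largest-remainder, then shuffled);
* per-gene independent Bernoulli tumor mutation, driven by a 27-gene panel
  frequency table headed by *TP53*;
* tumor VAFs from a truncated Beta on [0.05, 0.95], observed through
  binomial sampling at the tumor UMI depth;
* a ctDNA shedding model: the plasma VAF of a tumor variant is the tumor
  VAF attenuated by a per-patient ctDNA fraction drawn log-normally around
  a stage-dependent median, multiplied down for post-treatment patients;
  plasma alt reads are binomial at the plasma UMI depth and a call enters
  the plasma table only if at least one consensus read supports it and the
  implied VAF clears the caller noise floor (set *below* the analysis
  thresholds, so sensitivity is governed by the triage floors);
* heterozygous germline variants at ~50% VAF in both samples, split into a
  prior-study list and a plasma-window-discoverable remainder;
* annotation decoys (common polymorphisms, synonymous calls, ClinVar
  benign records, non-consensus missense) that the triage cascade must
  discard.

Every distributional choice is a default of :class:`SimulationConfig`, not
a claim about any real cohort.  A fixed seed makes the output
bit-reproducible.

The module also ships :func:`build_reference_fixture`, a deterministic
(RNG-free) cohort whose annotation-category composition matches a
published variant-accounting benchmark, so the whole cascade can be
checked against exact expected totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .errors import ConfigError, InputError
from .germline import GermlineEvidence, GermlineSource, write_germline_list
from .variant_io import (
    AnnotatedVariant,
    CallerMode,
    ClinVarClass,
    Consequence,
    FigoStage,
    Group,
    Histology,
    ManifestEntry,
    Outcome,
    PredictorCall,
    SampleTable,
    SampleType,
    Timing,
    normalize_key,
    write_manifest,
    write_variant_table,
)

__all__ = [
    "PANEL_GENES",
    "DEFAULT_GENE_FREQUENCY",
    "SimulationConfig",
    "SimulatedPatient",
    "SimulatedCohort",
    "simulate_patient",
    "simulate_cohort",
    "write_cohort",
    "build_reference_fixture",
    "ReferenceFixture",
]


# ---------------------------------------------------------------------------
# Panel definition

#: 27-gene ovarian-cancer panel with rough per-gene loci for locus realism.
PANEL_GENES: Dict[str, Tuple[str, int]] = {
    "TP53": ("chr17", 7_570_000),
    "BRCA1": ("chr17", 43_040_000),
    "ARID1A": ("chr1", 26_690_000),
    "KRAS": ("chr12", 25_200_000),
    "PIK3CA": ("chr3", 178_860_000),
    "PTEN": ("chr10", 87_860_000),
    "RB1": ("chr13", 48_300_000),
    "BRCA2": ("chr13", 32_310_000),
    "ATM": ("chr11", 108_220_000),
    "ATR": ("chr3", 142_440_000),
    "MSH6": ("chr2", 47_780_000),
    "CTNNB1": ("chr3", 41_190_000),
    "NF1": ("chr17", 31_090_000),
    "CDK12": ("chr17", 39_460_000),
    "FBXW7": ("chr4", 152_320_000),
    "PPP2R1A": ("chr19", 52_190_000),
    "CHEK2": ("chr22", 28_680_000),
    "PALB2": ("chr16", 23_600_000),
    "RAD51C": ("chr17", 58_690_000),
    "RAD51D": ("chr17", 35_100_000),
    "BRIP1": ("chr17", 61_680_000),
    "MLH1": ("chr3", 36_990_000),
    "MSH2": ("chr2", 47_400_000),
    "PMS2": ("chr7", 5_970_000),
    "SMARCA4": ("chr19", 10_960_000),
    "ERBB2": ("chr17", 39_680_000),
    "STK11": ("chr19", 1_200_000),
}

_HEAD_FREQ = {
    "TP53": 0.78,
    "BRCA1": 0.096,
    "ARID1A": 0.096,
    "KRAS": 0.096,
    "PIK3CA": 0.085,
    "PTEN": 0.064,
    "RB1": 0.064,
    "BRCA2": 0.053,
    "ATM": 0.053,
    "ATR": 0.053,
    "MSH6": 0.053,
}

#: Per-gene probability that a tumor carries >=1 somatic variant.
DEFAULT_GENE_FREQUENCY: Dict[str, float] = {
    gene: _HEAD_FREQ.get(gene, 0.02) for gene in PANEL_GENES
}

_DEFAULT_STAGE_DIST = {"I": 0.146, "II": 0.073, "III": 0.573, "IV": 0.208}
_DEFAULT_HISTOLOGY_DIST = {
    "high_grade_serous": 0.719,
    "low_grade_serous": 0.083,
    "clear_cell": 0.063,
    "endometrioid": 0.073,
    "mucinous": 0.010,
    "mixed": 0.031,
    "carcinosarcoma": 0.021,
}
# Within the post-treatment group: after surgery pre-chemo, at recurrence,
# at progression on treatment, otherwise on chemotherapy (7/12/6/48 of 73).
_DEFAULT_TIMING_DIST = {
    "post_surgery_pre_chemo": 7 / 73,
    "recurrence": 12 / 73,
    "progression": 6 / 73,
    "on_chemo": 48 / 73,
}
_DEFAULT_CTDNA_MEDIAN = {"I": 0.001, "II": 0.003, "III": 0.01, "IV": 0.03}
_DEFAULT_DECOY_RATES = {
    "common_maf": 12.0,
    "synonymous": 6.0,
    "benign": 2.0,
    "missense_nonconsensus": 5.0,
}


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic cohort (with ground truth).

    The defaults encode the cohort conditions the analysis is designed
    for: 96 patients (24% treatment-naive), the stated stage and histology
    mixes, UMI depths of 1276 (tumor) and 513 (plasma), 37 germline
    variants of which 26 come from a prior study, and a shedding model
    whose stage medians and post-treatment attenuation set plasma
    detectability.
    """

    n_patients: int = 96
    group_fractions: Dict[str, float] = field(
        default_factory=lambda: {"treatment_naive": 0.24, "post_treatment": 0.76}
    )
    stage_distribution: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_STAGE_DIST)
    )
    histology_distribution: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_HISTOLOGY_DIST)
    )
    timing_distribution: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_TIMING_DIST)
    )
    gene_frequency: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_FREQUENCY)
    )
    tumor_vaf_alpha: float = 2.0
    tumor_vaf_beta: float = 2.0
    tumor_vaf_bounds: Tuple[float, float] = (0.05, 0.95)
    ctdna_stage_median: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CTDNA_MEDIAN)
    )
    ctdna_sigma_log: float = 1.0
    post_treatment_multiplier: float = 0.1
    tumor_depth: int = 1276
    plasma_depth: int = 513
    n_germline_total: int = 37
    n_germline_prior: int = 26
    germline_vaf_mean: float = 0.5
    germline_vaf_sd: float = 0.03
    decoy_rates: Dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DECOY_RATES)
    )
    plasma_noise_floor: float = 0.001
    qc_fail_rate: float = 2 / 96
    patient_detection_probability: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be non-negative")
        for name, dist in (
            ("group_fractions", self.group_fractions),
            ("stage_distribution", self.stage_distribution),
            ("histology_distribution", self.histology_distribution),
            ("timing_distribution", self.timing_distribution),
        ):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-6:
                raise ConfigError(f"{name} must sum to 1, got {total}")
            if any(v < 0 for v in dist.values()):
                raise ConfigError(f"{name} has negative entries")
        for gene, freq in self.gene_frequency.items():
            if gene not in PANEL_GENES:
                raise ConfigError(f"gene {gene} not on the panel")
            if not 0.0 <= freq <= 1.0:
                raise ConfigError(f"gene frequency {freq} outside [0,1]")
        if self.tumor_depth <= 0 or self.plasma_depth <= 0:
            raise ConfigError("depths must be positive")
        if not 0 <= self.n_germline_prior <= self.n_germline_total:
            raise ConfigError("n_germline_prior must be within n_germline_total")
        if self.n_patients and self.n_germline_total > len(PANEL_GENES) * self.n_patients:
            raise ConfigError("n_germline_total exceeds panel capacity")
        if not 0.0 <= self.qc_fail_rate < 1.0:
            raise ConfigError("qc_fail_rate must be in [0,1)")
        if self.plasma_noise_floor >= 0.002:
            raise ConfigError(
                "plasma_noise_floor must stay below the analysis VAF floors"
            )
        if self.patient_detection_probability is not None and not (
            0.0 <= self.patient_detection_probability <= 1.0
        ):
            raise ConfigError("patient_detection_probability outside [0,1]")


# ---------------------------------------------------------------------------
# Allocation helpers

def _allocate(fractions: Dict[str, float], n: int) -> Dict[str, int]:
    """Largest-remainder allocation of n units to the given fractions."""
    raw = {k: f * n for k, f in fractions.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: (raw[k] - counts[k], k), reverse=True)[:short]:
        counts[k] += 1
    return counts


def _allocated_labels(fractions: Dict[str, float], n: int, rng) -> List[str]:
    labels: List[str] = []
    for k, c in _allocate(fractions, n).items():
        labels.extend([k] * c)
    rng.shuffle(labels)
    return labels


class _PositionAllocator:
    """Unique, deterministic per-gene positions (spaced to avoid collisions)."""

    def __init__(self) -> None:
        self._next: Dict[str, int] = {}

    def take(self, gene: str) -> Tuple[str, int]:
        chrom, base = PANEL_GENES[gene]
        offset = self._next.get(gene, 0)
        self._next[gene] = offset + 1
        return chrom, base + 10 * offset


_BASES = "ACGT"


def _alleles(rng, consequence: Consequence) -> Tuple[str, str]:
    i = int(rng.integers(4))
    ref = _BASES[i]
    if consequence == Consequence.INFRAME_INDEL:
        ins = "".join(_BASES[int(rng.integers(4))] for _ in range(3))
        return ref, ref + ins
    if consequence == Consequence.FRAMESHIFT:
        if rng.random() < 0.5:
            return ref, ref + _BASES[int(rng.integers(4))]
        return ref + _BASES[int(rng.integers(4))], ref
    alt = _BASES[(i + 1 + int(rng.integers(3))) % 4]
    return ref, alt


def _truncated_beta(rng, a: float, b: float, lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.beta(a, b)
        if lo <= x <= hi:
            return float(x)
    return float(lo)


_SOMATIC_CATEGORIES = ("clinvar_plp", "truncating", "inframe", "missense_consensus")
_SOMATIC_CATEGORY_P = (0.47, 0.20, 0.04, 0.29)


def _pick(rng, options, p=None):
    return options[int(rng.choice(len(options), p=p))]


def _annotate_somatic(rng, category: str) -> dict:
    """Annotation fields guaranteeing retention under default thresholds."""
    if category == "clinvar_plp":
        consequence = _pick(
            rng,
            [Consequence.MISSENSE, Consequence.FRAMESHIFT, Consequence.NONSENSE],
            p=[0.5, 0.3, 0.2],
        )
        clinvar = (
            ClinVarClass.PATHOGENIC
            if rng.random() < 0.6
            else ClinVarClass.LIKELY_PATHOGENIC
        )
        return {"consequence": consequence, "clinvar": clinvar}
    if category == "truncating":
        consequence = _pick(
            rng,
            [Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.CANONICAL_SPLICE],
            p=[0.4, 0.4, 0.2],
        )
        return {
            "consequence": consequence,
            "clinvar": ClinVarClass.NOT_IN_CLINVAR,
        }
    if category == "inframe":
        return {
            "consequence": Consequence.INFRAME_INDEL,
            "clinvar": ClinVarClass.NOT_IN_CLINVAR
            if rng.random() < 0.5
            else ClinVarClass.VUS,
        }
    return {
        "consequence": Consequence.MISSENSE,
        "clinvar": ClinVarClass.VUS
        if rng.random() < 0.6
        else ClinVarClass.NOT_IN_CLINVAR,
        "metalr": PredictorCall.DAMAGING,
        "metasvm": PredictorCall.DAMAGING,
        "cadd_phred": float(rng.uniform(21.0, 35.0)),
    }


def _annotate_decoy(rng, kind: str) -> dict:
    if kind == "common_maf":
        af = float(rng.uniform(0.02, 0.5))
        sources = ["thousand_genomes", "gnomad", "exac"]
        pop_af = {s: af for s in rng.choice(sources, size=int(rng.integers(1, 4)), replace=False)}
        return {
            "consequence": Consequence.MISSENSE,
            "clinvar": ClinVarClass.NOT_IN_CLINVAR,
            "pop_af": pop_af,
        }
    if kind == "synonymous":
        return {
            "consequence": Consequence.SYNONYMOUS,
            "clinvar": ClinVarClass.NOT_IN_CLINVAR,
            "pop_af": {"gnomad": float(rng.uniform(0.0, 0.009))},
        }
    if kind == "benign":
        consequence = _pick(rng, [Consequence.MISSENSE, Consequence.NONSENSE], p=[0.8, 0.2])
        clinvar = (
            ClinVarClass.BENIGN if rng.random() < 0.5 else ClinVarClass.LIKELY_BENIGN
        )
        return {"consequence": consequence, "clinvar": clinvar}
    # non-consensus missense: at least one predictor dissents or is absent
    mode = int(rng.integers(4))
    metalr = PredictorCall.TOLERATED if mode == 0 else PredictorCall.DAMAGING
    metasvm = PredictorCall.TOLERATED if mode == 1 else PredictorCall.DAMAGING
    if mode == 3:
        metalr = PredictorCall.ABSENT
    cadd = float(rng.uniform(1.0, 15.0)) if mode == 2 else float(rng.uniform(21.0, 35.0))
    return {
        "consequence": Consequence.MISSENSE,
        "clinvar": ClinVarClass.VUS,
        "metalr": metalr,
        "metasvm": metasvm,
        "cadd_phred": cadd,
    }


# ---------------------------------------------------------------------------
# Patient-level simulation

@dataclass
class SimulatedPatient:
    patient_id: str
    group: Group
    timing: Timing
    figo_stage: FigoStage
    histology: Histology
    outcome: Outcome
    ctdna_fraction: float
    tumor_table: SampleTable
    plasma_table: SampleTable
    germline: List[GermlineEvidence]  # ground-truth germline of this patient
    truth: List[dict]


def _observe(rng, depth: int, true_vaf: float) -> Tuple[int, float]:
    alt = int(rng.binomial(depth, min(true_vaf, 1.0)))
    return alt, alt / depth


def simulate_patient(
    config: SimulationConfig,
    rng,
    patient_id: str = "SIM001",
    group: Group = Group.TREATMENT_NAIVE,
    timing: Timing = Timing.DIAGNOSIS,
    figo_stage: FigoStage = FigoStage.III,
    histology: Histology = Histology.HIGH_GRADE_SEROUS,
    n_germline: int = 0,
    n_germline_prior: int = 0,
    tumor_qc_pass: bool = True,
    positions: Optional[_PositionAllocator] = None,
) -> SimulatedPatient:
    """Simulate one patient's paired tumor and plasma call tables.

    Tumor somatic variants are drawn per gene frequency; each receives a
    true tumor VAF and, through the shedding model, a true plasma VAF.
    Observed calls apply binomial read sampling at the configured depths.
    Ground-truth labels (role, true VAFs, detectability) ride along in
    ``truth``.
    """
    positions = positions or _PositionAllocator()
    stage_key = figo_stage.value
    median = config.ctdna_stage_median[stage_key]
    if group == Group.POST_TREATMENT:
        median *= config.post_treatment_multiplier
    ctdna_fraction = min(
        1.0, float(median * math.exp(config.ctdna_sigma_log * rng.normal()))
    )

    tumor_variants: List[AnnotatedVariant] = []
    plasma_variants: List[AnnotatedVariant] = []
    truth: List[dict] = []
    germline_records: List[GermlineEvidence] = []

    lo, hi = config.tumor_vaf_bounds
    somatic_pool: List[dict] = []
    for gene in PANEL_GENES:
        freq = config.gene_frequency.get(gene, 0.0)
        if rng.random() >= freq:
            continue
        category = _pick(rng, _SOMATIC_CATEGORIES, p=list(_SOMATIC_CATEGORY_P))
        ann = _annotate_somatic(rng, category)
        chrom, pos = positions.take(gene)
        ref, alt = _alleles(rng, ann["consequence"])
        true_tumor_vaf = _truncated_beta(
            rng, config.tumor_vaf_alpha, config.tumor_vaf_beta, lo, hi
        )
        alt_reads, called_vaf = _observe(rng, config.tumor_depth, true_tumor_vaf)
        variant = AnnotatedVariant(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            gene=gene,
            vaf=called_vaf,
            alt_reads=alt_reads,
            depth=config.tumor_depth,
            **ann,
        )
        if alt_reads >= 1:
            tumor_variants.append(variant)
        somatic_pool.append(
            {
                "variant": variant,
                "true_tumor_vaf": true_tumor_vaf,
                "tumor_called_vaf": called_vaf,
                "category": category,
            }
        )

    if config.patient_detection_probability is None:
        for item in somatic_pool:
            variant = item["variant"]
            true_plasma_vaf = item["true_tumor_vaf"] * ctdna_fraction
            alt_reads, called_vaf = _observe(rng, config.plasma_depth, true_plasma_vaf)
            detected = alt_reads >= 1 and called_vaf >= config.plasma_noise_floor
            if detected:
                plasma_variants.append(
                    replace(
                        variant,
                        vaf=called_vaf,
                        alt_reads=alt_reads,
                        depth=config.plasma_depth,
                        pop_af=dict(variant.pop_af),
                        flags=[],
                    )
                )
            truth.append(
                {
                    "patient_id": patient_id,
                    "role": "somatic",
                    "gene": variant.gene,
                    "key": normalize_key(variant),
                    "true_tumor_vaf": item["true_tumor_vaf"],
                    "true_plasma_vaf": true_plasma_vaf,
                    "plasma_detected": detected,
                    "plasma_called_vaf": called_vaf if detected else None,
                }
            )
    else:
        # Calibration mode: patient-level detection coin; one tumor-retained
        # variant is copied into plasma at a fixed detectable VAF.
        p = config.patient_detection_probability
        detectable = [
            item
            for item in somatic_pool
            if item["variant"] in tumor_variants
            and item["tumor_called_vaf"] >= config.tumor_vaf_bounds[0]
        ]
        hit = bool(detectable) and rng.random() < p
        chosen = detectable[0]["variant"] if hit else None
        for item in somatic_pool:
            variant = item["variant"]
            detected = variant is chosen
            if detected:
                alt_reads = max(1, round(0.03 * config.plasma_depth))
                plasma_variants.append(
                    replace(
                        variant,
                        vaf=alt_reads / config.plasma_depth,
                        alt_reads=alt_reads,
                        depth=config.plasma_depth,
                        pop_af=dict(variant.pop_af),
                        flags=[],
                    )
                )
            truth.append(
                {
                    "patient_id": patient_id,
                    "role": "somatic",
                    "gene": variant.gene,
                    "key": normalize_key(variant),
                    "true_tumor_vaf": item["true_tumor_vaf"],
                    "true_plasma_vaf": None,
                    "plasma_detected": detected,
                    "plasma_called_vaf": None,
                }
            )

    # Germline variants: ~50% VAF in both tumor and plasma.
    for g_idx in range(n_germline):
        gene = str(
            rng.choice(["BRCA1", "BRCA2", "ATM", "CHEK2", "PALB2", "RAD51C", "MSH6"])
        )
        chrom, pos = positions.take(gene)
        consequence = Consequence.FRAMESHIFT if rng.random() < 0.5 else Consequence.MISSENSE
        ref, alt = _alleles(rng, consequence)
        clinvar = ClinVarClass.PATHOGENIC
        true_vaf_t = float(
            np.clip(rng.normal(config.germline_vaf_mean, config.germline_vaf_sd), 0.3, 0.7)
        )
        true_vaf_p = float(
            np.clip(rng.normal(config.germline_vaf_mean, config.germline_vaf_sd), 0.3, 0.7)
        )
        alt_t, vaf_t = _observe(rng, config.tumor_depth, true_vaf_t)
        alt_p, vaf_p = _observe(rng, config.plasma_depth, true_vaf_p)
        base = AnnotatedVariant(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            gene=gene,
            consequence=consequence,
            clinvar=clinvar,
            vaf=vaf_t,
            alt_reads=alt_t,
            depth=config.tumor_depth,
        )
        tumor_variants.append(base)
        plasma_variants.append(
            replace(base, vaf=vaf_p, alt_reads=alt_p, depth=config.plasma_depth,
                    pop_af={}, flags=[])
        )
        prior = g_idx < n_germline_prior
        germline_records.append(
            GermlineEvidence(
                key=normalize_key(base),
                patient_id=patient_id,
                source=GermlineSource.PRIOR_STUDY
                if prior
                else GermlineSource.PLASMA_VAF_WINDOW,
                confirmed=True,
                vaf_plasma=vaf_p,
                gene=gene,
            )
        )
        truth.append(
            {
                "patient_id": patient_id,
                "role": "germline_prior" if prior else "germline_window",
                "gene": gene,
                "key": normalize_key(base),
                "true_tumor_vaf": true_vaf_t,
                "true_plasma_vaf": true_vaf_p,
                "plasma_detected": True,
                "plasma_called_vaf": vaf_p,
            }
        )

    # Decoys, injected into both sample tables with independent draws.
    for kind, rate in config.decoy_rates.items():
        for sample_kind in ("tumor", "plasma"):
            for _ in range(int(rng.poisson(rate))):
                ann = _annotate_decoy(rng, kind)
                gene = str(rng.choice(list(PANEL_GENES)))
                chrom, pos = positions.take(gene)
                ref, alt = _alleles(rng, ann["consequence"])
                depth = (
                    config.tumor_depth if sample_kind == "tumor" else config.plasma_depth
                )
                vaf = float(rng.uniform(0.06, 0.5)) if sample_kind == "tumor" else float(
                    rng.uniform(0.006, 0.05)
                )
                alt_reads = max(1, int(round(vaf * depth)))
                variant = AnnotatedVariant(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    vaf=alt_reads / depth,
                    alt_reads=alt_reads,
                    depth=depth,
                    **ann,
                )
                (tumor_variants if sample_kind == "tumor" else plasma_variants).append(
                    variant
                )
                truth.append(
                    {
                        "patient_id": patient_id,
                        "role": f"decoy_{kind}",
                        "gene": gene,
                        "key": normalize_key(variant),
                        "true_tumor_vaf": None,
                        "true_plasma_vaf": None,
                        "plasma_detected": sample_kind == "plasma",
                        "plasma_called_vaf": None,
                    }
                )

    any_detected = any(
        t["role"] == "somatic" and t["plasma_detected"] for t in truth
    )
    if timing == Timing.POST_SURGERY_PRE_CHEMO:
        outcome = Outcome.RELAPSED if any_detected else Outcome.DISEASE_FREE
    else:
        outcome = Outcome.UNKNOWN

    tumor_table = SampleTable(
        sample_id=f"{patient_id}-T",
        patient_id=patient_id,
        sample_type=SampleType.TUMOR_FFPE,
        caller_mode=CallerMode.GENEGLOBE,
        variants=tumor_variants,
        mean_depth=config.tumor_depth,
        qc_pass=tumor_qc_pass,
    )
    plasma_table = SampleTable(
        sample_id=f"{patient_id}-P",
        patient_id=patient_id,
        sample_type=SampleType.PLASMA,
        caller_mode=CallerMode.CLC,
        variants=plasma_variants,
        mean_depth=config.plasma_depth,
        qc_pass=True,
    )
    return SimulatedPatient(
        patient_id=patient_id,
        group=group,
        timing=timing,
        figo_stage=figo_stage,
        histology=histology,
        outcome=outcome,
        ctdna_fraction=ctdna_fraction,
        tumor_table=tumor_table,
        plasma_table=plasma_table,
        germline=germline_records,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Cohort-level simulation

@dataclass
class SimulatedCohort:
    config: SimulationConfig
    patients: List[SimulatedPatient]

    @property
    def truth(self) -> List[dict]:
        return [row for p in self.patients for row in p.truth]

    @property
    def germline_evidence(self) -> List[GermlineEvidence]:
        return [e for p in self.patients for e in p.germline]

    @property
    def confirmed_keys(self) -> set:
        """Ground-truth confirmation oracle: (patient_id, key) pairs."""
        return {
            (e.patient_id, e.key)
            for e in self.germline_evidence
            if e.source == GermlineSource.PLASMA_VAF_WINDOW
        }

    def patient_inputs(self) -> list:
        """Pipeline-ready inputs with the truth-derived confirmation oracle."""
        from .pipeline import PatientInput

        confirmed = self.confirmed_keys
        return [
            PatientInput(
                patient_id=p.patient_id,
                group=p.group,
                timing=p.timing,
                figo_stage=p.figo_stage,
                histology=p.histology,
                tumor_table=p.tumor_table,
                plasma_table=p.plasma_table,
                outcome=p.outcome,
                prior_germline=[
                    e for e in p.germline if e.source == GermlineSource.PRIOR_STUDY
                ],
                confirmed_keys=confirmed,
            )
            for p in self.patients
        ]


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Simulate a full paired cohort under the configured conditions.

    Group, stage, histology and (for post-treatment patients) timing are
    allocated to the configured fractions exactly and shuffled; germline
    variants are spread multinomially over patients; the configured number
    of tumor samples fails QC.  Output is bit-reproducible per seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    groups = [Group(g) for g in _allocated_labels(config.group_fractions, n, rng)]
    stages = [FigoStage(s) for s in _allocated_labels(config.stage_distribution, n, rng)]
    histologies = [
        Histology(h) for h in _allocated_labels(config.histology_distribution, n, rng)
    ]
    n_post = sum(1 for g in groups if g == Group.POST_TREATMENT)
    post_timings = [
        Timing(t) for t in _allocated_labels(config.timing_distribution, n_post, rng)
    ]

    n_fail = int(round(config.qc_fail_rate * n))
    fail_idx = set(rng.choice(n, size=n_fail, replace=False).tolist()) if n_fail else set()

    germ_counts = (
        rng.multinomial(config.n_germline_total, [1 / n] * n) if n else np.array([])
    )
    # Assign prior/window status cohort-wide: the first n_germline_prior of a
    # shuffled enumeration are prior-study entries.
    germ_slots = []
    for idx in range(n):
        germ_slots.extend([idx] * int(germ_counts[idx]) if n else [])
    order = rng.permutation(len(germ_slots))
    prior_rank = {int(order[i]): i < config.n_germline_prior for i in range(len(order))}
    per_patient_prior = {idx: 0 for idx in range(n)}
    slot_no = 0
    per_patient_slots: Dict[int, List[bool]] = {idx: [] for idx in range(n)}
    for slot_no, idx in enumerate(germ_slots):
        per_patient_slots[idx].append(prior_rank[slot_no])

    positions = _PositionAllocator()
    patients = []
    post_i = 0
    for idx in range(n):
        group = groups[idx]
        if group == Group.TREATMENT_NAIVE:
            timing = Timing.DIAGNOSIS
        else:
            timing = post_timings[post_i]
            post_i += 1
        slots = per_patient_slots[idx]
        # prior slots first so simulate_patient's prefix rule applies
        slots.sort(reverse=True)
        patients.append(
            simulate_patient(
                config,
                rng,
                patient_id=f"SIM{idx + 1:03d}",
                group=group,
                timing=timing,
                figo_stage=stages[idx],
                histology=histologies[idx],
                n_germline=len(slots),
                n_germline_prior=sum(slots),
                tumor_qc_pass=idx not in fail_idx,
                positions=positions,
            )
        )
    return SimulatedCohort(config=config, patients=patients)


# ---------------------------------------------------------------------------
# On-disk layout

_TRUTH_COLUMNS = [
    "patient_id",
    "role",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "true_tumor_vaf",
    "true_plasma_vaf",
    "plasma_detected",
    "plasma_called_vaf",
]


def write_cohort(cohort: SimulatedCohort, outdir, overwrite: bool = False) -> Path:
    """Write the exact file layout the pipeline consumes.

    ``manifest.tsv`` plus per-sample annotated variant TSVs, per-patient
    prior-germline lists, the ground-truth table and the configuration.
    Refuses a non-empty output directory unless ``overwrite`` is set.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise InputError(f"output directory {outdir} is not empty (use overwrite)")
    for sub in ("tumor", "plasma", "germline"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)

    entries = []
    for p in cohort.patients:
        tumor_path = outdir / "tumor" / f"{p.patient_id}.tsv"
        plasma_path = outdir / "plasma" / f"{p.patient_id}.tsv"
        germline_path = outdir / "germline" / f"{p.patient_id}.tsv"
        write_variant_table(p.tumor_table.variants, tumor_path)
        write_variant_table(p.plasma_table.variants, plasma_path)
        write_germline_list(
            [e for e in p.germline if e.source == GermlineSource.PRIOR_STUDY],
            germline_path,
        )
        # manifest paths are relative to the manifest itself, so the cohort
        # directory stays relocatable
        entries.append(
            ManifestEntry(
                patient_id=p.patient_id,
                group=p.group,
                timing=p.timing,
                figo_stage=p.figo_stage,
                histology=p.histology,
                tumor_path=tumor_path.relative_to(outdir),
                plasma_path=plasma_path.relative_to(outdir),
                germline_list_path=germline_path.relative_to(outdir),
                outcome=p.outcome,
                tumor_qc_pass=p.tumor_table.qc_pass,
            )
        )
    write_manifest(entries, outdir / "manifest.tsv")

    import csv as _csv

    with open(outdir / "truth.tsv", "w", newline="") as fh:
        writer = _csv.DictWriter(fh, fieldnames=_TRUTH_COLUMNS, delimiter="\t")
        writer.writeheader()
        for row in cohort.truth:
            key = row["key"]
            writer.writerow(
                {
                    "patient_id": row["patient_id"],
                    "role": row["role"],
                    "gene": row["gene"] or "",
                    "chrom": key.chrom,
                    "pos": key.pos,
                    "ref": key.ref,
                    "alt": key.alt,
                    "true_tumor_vaf": ""
                    if row["true_tumor_vaf"] is None
                    else repr(row["true_tumor_vaf"]),
                    "true_plasma_vaf": ""
                    if row["true_plasma_vaf"] is None
                    else repr(row["true_plasma_vaf"]),
                    "plasma_detected": str(row["plasma_detected"]).lower(),
                    "plasma_called_vaf": ""
                    if row["plasma_called_vaf"] is None
                    else repr(row["plasma_called_vaf"]),
                }
            )

    qc_fail = [p.patient_id for p in cohort.patients if not p.tumor_table.qc_pass]
    with open(outdir / "qc_fail.txt", "w") as fh:
        fh.write("\n".join(qc_fail) + ("\n" if qc_fail else ""))

    cfg = {
        k: (dict(v) if isinstance(v, dict) else list(v) if isinstance(v, tuple) else v)
        for k, v in vars(cohort.config).items()
    }
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return outdir


# ---------------------------------------------------------------------------
# Deterministic accounting fixture

@dataclass
class ReferenceFixture:
    """Deterministic benchmark cohort with exact category composition.

    Tumor (94 QC-passing samples): 335 prefilter survivors — 99 ClinVar
    P/LP (37 of them germline), 41 truncating/splice, 8 inframe indels and
    187 missense of which exactly 61 carry the three-way damaging
    consensus — plus prefilter decoys up to 7255 annotated calls.  Plasma
    under the 0.5%-floor caller: 237 survivors (43/39/5/150, 43 consensus)
    of 3414; plasma under the 0.2%-floor caller: 14280 survivors
    (1328/2794/1544/8614, 2104 consensus) of 21232.  The same 37
    (patient, key) germline pairs — 26 prior-study, 11 discoverable by the
    plasma ~50% VAF window — recur in the tumor and both plasma call sets,
    so germline exclusion yields 172 / 93 / 7733 somatic variants.
    """

    tumor_tables: List[SampleTable]
    plasma_geneglobe: List[SampleTable]
    plasma_clc: List[SampleTable]
    prior_germline: List[GermlineEvidence]
    confirmed_keys: set  # (patient_id, VariantKey) confirmation oracle
    meta: Dict[str, dict]  # patient_id -> strata fields

    def patient_inputs(self, mode: CallerMode) -> list:
        """Pipeline-ready inputs pairing each tumor with the plasma call
        set of the requested caller mode."""
        from .pipeline import PatientInput

        plasma = (
            self.plasma_geneglobe if mode == CallerMode.GENEGLOBE else self.plasma_clc
        )
        pmap = {t.patient_id: t for t in plasma}
        return [
            PatientInput(
                patient_id=tt.patient_id,
                **self.meta[tt.patient_id],
                tumor_table=tt,
                plasma_table=pmap[tt.patient_id],
                prior_germline=[
                    e for e in self.prior_germline if e.patient_id == tt.patient_id
                ],
                confirmed_keys=self.confirmed_keys,
            )
            for tt in self.tumor_tables
        ]

    def accounting(self, mode: CallerMode) -> Dict[str, int]:
        """Run the cascade and germline resolution; return cohort totals."""
        from .pipeline import analyze_cohort

        analyses = analyze_cohort(self.patient_inputs(mode), caller_mode=mode)
        classified = {
            ClinVarClass.PATHOGENIC,
            ClinVarClass.LIKELY_PATHOGENIC,
            ClinVarClass.BENIGN,
            ClinVarClass.LIKELY_BENIGN,
        }
        plasma_unclassified = sum(
            1
            for a in analyses
            for v, d in a.plasma_result.decisions
            if (
                d.retained
                or d.discard_reason.value
                in ("clinvar_benign", "missense_not_consensus", "unclassifiable")
            )
            and v.clinvar not in classified
        )
        return {
            "tumor_prefilter_pass": sum(
                a.tumor_result.n_prefilter_pass for a in analyses
            ),
            "tumor_retained": sum(len(a.tumor_result.retained) for a in analyses),
            "tumor_somatic": sum(len(a.record.tumor_somatic) for a in analyses),
            "tumor_germline": sum(
                len(a.tumor_result.retained) - len(a.record.tumor_somatic)
                for a in analyses
            ),
            "plasma_prefilter_pass": sum(
                a.plasma_result.n_prefilter_pass for a in analyses
            ),
            "plasma_retained": sum(len(a.plasma_result.retained) for a in analyses),
            "plasma_somatic": sum(len(a.record.plasma_somatic) for a in analyses),
            "plasma_unclassified": plasma_unclassified,
        }


def _fixture_variant(
    positions: _PositionAllocator,
    gene: str,
    consequence: Consequence,
    clinvar: ClinVarClass,
    vaf: float,
    depth: int,
    metalr: PredictorCall = PredictorCall.ABSENT,
    metasvm: PredictorCall = PredictorCall.ABSENT,
    cadd: Optional[float] = None,
    pop_af: Optional[dict] = None,
) -> AnnotatedVariant:
    chrom, pos = positions.take(gene)
    if consequence == Consequence.INFRAME_INDEL:
        ref, alt = "A", "AGTC"
    elif consequence == Consequence.FRAMESHIFT:
        ref, alt = "AG", "A"
    else:
        ref, alt = "C", "T"
    alt_reads = int(round(vaf * depth))
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        clinvar=clinvar,
        vaf=alt_reads / depth if depth else vaf,
        alt_reads=alt_reads,
        depth=depth,
        metalr=metalr,
        metasvm=metasvm,
        cadd_phred=cadd,
        pop_af=pop_af or {},
    )


def _cycle(seq, i):
    return seq[i % len(seq)]


_FIXTURE_GENES = list(PANEL_GENES)


def _fixture_block(
    positions,
    count: int,
    depth: int,
    vafs: Sequence[float],
    maker,
) -> List[AnnotatedVariant]:
    return [maker(positions, i, depth, _cycle(vafs, i)) for i in range(count)]


def build_reference_fixture() -> ReferenceFixture:
    """Construct the deterministic accounting fixture (identical every call)."""
    positions = _PositionAllocator()
    n_tumor = 94
    n_plasma = 96
    tumor_depth, plasma_depth = 1276, 513

    pids = [f"OC{i + 1:02d}" for i in range(96)]
    qc_fail_pids = {"OC65", "OC85"}
    tumor_pids = [p for p in pids if p not in qc_fail_pids]

    tumor_bins: Dict[str, List[AnnotatedVariant]] = {p: [] for p in pids}
    gg_bins: Dict[str, List[AnnotatedVariant]] = {p: [] for p in pids}
    clc_bins: Dict[str, List[AnnotatedVariant]] = {p: [] for p in pids}

    # --- shared germline variants: 37 pairs, ~50% VAF everywhere -----------
    prior_germline: List[GermlineEvidence] = []
    confirmed_keys: set = set()
    germ_genes = ["BRCA1", "BRCA2", "ATM", "CHEK2", "MSH6", "PALB2", "RAD51C"]
    for i in range(37):
        pid = tumor_pids[i % len(tumor_pids)]
        gene = _cycle(germ_genes, i)
        chrom, pos = positions.take(gene)
        vaf_t = 0.48 + 0.002 * (i % 5)
        vaf_p = 0.49 + 0.002 * (i % 5)
        def _germ(depth, vaf):
            alt_reads = int(round(vaf * depth))
            return AnnotatedVariant(
                chrom=chrom, pos=pos, ref="C", alt="T", gene=gene,
                consequence=Consequence.MISSENSE,
                clinvar=ClinVarClass.PATHOGENIC,
                vaf=alt_reads / depth, alt_reads=alt_reads, depth=depth,
            )
        tumor_bins[pid].append(_germ(tumor_depth, vaf_t))
        gg_bins[pid].append(_germ(plasma_depth, vaf_p))
        clc_bins[pid].append(_germ(plasma_depth, vaf_p))
        key = normalize_key(tumor_bins[pid][-1])
        if i < 26:
            prior_germline.append(
                GermlineEvidence(
                    key=key,
                    patient_id=pid,
                    source=GermlineSource.PRIOR_STUDY,
                    confirmed=True,
                    vaf_plasma=vaf_p,
                    gene=gene,
                )
            )
        else:
            confirmed_keys.add((pid, key))

    # --- block builders -----------------------------------------------------
    def plp(positions, i, depth, vaf):
        return _fixture_variant(
            positions, _cycle(_FIXTURE_GENES, i),
            _cycle([Consequence.MISSENSE, Consequence.FRAMESHIFT, Consequence.NONSENSE], i),
            _cycle([ClinVarClass.PATHOGENIC, ClinVarClass.LIKELY_PATHOGENIC], i),
            vaf, depth,
        )

    def trunc(positions, i, depth, vaf):
        return _fixture_variant(
            positions, _cycle(_FIXTURE_GENES, i + 3),
            _cycle(
                [Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.CANONICAL_SPLICE],
                i,
            ),
            ClinVarClass.NOT_IN_CLINVAR, vaf, depth,
        )

    def inframe(positions, i, depth, vaf):
        return _fixture_variant(
            positions, _cycle(_FIXTURE_GENES, i + 5), Consequence.INFRAME_INDEL,
            _cycle([ClinVarClass.NOT_IN_CLINVAR, ClinVarClass.VUS], i), vaf, depth,
        )

    def missense_hit(positions, i, depth, vaf):
        return _fixture_variant(
            positions, _cycle(_FIXTURE_GENES, i + 7),
            Consequence.MISSENSE,
            _cycle([ClinVarClass.VUS, ClinVarClass.NOT_IN_CLINVAR, ClinVarClass.CONFLICTING], i),
            vaf, depth,
            metalr=PredictorCall.DAMAGING, metasvm=PredictorCall.DAMAGING,
            cadd=25.0 + (i % 10),
        )

    def missense_miss(positions, i, depth, vaf):
        mode = i % 4
        return _fixture_variant(
            positions, _cycle(_FIXTURE_GENES, i + 11),
            Consequence.MISSENSE,
            _cycle([ClinVarClass.VUS, ClinVarClass.NOT_IN_CLINVAR], i),
            vaf, depth,
            metalr=PredictorCall.TOLERATED if mode == 0 else (
                PredictorCall.ABSENT if mode == 3 else PredictorCall.DAMAGING),
            metasvm=PredictorCall.TOLERATED if mode == 1 else PredictorCall.DAMAGING,
            cadd=10.0 if mode == 2 else 26.0,
        )

    def decoy(positions, i, depth, vaf, low_vaf_value):
        mode = i % 3
        if mode == 0:
            return _fixture_variant(
                positions, _cycle(_FIXTURE_GENES, i), Consequence.MISSENSE,
                ClinVarClass.NOT_IN_CLINVAR, vaf, depth,
                pop_af={"gnomad": 0.02 + 0.001 * (i % 30)},
            )
        if mode == 1:
            return _fixture_variant(
                positions, _cycle(_FIXTURE_GENES, i + 1), Consequence.SYNONYMOUS,
                ClinVarClass.NOT_IN_CLINVAR, vaf, depth,
            )
        return _fixture_variant(
            positions, _cycle(_FIXTURE_GENES, i + 2), Consequence.MISSENSE,
            ClinVarClass.NOT_IN_CLINVAR, low_vaf_value, depth,
        )

    def distribute(block: Sequence[AnnotatedVariant], bins, pid_list):
        for i, variant in enumerate(block):
            bins[pid_list[i % len(pid_list)]].append(variant)

    tumor_vafs = [0.06, 0.12, 0.2, 0.35, 0.53, 0.7, 0.9, 0.054]
    # Tumor survivors: 62 non-germline P/LP + 41 + 8 + 61 + 126 (+37 germline) = 335
    distribute(_fixture_block(positions, 62, tumor_depth, tumor_vafs, plp), tumor_bins, tumor_pids)
    distribute(_fixture_block(positions, 41, tumor_depth, tumor_vafs, trunc), tumor_bins, tumor_pids)
    distribute(_fixture_block(positions, 8, tumor_depth, tumor_vafs, inframe), tumor_bins, tumor_pids)
    distribute(_fixture_block(positions, 61, tumor_depth, tumor_vafs, missense_hit), tumor_bins, tumor_pids)
    distribute(_fixture_block(positions, 126, tumor_depth, tumor_vafs, missense_miss), tumor_bins, tumor_pids)
    distribute(
        [decoy(positions, i, tumor_depth, _cycle(tumor_vafs, i), 0.01) for i in range(7255 - 335)],
        tumor_bins, tumor_pids,
    )

    gg_vafs = [0.005, 0.007, 0.012, 0.02, 0.035, 0.05]
    distribute(_fixture_block(positions, 43 - 37, plasma_depth, gg_vafs, plp), gg_bins, pids)
    distribute(_fixture_block(positions, 39, plasma_depth, gg_vafs, trunc), gg_bins, pids)
    distribute(_fixture_block(positions, 5, plasma_depth, gg_vafs, inframe), gg_bins, pids)
    distribute(_fixture_block(positions, 43, plasma_depth, gg_vafs, missense_hit), gg_bins, pids)
    distribute(_fixture_block(positions, 150 - 43, plasma_depth, gg_vafs, missense_miss), gg_bins, pids)
    distribute(
        [decoy(positions, i, plasma_depth, _cycle(gg_vafs, i), 0.003) for i in range(3414 - 237)],
        gg_bins, pids,
    )

    # lowest value keeps >=2 alt reads so the implied VAF clears the 0.2% floor
    clc_vafs = [0.004, 0.006, 0.008, 0.012, 0.02, 0.05]
    distribute(_fixture_block(positions, 1328 - 37, plasma_depth, clc_vafs, plp), clc_bins, pids)
    distribute(_fixture_block(positions, 2794, plasma_depth, clc_vafs, trunc), clc_bins, pids)
    distribute(_fixture_block(positions, 1544, plasma_depth, clc_vafs, inframe), clc_bins, pids)
    distribute(_fixture_block(positions, 2104, plasma_depth, clc_vafs, missense_hit), clc_bins, pids)
    distribute(_fixture_block(positions, 8614 - 2104, plasma_depth, clc_vafs, missense_miss), clc_bins, pids)
    distribute(
        [decoy(positions, i, plasma_depth, _cycle(clc_vafs, i), 0.001) for i in range(21232 - 14280)],
        clc_bins, pids,
    )

    # --- strata metadata (Table-1-style composition) ------------------------
    group_labels = ["treatment_naive"] * 23 + ["post_treatment"] * 73
    stage_labels = ["I"] * 14 + ["II"] * 7 + ["III"] * 55 + ["IV"] * 20
    meta = {}
    for i, pid in enumerate(pids):
        group = Group(group_labels[i])
        meta[pid] = {
            "group": group,
            "timing": Timing.DIAGNOSIS
            if group == Group.TREATMENT_NAIVE
            else Timing.ON_CHEMO,
            "figo_stage": FigoStage(stage_labels[i]),
            "histology": Histology.HIGH_GRADE_SEROUS,
            "outcome": Outcome.UNKNOWN,
        }

    tumor_tables = [
        SampleTable(
            sample_id=f"{pid}-T",
            patient_id=pid,
            sample_type=SampleType.TUMOR_FFPE,
            caller_mode=CallerMode.GENEGLOBE,
            variants=tumor_bins[pid],
            mean_depth=tumor_depth,
            qc_pass=pid not in qc_fail_pids,
        )
        for pid in pids
    ]
    plasma_gg = [
        SampleTable(
            sample_id=f"{pid}-P",
            patient_id=pid,
            sample_type=SampleType.PLASMA,
            caller_mode=CallerMode.GENEGLOBE,
            variants=gg_bins[pid],
            mean_depth=plasma_depth,
        )
        for pid in pids
    ]
    plasma_clc = [
        SampleTable(
            sample_id=f"{pid}-P",
            patient_id=pid,
            sample_type=SampleType.PLASMA,
            caller_mode=CallerMode.CLC,
            variants=clc_bins[pid],
            mean_depth=plasma_depth,
        )
        for pid in pids
    ]
    return ReferenceFixture(
        tumor_tables=tumor_tables,
        plasma_geneglobe=plasma_gg,
        plasma_clc=plasma_clc,
        prior_germline=prior_germline,
        confirmed_keys=confirmed_keys,
        meta=meta,
    )
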