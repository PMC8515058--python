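from __future__ import annotations

import pytest

from ctdna_concord.synthetic_cohort import (
    SimulationConfig,
    build_reference_fixture,
    simulate_cohort,
)
from ctdna_concord.triage import TriageThresholds
from ctdna_concord.variant_io import (
    AnnotatedVariant,
    CallerMode,
    ClinVarClass,
    Consequence,
    PredictorCall,
    SampleTable,
    SampleType,
)


@pytest.fixture(scope="session")
def thresholds():
    return TriageThresholds()


@pytest.fixture(scope="session")
def reference_fixture():
    return build_reference_fixture()


@pytest.fixture(scope="session")
def sim_cohort():
    return simulate_cohort(SimulationConfig(seed=11))


def make_variant(
    chrom="chr17",
    pos=7578406,
    ref="C",
    alt="T",
    gene="TP53",
    consequence=Consequence.MISSENSE,
    vaf=0.2,
    depth=1000,
    clinvar=ClinVarClass.NOT_IN_CLINVAR,
    metalr=PredictorCall.ABSENT,
    metasvm=PredictorCall.ABSENT,
    cadd=None,
    pop_af=None,
    alt_reads=None,
):
    if alt_reads is None and vaf is not None and depth is not None:
        alt_reads = round(vaf * depth)
    return AnnotatedVariant(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        vaf=vaf,
        alt_reads=alt_reads,
        depth=depth,
        clinvar=clinvar,
        metalr=metalr,
        metasvm=metasvm,
        cadd_phred=cadd,
        pop_af=pop_af or {},
    )


def make_table(variants, sample_type=SampleType.TUMOR_FFPE,
               caller_mode=CallerMode.GENEGLOBE, patient_id="P01",
               qc_pass=True):
    suffix = "T" if sample_type == SampleType.TUMOR_FFPE else "P"
    return SampleTable(
        sample_id=f"{patient_id}-{suffix}",
        patient_id=patient_id,
        sample_type=sample_type,
        caller_mode=caller_mode,
        variants=list(variants),
        qc_pass=qc_pass,
    )
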