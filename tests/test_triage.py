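"""Triage cascade: gate order, classification precedence, sample accounting."""

from __future__ import annotations

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_table, make_variant
from oracle_utils import classify_oracle

from ctdna_concord.errors import ConfigError
from ctdna_concord.triage import (
    Category,
    DiscardReason,
    TriageThresholds,
    classify,
    decide,
    prefilter,
    triage_sample,
)
from ctdna_concord.variant_io import (
    CallerMode,
    ClinVarClass,
    Consequence,
    PredictorCall,
    SampleType,
    normalize_key,
)


class TestPrefilter:
    @pytest.mark.parametrize(
        "vaf, sample_type, mode, expect_pass, expect_reason",
        [
            (0.054, SampleType.TUMOR_FFPE, None, True, None),
            (0.05, SampleType.TUMOR_FFPE, None, True, None),  # floor inclusive
            (0.049, SampleType.TUMOR_FFPE, None, False, DiscardReason.LOW_VAF),
            (0.007, SampleType.PLASMA, CallerMode.GENEGLOBE, True, None),
            (0.007, SampleType.PLASMA, CallerMode.CLC, True, None),
            (0.004, SampleType.PLASMA, CallerMode.CLC, True, None),
            (0.004, SampleType.PLASMA, CallerMode.GENEGLOBE, False, DiscardReason.LOW_VAF),
            (0.002, SampleType.PLASMA, CallerMode.CLC, True, None),  # floor inclusive
            (None, SampleType.TUMOR_FFPE, None, False, DiscardReason.NO_VAF),
        ],
    )
    def test_vaf_floors(self, thresholds, vaf, sample_type, mode, expect_pass, expect_reason):
        v = make_variant(vaf=vaf, alt_reads=None if vaf is None else None,
                         depth=None if vaf is None else 10000)
        passed, reason, trace = prefilter(v, sample_type, mode, thresholds)
        assert passed is expect_pass
        assert reason == expect_reason

    def test_common_population_variant_fails_first(self, thresholds):
        v = make_variant(pop_af={"gnomad": 0.02}, consequence=Consequence.SYNONYMOUS)
        passed, reason, trace = prefilter(v, SampleType.TUMOR_FFPE, None, thresholds)
        assert not passed and reason == DiscardReason.COMMON_MAF
        assert trace[0].startswith("maf:fail")

    def test_absent_population_frequency_never_fails_maf(self, thresholds):
        v = make_variant(vaf=0.2)
        passed, _, trace = prefilter(v, SampleType.TUMOR_FFPE, None, thresholds)
        assert passed and "maf:pass(absent)" in trace

    def test_synonymous_checked_before_vaf(self, thresholds):
        v = make_variant(consequence=Consequence.SYNONYMOUS, vaf=0.01)
        _, reason, _ = prefilter(v, SampleType.TUMOR_FFPE, None, thresholds)
        assert reason == DiscardReason.SYNONYMOUS

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ConfigError):
            TriageThresholds(min_plasma_vaf_clc=0.006)
        with pytest.raises(ConfigError):
            TriageThresholds(max_pop_af=0.0)


_CADD_STATES = (None, 5.0, 19.9, 20.0, 31.0)


class TestClassify:
    @pytest.mark.parametrize(
        "kwargs, retained, label",
        [
            # frameshift BRCA1-like, not in ClinVar
            (dict(consequence=Consequence.FRAMESHIFT, ref="CT", alt="C"),
             True, Category.TRUNCATING_OR_SPLICE),
            # consensus requires all three predictors
            (dict(consequence=Consequence.MISSENSE, metalr=PredictorCall.DAMAGING,
                  metasvm=PredictorCall.TOLERATED, cadd=28.0),
             False, DiscardReason.MISSENSE_NOT_CONSENSUS),
            (dict(consequence=Consequence.MISSENSE, metalr=PredictorCall.DAMAGING,
                  metasvm=PredictorCall.DAMAGING, cadd=28.0),
             True, Category.MISSENSE_CONSENSUS_DAMAGING),
            # ClinVar outranks consequence in both directions
            (dict(consequence=Consequence.NONSENSE, clinvar=ClinVarClass.BENIGN),
             False, DiscardReason.CLINVAR_BENIGN),
            (dict(consequence=Consequence.SYNONYMOUS, clinvar=ClinVarClass.PATHOGENIC),
             True, Category.CLINVAR_PATHOGENIC),
            (dict(consequence=Consequence.INFRAME_INDEL, ref="C", alt="CGAT"),
             True, Category.INFRAME_INDEL),
            (dict(consequence=Consequence.OTHER),
             False, DiscardReason.UNCLASSIFIABLE),
        ],
    )
    def test_precedence_examples(self, kwargs, retained, label):
        decision = classify(make_variant(**kwargs))
        assert decision.retained is retained
        if retained:
            assert decision.category == label
        else:
            assert decision.discard_reason == label

    def test_absent_predictor_named_in_trace(self):
        decision = classify(
            make_variant(consequence=Consequence.MISSENSE,
                         metalr=PredictorCall.ABSENT,
                         metasvm=PredictorCall.DAMAGING, cadd=30.0)
        )
        assert not decision.retained
        assert decision.discard_reason == DiscardReason.MISSENSE_NOT_CONSENSUS
        assert any("metalr" in step for step in decision.stage_trace)

    def test_exhaustive_truth_table_equivalence(self, thresholds):
        """classify() agrees with the flat rule-table oracle everywhere."""
        combos = itertools.product(
            ClinVarClass, Consequence, PredictorCall, PredictorCall, _CADD_STATES
        )
        checked = 0
        for clinvar, consequence, metalr, metasvm, cadd in combos:
            v = make_variant(
                consequence=consequence,
                clinvar=clinvar,
                metalr=metalr,
                metasvm=metasvm,
                cadd=cadd,
            )
            decision = classify(v, thresholds)
            verdict, label = classify_oracle(
                clinvar.value, consequence.value, metalr.value, metasvm.value,
                cadd, thresholds.cadd_phred_cutoff,
            )
            assert decision.retained == (verdict == "retained"), (clinvar, consequence)
            actual = (
                decision.category.value if decision.retained
                else decision.discard_reason.value
            )
            assert actual == label, (clinvar, consequence, metalr, metasvm, cadd)
            # retained XOR discard_reason, category only when retained
            assert decision.retained == (decision.discard_reason is None)
            checked += 1
        assert checked == len(ClinVarClass) * len(Consequence) * 9 * len(_CADD_STATES)


def _mixed_sample():
    variants = []
    # 3 ClinVar P/LP, 2 truncating, 1 inframe, 4 missense (2 consensus),
    # 2 benign, 3 prefilter decoys
    for i in range(3):
        variants.append(make_variant(pos=1000 + i, clinvar=ClinVarClass.PATHOGENIC))
    for i in range(2):
        variants.append(make_variant(pos=2000 + i, consequence=Consequence.NONSENSE))
    variants.append(make_variant(pos=3000, consequence=Consequence.INFRAME_INDEL,
                                 ref="C", alt="CTTA"))
    for i in range(2):
        variants.append(make_variant(pos=4000 + i, consequence=Consequence.MISSENSE,
                                     metalr=PredictorCall.DAMAGING,
                                     metasvm=PredictorCall.DAMAGING, cadd=25.0))
    for i in range(2):
        variants.append(make_variant(pos=5000 + i, consequence=Consequence.MISSENSE,
                                     metalr=PredictorCall.TOLERATED,
                                     metasvm=PredictorCall.DAMAGING, cadd=25.0))
    for i in range(2):
        variants.append(make_variant(pos=6000 + i, clinvar=ClinVarClass.BENIGN))
    variants.append(make_variant(pos=7000, pop_af={"exac": 0.05}))
    variants.append(make_variant(pos=7001, consequence=Consequence.SYNONYMOUS))
    variants.append(make_variant(pos=7002, vaf=0.01))
    return variants


class TestTriageSample:
    def test_category_counts_reconcile(self):
        result = triage_sample(make_table(_mixed_sample()))
        counts = result.category_counts
        assert counts[Category.CLINVAR_PATHOGENIC] == 3
        assert counts[Category.TRUNCATING_OR_SPLICE] == 2
        assert counts[Category.INFRAME_INDEL] == 1
        assert counts[Category.MISSENSE_CONSENSUS_DAMAGING] == 2
        assert sum(counts.values()) == len(result.retained) == 8
        assert len(result.decisions) == len(result.retained) + sum(
            result.discard_counts.values()
        )
        assert result.n_prefilter_pass == 12

    def test_empty_sample(self):
        result = triage_sample(make_table([]))
        assert result.retained == [] and not result.qc_fail

    def test_all_common_maf(self):
        variants = [
            make_variant(pos=100 + i, pop_af={"gnomad": 0.05}) for i in range(10)
        ]
        result = triage_sample(make_table(variants))
        assert len(result.retained) == 0
        assert result.discard_counts[DiscardReason.COMMON_MAF] == 10

    def test_qc_fail_sample_yields_flagged_empty_result(self):
        result = triage_sample(make_table(_mixed_sample(), qc_pass=False))
        assert result.qc_fail and result.retained == [] and result.decisions == []

    def test_order_independence(self):
        variants = _mixed_sample()
        shuffled = variants[:]
        random.Random(5).shuffle(shuffled)
        a = triage_sample(make_table(variants))
        b = triage_sample(make_table(shuffled))
        keys = lambda r: {normalize_key(v) for v in r.retained}  # noqa: E731
        assert keys(a) == keys(b)
        assert a.category_counts == b.category_counts


@st.composite
def plasma_variants(draw):
    n = draw(st.integers(0, 25))
    out = []
    for i in range(n):
        vaf = draw(st.floats(0.0005, 0.05))
        consequence = draw(st.sampled_from(list(Consequence)))
        clinvar = draw(st.sampled_from(list(ClinVarClass)))
        out.append(
            make_variant(pos=10_000 + i, vaf=vaf, depth=None, alt_reads=None,
                         consequence=consequence, clinvar=clinvar,
                         metalr=draw(st.sampled_from(list(PredictorCall))),
                         metasvm=draw(st.sampled_from(list(PredictorCall))),
                         cadd=draw(st.sampled_from([None, 10.0, 30.0])))
        )
    return out


class TestMonotonicity:
    @settings(max_examples=60, derandomize=True)
    @given(plasma_variants())
    def test_lower_floor_retains_superset(self, variants):
        """Dropping the plasma floor 0.5% -> 0.2% never loses a variant."""
        gg = triage_sample(make_table(variants, sample_type=SampleType.PLASMA,
                                      caller_mode=CallerMode.GENEGLOBE))
        clc = triage_sample(make_table(variants, sample_type=SampleType.PLASMA,
                                       caller_mode=CallerMode.CLC))
        gg_keys = {normalize_key(v) for v in gg.retained}
        clc_keys = {normalize_key(v) for v in clc.retained}
        assert gg_keys <= clc_keys

    @settings(max_examples=60, derandomize=True)
    @given(plasma_variants())
    def test_partition_accounting(self, variants):
        """Every input row gets exactly one verdict; counts reconcile."""
        result = triage_sample(make_table(variants, sample_type=SampleType.PLASMA,
                                          caller_mode=CallerMode.CLC))
        assert len(result.decisions) == len(variants)
        n_ret = sum(1 for _, d in result.decisions if d.retained)
        assert n_ret == len(result.retained) == sum(result.category_counts.values())
        assert len(variants) == n_ret + sum(result.discard_counts.values())
        for _, d in result.decisions:
            assert d.retained == (d.discard_reason is None)
            assert (d.category != Category.NONE) == d.retained


def test_decide_composes_prefilter_and_classify(thresholds):
    v = make_variant(vaf=0.01)  # below tumor floor
    decision = decide(v, SampleType.TUMOR_FFPE, None, thresholds)
    assert decision.discard_reason == DiscardReason.LOW_VAF
    v2 = make_variant(vaf=0.054, clinvar=ClinVarClass.LIKELY_PATHOGENIC)
    assert decide(v2, SampleType.TUMOR_FFPE, None, thresholds).retained
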