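"""Cohort-level orchestration: triage -> germline -> concordance -> heterogeneity.

`analyze_cohort` is the in-memory core; `run_pipeline` wraps it with file
I/O (manifest in, TSV report bundle out) and a run manifest recording
thresholds, package version and input digests, so every report number is
recomputable from persisted intermediates.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from . import __version__
from .concordance import (
    STRATIFIERS,
    PatientRecord,
    SomaticCall,
    concordance_by,
    concordance_frame,
    gene_spectrum,
    outcome_split,
    shared_variants,
)
from .errors import InputError
from .germline import (
    DEFAULT_WINDOW,
    GermlineEvidence,
    GermlineSource,
    exclude_germline,
    flag_suspected_germline,
    read_germline_list,
    write_germline_list,
)
from .heterogeneity import plasma_only_variants
from .triage import TriageResult, TriageThresholds, audit_rows, triage_sample
from .variant_io import (
    CallerMode,
    FigoStage,
    Group,
    Histology,
    ManifestEntry,
    Outcome,
    SampleTable,
    SampleType,
    Timing,
    normalize_key,
    read_manifest,
    read_variant_table,
)

logger = logging.getLogger("ctdna_concord")

__all__ = [
    "PatientInput",
    "PatientAnalysis",
    "RunConfig",
    "analyze_patient",
    "analyze_cohort",
    "run_pipeline",
    "compare_modes",
]


@dataclass
class PatientInput:
    """Everything needed to analyze one patient in memory."""

    patient_id: str
    group: Group
    timing: Timing
    figo_stage: FigoStage
    histology: Histology
    tumor_table: SampleTable
    plasma_table: SampleTable
    outcome: Outcome = Outcome.UNKNOWN
    prior_germline: List[GermlineEvidence] = field(default_factory=list)
    confirmed_keys: Set[tuple] = field(default_factory=set)  # (patient_id, key)


@dataclass
class PatientAnalysis:
    record: PatientRecord
    tumor_result: TriageResult
    plasma_result: TriageResult
    evidence: List[GermlineEvidence]
    germline_excluded: List[GermlineEvidence]
    pending_confirmation: List[GermlineEvidence]
    warnings: List[str]


def _to_calls(variants) -> List[SomaticCall]:
    return [SomaticCall(normalize_key(v), v.vaf, v.gene) for v in variants]


def analyze_patient(
    pin: PatientInput,
    thresholds: TriageThresholds = TriageThresholds(),
    germline_window: Tuple[float, float] = DEFAULT_WINDOW,
    caller_mode: Optional[CallerMode] = None,
) -> PatientAnalysis:
    """Triage both samples, resolve germline, build the patient record.

    Germline evidence = the prior-study list plus plasma VAF-window
    suspects; suspects exclude only once confirmed (the confirmation
    oracle is ``pin.confirmed_keys``).  The same evidence subtracts
    germline from both the tumor and the plasma retained sets.
    """
    plasma_table = pin.plasma_table
    if caller_mode is not None and plasma_table.caller_mode != caller_mode:
        plasma_table = replace(plasma_table, caller_mode=caller_mode)
    tumor_result = triage_sample(pin.tumor_table, thresholds)
    plasma_result = triage_sample(plasma_table, thresholds)

    suspects = flag_suspected_germline(plasma_result, germline_window)
    prior_keys = {e.key for e in pin.prior_germline}
    for i, suspect in enumerate(suspects):
        if (pin.patient_id, suspect.key) in pin.confirmed_keys:
            suspects[i] = replace(suspect, confirmed=True)
    evidence = list(pin.prior_germline) + suspects

    tumor_somatic, tumor_germ, warn_t = exclude_germline(
        tumor_result.retained, evidence, pin.patient_id
    )
    plasma_somatic, plasma_germ, warn_p = exclude_germline(
        plasma_result.retained, evidence, pin.patient_id
    )
    pending = [
        s for s in suspects if not s.confirmed and s.key not in prior_keys
    ]
    excluded_keys = {normalize_key(v) for v in tumor_germ} | {
        normalize_key(v) for v in plasma_germ
    }
    germline_excluded = [e for e in evidence if e.excludes and e.key in excluded_keys]

    record = PatientRecord(
        patient_id=pin.patient_id,
        group=pin.group,
        timing=pin.timing,
        figo_stage=pin.figo_stage,
        histology=pin.histology,
        tumor_somatic=_to_calls(tumor_somatic),
        plasma_somatic=_to_calls(plasma_somatic),
        outcome=pin.outcome,
        tumor_qc_pass=not tumor_result.qc_fail,
    )
    return PatientAnalysis(
        record=record,
        tumor_result=tumor_result,
        plasma_result=plasma_result,
        evidence=evidence,
        germline_excluded=germline_excluded,
        pending_confirmation=pending,
        warnings=warn_t + warn_p,
    )


def analyze_cohort(
    inputs: Sequence[PatientInput],
    thresholds: TriageThresholds = TriageThresholds(),
    germline_window: Tuple[float, float] = DEFAULT_WINDOW,
    caller_mode: Optional[CallerMode] = None,
) -> List[PatientAnalysis]:
    return [
        analyze_patient(pin, thresholds, germline_window, caller_mode)
        for pin in inputs
    ]


# ---------------------------------------------------------------------------
# Mode contrast

def compare_modes(
    inputs: Sequence[PatientInput],
    thresholds: TriageThresholds = TriageThresholds(),
    germline_window: Tuple[float, float] = DEFAULT_WINDOW,
    stratifiers: Sequence[str] = ("overall", "group", "figo_stage"),
) -> pd.DataFrame:
    """Per-stratum concordance under the 0.5% vs 0.2% plasma VAF floors.

    Re-triages the same plasma calls in both caller modes, checks the
    retained-set monotonicity property (the lower floor retains a superset
    per sample), and tabulates concordance deltas.
    """
    results = {}
    for mode in (CallerMode.GENEGLOBE, CallerMode.CLC):
        analyses = analyze_cohort(inputs, thresholds, germline_window, mode)
        results[mode] = analyses
    for gg, clc in zip(results[CallerMode.GENEGLOBE], results[CallerMode.CLC]):
        gg_keys = {normalize_key(v) for v in gg.plasma_result.retained}
        clc_keys = {normalize_key(v) for v in clc.plasma_result.retained}
        if not gg_keys <= clc_keys:
            raise AssertionError(
                f"monotonicity violated for {gg.record.patient_id}: "
                "0.2% floor lost retained plasma variants present at 0.5%"
            )
    rows = []
    for stratifier in stratifiers:
        by_mode = {
            mode: {
                s.stratum: s
                for s in concordance_by([a.record for a in analyses], stratifier)
            }
            for mode, analyses in results.items()
        }
        for stratum, gg_summary in by_mode[CallerMode.GENEGLOBE].items():
            clc_summary = by_mode[CallerMode.CLC][stratum]
            rows.append(
                {
                    "stratifier": stratifier,
                    "stratum": stratum,
                    "n_eligible": gg_summary.n_eligible,
                    "pct_geneglobe": gg_summary.percentage,
                    "pct_clc": clc_summary.percentage,
                    "delta": None
                    if gg_summary.percentage is None
                    else round(clc_summary.percentage - gg_summary.percentage, 1),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File-backed run

@dataclass
class RunConfig:
    manifest: Path
    caller_mode: CallerMode = CallerMode.CLC
    thresholds: TriageThresholds = TriageThresholds()
    germline_window: Tuple[float, float] = DEFAULT_WINDOW
    outdir: Path = Path("results")
    confirmations: Optional[Path] = None
    log_level: str = "INFO"


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _read_confirmations(path: Optional[Path]) -> Set[tuple]:
    if path is None:
        return set()
    confirmed = set()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            from .variant_io import parse_key

            confirmed.add(
                (
                    row["patient_id"],
                    parse_key(row["chrom"], int(row["pos"]), row["ref"], row["alt"]),
                )
            )
    return confirmed


def load_patient_inputs(
    entries: Iterable[ManifestEntry],
    caller_mode: CallerMode,
    confirmed_keys: Optional[Set[tuple]] = None,
) -> Tuple[List[PatientInput], List[str]]:
    """Materialize manifest rows; a patient with a missing table is skipped
    with a warning rather than failing the run."""
    inputs: List[PatientInput] = []
    warnings: List[str] = []
    for entry in entries:
        missing = [
            str(p)
            for p in (entry.tumor_path, entry.plasma_path)
            if p is None or not Path(p).exists()
        ]
        if missing:
            warnings.append(
                f"patient {entry.patient_id}: skipped (missing {', '.join(missing)})"
            )
            continue
        tumor_table = SampleTable(
            sample_id=f"{entry.patient_id}-T",
            patient_id=entry.patient_id,
            sample_type=SampleType.TUMOR_FFPE,
            caller_mode=CallerMode.GENEGLOBE,
            variants=read_variant_table(entry.tumor_path),
            qc_pass=entry.tumor_qc_pass,
        )
        plasma_table = SampleTable(
            sample_id=f"{entry.patient_id}-P",
            patient_id=entry.patient_id,
            sample_type=SampleType.PLASMA,
            caller_mode=caller_mode,
            variants=read_variant_table(entry.plasma_path),
        )
        prior = (
            read_germline_list(entry.germline_list_path)
            if entry.germline_list_path and Path(entry.germline_list_path).exists()
            else []
        )
        inputs.append(
            PatientInput(
                patient_id=entry.patient_id,
                group=entry.group,
                timing=entry.timing,
                figo_stage=entry.figo_stage,
                histology=entry.histology,
                tumor_table=tumor_table,
                plasma_table=plasma_table,
                outcome=entry.outcome,
                prior_germline=[e for e in prior if e.patient_id == entry.patient_id],
                confirmed_keys=confirmed_keys or set(),
            )
        )
    return inputs, warnings


def _write_tsv(rows: List[dict], columns: List[str], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and persist a report bundle.

    Writes, under ``config.outdir``: the per-variant audit table, the
    stratified concordance table, per-patient shared variants, the gene
    spectrum, the post-surgery outcome cross-tab, plasma-only variant
    lists, germline exclusions, pending confirmations and a run manifest
    (thresholds, version, input digests).  Returns the bundle in memory.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    entries = read_manifest(config.manifest, check_files=False)
    confirmed = _read_confirmations(config.confirmations)
    inputs, warnings = load_patient_inputs(entries, config.caller_mode, confirmed)
    for w in warnings:
        logger.warning(w)

    analyses = analyze_cohort(
        inputs, config.thresholds, config.germline_window, config.caller_mode
    )
    records = [a.record for a in analyses]

    audit = [
        row
        for a in analyses
        for row in audit_rows(a.tumor_result) + audit_rows(a.plasma_result)
    ]
    if audit:
        _write_tsv(audit, list(audit[0].keys()), outdir / "audit.tsv")
    else:
        _write_tsv([], ["patient_id"], outdir / "audit.tsv")

    summaries = [s for strat in STRATIFIERS for s in concordance_by(records, strat)]
    concordance_frame(summaries).to_csv(
        outdir / "concordance.tsv", sep="\t", index=False
    )

    shared_rows = []
    for record in records:
        for s in shared_variants(record):
            shared_rows.append(
                {
                    "patient_id": record.patient_id,
                    "chrom": s.key.chrom,
                    "pos": s.key.pos,
                    "ref": s.key.ref or "-",
                    "alt": s.key.alt or "-",
                    "gene": s.gene or "",
                    "vaf_tumor": "" if s.vaf_tumor is None else repr(s.vaf_tumor),
                    "vaf_plasma": "" if s.vaf_plasma is None else repr(s.vaf_plasma),
                }
            )
    _write_tsv(
        shared_rows,
        ["patient_id", "chrom", "pos", "ref", "alt", "gene", "vaf_tumor", "vaf_plasma"],
        outdir / "shared_variants.tsv",
    )

    gene_spectrum(records).to_csv(outdir / "spectrum.tsv", sep="\t", index=False)
    outcome_split(records).to_csv(outdir / "outcomes.tsv", sep="\t")

    plasma_only_rows = []
    for record in records:
        for key in plasma_only_variants(record):
            plasma_only_rows.append(
                {
                    "patient_id": record.patient_id,
                    "chrom": key.chrom,
                    "pos": key.pos,
                    "ref": key.ref or "-",
                    "alt": key.alt or "-",
                }
            )
    _write_tsv(
        plasma_only_rows,
        ["patient_id", "chrom", "pos", "ref", "alt"],
        outdir / "plasma_only.tsv",
    )

    write_germline_list(
        [e for a in analyses for e in a.germline_excluded],
        outdir / "germline_excluded.tsv",
    )
    write_germline_list(
        [e for a in analyses for e in a.pending_confirmation],
        outdir / "pending_confirmation.tsv",
    )
    all_warnings = warnings + [w for a in analyses for w in a.warnings]
    (outdir / "warnings.log").write_text(
        "\n".join(all_warnings) + ("\n" if all_warnings else "")
    )

    run_manifest = {
        "version": __version__,
        "caller_mode": config.caller_mode.value,
        "thresholds": vars(config.thresholds),
        "germline_window": list(config.germline_window),
        "inputs": {
            str(e.patient_id): {
                "tumor": _sha256(e.tumor_path) if Path(e.tumor_path).exists() else None,
                "plasma": _sha256(e.plasma_path)
                if Path(e.plasma_path).exists()
                else None,
            }
            for e in entries
        },
    }
    (outdir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2))

    return {
        "analyses": analyses,
        "records": records,
        "summaries": summaries,
        "warnings": all_warnings,
        "outdir": outdir,
    }
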