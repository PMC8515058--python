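"""Reading, normalization and writing of annotated variant calls.

Variant calls enter the pipeline as annotated tables — one row per single-alt
variant carrying the locus, alleles, gene, consequence class, VAF and UMI
depth, population allele frequencies (1000G / gnomAD / ExAC), the ClinVar
classification and in-silico predictor outputs (MetaLR, MetaSVM, CADD).
The canonical interchange is a tab-separated sidecar with a documented
column set (:data:`VARIANT_COLUMNS`); a VCF reader is provided as a
convenience layer on top of :mod:`pysam` for calls whose annotations were
written into INFO.

Coordinates are 1-based (VCF convention) throughout.  Tumor and plasma calls
of the same biological event are matched on a :class:`VariantKey`: a
left/right-trimmed minimal representation in which indel alleles may be
empty, so that every padded spelling of the same insertion or deletion
collapses to one key without requiring a reference genome.  Full
left-alignment through homopolymer runs is available when a reference
context window is supplied (:func:`left_align`).
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import yaml

from .errors import ConfigError, FormatError, InputError, UnsupportedAlleleError

__all__ = [
    "Consequence",
    "ClinVarClass",
    "PredictorCall",
    "SampleType",
    "CallerMode",
    "Group",
    "Timing",
    "FigoStage",
    "Histology",
    "Outcome",
    "AnnotatedVariant",
    "VariantKey",
    "SampleTable",
    "ManifestEntry",
    "normalize_key",
    "minimal_key",
    "left_align",
    "trim_anchored",
    "read_vcf",
    "read_manifest",
    "read_variant_table",
    "write_variant_table",
    "POP_AF_SOURCES",
    "VARIANT_COLUMNS",
]


# ---------------------------------------------------------------------------
# Enumerations

class Consequence(str, enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    CANONICAL_SPLICE = "canonical_splice"
    INFRAME_INDEL = "inframe_indel"
    OTHER = "other"


#: Consequence classes with very strong evidence of pathogenicity
#: (protein-truncating or splice-disrupting).
TRUNCATING = frozenset(
    {Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.CANONICAL_SPLICE}
)


class ClinVarClass(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    NOT_IN_CLINVAR = "not_in_clinvar"
    CONFLICTING = "conflicting"


class PredictorCall(str, enum.Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    ABSENT = "absent"


class SampleType(str, enum.Enum):
    TUMOR_FFPE = "tumor_ffpe"
    PLASMA = "plasma"


class CallerMode(str, enum.Enum):
    GENEGLOBE = "geneglobe"
    CLC = "clc"


class Group(str, enum.Enum):
    TREATMENT_NAIVE = "treatment_naive"
    POST_TREATMENT = "post_treatment"


class Timing(str, enum.Enum):
    DIAGNOSIS = "diagnosis"
    POST_SURGERY_PRE_CHEMO = "post_surgery_pre_chemo"
    ON_CHEMO = "on_chemo"
    RECURRENCE = "recurrence"
    PROGRESSION = "progression"


class FigoStage(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


class Histology(str, enum.Enum):
    HIGH_GRADE_SEROUS = "high_grade_serous"
    LOW_GRADE_SEROUS = "low_grade_serous"
    CLEAR_CELL = "clear_cell"
    ENDOMETRIOID = "endometrioid"
    MUCINOUS = "mucinous"
    MIXED = "mixed"
    CARCINOSARCOMA = "carcinosarcoma"


class Outcome(str, enum.Enum):
    DISEASE_FREE = "disease_free"
    RELAPSED = "relapsed"
    DECEASED = "deceased"
    UNKNOWN = "unknown"


POP_AF_SOURCES = ("thousand_genomes", "gnomad", "exac")

_SYMBOLIC_CHARS = set("<>[]*")


# ---------------------------------------------------------------------------
# Core records

class VariantKey(NamedTuple):
    """Normalized identity of a variant; equal keys mean the same event.

    ``ref``/``alt`` hold the minimal (fully trimmed) allele spelling and may
    be empty strings for pure insertions/deletions; ``pos`` is the 1-based
    position of the first remaining (or removed) reference base.
    """

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class AnnotatedVariant:
    """One called variant with its annotations, VAF and depth.

    ``pop_af`` maps a population database name (see :data:`POP_AF_SOURCES`)
    to an allele frequency; absent databases are simply missing keys.
    ``mmaf`` — the maximum minor allele frequency over available sources —
    is derived, never stored.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    hgvs_c: Optional[str] = None
    consequence: Consequence = Consequence.OTHER
    vaf: Optional[float] = None
    alt_reads: Optional[int] = None
    depth: Optional[int] = None
    pop_af: dict = field(default_factory=dict)
    clinvar: ClinVarClass = ClinVarClass.NOT_IN_CLINVAR
    metalr: PredictorCall = PredictorCall.ABSENT
    metasvm: PredictorCall = PredictorCall.ABSENT
    cadd_phred: Optional[float] = None
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise InputError(f"empty allele at {self.chrom}:{self.pos}")
        if "," in self.alt:
            raise InputError(
                f"multiallelic record at {self.chrom}:{self.pos}; split upstream"
            )
        if self.pos < 1:
            raise InputError(f"position must be 1-based positive, got {self.pos}")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise InputError(f"VAF {self.vaf} outside [0,1] at {self.chrom}:{self.pos}")
        if self.depth is not None and self.depth <= 0:
            raise InputError(f"non-positive depth at {self.chrom}:{self.pos}")
        if self.alt_reads is not None:
            if self.alt_reads < 0:
                raise InputError(f"negative alt_reads at {self.chrom}:{self.pos}")
            if self.depth is not None and self.alt_reads > self.depth:
                raise InputError(
                    f"alt_reads {self.alt_reads} > depth {self.depth} "
                    f"at {self.chrom}:{self.pos}"
                )
            if (
                self.vaf is not None
                and self.depth is not None
                and abs(self.vaf - self.alt_reads / self.depth) > 2.0 / self.depth
            ):
                raise InputError(
                    f"VAF {self.vaf} inconsistent with {self.alt_reads}/{self.depth} "
                    f"at {self.chrom}:{self.pos}"
                )
        for src, af in self.pop_af.items():
            if src not in POP_AF_SOURCES:
                raise InputError(f"unknown population AF source {src!r}")
            if not 0.0 <= af <= 1.0:
                raise InputError(f"population AF {af} outside [0,1]")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise InputError(f"negative CADD score at {self.chrom}:{self.pos}")

    @property
    def mmaf(self) -> Optional[float]:
        """Maximum minor allele frequency over the available databases."""
        return max(self.pop_af.values()) if self.pop_af else None

    @property
    def key(self) -> VariantKey:
        return normalize_key(self)


@dataclass
class SampleTable:
    """All variant calls of one sample plus sample-level metadata."""

    sample_id: str
    patient_id: str
    sample_type: SampleType
    variants: list
    caller_mode: Optional[CallerMode] = None
    mean_depth: Optional[float] = None
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.sample_type == SampleType.PLASMA and self.caller_mode is None:
            raise InputError(
                f"plasma table {self.sample_id}: caller_mode is mandatory "
                "(it sets the VAF floor)"
            )
        if self.mean_depth is not None and self.mean_depth <= 0:
            raise InputError(f"non-positive mean depth for {self.sample_id}")


@dataclass
class ManifestEntry:
    """One cohort-manifest row: a patient with paired tumor/plasma tables."""

    patient_id: str
    group: Group
    timing: Timing
    figo_stage: FigoStage
    histology: Histology
    tumor_path: Path
    plasma_path: Path
    germline_list_path: Optional[Path] = None
    outcome: Outcome = Outcome.UNKNOWN
    tumor_qc_pass: bool = True


# ---------------------------------------------------------------------------
# Normalization

def _check_allele(allele: str, chrom: str, pos: int) -> None:
    if not allele or _SYMBOLIC_CHARS.intersection(allele):
        raise UnsupportedAlleleError(
            f"unsupported allele {allele!r} at {chrom}:{pos}"
        )


def trim_anchored(chrom: str, pos: int, ref: str, alt: str) -> tuple:
    """VCF-style parsimonious trim keeping at least one base in each allele.

    Shared trailing bases are removed while both alleles have length > 1,
    then shared leading bases likewise (advancing ``pos``).  SNVs are
    returned unchanged.
    """
    _check_allele(ref, chrom, pos)
    _check_allele(alt, chrom, pos)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


def _minimal(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    # Suffix- then prefix-trim, allowing an allele to empty out entirely as
    # long as the other still carries sequence; this collapses left- and
    # right-padded spellings of the same indel onto one representation.
    while ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0] and (len(ref) > 1 or len(alt) > 1):
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt)


def minimal_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Normalize raw alleles (any padded spelling) to a comparison key."""
    _check_allele(ref, chrom, pos)
    _check_allele(alt, chrom, pos)
    return _minimal(chrom, pos, ref, alt)


def parse_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Parse serialized key alleles, where ``-`` (or blank) means empty.

    Accepts both minimal representations (pure-indel empty alleles) and
    anchored VCF-style spellings, returning the minimal key either way.
    """
    ref = "" if ref in ("", "-") else ref
    alt = "" if alt in ("", "-") else alt
    if not ref and not alt:
        raise InputError(f"both alleles empty at {chrom}:{pos}")
    if not ref or not alt:
        _check_allele(ref or alt, chrom, pos)
        return VariantKey(chrom, pos, ref, alt)
    return minimal_key(chrom, pos, ref, alt)


def format_allele(allele: str) -> str:
    """Serialize a key allele (empty becomes ``-``)."""
    return allele or "-"


def normalize_key(variant: AnnotatedVariant) -> VariantKey:
    """Normalized comparison key for a single-alt variant.

    Idempotent; SNVs map to themselves; indels are reduced to their minimal
    spelling so tumor and plasma calls of one event compare equal.  Symbolic
    alleles (``<DEL>``, breakends) are rejected.
    """
    _check_allele(variant.ref, variant.chrom, variant.pos)
    _check_allele(variant.alt, variant.chrom, variant.pos)
    return _minimal(variant.chrom, variant.pos, variant.ref, variant.alt)


def left_align(key: VariantKey, context: str, context_start: int) -> VariantKey:
    """Left-align an indel key through a homopolymer/repeat run.

    ``context`` is reference sequence starting at 1-based ``context_start``.
    The key is shifted left while its trailing base matches the reference
    base preceding it (the standard shift-then-trim algorithm), then reduced
    to the minimal representation.  Keys that are not pure indels, or whose
    window is exhausted, are returned (minimally trimmed) as is.
    """
    chrom, pos, ref, alt = key
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            continue
        if (not ref) or (not alt):
            prev = pos - 1
            if prev < context_start or prev - context_start >= len(context):
                break
            base = context[prev - context_start]
            ref, alt = base + ref, base + alt
            pos -= 1
            continue
        break
    return _minimal(chrom, pos, ref, alt)


# ---------------------------------------------------------------------------
# Delimited-table interchange

VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "hgvs_c",
    "consequence",
    "vaf",
    "alt_reads",
    "depth",
    "af_thousand_genomes",
    "af_gnomad",
    "af_exac",
    "clinvar",
    "metalr",
    "metasvm",
    "cadd_phred",
    "flags",
]

_AF_COLS = {
    "af_thousand_genomes": "thousand_genomes",
    "af_gnomad": "gnomad",
    "af_exac": "exac",
}


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, enum.Enum):
        return value.value
    if isinstance(value, float):
        return repr(value)
    return str(value)


def variant_to_row(v: AnnotatedVariant) -> dict:
    row = {
        "chrom": v.chrom,
        "pos": str(v.pos),
        "ref": v.ref,
        "alt": v.alt,
        "gene": _fmt(v.gene),
        "hgvs_c": _fmt(v.hgvs_c),
        "consequence": v.consequence.value,
        "vaf": _fmt(v.vaf),
        "alt_reads": _fmt(v.alt_reads),
        "depth": _fmt(v.depth),
        "clinvar": v.clinvar.value,
        "metalr": v.metalr.value,
        "metasvm": v.metasvm.value,
        "cadd_phred": _fmt(v.cadd_phred),
        "flags": ";".join(v.flags),
    }
    for col, src in _AF_COLS.items():
        row[col] = _fmt(v.pop_af.get(src))
    return row


def row_to_variant(row: Mapping, line_no: Optional[int] = None) -> AnnotatedVariant:
    where = f" (line {line_no})" if line_no is not None else ""
    try:
        pop_af = {}
        for col, src in _AF_COLS.items():
            if row.get(col, "") != "":
                pop_af[src] = float(row[col])
        return AnnotatedVariant(
            chrom=row["chrom"],
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            gene=row.get("gene") or None,
            hgvs_c=row.get("hgvs_c") or None,
            consequence=Consequence(row["consequence"]),
            vaf=float(row["vaf"]) if row.get("vaf", "") != "" else None,
            alt_reads=int(row["alt_reads"]) if row.get("alt_reads", "") != "" else None,
            depth=int(row["depth"]) if row.get("depth", "") != "" else None,
            pop_af=pop_af,
            clinvar=ClinVarClass(row["clinvar"]),
            metalr=PredictorCall(row["metalr"]),
            metasvm=PredictorCall(row["metasvm"]),
            cadd_phred=float(row["cadd_phred"])
            if row.get("cadd_phred", "") != ""
            else None,
            flags=[f for f in row.get("flags", "").split(";") if f],
        )
    except (KeyError, ValueError) as exc:
        raise FormatError(f"bad variant row{where}: {exc}") from exc


def write_variant_table(variants: Iterable[AnnotatedVariant], path) -> None:
    """Write variants as the canonical TSV sidecar (stable column order)."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=VARIANT_COLUMNS, delimiter="\t")
        writer.writeheader()
        for v in variants:
            writer.writerow(variant_to_row(v))


def read_variant_table(path) -> list:
    """Read the canonical TSV sidecar back into :class:`AnnotatedVariant` s.

    Round-trips bit-exactly with :func:`write_variant_table`.
    """
    variants = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "chrom" not in reader.fieldnames:
            raise FormatError(f"{path}: missing variant-table header")
        for i, row in enumerate(reader, start=2):
            variants.append(row_to_variant(row, line_no=i))
    return variants


# ---------------------------------------------------------------------------
# VCF convenience layer

_INFO_ENUMS = {
    "CONSEQUENCE": ("consequence", Consequence),
    "CLINVAR": ("clinvar", ClinVarClass),
    "METALR": ("metalr", PredictorCall),
    "METASVM": ("metasvm", PredictorCall),
}
_INFO_AF = {"AF_1000G": "thousand_genomes", "AF_GNOMAD": "gnomad", "AF_EXAC": "exac"}


def _info_scalar(info, tag, alt_index):
    if tag not in info:
        return None
    value = info[tag]
    if isinstance(value, tuple):
        value = value[alt_index] if alt_index < len(value) else None
    return value


def read_vcf(
    path,
    sample_type: SampleType,
    caller_mode: Optional[CallerMode] = None,
    sample: Optional[str] = None,
) -> SampleTable:
    """Read a VCF into a :class:`SampleTable`.

    Multiallelic records are split into one variant per alt, each trimmed to
    its anchored parsimonious spelling.  VAF evidence is taken from the
    per-sample AD/DP fields, falling back to a FORMAT AF; a record with no
    evidence keeps ``vaf=None`` and is flagged ``no_vaf_evidence`` rather
    than dropped.  Annotations are read from the INFO tags GENE, HGVSC,
    CONSEQUENCE, CLINVAR, METALR, METASVM, CADD_PHRED, AF_1000G, AF_GNOMAD
    and AF_EXAC when present.
    """
    import pysam

    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: unparsable VCF ({exc})") from exc

    sample_names = list(vcf.header.samples)
    if sample is None:
        sample = sample_names[0] if sample_names else None
    elif sample not in sample_names:
        raise InputError(f"{path}: sample {sample!r} not in VCF")

    variants: list = []
    depths: list = []
    for rec_no, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
        try:
            alts = rec.alts or ()
            call = rec.samples[sample] if sample is not None else None
            ad = call.get("AD") if call is not None else None
            dp = call.get("DP") if call is not None else None
            af = call.get("AF") if call is not None else None
            if dp is None and ad is not None and None not in ad:
                dp = sum(ad)
            for i, alt in enumerate(alts):
                if alt is None:
                    continue
                chrom, pos, ref_t, alt_t = trim_anchored(
                    rec.chrom, rec.pos, rec.ref, alt
                )
                alt_reads = None
                vaf = None
                flags = []
                if ad is not None and len(ad) > i + 1 and ad[i + 1] is not None:
                    alt_reads = ad[i + 1]
                if alt_reads is not None and dp:
                    vaf = alt_reads / dp
                elif af is not None:
                    vaf = af[i] if isinstance(af, tuple) else af
                if vaf is None:
                    flags.append("no_vaf_evidence")
                pop_af = {}
                for tag, src in _INFO_AF.items():
                    value = _info_scalar(rec.info, tag, i)
                    if value is not None:
                        pop_af[src] = float(value)
                fields = {}
                for tag, (name, enum_cls) in _INFO_ENUMS.items():
                    value = _info_scalar(rec.info, tag, i)
                    if value is not None:
                        fields[name] = enum_cls(str(value))
                cadd = _info_scalar(rec.info, "CADD_PHRED", i)
                variants.append(
                    AnnotatedVariant(
                        chrom=chrom,
                        pos=pos,
                        ref=ref_t,
                        alt=alt_t,
                        gene=_info_scalar(rec.info, "GENE", i),
                        hgvs_c=_info_scalar(rec.info, "HGVSC", i),
                        vaf=float(vaf) if vaf is not None else None,
                        alt_reads=int(alt_reads) if alt_reads is not None else None,
                        depth=int(dp) if dp else None,
                        pop_af=pop_af,
                        cadd_phred=float(cadd) if cadd is not None else None,
                        flags=flags,
                        **fields,
                    )
                )
            if dp:
                depths.append(dp)
        except (ValueError, KeyError, TypeError) as exc:
            raise FormatError(
                f"{path}: record {rec_no} ({rec.chrom}:{rec.pos}): {exc}"
            ) from exc

    sample_id = sample if sample is not None else Path(str(path)).stem
    return SampleTable(
        sample_id=sample_id,
        patient_id=sample_id,
        sample_type=sample_type,
        caller_mode=caller_mode,
        variants=variants,
        mean_depth=(sum(depths) / len(depths)) if depths else None,
        qc_pass=True,
    )


# ---------------------------------------------------------------------------
# Cohort manifest

_MANIFEST_REQUIRED = [
    "patient_id",
    "group",
    "timing",
    "figo_stage",
    "histology",
    "tumor_path",
    "plasma_path",
]


def _manifest_entry(row: Mapping, base: Path, check_files: bool) -> ManifestEntry:
    pid = str(row.get("patient_id", "")).strip()
    if not pid:
        raise InputError("manifest row without patient_id")
    missing = [c for c in _MANIFEST_REQUIRED if not str(row.get(c, "")).strip()]
    if missing:
        raise InputError(f"patient {pid}: missing manifest columns {missing}")

    def _enum(cls, col):
        raw = str(row[col]).strip()
        try:
            return cls(raw)
        except ValueError:
            raise InputError(
                f"patient {pid}: invalid {col} {raw!r} "
                f"(expected one of {[e.value for e in cls]})"
            ) from None

    group = _enum(Group, "group")
    timing = _enum(Timing, "timing")
    if group == Group.TREATMENT_NAIVE and timing != Timing.DIAGNOSIS:
        raise InputError(
            f"patient {pid}: treatment-naive patients must be sampled at diagnosis"
        )

    def _path(col, required=True):
        raw = str(row.get(col, "") or "").strip()
        if not raw:
            return None
        p = Path(raw)
        if not p.is_absolute():
            p = base / p
        if check_files and not p.exists():
            raise InputError(f"patient {pid}: missing file {p} ({col})")
        return p

    raw_outcome = str(row.get("outcome") or "unknown").strip()
    try:
        outcome = Outcome(raw_outcome)
    except ValueError:
        raise InputError(f"patient {pid}: invalid outcome {raw_outcome!r}") from None
    qc_raw = str(row.get("tumor_qc_pass", "true") or "true").strip().lower()
    return ManifestEntry(
        patient_id=pid,
        group=group,
        timing=timing,
        figo_stage=_enum(FigoStage, "figo_stage"),
        histology=_enum(Histology, "histology"),
        tumor_path=_path("tumor_path"),
        plasma_path=_path("plasma_path"),
        germline_list_path=_path("germline_list_path", required=False),
        outcome=outcome,
        tumor_qc_pass=qc_raw in {"1", "true", "yes"},
    )


def read_manifest(path, check_files: bool = True) -> list:
    """Read a cohort manifest (TSV or YAML) into :class:`ManifestEntry` rows.

    Duplicate patient ids and unknown enum values are rejected; referenced
    files must exist (paths resolve relative to the manifest) unless
    ``check_files`` is off.  An empty manifest is an empty cohort.
    """
    path = Path(path)
    base = path.parent
    rows: Sequence[Mapping]
    if path.suffix in {".yaml", ".yml"}:
        with open(path) as fh:
            data = yaml.safe_load(fh) or []
        if isinstance(data, Mapping):
            data = data.get("patients", [])
        rows = list(data)
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            rows = list(reader)
            if rows and reader.fieldnames and "patient_id" not in reader.fieldnames:
                raise FormatError(f"{path}: missing patient_id column")
    entries = []
    seen = set()
    for row in rows:
        entry = _manifest_entry(row, base, check_files)
        if entry.patient_id in seen:
            raise InputError(f"duplicate patient_id {entry.patient_id}")
        seen.add(entry.patient_id)
        entries.append(entry)
    return entries


def write_manifest(entries: Iterable[ManifestEntry], path) -> None:
    cols = _MANIFEST_REQUIRED + ["germline_list_path", "outcome", "tumor_qc_pass"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols, delimiter="\t")
        writer.writeheader()
        for e in entries:
            writer.writerow(
                {
                    "patient_id": e.patient_id,
                    "group": e.group.value,
                    "timing": e.timing.value,
                    "figo_stage": e.figo_stage.value,
                    "histology": e.histology.value,
                    "tumor_path": str(e.tumor_path),
                    "plasma_path": str(e.plasma_path),
                    "germline_list_path": str(e.germline_list_path or ""),
                    "outcome": e.outcome.value,
                    "tumor_qc_pass": str(e.tumor_qc_pass).lower(),
                }
            )
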