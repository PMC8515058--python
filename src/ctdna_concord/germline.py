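"""Germline/somatic disambiguation of retained variants.

A heterozygous germline variant is carried by essentially every cell, so in
plasma — where total cfDNA is overwhelmingly non-tumor — it appears at a
VAF near 50%, whereas tumor-derived (ctDNA) variants are diluted to low
VAF.  The module flags retained plasma variants inside a configurable VAF
window (default [0.40, 0.60], closed) as *suspected* germline; a suspect
excludes nothing until orthogonally confirmed (e.g. by Sanger on blood),
which enters as a boolean input.  Confirmed suspects and variants on a
patient's prior-study germline list are subtracted from the retained set,
yielding the somatic variants.  Evidence is keyed per (patient, variant
key): the same allele in two patients is independent evidence.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

from .errors import ConfigError, FormatError
from .triage import TriageResult
from .variant_io import (
    AnnotatedVariant,
    VariantKey,
    format_allele,
    normalize_key,
    parse_key,
)

__all__ = [
    "GermlineSource",
    "GermlineEvidence",
    "flag_suspected_germline",
    "exclude_germline",
    "read_germline_list",
    "write_germline_list",
]

DEFAULT_WINDOW = (0.40, 0.60)


class GermlineSource(str, enum.Enum):
    PRIOR_STUDY = "prior_study"
    PLASMA_VAF_WINDOW = "plasma_vaf_window"


@dataclass
class GermlineEvidence:
    """Evidence that a (patient, variant) is germline.

    Only prior-study entries and confirmed window suspects are excluding;
    an unconfirmed suspect is reported but stays somatic pending
    confirmation.
    """

    key: VariantKey
    patient_id: str
    source: GermlineSource
    confirmed: bool = False
    vaf_plasma: Optional[float] = None
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.source == GermlineSource.PLASMA_VAF_WINDOW and self.vaf_plasma is None:
            raise ConfigError("plasma_vaf_window evidence requires vaf_plasma")

    @property
    def excludes(self) -> bool:
        return self.source == GermlineSource.PRIOR_STUDY or self.confirmed


def flag_suspected_germline(
    plasma_result: TriageResult,
    window: Tuple[float, float] = DEFAULT_WINDOW,
) -> list:
    """Flag retained plasma variants whose VAF falls in the germline window.

    The window is a closed interval; suspects are emitted unconfirmed
    (confirmation is an external input).
    """
    low, high = window
    if low >= high:
        raise ConfigError(f"germline window low {low} must be below high {high}")
    evidence = []
    for variant in plasma_result.retained:
        if variant.vaf is not None and low <= variant.vaf <= high:
            evidence.append(
                GermlineEvidence(
                    key=normalize_key(variant),
                    patient_id=plasma_result.patient_id,
                    source=GermlineSource.PLASMA_VAF_WINDOW,
                    confirmed=False,
                    vaf_plasma=variant.vaf,
                    gene=variant.gene,
                )
            )
    return evidence


def exclude_germline(
    retained: Sequence[AnnotatedVariant],
    evidence: Iterable[GermlineEvidence],
    patient_id: str,
) -> tuple:
    """Partition a patient's retained variants into somatic and germline.

    Returns ``(somatic, germline, warnings)``; the two lists are disjoint
    and their union is the input.  Excluding evidence whose key matches no
    retained variant raises only a warning — a germline allele may fall
    outside the panel's calls.  Idempotent.
    """
    excluding = {
        e.key for e in evidence if e.patient_id == patient_id and e.excludes
    }
    somatic, germline = [], []
    seen = set()
    for variant in retained:
        key = normalize_key(variant)
        seen.add(key)
        (germline if key in excluding else somatic).append(variant)
    warnings = [
        f"patient {patient_id}: germline evidence {key.chrom}:{key.pos} "
        f"{key.ref or '-'}>{key.alt or '-'} matches no retained variant"
        for key in sorted(excluding - seen)
    ]
    return somatic, germline, warnings


# ---------------------------------------------------------------------------
# Prior-germline list interchange (TSV)

_GERMLINE_COLUMNS = ["patient_id", "chrom", "pos", "ref", "alt", "gene", "confirmed", "source", "vaf_plasma"]


def read_germline_list(path) -> list:
    """Read a prior-germline TSV into :class:`GermlineEvidence` records."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "patient_id" not in reader.fieldnames:
            raise FormatError(f"{path}: missing germline-list header")
        for i, row in enumerate(reader, start=2):
            try:
                vaf = row.get("vaf_plasma", "")
                records.append(
                    GermlineEvidence(
                        key=parse_key(
                            row["chrom"], int(row["pos"]), row["ref"], row["alt"]
                        ),
                        patient_id=row["patient_id"],
                        source=GermlineSource(row.get("source") or "prior_study"),
                        confirmed=str(row.get("confirmed", "true")).lower()
                        in {"1", "true", "yes"},
                        vaf_plasma=float(vaf) if vaf not in ("", None) else None,
                        gene=row.get("gene") or None,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path} line {i}: {exc}") from exc
    return records


def write_germline_list(records: Iterable[GermlineEvidence], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_GERMLINE_COLUMNS, delimiter="\t")
        writer.writeheader()
        for r in records:
            writer.writerow(
                {
                    "patient_id": r.patient_id,
                    "chrom": r.key.chrom,
                    "pos": r.key.pos,
                    "ref": format_allele(r.key.ref),
                    "alt": format_allele(r.key.alt),
                    "gene": r.gene or "",
                    "confirmed": str(r.confirmed).lower(),
                    "source": r.source.value,
                    "vaf_plasma": "" if r.vaf_plasma is None else repr(r.vaf_plasma),
                }
            )
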