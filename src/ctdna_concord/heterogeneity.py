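"""Reverse analysis: plasma-only variants and clonal relatedness of sites.

Plasma integrates DNA shed by every tumor site, so somatic variants found
in plasma but absent from the index tumor sample point at unsampled sites
(inter-/intra-tumor heterogeneity).  When profiles from additional sites
are available, plasma-only variants are attributed to the sites carrying
them, and two sites sharing a sufficiently improbable combination of
somatic variants (default: at least two) are called clonally related.
Rarity itself is not computed — the verdict is purely count-based.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .concordance import PatientRecord
from .variant_io import VariantKey

__all__ = [
    "Assay",
    "SiteProfile",
    "ClonalityVerdict",
    "plasma_only_variants",
    "clonal_relatedness",
    "attribute_plasma_variants",
]


class Assay(str, enum.Enum):
    NGS_PANEL = "ngs_panel"
    SANGER_TARGETED = "sanger_targeted"


class Verdict(str, enum.Enum):
    CLONALLY_RELATED = "clonally_related"
    INDEPENDENT = "independent"
    INDETERMINATE = "indeterminate"


@dataclass
class SiteProfile:
    """Somatic variants observed at one anatomic site.

    Sanger-targeted profiles are partial: only queried keys carry
    presence/absence, so absence of an unqueried key is unknown, never
    negative.
    """

    patient_id: str
    site: str
    variants: dict  # VariantKey -> vaf (or None for presence-only)
    assay: Assay = Assay.NGS_PANEL

    @property
    def keys(self) -> frozenset:
        return frozenset(self.variants)


@dataclass
class ClonalityVerdict:
    verdict: Verdict
    shared: frozenset
    private_a: frozenset
    private_b: frozenset


def plasma_only_variants(patient: PatientRecord) -> list:
    """Plasma somatic keys absent from the index tumor's somatic set."""
    tumor_keys = {c.key for c in patient.tumor_somatic}
    out = []
    seen = set()
    for call in patient.plasma_somatic:
        if call.key not in tumor_keys and call.key not in seen:
            seen.add(call.key)
            out.append(call.key)
    return out


def clonal_relatedness(
    profile_a: SiteProfile, profile_b: SiteProfile, min_shared: int = 2
) -> ClonalityVerdict:
    """Count-based clonality call for two somatic site profiles.

    ``clonally_related`` when the sites share at least ``min_shared``
    variants; ``independent`` when both are non-empty yet share none;
    otherwise ``indeterminate`` (including any empty profile — a single
    shared hotspot can recur independently, so the default demands two).
    Symmetric in its arguments; private sets flag candidate clonal
    divergence.
    """
    a, b = profile_a.keys, profile_b.keys
    shared = a & b
    if not a or not b:
        verdict = Verdict.INDETERMINATE
    elif len(shared) >= min_shared:
        verdict = Verdict.CLONALLY_RELATED
    elif not shared:
        verdict = Verdict.INDEPENDENT
    else:
        verdict = Verdict.INDETERMINATE
    return ClonalityVerdict(
        verdict=verdict,
        shared=frozenset(shared),
        private_a=frozenset(a - b),
        private_b=frozenset(b - a),
    )


def attribute_plasma_variants(
    patient: PatientRecord, extra_profiles: Sequence[SiteProfile] = ()
) -> dict:
    """Map each plasma-only key to the extra sites containing it.

    Keys found in no supplied profile map to the empty tuple
    ("unattributed").
    """
    attribution = {}
    for key in plasma_only_variants(patient):
        sites = tuple(
            profile.site for profile in extra_profiles if key in profile.variants
        )
        attribution[key] = sites
    return attribution
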