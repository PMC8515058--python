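"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the truth-table
classifier is a flat rule list on plain strings, Kendall's tau is O(n^2)
pair counting, the indel re-speller enumerates padded spellings on an
explicit context, and the conditional detection bias is an exact binomial
enumeration.
"""

from __future__ import annotations

import math
from itertools import combinations


def classify_oracle(clinvar, consequence, metalr, metasvm, cadd, cutoff=20.0):
    """Flat truth table over annotation states -> (verdict, label)."""
    if clinvar in ("pathogenic", "likely_pathogenic"):
        return ("retained", "clinvar_pathogenic")
    if clinvar in ("benign", "likely_benign"):
        return ("discarded", "clinvar_benign")
    if consequence in ("nonsense", "frameshift", "canonical_splice"):
        return ("retained", "truncating_or_splice")
    if consequence == "inframe_indel":
        return ("retained", "inframe_indel")
    if consequence == "missense":
        consensus = (
            metalr == "damaging"
            and metasvm == "damaging"
            and cadd is not None
            and cadd >= cutoff
        )
        if consensus:
            return ("retained", "missense_consensus_damaging")
        return ("discarded", "missense_not_consensus")
    return ("discarded", "unclassifiable")


def kendall_tau_bruteforce(xs, ys):
    """Tau-a by explicit pair counting (no ties expected in inputs)."""
    n = len(xs)
    concordant = discordant = 0
    for i, j in combinations(range(n), 2):
        sx = (xs[i] > xs[j]) - (xs[i] < xs[j])
        sy = (ys[i] > ys[j]) - (ys[i] < ys[j])
        if sx * sy > 0:
            concordant += 1
        elif sx * sy < 0:
            discordant += 1
    return (concordant - discordant) / (n * (n - 1) / 2)


def respellings(context, context_start, pos, ref, alt, max_pad=3):
    """Equivalent padded spellings of (pos, ref, alt) on a context window.

    Pads up to ``max_pad`` shared leading bases (taken from the context,
    moving pos left) and up to ``max_pad`` shared trailing bases (taken
    from the context after the ref allele), in all combinations.
    """
    out = []
    for lead in range(max_pad + 1):
        start = pos - lead
        if start < context_start:
            break
        prefix = context[start - context_start : pos - context_start]
        for trail in range(max_pad + 1):
            end = pos + len(ref) - context_start
            suffix = context[end : end + trail]
            if len(suffix) < trail:
                break
            out.append((start, prefix + ref + suffix, prefix + alt + suffix))
    return out


def binom_pmf(k, n, p):
    return math.comb(n, k) * p**k * (1 - p) ** (n - k)


def conditional_called_vaf_mean(true_vaf, depth, min_alt):
    """E[called VAF | alt reads >= min_alt] by exact enumeration."""
    num = 0.0
    den = 0.0
    for k in range(min_alt, depth + 1):
        w = binom_pmf(k, depth, true_vaf)
        num += (k / depth) * w
        den += w
    return num / den if den > 0 else float("nan")
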