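"""Variant-set comparison between paired tumors.

Identity of a variant across samples is its normalized (chrom, pos, ref, alt)
tuple: redundant padding bases are parsimony-trimmed, and when a reference
sequence is supplied indels are additionally left-aligned, so that different
caller representations of the same event compare equal.  Gene and effect
annotations are ignored for identity.

The sharing percentage between two lesions is
shared / (shared + unique_1 + unique_2); the directional fractions divide the
shared count by each lesion's own total.
"""

from __future__ import annotations

from typing import Callable, Iterable, Mapping, Optional, Union

from .filtering import FilterPolicy, significant_somatic
from .models import SharingResult, SomaticVariant

VariantKey = tuple[str, int, str, str]

ReferenceLookup = Union[
    Mapping[str, str], Callable[[str, int, int], str], None
]


def _ref_slice(reference: ReferenceLookup, chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice of the reference (mapping of full sequences,
    or a callable such as a pyfaidx wrapper)."""
    if reference is None:
        return ""
    if callable(reference):
        return reference(chrom, start, end)
    return str(reference[chrom][start - 1 : end])


def normalize(
    chrom: str, pos: int, ref: str, alt: str, reference: ReferenceLookup = None
) -> VariantKey:
    """Parsimony-trim and (with a reference) left-align an allele pair.

    Standard variant normalization: truncate shared rightmost bases, and when
    an allele empties, extend both alleles leftward with the reference base
    preceding the record — repeated, this left-shifts indels through repeat
    tracts.  Finally shared leading bases are trimmed (advancing ``pos``)
    while both alleles keep at least one base.  Without a reference the
    left-shift is skipped and only parsimony trimming applies.
    """
    ref, alt = ref.upper(), alt.upper()
    if reference is None:
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
    else:
        while ref[-1] == alt[-1]:
            if (len(ref) == 1 or len(alt) == 1) and pos > 1:
                prev = _ref_slice(reference, chrom, pos - 1, pos - 1).upper()
                ref, alt = prev + ref[:-1], prev + alt[:-1]
                pos -= 1
            elif len(ref) > 1 and len(alt) > 1:
                ref, alt = ref[:-1], alt[:-1]
            else:
                break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return (chrom, pos, ref, alt)


def variant_key(
    v: SomaticVariant, reference: ReferenceLookup = None
) -> VariantKey:
    """Canonical identity of a variant call."""
    return normalize(v.chrom, v.pos, v.ref, v.alt, reference)


def compare_pair(
    variants_1: Iterable[SomaticVariant],
    variants_2: Iterable[SomaticVariant],
    policy: Optional[FilterPolicy] = None,
    policy_2: Optional[FilterPolicy] = None,
    sample_id_1: str = "sample_1",
    sample_id_2: str = "sample_2",
    reference: ReferenceLookup = None,
) -> SharingResult:
    """Set algebra over normalized variant keys for a sample pair.

    Both lists must be filtered under the same policy (pass ``policy`` once;
    supplying a different ``policy_2`` is rejected — asymmetric comparisons
    would bias the sharing statistics).  A pair with no variants at all is
    returned with ``sharing_pct`` 0 and the degenerate flag set.
    """
    if policy_2 is not None and policy_2 != policy:
        raise ValueError("both samples of a pair must use the same filter policy")
    v1, v2 = list(variants_1), list(variants_2)
    if policy is not None:
        v1 = significant_somatic(v1, policy)
        v2 = significant_somatic(v2, policy)
    keys_1 = {variant_key(v, reference) for v in v1}
    keys_2 = {variant_key(v, reference) for v in v2}
    shared = keys_1 & keys_2
    return SharingResult(
        sample_id_1=sample_id_1,
        sample_id_2=sample_id_2,
        n_shared=len(shared),
        n_unique_1=len(keys_1 - keys_2),
        n_unique_2=len(keys_2 - keys_1),
        shared_keys=frozenset(shared),
        degenerate=not keys_1 and not keys_2,
    )
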