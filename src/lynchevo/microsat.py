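"""Microsatellite-region scanner and variant-in-repeat annotation.

A microsatellite is a maximal tandem repetition of a 1-5 bp unit with at
least 3 complete units and a total span of at least 5 bases.  Trailing
partial units extend the region (standard repeat-finder behavior) but do not
count toward the unit minimum; counting the partial bases toward the
length minimum is configurable.  Units are canonicalized to their smallest
period, so a poly-A run is reported once (unit A), never additionally as
AA/AAA.  Overlaps between regions of different units are resolved by
priority: longer region first, then smaller unit, then leftmost start.

Coordinates are 0-based half-open (BED convention) on output; variants use
1-based VCF convention on input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .models import SomaticVariant

_VALID = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class MicrosatRegion:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    unit: str
    n_units: int  # complete units only

    @property
    def length(self) -> int:
        return self.end - self.start


def _smallest_period(s: str) -> int:
    n = len(s)
    for period in range(1, n + 1):
        if n % period == 0 and s == s[:period] * (n // period):
            return period
    return n  # pragma: no cover - unreachable


def scan_repeats(
    sequence: str,
    chrom: str = "seq",
    min_unit: int = 1,
    max_unit: int = 5,
    min_units: int = 3,
    min_length: int = 5,
    count_partial_bases: bool = True,
) -> list[MicrosatRegion]:
    """All maximal microsatellite regions of a sequence, ordered by start.

    ``N`` (or any non-ACGT character) never extends a repeat.  When
    ``count_partial_bases`` is false, only complete units count toward the
    ``min_length`` criterion (the reported region still includes the partial
    tail).
    """
    seq = sequence.upper()
    n = len(seq)
    candidates: list[MicrosatRegion] = []
    for k in range(min_unit, max_unit + 1):
        i = 0
        while i + k < n:
            if seq[i] not in _VALID or seq[i] != seq[i + k]:
                i += 1
                continue
            # extend the periodic stretch
            j = i
            while j + k < n and seq[j + k] in _VALID and seq[j] == seq[j + k]:
                j += 1
            # periodic region is [i, j + k)
            start, end = i, j + k
            unit = seq[start : start + k]
            if set(unit) <= _VALID and _smallest_period(unit) == k:
                span = end - start
                complete = span // k
                effective_len = span if count_partial_bases else complete * k
                if complete >= min_units and effective_len >= min_length:
                    candidates.append(
                        MicrosatRegion(chrom, start, end, unit, complete)
                    )
            i = j + 1
    return resolve_overlaps(candidates)


def resolve_overlaps(candidates: Iterable[MicrosatRegion]) -> list[MicrosatRegion]:
    """Greedy selection: longer region wins, ties by smaller unit length,
    then leftmost start; output ordered by start."""
    ranked = sorted(
        candidates, key=lambda r: (-r.length, len(r.unit), r.start)
    )
    kept: list[MicrosatRegion] = []
    for region in ranked:
        if all(
            region.end <= other.start or region.start >= other.end
            or region.chrom != other.chrom
            for other in kept
        ):
            kept.append(region)
    return sorted(kept, key=lambda r: (r.chrom, r.start))


def _affected_interval(variant: SomaticVariant) -> tuple[int, int]:
    """0-based half-open genomic interval touched by a variant call.

    SNVs/MNPs and deletions cover their reference span (anchor included);
    insertions cover the anchor base and the junction base to its right.
    """
    start = variant.pos - 1
    if len(variant.alt) > len(variant.ref):  # insertion
        return start, start + len(variant.ref) + 1
    return start, start + len(variant.ref)


def variant_in_repeat(
    variant: SomaticVariant, regions: Iterable[MicrosatRegion]
) -> bool:
    """True iff the variant's affected interval intersects any region."""
    v_start, v_end = _affected_interval(variant)
    return any(
        r.chrom == variant.chrom and v_start < r.end and r.start < v_end
        for r in regions
    )


def gene_repeat_fraction(
    gene: str,
    variants: Iterable[SomaticVariant],
    regions: Iterable[MicrosatRegion],
) -> Optional[float]:
    """Proportion of a gene's variants that fall in microsatellite regions;
    None (missing) when the gene has no qualifying variants."""
    regions = list(regions)
    in_gene = [v for v in variants if v.gene == gene]
    if not in_gene:
        return None
    n_hit = sum(1 for v in in_gene if variant_in_repeat(v, regions))
    return n_hit / len(in_gene)


def write_bed(regions: Iterable[MicrosatRegion], path) -> None:
    """BED (0-based half-open): chrom, start, end, unit, n_units."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.unit}\t{r.n_units}\n")


def scan_fasta(path, **kwargs) -> list[MicrosatRegion]:
    """Scan every record of a FASTA file (via pyfaidx)."""
    from pyfaidx import Fasta

    regions: list[MicrosatRegion] = []
    fasta = Fasta(str(path))
    try:
        for name in fasta.keys():
            regions.extend(scan_repeats(str(fasta[name][:]), chrom=name, **kwargs))
    finally:
        fasta.close()
    return regions
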