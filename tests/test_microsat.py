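"""Microsatellite scanner vs a regex brute-force oracle; repeat annotation."""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_variant
from lynchevo.microsat import (
    MicrosatRegion,
    gene_repeat_fraction,
    resolve_overlaps,
    scan_repeats,
    variant_in_repeat,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def oracle_scan(seq, chrom="seq", min_units=3, min_length=5):
    """Regex enumeration of every primitive unit and start position."""
    candidates = set()
    n = len(seq)
    for k in range(1, 6):
        for start in range(n - k):
            unit = seq[start : start + k]
            if not set(unit) <= set("ACGT"):
                continue
            if any(
                len(unit) % p == 0 and unit == unit[: p] * (len(unit) // p)
                for p in range(1, len(unit))
            ):
                continue  # non-primitive unit
            m = re.match(f"(?:{re.escape(unit)})+", seq[start:])
            complete = len(m.group(0)) // k
            # extend with the trailing partial unit
            end = start + complete * k
            partial = 0
            while end + partial < n and seq[end + partial] == unit[partial % k]:
                partial += 1
            span = complete * k + partial
            if complete >= min_units and span >= min_length:
                # keep only maximal stretches: drop if extendable to the left
                if start >= 1 and seq[start - 1] == unit[(k - 1) % k] and \
                        seq[start - 1] == seq[start - 1 + k]:
                    continue
                candidates.add(
                    MicrosatRegion(chrom, start, start + span, unit, complete)
                )
    return resolve_overlaps(candidates)


class TestScanRepeats:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAAA", [("A", 0, 5, 5)]),        # 5 units, length 5: boundary
            ("ATATAT", [("AT", 0, 6, 3)]),      # 3 units, length 6: boundary
            ("AAAA", []),                        # length 4 < 5
            ("ACGACG", []),                      # 2 units < 3
            ("", []),
        ],
    )
    def test_rule_boundaries(self, seq, expected):
        got = [(r.unit, r.start, r.end, r.n_units) for r in scan_repeats(seq)]
        assert got == expected

    def test_trailing_partial_unit_extends_region(self):
        # CAGCAGCAGCA: 3 complete CAG units plus partial 'CA'
        (r,) = scan_repeats("CAGCAGCAGCA")
        assert (r.unit, r.start, r.end, r.n_units) == ("CAG", 0, 11, 3)

    def test_partial_bases_can_be_excluded_from_length(self):
        # 3 complete AC units = 6 bases -> passes either way; 2+partial fails
        assert scan_repeats("GACACACAG", count_partial_bases=False)
        (r,) = scan_repeats("GACACACAG")
        assert r.n_units == 3

    def test_n_never_extends_a_repeat(self):
        assert scan_repeats("AANAAA") == []
        (r,) = scan_repeats("AANAAAAA")
        assert (r.start, r.end) == (3, 8)

    def test_smallest_period_reported_once(self):
        regions = scan_repeats("AAAAAA")
        assert len(regions) == 1 and regions[0].unit == "A"

    @settings(max_examples=150, deadline=None)
    @given(st.integers(0, 10_000))
    def test_equivalence_with_regex_oracle_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(10, 300))
        # AT-rich alphabet raises repeat density; occasional N
        seq = "".join(
            rng.choice(list("ACGTATN"), size=length, p=[.2, .1, .1, .2, .2, .15, .05])
        )
        assert scan_repeats(seq) == oracle_scan(seq)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 10_000))
    def test_reverse_complement_invariance(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(10, 200))
        seq = "".join(rng.choice(list("ACGT"), size=length, p=[.3, .2, .2, .3]))
        rc = seq.translate(_COMPLEMENT)[::-1]
        forward = scan_repeats(seq)
        mirrored = {
            (length - r.end, length - r.start, r.length) for r in scan_repeats(rc)
        }
        assert {(r.start, r.end, r.length) for r in forward} == mirrored


class TestVariantInRepeat:
    REGIONS = [MicrosatRegion("chr1", 100, 108, "A", 8)]  # A8 run, 0-based

    def test_snv_inside_run(self):
        v = make_variant(pos=105, ref="A", alt="T")
        assert variant_in_repeat(v, self.REGIONS)

    def test_snv_one_bp_past_half_open_end(self):
        v = make_variant(pos=109, ref="C", alt="T")  # 0-based 108 == end
        assert not variant_in_repeat(v, self.REGIONS)

    def test_deletion_anchored_on_base_before_run(self):
        # anchor at 1-based 100 (0-based 99, outside), deleted base inside
        v = make_variant(pos=100, ref="CA", alt="C")
        assert variant_in_repeat(v, self.REGIONS)

    def test_insertion_at_run_boundary(self):
        v = make_variant(pos=100, ref="C", alt="CA")
        assert variant_in_repeat(v, self.REGIONS)

    def test_other_chromosome_never_hits(self):
        v = make_variant(chrom="chr2", pos=105, ref="A", alt="T")
        assert not variant_in_repeat(v, self.REGIONS)


class TestGeneRepeatFraction:
    def test_no_variant_in_repeat(self):
        variants = [make_variant(gene="PIK3CA", pos=500 + i) for i in range(4)]
        assert gene_repeat_fraction("PIK3CA", variants, self_regions()) == 0.0

    def test_all_in_repeat(self):
        variants = [
            make_variant(gene="BAX", pos=101 + i, ref="A", alt="T")
            for i in range(5)
        ]
        assert gene_repeat_fraction("BAX", variants, self_regions()) == 1.0

    def test_synthetic_placement_matches_construction(self):
        regions = self_regions()
        inside = [make_variant(gene="G", pos=103 + i, ref="A", alt="T")
                  for i in range(3)]
        outside = [make_variant(gene="G", pos=900 + i) for i in range(7)]
        frac = gene_repeat_fraction("G", inside + outside, regions)
        assert frac == pytest.approx(0.3)

    def test_missing_when_denominator_zero(self):
        assert gene_repeat_fraction("G", [], self_regions()) is None


def self_regions():
    return [MicrosatRegion("chr1", 100, 108, "A", 8)]
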