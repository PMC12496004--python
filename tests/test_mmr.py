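"""MSI calling, MMR classification, LOH ratios, second-hit calling."""

import pytest

from conftest import make_patient, make_sample, make_variant
from lynchevo.mmr import (
    LOHCall,
    LOHResult,
    LOHThresholds,
    NotEvaluableError,
    call_msi,
    call_second_hits,
    classify_loh,
    classify_mmr,
    loh_ratio,
    mutual_exclusivity,
)
from lynchevo.models import IHCStatus, SecondHitMechanism


class TestMsi:
    @pytest.mark.parametrize(
        "deviations,msi",
        [
            ({"BAT25": 0, "BAT26": 3}, True),
            ({"BAT25": 1, "BAT26": 1}, False),
            ({"BAT25": 2, "BAT26": None}, True),  # boundary, one missing
        ],
    )
    def test_two_nt_rule(self, deviations, msi):
        assert call_msi(deviations).msi is msi

    def test_all_markers_missing_not_evaluable(self):
        with pytest.raises(NotEvaluableError):
            call_msi({"BAT25": None, "BAT26": None})


class TestClassifyMmr:
    @pytest.mark.parametrize(
        "dev,ihc,expected",
        [
            ({"BAT26": 0}, IHCStatus.loss, "dMMR"),
            ({"BAT26": 0}, IHCStatus.retained, "pMMR"),
            ({"BAT26": 5}, IHCStatus.not_done, "dMMR"),
            ({"BAT26": 0}, IHCStatus.not_done, "pMMR"),
        ],
    )
    def test_msi_or_ihc_definition(self, dev, ihc, expected):
        assert classify_mmr(call_msi(dev), ihc).value == expected

    def test_no_evidence_at_all(self):
        assert classify_mmr(None, IHCStatus.not_done).value == "not_evaluable"


class TestLohRatio:
    @pytest.mark.parametrize(
        "counts,expected",
        [((50, 50, 50, 50), 1.0), ((80, 20, 50, 50), 4.0),
         ((20, 80, 50, 50), 0.25)],
    )
    def test_hand_computed_ratios(self, counts, expected):
        assert loh_ratio(*counts) == pytest.approx(expected)

    def test_homozygous_normal_not_informative(self):
        assert loh_ratio(50, 50, 0, 0) is None
        assert classify_loh(None).call == LOHCall.not_informative

    def test_zero_counts_get_pseudocount(self):
        # (80.5/0.5)/(50.5/50.5) = 161, finite and strongly LOH
        ratio = loh_ratio(80, 0, 50, 50)
        assert ratio == pytest.approx(161.0)


class TestClassifyLoh:
    @pytest.mark.parametrize(
        "ratio,call,wildtype_lost",
        [
            (4.0, LOHCall.LOH, True),
            (2.0, LOHCall.LOH, True),
            (1.7, LOHCall.pLOH, True),
            (1.0, LOHCall.none, False),
            (0.25, LOHCall.LOH, False),   # mutant-allele loss: recorded,
            (0.6, LOHCall.pLOH, False),   # never a second hit
        ],
    )
    def test_threshold_bands(self, ratio, call, wildtype_lost):
        res = classify_loh(ratio)
        assert (res.call, res.wildtype_lost) == (call, wildtype_lost)

    def test_misordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            LOHThresholds(strict_upper=1.2, putative_upper=1.5)

    def test_never_both_loh_and_ploh(self):
        for ratio in [0.1 * i for i in range(1, 60)]:
            assert classify_loh(ratio).call in set(LOHCall)


def _three_lesion_patient(vafs, gene="MLH1"):
    samples = [
        make_sample("P1_CAH", "CAH", timepoint=-1),
        make_sample("P1_EEC", "EEC"),
        make_sample("P1_EOC", "EOC"),
    ]
    tables = {
        s.sample_id: [
            make_variant(chrom="chr3", pos=37000000, ref="C", alt="T",
                         gene=gene, effect="nonsense", vaf=vaf)
        ]
        for s, vaf in zip(samples, vafs)
    }
    return make_patient(samples, tables)


class TestCallSecondHits:
    def test_same_variant_called_in_every_lesion(self):
        patient = _three_lesion_patient([0.26, 0.21, 0.24])
        calls = {c.sample_id: c for c in call_second_hits(patient)}
        assert len(calls) == 3
        for c in calls.values():
            assert c.mechanisms == {SecondHitMechanism.somatic_variant}
            assert not c.variants[0].sub_threshold

    def test_sub_threshold_occurrence_rescued_by_anchor(self):
        patient = _three_lesion_patient([0.02, 0.07, 0.0])
        # drop the zero-VAF occurrence entirely
        patient.variant_tables["P1_EOC"] = []
        calls = {c.sample_id: c for c in call_second_hits(patient)}
        assert calls["P1_EEC"].variants[0].sub_threshold is False
        rescued = calls["P1_CAH"].variants[0]
        assert rescued.sub_threshold is True and rescued.vaf == 0.02
        assert calls["P1_CAH"].any_hit
        assert not calls["P1_EOC"].any_hit

    def test_no_anchor_means_no_rescue(self):
        patient = _three_lesion_patient([0.02, 0.04, 0.03])
        calls = call_second_hits(patient)
        assert all(not c.any_hit for c in calls)

    def test_loh_only_sample(self):
        patient = make_patient([make_sample("P1_EEC", "EEC")],
                               {"P1_EEC": []})
        loh = {"P1_EEC": LOHResult(4.0, LOHCall.LOH, True)}
        (call,) = call_second_hits(patient, loh_results=loh)
        assert call.mechanisms == {SecondHitMechanism.LOH}
        assert call.variants == []

    def test_mutant_allele_loss_is_not_a_second_hit(self):
        patient = make_patient([make_sample("P1_EEC", "EEC")],
                               {"P1_EEC": []})
        loh = {"P1_EEC": LOHResult(0.2, LOHCall.LOH, False)}
        (call,) = call_second_hits(patient, loh_results=loh)
        assert not call.any_hit

    def test_order_invariance(self):
        patient = _three_lesion_patient([0.02, 0.07, 0.24])
        reversed_patient = make_patient(
            list(reversed(patient.samples)),
            dict(reversed(list(patient.variant_tables.items()))),
        )
        a = {(c.sample_id, frozenset(c.mechanisms))
             for c in call_second_hits(patient)}
        b = {(c.sample_id, frozenset(c.mechanisms))
             for c in call_second_hits(reversed_patient)}
        assert a == b

    def test_gene_absent_from_panel_errors(self):
        patient = _three_lesion_patient([0.2, 0.2, 0.2])
        with pytest.raises(ValueError, match="absent"):
            call_second_hits(patient, panel_genes={"PTEN", "TP53"})


class TestMutualExclusivity:
    def test_fixture_mechanisms_are_mutually_exclusive(self, cohort):
        pairs = [
            (row.loh in ("LOH", "pLOH"),
             any(not h.sub_threshold for h in row.second_hits))
            for row in cohort.itertuples()
        ]
        table, p = mutual_exclusivity(pairs)
        # one doubly-hit sample; 36 somatic-variant samples in total
        assert table[0][0] == 1
        assert table[0][0] + table[1][0] == 36
        assert sum(map(sum, table)) == 64
        assert p < 0.001

    def test_degenerate_margin_gives_p_one(self):
        # nobody carries LOH: the table has a zero margin, no association
        # is testable and p is 1 by convention
        pairs = [(False, True)] * 6 + [(False, False)] * 4
        table, p = mutual_exclusivity(pairs)
        assert table == [[0, 0], [6, 4]]
        assert p == 1.0

    def test_independent_mechanisms_give_uniformish_p(self):
        # simulated independence: p spread over (0,1], not stacked near 0
        import numpy as np

        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            pairs = zip(rng.random(60) < 0.3, rng.random(60) < 0.5)
            ps.append(mutual_exclusivity(pairs)[1])
        assert np.mean(np.asarray(ps) < 0.05) < 0.10
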