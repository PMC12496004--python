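"""Trajectory construction rules, normal-tissue probing, diagram export."""

import warnings

import pytest

from conftest import make_patient, make_sample, make_variant
from lynchevo.sharing import compare_pair
from lynchevo.trajectory import (
    CosmicGeneSets,
    GeneSetClass,
    build_trajectories,
    export_diagram,
    probe_normals,
    vaf_bin,
)

COSMIC = CosmicGeneSets({"EEC": ("PTEN", "ARID1A", "PIK3CA")})


def _patient(tables):
    samples = [
        make_sample("P1_NE", "NE", timepoint=-4),
        make_sample("P1_CAH1", "CAH", timepoint=-3),
        make_sample("P1_CAH2", "CAH", timepoint=0),
        make_sample("P1_EEC", "EEC", timepoint=0),
    ]
    return make_patient(samples, tables)


def v_at(pos, gene="PTEN", vaf=0.24, **kw):
    return make_variant(pos=pos, gene=gene, vaf=vaf, **kw)


class TestInclusionRules:
    def test_cosmic_gene_needs_one_hyperplasia(self):
        patient = _patient({
            "P1_EEC": [v_at(10)], "P1_CAH1": [v_at(10)], "P1_CAH2": [],
        })
        (ev,) = build_trajectories(patient, COSMIC)
        assert ev.gene_set == GeneSetClass.COSMIC_top20
        assert set(ev.presence) == {"P1_EEC", "P1_CAH1"}

    def test_non_cosmic_gene_needs_two_hyperplasias(self):
        one = _patient({
            "P1_EEC": [v_at(10, gene="OTHER")],
            "P1_CAH1": [v_at(10, gene="OTHER")],
            "P1_CAH2": [],
        })
        assert build_trajectories(one, COSMIC) == []
        two = _patient({
            "P1_EEC": [v_at(10, gene="OTHER")],
            "P1_CAH1": [v_at(10, gene="OTHER")],
            "P1_CAH2": [v_at(10, gene="OTHER")],
        })
        (ev,) = build_trajectories(two, COSMIC)
        assert ev.gene_set == GeneSetClass.other_panel

    def test_variant_absent_from_carcinoma_never_listed(self):
        patient = _patient({
            "P1_EEC": [],
            "P1_CAH1": [v_at(10)], "P1_CAH2": [v_at(10)],
        })
        assert build_trajectories(patient, COSMIC) == []

    def test_every_event_is_called_in_a_carcinoma(self):
        patient = _patient({
            "P1_EEC": [v_at(10), v_at(20, gene="OTHER")],
            "P1_CAH1": [v_at(10), v_at(20, gene="OTHER")],
            "P1_CAH2": [v_at(20, gene="OTHER")],
        })
        for ev in build_trajectories(patient, COSMIC):
            assert ev.presence["P1_EEC"].status == "called"

    def test_mmr_second_hit_always_traced_with_rule_flag(self):
        patient = _patient({
            "P1_EEC": [v_at(99, gene="MLH1", effect="nonsense", vaf=0.07)],
            "P1_CAH1": [v_at(99, gene="MLH1", effect="nonsense", vaf=0.02)],
            "P1_CAH2": [],
        })
        (ev,) = build_trajectories(patient, COSMIC)
        assert ev.gene_set == GeneSetClass.MMR_second_hit
        assert ev.rule_satisfied  # shared with >= 1 hyperplasia
        assert ev.presence["P1_CAH1"].vaf == 0.02  # sub-threshold kept

    def test_removing_a_hyperplasia_never_adds_events(self):
        tables = {
            "P1_EEC": [v_at(10), v_at(20, gene="OTHER")],
            "P1_CAH1": [v_at(10), v_at(20, gene="OTHER")],
            "P1_CAH2": [v_at(20, gene="OTHER")],
        }
        full = {e.key for e in build_trajectories(_patient(tables), COSMIC)}
        reduced_tables = {k: v for k, v in tables.items() if k != "P1_CAH2"}
        reduced_patient = make_patient(
            [s for s in _patient({}).samples if s.sample_id != "P1_CAH2"],
            reduced_tables,
        )
        reduced = {e.key for e in build_trajectories(reduced_patient, COSMIC)}
        assert reduced <= full

    def test_no_carcinoma_warns_and_returns_empty(self):
        patient = make_patient(
            [make_sample("P1_CAH1", "CAH")], {"P1_CAH1": [v_at(10)]}
        )
        with pytest.warns(UserWarning, match="no carcinoma"):
            assert build_trajectories(patient, COSMIC) == []

    def test_empty_gene_sets_warn_loudly(self):
        with pytest.warns(UserWarning, match="empty"):
            CosmicGeneSets({})


class TestProbeNormals:
    def test_low_level_presence_statuses(self):
        patient = _patient({
            "P1_EEC": [v_at(10)], "P1_CAH1": [v_at(10)], "P1_CAH2": [],
        })
        events = build_trajectories(patient, COSMIC)
        reads = {
            ("P1_NE", ("chr1", 10, "C", "T")): (8, 400),
        }
        probed = probe_normals(
            events, patient.samples, lambda sid, key: reads.get((sid, key))
        )
        entry = probed[0].presence["P1_NE"]
        assert entry.status == "probed_present"
        assert entry.vaf == pytest.approx(0.02)

    def test_absent_and_no_coverage(self):
        patient = _patient({
            "P1_EEC": [v_at(10), v_at(30)],
            "P1_CAH1": [v_at(10), v_at(30)], "P1_CAH2": [],
        })
        events = build_trajectories(patient, COSMIC)
        reads = {("P1_NE", ("chr1", 10, "C", "T")): (3, 600)}
        probed = probe_normals(
            events, patient.samples, lambda sid, key: reads.get((sid, key))
        )
        by_key = {e.key: e for e in probed}
        assert by_key[("chr1", 10, "C", "T")].presence["P1_NE"].status == \
            "probed_absent"
        assert by_key[("chr1", 30, "C", "T")].presence["P1_NE"].status == \
            "no_coverage"

    def test_blood_never_probed(self):
        samples = [make_sample("P1_B", "B"), make_sample("P1_EEC", "EEC"),
                   make_sample("P1_CAH1", "CAH")]
        patient = make_patient(samples, {
            "P1_EEC": [v_at(10)], "P1_CAH1": [v_at(10)],
        })
        events = build_trajectories(patient, COSMIC)
        probed = probe_normals(events, samples, lambda sid, key: (50, 100))
        assert "P1_B" not in probed[0].presence


class TestVafBin:
    @pytest.mark.parametrize(
        "vaf,label",
        [(0.24, "15-30%"), (0.02, "<5%"), (0.0, "<5%"),
         (0.07, "5-15%"), (0.5, ">30%")],
    )
    def test_default_bins(self, vaf, label):
        assert vaf_bin(vaf) == label


class TestExportDiagram:
    def _patient_with_events(self):
        tables = {
            "P1_EEC": [v_at(10), v_at(40, gene="OTHER")],
            "P1_CAH1": [v_at(10)],
            "P1_CAH2": [v_at(40, gene="OTHER")],
        }
        return _patient(tables)

    def test_samples_ordered_by_timepoint_then_id(self):
        patient = self._patient_with_events()
        doc = export_diagram(patient, build_trajectories(patient, COSMIC))
        assert [s["sample_id"] for s in doc["samples"]] == [
            "P1_CAH1", "P1_CAH2", "P1_EEC"
        ]

    def test_empty_event_list_still_describes_samples(self):
        patient = self._patient_with_events()
        doc = export_diagram(patient, [])
        assert doc["events"] == [] and len(doc["samples"]) == 3

    def test_pair_counts_equal_brute_force_intersections(self):
        patient = self._patient_with_events()
        doc = export_diagram(patient, build_trajectories(patient, COSMIC))
        for entry in doc["pairwise_shared_counts"]:
            res = compare_pair(
                patient.variant_tables.get(entry["sample_1"], []),
                patient.variant_tables.get(entry["sample_2"], []),
            )
            assert entry["n_shared"] == res.n_shared
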