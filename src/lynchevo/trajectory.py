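"""Chronological shared-variant trajectories within one patient.

For each patient with at least one carcinoma and one hyperplasia specimen,
variants are traced across the specimen series ordered by timepoint:

* somatic second-hit variants of the predisposing MMR gene are always traced;
* variants in the histology-specific top-20 driver gene set (configured, see
  :class:`CosmicGeneSets`) require sharing between the carcinoma and at least
  one hyperplasia sample;
* variants of other panel genes require sharing between the carcinoma and at
  least two hyperplasia samples.

Histologically normal samples are then probed at the event sites with the
low-level presence rule (>= 5 supporting reads and >= 1% VAF); blood — the
calling reference — is never probed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Mapping, Optional

import yaml

from .filtering import FilterPolicy, ProbeStatus, probe_low_level, significant_somatic
from .models import EffectClass, PatientRecord, SampleRecord, SomaticVariant
from .sharing import ReferenceLookup, VariantKey, compare_pair, variant_key

#: Default VAF display bins (upper edges, fractions).  The binning is a
#: reporting convention of this package, not a quantity estimated from data;
#: exact VAFs are carried alongside for sub-5% and probed normal-tissue values.
DEFAULT_VAF_BINS: tuple[float, ...] = (0.05, 0.15, 0.30)


def vaf_bin(vaf: float, bins: tuple[float, ...] = DEFAULT_VAF_BINS) -> str:
    """Map a VAF to its display bin label (e.g. '<5%', '5-15%', '>30%')."""
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf must lie in [0,1], got {vaf}")
    edges = sorted(bins)
    if vaf < edges[0]:
        return f"<{edges[0]:.0%}"
    for lo, hi in zip(edges, edges[1:]):
        if vaf < hi:
            return f"{lo:.0%}-{hi:.0%}".replace("%-", "-")
    return f">{edges[-1]:.0%}"


class GeneSetClass(str, Enum):
    MMR_second_hit = "MMR_second_hit"
    COSMIC_top20 = "COSMIC_top20"
    other_panel = "other_panel"


@dataclass
class CosmicGeneSets:
    """Histology-specific frequently-mutated driver gene lists.

    The study consulted the top-20 genes per carcinoma histology from the
    COSMIC database; those lists are supplementary/versioned content and are
    therefore supplied as configuration, not shipped.  The default is empty,
    with a loud warning, so that results are reproducible only from explicit
    configuration.
    """

    sets: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for histology, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate genes in set for {histology!r}")
        if not self.sets:
            warnings.warn(
                "CosmicGeneSets is empty: no histology-specific driver genes "
                "configured; only MMR second-hit and other-panel rules apply",
                stacklevel=2,
            )

    @classmethod
    def from_yaml(cls, path) -> "CosmicGeneSets":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls({h: tuple(genes) for h, genes in raw.items()})

    def genes_for(self, histology: str) -> frozenset[str]:
        return frozenset(self.sets.get(histology, ()))


@dataclass
class PresenceEntry:
    status: str  # called / probed_present / probed_absent / no_coverage
    vaf: Optional[float] = None
    vaf_bin: Optional[str] = None


@dataclass
class TrajectoryEvent:
    patient_id: str
    key: VariantKey
    gene: str
    effect_class: EffectClass
    gene_set: GeneSetClass
    rule_satisfied: bool
    presence: dict[str, PresenceEntry] = field(default_factory=dict)


#: (sample_id, variant key) -> (alt_reads, total_reads), or None if the site
#: has no read-level data for that sample.
NormalReadLookup = Callable[[str, VariantKey], Optional[tuple[int, int]]]


def build_trajectories(
    patient: PatientRecord,
    cosmic: CosmicGeneSets,
    policy: FilterPolicy = FilterPolicy(),
    reference: ReferenceLookup = None,
) -> list[TrajectoryEvent]:
    """Trace shared variants across a patient's specimen series.

    Returns one event per qualifying variant with per-sample presence and
    VAF.  A patient without a carcinoma sample yields an empty list with a
    warning.  Second-hit variants of the predisposing MMR gene are always
    traced; their sharing-rule satisfaction is flagged separately.
    """
    carcinomas = [s for s in patient.neoplastic_samples
                  if s.tissue_class.value == "carcinoma"]
    hyperplasias = [s for s in patient.neoplastic_samples
                    if s.tissue_class.value != "carcinoma"]
    if not carcinomas:
        warnings.warn(
            f"{patient.patient_id}: no carcinoma sample; no trajectories built",
            stacklevel=2,
        )
        return []

    filtered: dict[str, dict[VariantKey, SomaticVariant]] = {}
    for s in patient.neoplastic_samples:
        table = patient.variant_tables.get(s.sample_id, [])
        filtered[s.sample_id] = {
            variant_key(v, reference): v
            for v in significant_somatic(table, policy)
        }
    # sub-threshold occurrences of MMR second-hit variants stay visible
    relaxed = FilterPolicy(
        p_max=policy.p_max, vaf_min=0.0, require_pass=policy.require_pass,
        nonsynonymous_only=policy.nonsynonymous_only,
    )
    mmr_gene = patient.predisposing_gene.value
    mmr_occurrences: dict[str, dict[VariantKey, SomaticVariant]] = {}
    for s in patient.neoplastic_samples:
        table = patient.variant_tables.get(s.sample_id, [])
        mmr_occurrences[s.sample_id] = {
            variant_key(v, reference): v
            for v in significant_somatic(table, relaxed)
            if v.gene == mmr_gene
        }

    cosmic_genes: frozenset[str] = frozenset().union(
        *(cosmic.genes_for(c.histology.value) for c in carcinomas)
    ) if carcinomas else frozenset()

    events: dict[VariantKey, TrajectoryEvent] = {}

    def event_for(key: VariantKey, v: SomaticVariant,
                  gene_set: GeneSetClass, rule_ok: bool) -> TrajectoryEvent:
        ev = events.get(key)
        if ev is None:
            ev = TrajectoryEvent(
                patient_id=patient.patient_id, key=key, gene=v.gene,
                effect_class=v.effect_class, gene_set=gene_set,
                rule_satisfied=rule_ok,
            )
            events[key] = ev
        return ev

    all_keys = set()
    for table in filtered.values():
        all_keys |= table.keys()
    for key in sorted(all_keys):
        in_carcinoma = [c for c in carcinomas if key in filtered[c.sample_id]]
        if not in_carcinoma:
            continue
        n_hyper = sum(1 for h in hyperplasias if key in filtered[h.sample_id])
        v = filtered[in_carcinoma[0].sample_id][key]
        if v.gene == mmr_gene:
            continue  # handled below with the relaxed rule
        if v.gene in cosmic_genes:
            if n_hyper >= 1:
                event_for(key, v, GeneSetClass.COSMIC_top20, True)
        else:
            if n_hyper >= 2:
                event_for(key, v, GeneSetClass.other_panel, True)

    # MMR second-hit variants: always traced, rule satisfaction flagged
    mmr_keys = set()
    for table in mmr_occurrences.values():
        mmr_keys |= table.keys()
    anchored = {
        key for key in mmr_keys
        if any(policy.vaf_passes(t[key].vaf)
               for t in mmr_occurrences.values() if key in t)
    }
    for key in sorted(anchored):
        v = next(t[key] for t in mmr_occurrences.values() if key in t)
        in_carc = any(key in mmr_occurrences[c.sample_id] for c in carcinomas)
        n_hyper = sum(1 for h in hyperplasias if key in mmr_occurrences[h.sample_id])
        event_for(key, v, GeneSetClass.MMR_second_hit,
                  rule_ok=in_carc and n_hyper >= 1)

    ordered_samples = _chronological(patient.neoplastic_samples)
    for ev in events.values():
        source = (mmr_occurrences if ev.gene_set == GeneSetClass.MMR_second_hit
                  else filtered)
        for s in ordered_samples:
            v = source[s.sample_id].get(ev.key)
            if v is not None:
                ev.presence[s.sample_id] = PresenceEntry(
                    status="called", vaf=v.vaf, vaf_bin=vaf_bin(v.vaf)
                )
    return sorted(events.values(), key=lambda e: e.key)


def probe_normals(
    events: Iterable[TrajectoryEvent],
    normal_samples: Iterable[SampleRecord],
    normal_read_lookup: NormalReadLookup,
) -> list[TrajectoryEvent]:
    """Annotate events with low-level presence in normal-tissue samples.

    Blood is the calling reference and is never probed; samples without
    read-level data at a site get the no-coverage status.
    """
    normals = [s for s in normal_samples if s.is_normal_tissue]
    events = list(events)
    for ev in events:
        for s in normals:
            reads = normal_read_lookup(s.sample_id, ev.key)
            if reads is None:
                ev.presence[s.sample_id] = PresenceEntry(status="no_coverage")
                continue
            alt, total = reads
            verdict = probe_low_level(alt, total)
            if verdict.status == ProbeStatus.no_coverage:
                ev.presence[s.sample_id] = PresenceEntry(status="no_coverage")
            elif verdict.status == ProbeStatus.present:
                ev.presence[s.sample_id] = PresenceEntry(
                    status="probed_present", vaf=verdict.vaf,
                    vaf_bin=vaf_bin(verdict.vaf),
                )
            else:
                ev.presence[s.sample_id] = PresenceEntry(
                    status="probed_absent", vaf=verdict.vaf
                )
    return events


def _chronological(samples: Iterable[SampleRecord]) -> list[SampleRecord]:
    """Most negative timepoint first; ties broken by sample id."""
    return sorted(samples, key=lambda s: (s.timepoint_years, s.sample_id))


def export_diagram(
    patient: PatientRecord,
    events: Iterable[TrajectoryEvent],
    policy: Optional[FilterPolicy] = None,
    reference: ReferenceLookup = None,
) -> dict:
    """Machine-readable chronological diagram for one patient.

    Samples are ordered by timepoint (most negative first, ties by sample
    id); each event row carries per-sample status/VAF/bin; pairwise total
    shared-variant counts between neoplastic samples are included (the
    "numbers next to the dots").
    """
    ordered = _chronological(patient.neoplastic_samples)
    pair_counts = []
    for i, s1 in enumerate(ordered):
        for s2 in ordered[i + 1:]:
            res = compare_pair(
                patient.variant_tables.get(s1.sample_id, []),
                patient.variant_tables.get(s2.sample_id, []),
                policy=policy,
                sample_id_1=s1.sample_id,
                sample_id_2=s2.sample_id,
                reference=reference,
            )
            pair_counts.append(
                {"sample_1": s1.sample_id, "sample_2": s2.sample_id,
                 "n_shared": res.n_shared}
            )
    return {
        "patient_id": patient.patient_id,
        "predisposing_gene": patient.predisposing_gene.value,
        "samples": [
            {"sample_id": s.sample_id, "histology": s.histology.value,
             "timepoint_years": s.timepoint_years}
            for s in ordered
        ],
        "events": [
            {
                "key": {"chrom": ev.key[0], "pos": ev.key[1],
                        "ref": ev.key[2], "alt": ev.key[3]},
                "gene": ev.gene,
                "effect": ev.effect_class.value,
                "gene_set": ev.gene_set.value,
                "rule_satisfied": ev.rule_satisfied,
                "presence": {
                    sid: {"status": p.status, "vaf": p.vaf, "vaf_bin": p.vaf_bin}
                    for sid, p in ev.presence.items()
                },
            }
            for ev in events
        ],
        "pairwise_shared_counts": pair_counts,
    }
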