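"""Synthetic MMR-deficient tumor-cohort generator.

Emulates the statistical structure of a Lynch-syndrome gynecological tumor
series so every analysis stage is testable without any external download:

* a heterozygous germline pathogenic MMR-gene variant per patient;
* hypermutator mutation accumulation on a targeted panel (per-lesion counts
  Poisson with rate x panel size; hypermutators vs non-hypermutators);
* truncal sharing between consecutive lesions of one patient — a truncal
  variant set carried by every lesion plus private sets per lesion.  The
  truncal fraction ``xi_sim`` is the expected fraction of a lesion's
  variants that are truncal, so the directional sharing fraction of a lesion
  pair estimates it directly (the symmetric sharing percentage converges to
  ``xi/(2-xi)``);
* a second hit per lesion: loss of heterozygosity (allelic-depth shift at
  the germline site: with tumor purity phi the pathogenic-allele fraction
  rises to 1/(2-phi)) or a clonal somatic MMR-gene variant;
* microsatellite-biased frameshifts: frameshift indels land inside a repeat
  tract of the gene's synthetic sequence with configurable probability;
* binomial read sampling of VAFs (true VAF = clone fraction x purity / 2) at
  negative-binomially distributed depth.

One dominant clone per lesion; no subclonal structure, no copy-number events
beyond the single LOH site, no sequence-context mutational signatures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .microsat import MicrosatRegion, scan_repeats
from .models import (
    EffectClass,
    Histology,
    IHCStatus,
    MMRGene,
    PatientRecord,
    SampleRecord,
    SomaticVariant,
)

_BASES = np.array(list("ACGT"))
_MMR_GENE_NAMES = frozenset(g.value for g in MMRGene)


@dataclass(frozen=True)
class GeneModel:
    name: str
    sequence: str
    repeat_regions: tuple[MicrosatRegion, ...]


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic cohort.

    The defaults mirror the emulated surveillance series: 33 patients
    (MLH1 : MSH2 carriers about 28 : 5), one carcinoma per patient with an
    atypical hyperplasia in about two thirds (of which about a quarter
    precede the carcinoma by 1-9 years) and a synchronous second carcinoma
    in about a quarter; blood available for most patients, otherwise a
    normal-endometrium reference; hypermutators (about 80% of lesions'
    patients) accumulate 40 non-synonymous variants/Mb against 2/Mb
    otherwise on a 6.4 Mb panel; truncal fraction 0.26 (the observed mean
    directional sharing between hyperplasia and carcinoma); tumor purity
    0.7; mean depth 200 (targeted deep panel).
    """

    n_patients: int = 33
    seed: int = 0
    p_msh2: float = 5 / 33
    p_hyperplasia: float = 21 / 33
    p_preceding_hyperplasia: float = 6 / 22
    p_synchronous: float = 9 / 33
    p_blood: float = 24 / 33
    rate_hypermutator: float = 40.0  # variants/Mb/lesion
    rate_normal: float = 2.0
    p_hypermutator: float = 0.8
    truncal_sharing_fraction: float = 0.26
    p_second_hit_loh: float = 0.3
    tumor_purity: float = 0.7
    mean_depth: float = 200.0
    depth_dispersion: float = 10.0
    microsat_indel_bias: float = 0.7
    p_frameshift: float = 0.35
    p_synonymous: float = 0.0
    panel_mb: float = 6.4
    n_genes: int = 40
    gene_footprint_bp: int = 2000

    def __post_init__(self) -> None:
        for name in (
            "p_msh2", "p_hyperplasia", "p_preceding_hyperplasia",
            "p_synchronous", "p_blood", "p_hypermutator", "p_second_hit_loh",
            "tumor_purity", "microsat_indel_bias", "p_frameshift",
            "p_synonymous", "truncal_sharing_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.rate_hypermutator < 0 or self.rate_normal < 0:
            raise ValueError("mutation rates must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class TruthRecord:
    patient_id: str
    truncal_keys: frozenset
    private_keys: dict[str, frozenset]
    second_hit_mechanism: dict[str, str]  # sample_id -> 'LOH' | 'variant'
    clonal_pairs: tuple[tuple[str, str], ...]
    hypermutator: dict[str, bool]
    xi_sim: float


@dataclass
class CohortBundle:
    config: SimulationConfig
    genes: tuple[GeneModel, ...]
    patients: list[PatientRecord]
    truth: list[TruthRecord]
    loh_table: pd.DataFrame

    def write(self, out_dir) -> None:
        """Emit the exact formats the readers consume: sample sheet, per-
        sample variant TSVs, LOH read-count TSV, reference FASTA, truth."""
        from .io import write_sample_sheet, write_variant_table

        out = Path(out_dir)
        (out / "variants").mkdir(parents=True, exist_ok=True)
        samples = [s for p in self.patients for s in p.samples]
        write_sample_sheet(samples, out / "sample_sheet.tsv")
        for p in self.patients:
            for sid, table in p.variant_tables.items():
                write_variant_table(table, out / "variants" / f"{sid}.tsv")
        self.loh_table.to_csv(out / "loh.tsv", sep="\t", index=False)
        with open(out / "reference.fa", "w") as fh:
            for g in self.genes:
                fh.write(f">{g.name}\n")
                for i in range(0, len(g.sequence), 80):
                    fh.write(g.sequence[i : i + 80] + "\n")
        with open(out / "truth.json", "w") as fh:
            json.dump(
                [
                    {
                        "patient_id": t.patient_id,
                        "truncal_keys": sorted(map(list, t.truncal_keys)),
                        "private_keys": {
                            sid: sorted(map(list, keys))
                            for sid, keys in t.private_keys.items()
                        },
                        "second_hit_mechanism": t.second_hit_mechanism,
                        "clonal_pairs": [list(p) for p in t.clonal_pairs],
                        "hypermutator": t.hypermutator,
                        "xi_sim": t.xi_sim,
                    }
                    for t in self.truth
                ],
                fh,
                indent=1,
            )


def build_gene_universe(config: SimulationConfig) -> tuple[GeneModel, ...]:
    """Synthetic panel genes: random sequence with embedded repeat tracts.

    The four MMR genes head the universe (the panel must annotate them for
    second-hit calling); the rest are anonymous panel genes.  Each sequence
    gets a few planted mononucleotide/dinucleotide tracts; the authoritative
    repeat map is whatever the scanner finds on the finished sequence, so
    incidental repeats in the random background are honored too.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xFEED]))
    names = [g.value for g in MMRGene]
    names += [f"PAN{i:03d}" for i in range(1, config.n_genes - len(names) + 1)]
    genes = []
    for name in names:
        seq = rng.choice(_BASES, size=config.gene_footprint_bp)
        for _ in range(3):  # planted tracts
            start = int(rng.integers(0, config.gene_footprint_bp - 20))
            base = str(rng.choice(_BASES))
            run = int(rng.integers(6, 12))
            seq[start : start + run] = base
        sequence = "".join(seq)
        regions = tuple(scan_repeats(sequence, chrom=name))
        genes.append(GeneModel(name=name, sequence=sequence, repeat_regions=regions))
    return tuple(genes)


def _draw_depth(rng: np.random.Generator, config: SimulationConfig) -> int:
    n = config.depth_dispersion
    p = n / (n + config.mean_depth)
    return max(int(rng.negative_binomial(n, p)), 1)


def _observe(
    rng: np.random.Generator, config: SimulationConfig, true_vaf: float
) -> tuple[int, int, float]:
    depth = _draw_depth(rng, config)
    alt = int(rng.binomial(depth, true_vaf))
    return alt, depth - alt, alt / depth


class _VariantFactory:
    """Places variants on the synthetic gene sequences without collisions."""

    def __init__(self, genes: tuple[GeneModel, ...], rng: np.random.Generator,
                 config: SimulationConfig):
        self.genes = genes
        self.rng = rng
        self.config = config
        self.used: set[tuple[str, int]] = set()

    def _pick_position(self, gene: GeneModel, in_repeat: bool) -> int:
        rng = self.rng
        for _ in range(200):
            if in_repeat and gene.repeat_regions:
                region = gene.repeat_regions[
                    int(rng.integers(0, len(gene.repeat_regions)))
                ]
                pos0 = int(rng.integers(region.start, region.end))
            else:
                pos0 = int(rng.integers(0, len(gene.sequence) - 2))
                if not in_repeat and any(
                    r.start <= pos0 < r.end for r in gene.repeat_regions
                ):
                    continue
            if (gene.name, pos0) not in self.used:
                self.used.add((gene.name, pos0))
                return pos0
        raise RuntimeError("could not place variant (sequence saturated)")

    def new_event(self) -> tuple[GeneModel, int, str, str, EffectClass]:
        """Draw gene, position, alleles and effect for one somatic event.

        Passengers go to non-MMR panel genes only: the MMR genes carry the
        explicitly planted second-hit events, keeping the simulated
        inactivation mechanism unambiguous."""
        rng, cfg = self.rng, self.config
        passengers = [g for g in self.genes if g.name not in _MMR_GENE_NAMES]
        gene = passengers[int(rng.integers(0, len(passengers)))]
        u = rng.random()
        if u < cfg.p_frameshift:
            effect = EffectClass.frameshift
            in_repeat = rng.random() < cfg.microsat_indel_bias
            pos0 = self._pick_position(gene, in_repeat)
            anchor = gene.sequence[pos0]
            nxt = gene.sequence[pos0 + 1] if pos0 + 1 < len(gene.sequence) else "A"
            if rng.random() < 0.5:  # 1-bp deletion
                ref, alt = anchor + nxt, anchor
            else:  # 1-bp insertion
                ins = str(rng.choice(_BASES))
                ref, alt = anchor, anchor + ins
        else:
            if u < cfg.p_frameshift + cfg.p_synonymous:
                effect = EffectClass.synonymous
            else:
                snv_effects = (
                    EffectClass.missense, EffectClass.nonsense, EffectClass.splice,
                )
                effect = snv_effects[
                    int(rng.choice(3, p=[0.75, 0.15, 0.10]))
                ]
            pos0 = self._pick_position(gene, in_repeat=False)
            ref = gene.sequence[pos0]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return gene, pos0 + 1, ref, alt, effect


def simulate_patient(
    config: SimulationConfig,
    rng: np.random.Generator,
    patient_index: int,
    genes: Optional[tuple[GeneModel, ...]] = None,
) -> tuple[PatientRecord, TruthRecord, list[dict]]:
    """One patient: specimens, somatic variant tables, LOH read counts, truth.

    Same generator state in, bit-identical output out.
    """
    if genes is None:
        genes = build_gene_universe(config)
    pid = f"SIM{patient_index + 1:03d}"
    germline_gene = MMRGene.MSH2 if rng.random() < config.p_msh2 else MMRGene.MLH1

    # ---- specimen structure -------------------------------------------------
    samples: list[SampleRecord] = []
    lesion_specs: list[tuple[str, Histology, int]] = []
    lesion_specs.append((f"{pid}_EEC", Histology.EEC, 0))
    synchronous = rng.random() < config.p_synchronous
    if synchronous:
        lesion_specs.append((f"{pid}_EOC", Histology.EOC, 0))
    if rng.random() < config.p_hyperplasia:
        tp = 0
        if rng.random() < config.p_preceding_hyperplasia:
            tp = -int(rng.integers(1, 10))
        lesion_specs.append((f"{pid}_CAH", Histology.CAH, tp))
    has_blood = rng.random() < config.p_blood
    hypermutator = rng.random() < config.p_hypermutator

    for sid, hist, tp in lesion_specs:
        samples.append(
            SampleRecord(
                sample_id=sid, patient_id=pid, predisposing_gene=germline_gene,
                histology=hist, timepoint_years=tp,
                msi_deviations={"BAT25": int(rng.integers(0, 2)),
                                "BAT26": int(rng.integers(2, 9))},
                ihc_loss=IHCStatus.loss,
            )
        )
    if has_blood:
        samples.append(
            SampleRecord(
                sample_id=f"{pid}_B", patient_id=pid,
                predisposing_gene=germline_gene, histology=Histology.B,
                timepoint_years=0,
                msi_deviations={"BAT25": 0, "BAT26": 0},
                ihc_loss=IHCStatus.retained,
            )
        )
    else:
        samples.append(
            SampleRecord(
                sample_id=f"{pid}_NE", patient_id=pid,
                predisposing_gene=germline_gene, histology=Histology.NE,
                timepoint_years=min(s[2] for s in lesion_specs),
                msi_deviations={"BAT25": 0, "BAT26": 0},
                ihc_loss=IHCStatus.retained,
            )
        )

    # ---- somatic variants ---------------------------------------------------
    factory = _VariantFactory(genes, rng, config)
    rate = config.rate_hypermutator if hypermutator else config.rate_normal
    xi = config.truncal_sharing_fraction
    purity = config.tumor_purity

    n_truncal = int(rng.poisson(xi * rate * config.panel_mb))
    truncal_events = [factory.new_event() for _ in range(n_truncal)]
    truncal_keys = frozenset(
        (g.name, pos, ref, alt) for g, pos, ref, alt, _ in truncal_events
    )

    variant_tables: dict[str, list[SomaticVariant]] = {}
    private_keys: dict[str, frozenset] = {}
    second_hit_mechanism: dict[str, str] = {}
    gene_by_name = {g.name: g for g in genes}

    loh_rows: list[dict] = []
    germline_gene_model = gene_by_name[germline_gene.value]
    germ_pos0 = len(germline_gene_model.sequence) // 2
    germ_ref = germline_gene_model.sequence[germ_pos0]
    germ_alt = str({"A": "G", "C": "T", "G": "A", "T": "C"}[germ_ref])
    n_alt, n_ref_reads, _ = _observe(rng, config, 0.5)  # reference tissue

    for sid, _hist, _tp in lesion_specs:
        table: list[SomaticVariant] = []
        # truncal set: clonal in every lesion
        for g, pos, ref, alt, effect in truncal_events:
            alt_r, ref_r, vaf = _observe(rng, config, purity / 2)
            table.append(
                SomaticVariant(
                    chrom=g.name, pos=pos, ref=ref, alt=alt, gene=g.name,
                    effect_class=effect, vaf=vaf, alt_reads=alt_r,
                    ref_reads=ref_r,
                    somatic_p=float(rng.uniform(0, 0.005)),
                    caller_filter="PASS",
                )
            )
        # private set
        n_private = int(rng.poisson((1 - xi) * rate * config.panel_mb))
        priv = []
        for _ in range(n_private):
            g, pos, ref, alt, effect = factory.new_event()
            clone_fraction = float(rng.uniform(0.5, 1.0))
            alt_r, ref_r, vaf = _observe(rng, config, clone_fraction * purity / 2)
            priv.append((g.name, pos, ref, alt))
            table.append(
                SomaticVariant(
                    chrom=g.name, pos=pos, ref=ref, alt=alt, gene=g.name,
                    effect_class=effect, vaf=vaf, alt_reads=alt_r,
                    ref_reads=ref_r,
                    somatic_p=float(rng.uniform(0, 0.005)),
                    caller_filter="PASS",
                )
            )
        private_keys[sid] = frozenset(priv)

        # second hit
        mechanism = "LOH" if rng.random() < config.p_second_hit_loh else "variant"
        second_hit_mechanism[sid] = mechanism
        if mechanism == "LOH":
            t_vaf = 1.0 / (2.0 - purity)  # wild-type allele lost
        else:
            t_vaf = 0.5  # germline site stays balanced
            hit_pos0 = factory._pick_position(germline_gene_model, in_repeat=False)
            hit_ref = germline_gene_model.sequence[hit_pos0]
            hit_alt = str({"A": "T", "C": "G", "G": "C", "T": "A"}[hit_ref])
            alt_r, ref_r, vaf = _observe(rng, config, purity / 2)
            table.append(
                SomaticVariant(
                    chrom=germline_gene.value, pos=hit_pos0 + 1, ref=hit_ref,
                    alt=hit_alt, gene=germline_gene.value,
                    effect_class=EffectClass.nonsense, vaf=vaf,
                    alt_reads=alt_r, ref_reads=ref_r,
                    somatic_p=float(rng.uniform(0, 0.005)),
                    caller_filter="PASS",
                )
            )
        t_alt, t_ref, _ = _observe(rng, config, t_vaf)
        loh_rows.append(
            {
                "sample_id": sid, "chrom": germline_gene.value,
                "pos": germ_pos0 + 1, "ref": germ_ref, "alt": germ_alt,
                "t_alt": t_alt, "t_ref": t_ref,
                "n_alt": n_alt, "n_ref": n_ref_reads,
                "is_pathogenic_germline": 1,
            }
        )
        variant_tables[sid] = table

    patient = PatientRecord(
        patient_id=pid, predisposing_gene=germline_gene,
        samples=samples, variant_tables=variant_tables,
    )
    lesion_ids = [sid for sid, _, _ in lesion_specs]
    truth = TruthRecord(
        patient_id=pid,
        truncal_keys=truncal_keys,
        private_keys=private_keys,
        second_hit_mechanism=second_hit_mechanism,
        clonal_pairs=tuple(
            (a, b)
            for i, a in enumerate(lesion_ids)
            for b in lesion_ids[i + 1:]
        ),
        hypermutator={sid: hypermutator for sid in lesion_ids},
        xi_sim=xi,
    )
    return patient, truth, loh_rows


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Simulate ``n_patients`` with independent seeded substreams, so a
    cohort can grow without perturbing existing patients."""
    genes = build_gene_universe(config)
    root = np.random.SeedSequence([config.seed, 0xC040])
    children = root.spawn(config.n_patients)
    patients, truth, loh_rows = [], [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        p, t, rows = simulate_patient(config, rng, i, genes=genes)
        patients.append(p)
        truth.append(t)
        loh_rows.extend(rows)
    loh_table = pd.DataFrame(
        loh_rows,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "t_alt", "t_ref",
                 "n_alt", "n_ref", "is_pathogenic_germline"],
    )
    return CohortBundle(
        config=config, genes=genes, patients=patients, truth=truth,
        loh_table=loh_table,
    )
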