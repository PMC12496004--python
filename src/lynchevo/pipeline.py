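"""End-to-end orchestration over a cohort directory.

Expected input layout (exactly what :meth:`lynchevo.simulate.CohortBundle.write`
emits, and what external cohorts should be converted to)::

    sample_sheet.tsv          patient/tissue/histology/timepoint/MSI/IHC
    variants/<sample_id>.tsv  somatic variant tables (TSV dialect or .vcf)
    loh.tsv                   germline-site read counts (optional)
    reference.fa              panel reference sequences (optional)
    cosmic_sets.yaml          histology -> driver gene list (optional)

``run_all`` executes every stage that its inputs allow — filtering, burden,
MMR status, LOH and second hits, pairwise sharing, trajectories, clonality
of synchronous carcinoma pairs, microsatellite annotation, group summaries —
and writes one TSV/JSON per stage plus a manifest.  Output is a pure
function of inputs + config (re-running is byte-identical); skipped stages
are recorded with the reason.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import burden as burden_mod
from .clonality import clonality_p, estimate_reference_frequencies
from .filtering import FilterPolicy, significant_somatic
from .fixture import FixtureSecondHit
from .io import group_patients, read_sample_sheet, read_variant_table
from .microsat import gene_repeat_fraction, scan_fasta, variant_in_repeat, write_bed
from .mmr import (
    LOHCall,
    LOHResult,
    LOHThresholds,
    call_msi,
    call_second_hits,
    classify_loh,
    classify_mmr,
    loh_ratio,
    mutual_exclusivity,
)
from .models import CARCINOMA_GROUP, Histology, IHCStatus, SecondHitMechanism
from .sharing import compare_pair
from .stats import summarize_groups
from .trajectory import CosmicGeneSets, build_trajectories, export_diagram

logger = logging.getLogger("lynchevo.pipeline")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, context: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed ({context}): {cause}")
        self.stage = stage
        self.context = context


@dataclass
class RunConfig:
    input_dir: str
    out_dir: str
    policy: FilterPolicy = field(default_factory=FilterPolicy)
    panel_mb: float = burden_mod.DEFAULT_PANEL_MB
    loh_thresholds: LOHThresholds = field(default_factory=LOHThresholds)
    cosmic_sets_path: Optional[str] = None
    clonality_n_sim: int = 999
    seed: int = 0
    verbose: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        policy = FilterPolicy(**raw.pop("policy", {}))
        loh = LOHThresholds(**raw.pop("loh_thresholds", {}))
        return cls(policy=policy, loh_thresholds=loh, **raw)

    def validate(self) -> None:
        root = Path(self.input_dir)
        if not (root / "sample_sheet.tsv").exists():
            raise FileNotFoundError(f"{root}/sample_sheet.tsv not found")
        if self.cosmic_sets_path and not Path(self.cosmic_sets_path).exists():
            raise FileNotFoundError(self.cosmic_sets_path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to the bundle)."""
    config.validate()
    logging.basicConfig(
        level=logging.INFO if config.verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )
    root = Path(config.input_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            "policy": vars(config.policy) | {},
            "panel_mb": config.panel_mb,
            "loh_thresholds": {
                "strict_upper": config.loh_thresholds.strict_upper,
                "putative_upper": config.loh_thresholds.putative_upper,
            },
            "clonality_n_sim": config.clonality_n_sim,
            "seed": config.seed,
        },
        "stages": {},
        "outputs": {},
    }

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self.t0, 3),
                    "status": "failed" if exc else "completed",
                }
                return False

        return _Timer()

    # ---- load ---------------------------------------------------------------
    with stage("load"):
        try:
            samples = read_sample_sheet(root / "sample_sheet.tsv")
            patients = group_patients(samples)
            variant_dir = root / "variants"
            have_tables = False
            if variant_dir.is_dir():
                for p in patients.values():
                    for s in p.samples:
                        for ext in (".tsv", ".vcf"):
                            path = variant_dir / f"{s.sample_id}{ext}"
                            if path.exists():
                                p.variant_tables[s.sample_id] = read_variant_table(path)
                                have_tables = True
                                break
        except Exception as exc:
            raise PipelineStageError("load", str(root), exc) from exc

    neoplastic = [
        (p, s) for p in patients.values() for s in p.neoplastic_samples
    ]

    # ---- filtering + burden -------------------------------------------------
    filtered: dict[str, list] = {}
    if have_tables:
        with stage("filter_burden"):
            rows = []
            for p, s in neoplastic:
                try:
                    table = p.variant_tables.get(s.sample_id, [])
                    kept = significant_somatic(table, config.policy)
                    filtered[s.sample_id] = kept
                    res = burden_mod.BurdenResult(
                        s.sample_id, len(kept), config.panel_mb
                    )
                    rows.append(
                        {
                            "sample_id": s.sample_id,
                            "n_raw": len(table),
                            "n_significant": len(kept),
                            "tmb": res.tmb_display,
                            "hypermutated": int(res.hypermutated),
                        }
                    )
                except Exception as exc:
                    raise PipelineStageError(
                        "filter_burden", s.sample_id, exc
                    ) from exc
            burden_df = pd.DataFrame(rows)
            burden_df.to_csv(out / "burden.tsv", sep="\t", index=False)
    else:
        manifest["stages"]["filter_burden"] = {
            "status": "skipped", "reason": "no variant tables"
        }
        burden_df = pd.DataFrame()

    # ---- MMR status ---------------------------------------------------------
    with stage("mmr_status"):
        rows = []
        for p, s in neoplastic:
            try:
                msi = (
                    call_msi(s.msi_deviations) if s.msi_deviations else None
                )
                status = classify_mmr(msi, s.ihc_loss)
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "msi": int(msi.msi) if msi else "",
                        "ihc": s.ihc_loss.value,
                        "mmr_status": status.value,
                    }
                )
            except Exception as exc:
                raise PipelineStageError("mmr_status", s.sample_id, exc) from exc
        mmr_df = pd.DataFrame(rows)
        mmr_df.to_csv(out / "mmr_status.tsv", sep="\t", index=False)

    # ---- LOH ----------------------------------------------------------------
    loh_results: dict[str, LOHResult] = {}
    loh_path = root / "loh.tsv"
    if loh_path.exists():
        with stage("loh"):
            loh_in = pd.read_csv(loh_path, sep="\t")
            rows = []
            for r in loh_in.itertuples():
                try:
                    if not r.is_pathogenic_germline:
                        continue
                    ratio = loh_ratio(r.t_alt, r.t_ref, r.n_alt, r.n_ref)
                    res = classify_loh(ratio, config.loh_thresholds)
                    loh_results[r.sample_id] = res
                    rows.append(
                        {
                            "sample_id": r.sample_id,
                            "ratio": "" if res.ratio is None
                            else round(res.ratio, 4),
                            "call": res.call.value,
                            "wildtype_lost": int(res.wildtype_lost),
                        }
                    )
                except Exception as exc:
                    raise PipelineStageError("loh", str(r.sample_id), exc) from exc
            pd.DataFrame(rows).to_csv(out / "loh_calls.tsv", sep="\t", index=False)
    else:
        manifest["stages"]["loh"] = {"status": "skipped", "reason": "no loh.tsv"}

    # ---- second hits --------------------------------------------------------
    second_hit_rows = []
    second_hits = {}
    if have_tables:
        with stage("second_hits"):
            for p in patients.values():
                try:
                    calls = call_second_hits(
                        p, loh_results=loh_results, policy=config.policy
                    )
                except Exception as exc:
                    raise PipelineStageError(
                        "second_hits", p.patient_id, exc
                    ) from exc
                for call in calls:
                    second_hits[call.sample_id] = call
                    second_hit_rows.append(
                        {
                            "sample_id": call.sample_id,
                            "mechanisms": "+".join(
                                sorted(m.value for m in call.mechanisms)
                            ) or "none",
                            "n_variants": len(call.variants),
                            "any_hit": int(call.any_hit),
                        }
                    )
            pd.DataFrame(second_hit_rows).to_csv(
                out / "second_hits.tsv", sep="\t", index=False
            )
    else:
        manifest["stages"]["second_hits"] = {
            "status": "skipped", "reason": "no variant tables"
        }

    # ---- sharing ------------------------------------------------------------
    if have_tables:
        with stage("sharing"):
            rows = []
            for p in patients.values():
                lesions = p.neoplastic_samples
                for i, s1 in enumerate(lesions):
                    for s2 in lesions[i + 1:]:
                        res = compare_pair(
                            p.variant_tables.get(s1.sample_id, []),
                            p.variant_tables.get(s2.sample_id, []),
                            policy=config.policy,
                            sample_id_1=s1.sample_id,
                            sample_id_2=s2.sample_id,
                        )
                        rows.append(
                            {
                                "patient_id": p.patient_id,
                                "sample_1": s1.sample_id,
                                "sample_2": s2.sample_id,
                                "n_shared": res.n_shared,
                                "n_unique_1": res.n_unique_1,
                                "n_unique_2": res.n_unique_2,
                                "sharing_pct": round(100 * res.sharing_pct, 2),
                                "directional_1": round(100 * res.directional_1, 2),
                                "directional_2": round(100 * res.directional_2, 2),
                            }
                        )
            sharing_df = pd.DataFrame(rows)
            sharing_df.to_csv(out / "sharing.tsv", sep="\t", index=False)
    else:
        manifest["stages"]["sharing"] = {
            "status": "skipped", "reason": "no variant tables"
        }

    # ---- trajectories -------------------------------------------------------
    if have_tables:
        with stage("trajectories"):
            if config.cosmic_sets_path:
                cosmic = CosmicGeneSets.from_yaml(config.cosmic_sets_path)
            else:
                cosmic = CosmicGeneSets({"_unconfigured": ()})
            diagrams = []
            for p in patients.values():
                try:
                    carcinomas = [
                        s for s in p.neoplastic_samples
                        if s.tissue_class.value == "carcinoma"
                    ]
                    if not carcinomas:
                        continue
                    events = build_trajectories(p, cosmic, config.policy)
                    diagrams.append(export_diagram(p, events, config.policy))
                except Exception as exc:
                    raise PipelineStageError(
                        "trajectories", p.patient_id, exc
                    ) from exc
            with open(out / "trajectories.json", "w") as fh:
                json.dump(diagrams, fh, indent=1, sort_keys=True)
    else:
        manifest["stages"]["trajectories"] = {
            "status": "skipped", "reason": "no variant tables"
        }

    # ---- clonality of synchronous carcinoma pairs ---------------------------
    if have_tables:
        with stage("clonality"):
            gene_universe = sorted(
                {
                    v.gene
                    for p in patients.values()
                    for table in p.variant_tables.values()
                    for v in table
                    if v.gene
                }
            )
            rows = []
            if gene_universe:
                profiles = {
                    s.sample_id: {
                        v.gene for v in filtered.get(s.sample_id, []) if v.gene
                    }
                    for p, s in neoplastic
                }
                for p in patients.values():
                    carcinomas = [
                        s for s in p.neoplastic_samples
                        if s.tissue_class.value == "carcinoma"
                        and s.timepoint_years == 0
                    ]
                    if len(carcinomas) < 2:
                        continue
                    ref_ids = [
                        s.sample_id for q, s in neoplastic
                        if q.patient_id != p.patient_id
                    ]
                    if not ref_ids:
                        continue
                    matrix = [
                        [int(g in profiles[sid]) for g in gene_universe]
                        for sid in ref_ids
                    ]
                    ref = estimate_reference_frequencies(
                        (matrix, gene_universe), pseudocount=0.5
                    )
                    s1, s2 = carcinomas[:2]
                    try:
                        verdict = clonality_p(
                            profiles[s1.sample_id], profiles[s2.sample_id],
                            ref, n_sim=config.clonality_n_sim,
                            seed=config.seed,
                        )
                    except Exception as exc:
                        raise PipelineStageError(
                            "clonality", p.patient_id, exc
                        ) from exc
                    rows.append(
                        {
                            "patient_id": p.patient_id,
                            "sample_1": s1.sample_id,
                            "sample_2": s2.sample_id,
                            "lr": round(verdict.lr_statistic, 4),
                            "xi_hat": round(verdict.xi_hat, 4),
                            "p_value": verdict.p_value,
                            "n_sim": verdict.n_sim,
                        }
                    )
            pd.DataFrame(
                rows,
                columns=["patient_id", "sample_1", "sample_2", "lr",
                         "xi_hat", "p_value", "n_sim"],
            ).to_csv(out / "clonality.tsv", sep="\t", index=False)
    else:
        manifest["stages"]["clonality"] = {
            "status": "skipped", "reason": "no variant tables"
        }

    # ---- microsatellites ----------------------------------------------------
    ref_fa = root / "reference.fa"
    if ref_fa.exists() and have_tables:
        with stage("microsat"):
            regions = scan_fasta(ref_fa)
            write_bed(regions, out / "microsat_regions.bed")
            all_kept = [v for kept in filtered.values() for v in kept]
            genes = sorted({v.gene for v in all_kept if v.gene})
            rows = []
            for g in genes:
                frac = gene_repeat_fraction(g, all_kept, regions)
                n_in_gene = sum(1 for v in all_kept if v.gene == g)
                rows.append(
                    {
                        "gene": g,
                        "n_variants": n_in_gene,
                        "repeat_fraction": "" if frac is None
                        else round(frac, 4),
                        "n_in_repeat": sum(
                            1 for v in all_kept
                            if v.gene == g and variant_in_repeat(v, regions)
                        ),
                    }
                )
            pd.DataFrame(rows).to_csv(
                out / "repeat_fractions.tsv", sep="\t", index=False
            )
    else:
        manifest["stages"]["microsat"] = {
            "status": "skipped",
            "reason": "no reference.fa" if have_tables else "no variant tables",
        }

    # ---- group summaries ----------------------------------------------------
    with stage("summaries"):
        rows = []
        for p, s in neoplastic:
            group = CARCINOMA_GROUP.get(s.histology)
            if group is None:
                group = "AH" if s.histology == Histology.CAH else None
            msi = call_msi(s.msi_deviations) if s.msi_deviations else None
            call = second_hits.get(s.sample_id)
            loh_res = loh_results.get(s.sample_id)
            wt_loh = (
                loh_res is not None
                and loh_res.wildtype_lost
                and loh_res.call in (LOHCall.LOH, LOHCall.pLOH)
            )
            hits = tuple(
                FixtureSecondHit(
                    gene=sv.variant.gene,
                    effect=sv.variant.effect_class.value,
                    vaf_pct=round(100 * sv.vaf),
                    sub_threshold=sv.sub_threshold,
                )
                for sv in (call.variants if call else [])
            )
            n_sig = len(filtered.get(s.sample_id, []))
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "group": group,
                    "timepoint": s.timepoint_years,
                    "mmr_status": classify_mmr(msi, s.ihc_loss).value,
                    "loh": (loh_res.call.value if wt_loh else "No")
                    if loh_res is not None else "N/A",
                    "second_hits": hits,
                    "any_hit_strict": wt_loh
                    or any(not h.sub_threshold for h in hits),
                    "tmb": n_sig / config.panel_mb if have_tables else float("nan"),
                    "hypermutated": (
                        burden_mod.classify_hypermutated(n_sig / config.panel_mb)
                        if have_tables else False
                    ),
                }
            )
        cohort_df = pd.DataFrame(rows)
        summaries = summarize_groups(cohort_df, config.panel_mb)
        pd.DataFrame(
            [
                {
                    "group": g.group,
                    "n_samples": g.n_samples,
                    "n_dMMR": g.n_dmmr,
                    "n_any_second_hit": g.n_any_second_hit,
                    "n_loh": g.n_loh,
                    "n_somatic_hit": g.n_somatic_hit,
                    "mean_variants": g.mean_variants,
                    "mean_tmb": g.mean_tmb,
                    "tmb_min": g.tmb_range[0] if g.tmb_range else "",
                    "tmb_max": g.tmb_range[1] if g.tmb_range else "",
                    "n_hypermutated": g.n_hypermutated,
                }
                for g in summaries
            ]
        ).to_csv(out / "group_summary.tsv", sep="\t", index=False)
        if second_hits:
            table, p_val = mutual_exclusivity(
                (
                    bool(r["loh"] in ("LOH", "pLOH")),
                    any(not h.sub_threshold for h in r["second_hits"]),
                )
                for r in rows
                if r["group"] is not None
            )
            with open(out / "mutual_exclusivity.json", "w") as fh:
                json.dump({"table": table, "fisher_p": p_val}, fh, indent=1)

    for path in sorted(out.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][path.name] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
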