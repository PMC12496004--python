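#!/usr/bin/env python
"""Microsatellite annotation of simulated variants.

Scans the synthetic panel reference for microsatellite regions (unit 1-5 bp,
>= 3 complete units, >= 5 bases) and measures, per gene, the fraction of
somatic variants falling in a repeat — separately for frameshift indels
(which the generator biases into repeats, emulating MMR-deficient slippage)
and for substitutions.

Writes results/repeat_fractions.tsv.
"""

from pathlib import Path

import pandas as pd

from lynchevo.filtering import FilterPolicy, significant_somatic
from lynchevo.microsat import variant_in_repeat
from lynchevo.models import EffectClass
from lynchevo.simulate import SimulationConfig, simulate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = SimulationConfig(n_patients=12, seed=77, p_hypermutator=1.0)
    bundle = simulate_cohort(cfg)
    regions = [r for g in bundle.genes for r in g.repeat_regions]
    policy = FilterPolicy()

    kept = [
        v
        for p in bundle.patients
        for table in p.variant_tables.values()
        for v in significant_somatic(table, policy)
    ]
    rows = []
    for gene in sorted({v.gene for v in kept}):
        in_gene = [v for v in kept if v.gene == gene]
        fs = [v for v in in_gene if v.effect_class == EffectClass.frameshift]
        subs = [v for v in in_gene if v.effect_class != EffectClass.frameshift]
        rows.append(
            {
                "gene": gene,
                "n_variants": len(in_gene),
                "repeat_fraction": round(
                    sum(variant_in_repeat(v, regions) for v in in_gene)
                    / len(in_gene), 3,
                ),
                "repeat_fraction_frameshift": round(
                    sum(variant_in_repeat(v, regions) for v in fs) / len(fs), 3
                ) if fs else "",
                "repeat_fraction_substitution": round(
                    sum(variant_in_repeat(v, regions) for v in subs)
                    / len(subs), 3,
                ) if subs else "",
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "repeat_fractions.tsv", sep="\t", index=False)
    print(df.head(12).to_string(index=False))
    overall_fs = df["repeat_fraction_frameshift"].replace("", pd.NA).dropna()
    overall_sub = df["repeat_fraction_substitution"].replace("", pd.NA).dropna()
    print(
        f"\nmean repeat fraction: {overall_fs.astype(float).mean():.2f} for "
        f"frameshifts vs {overall_sub.astype(float).mean():.2f} for "
        "substitutions (generator bias 0.7; substitutions avoid repeats by "
        "construction, so their in-repeat fraction reflects boundary overlap "
        "of indel-anchored intervals only)"
    )


if __name__ == "__main__":
    main()
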