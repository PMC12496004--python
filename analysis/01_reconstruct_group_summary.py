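#!/usr/bin/env python
"""Reconstruct the group-level summary of the tumor series.

Loads the packaged per-sample cohort table (64 neoplastic specimens of 33
Lynch-syndrome carriers) and recomputes the group summaries: sample counts,
MMR-deficiency and second-hit proportions, mean non-synonymous variant
counts and mutational burdens with ranges, and hypermutation counts for EC,
OC, the combined carcinomas and atypical hyperplasia — plus the hyperplasia
burdens stratified by whether the specimen was concurrent with or preceded
the carcinoma.

Writes results/group_summary.tsv and results/ah_stratified.tsv.
"""

from pathlib import Path

import pandas as pd

from lynchevo.fixture import load_cohort_fixture
from lynchevo.stats import stratify_hyperplasia, summarize_groups

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cohort = load_cohort_fixture()
    rows = []
    for g in summarize_groups(cohort):
        rows.append(
            {
                "group": g.group,
                "n_samples": g.n_samples,
                "n_dMMR": g.n_dmmr,
                "n_any_second_hit": g.n_any_second_hit,
                "n_LOH_or_pLOH": g.n_loh,
                "n_somatic_hit": g.n_somatic_hit,
                "mean_variants": g.mean_variants,
                "mean_tmb": g.mean_tmb,
                "tmb_min": g.tmb_range[0],
                "tmb_max": g.tmb_range[1],
                "n_hypermutated": g.n_hypermutated,
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "group_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))

    mean_c, mean_p, n_c, n_p = stratify_hyperplasia(cohort)
    strat = pd.DataFrame(
        [
            {"stratum": "concurrent", "n": n_c, "mean_tmb": mean_c},
            {"stratum": "preceding", "n": n_p, "mean_tmb": mean_p},
        ]
    )
    strat.to_csv(RESULTS / "ah_stratified.tsv", sep="\t", index=False)
    print()
    print("Atypical hyperplasia by timing relative to the carcinoma endpoint:")
    print(strat.to_string(index=False))
    print(
        "\nMMR deficiency is near-universal in both carcinomas "
        f"({summary.set_index('group').loc['EC+OC', 'n_dMMR']}/42) and "
        f"hyperplasias ({summary.set_index('group').loc['AH', 'n_dMMR']}/22); "
        "hyperplasia burdens approach carcinoma levels only at timepoint 0."
    )


if __name__ == "__main__":
    main()
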