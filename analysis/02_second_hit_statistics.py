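#!/usr/bin/env python
"""Exact tests on second-hit patterns in the cohort table.

Two questions: (1) do MMR-deficient hyperplasias carry somatic second hits
more often than MMR-proficient ones, and (2) are LOH and somatic MMR-gene
variants mutually exclusive inactivation mechanisms across all 64 samples?

Writes results/second_hit_tests.json.
"""

import json
from pathlib import Path

from lynchevo.fixture import load_cohort_fixture
from lynchevo.stats import fisher_2x2, format_p

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cohort = load_cohort_fixture()

    ah = cohort[cohort["group"] == "AH"]
    dmmr = ah["mmr_status"] == "dMMR"
    hit = ah["any_hit_strict"]
    table_ah = [
        [int((dmmr & hit).sum()), int((dmmr & ~hit).sum())],
        [int((~dmmr & hit).sum()), int((~dmmr & ~hit).sum())],
    ]
    p_ah = fisher_2x2(table_ah)

    loh = cohort["loh"].isin(["LOH", "pLOH"])
    somatic = cohort["second_hits"].map(
        lambda hits: any(not h.sub_threshold for h in hits)
    )
    table_excl = [
        [int((loh & somatic).sum()), int((loh & ~somatic).sum())],
        [int((~loh & somatic).sum()), int((~loh & ~somatic).sum())],
    ]
    p_excl = fisher_2x2(table_excl)

    out = {
        "second_hit_by_mmr_status_in_AH": {
            "table": table_ah, "fisher_p": p_ah, "display": format_p(p_ah),
        },
        "loh_vs_somatic_variant_exclusivity": {
            "table": table_excl, "fisher_p": p_excl,
            "display": format_p(p_excl),
        },
    }
    with open(RESULTS / "second_hit_tests.json", "w") as fh:
        json.dump(out, fh, indent=1)

    print(
        f"Second hit in {table_ah[0][0]}/{sum(table_ah[0])} dMMR vs "
        f"{table_excl and table_ah[1][0]}/{sum(table_ah[1])} pMMR "
        f"hyperplasias (Fisher p = {format_p(p_ah)})."
    )
    print(
        f"Mechanism exclusivity: {table_excl[0][0]} doubly-hit sample among "
        f"{int(loh.sum())} with LOH/pLOH and {int(somatic.sum())} with a "
        f"somatic second-hit variant (Fisher p {format_p(p_excl)})."
    )


if __name__ == "__main__":
    main()
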