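"""Group summaries and the statistical tests used across the cohort.

``summarize_groups`` reconstructs the group-level summary (EC / OC / EC+OC /
AH) from a per-sample cohort table: MMR-deficiency proportions, second-hit
counts, mean variant counts and TMB with ranges, and hypermutation counts.
Two notions of the second-hit count are reported: the strict one (wild-type
LOH/pLOH or a somatic MMR-gene variant at VAF >= 5%) used for all summary
statistics, and the count including cross-sample-rescued sub-threshold
variants, which is informative at the per-sample level only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .burden import DEFAULT_PANEL_MB, round_half_up


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n_samples: int
    n_dmmr: int
    n_any_second_hit: int
    n_loh: int
    n_somatic_hit: int
    mean_variants: Optional[float]
    mean_tmb: Optional[float]
    tmb_range: Optional[tuple[float, float]]
    n_hypermutated: int


_GROUP_FILTERS = {
    "EC": lambda df: df["group"] == "EC",
    "OC": lambda df: df["group"] == "OC",
    "EC+OC": lambda df: df["group"].isin(["EC", "OC"]),
    "AH": lambda df: df["group"] == "AH",
}


def summarize_groups(
    cohort: pd.DataFrame, panel_mb: float = DEFAULT_PANEL_MB
) -> list[GroupSummary]:
    """One summary per group (EC, OC, EC+OC, AH) from a per-sample table.

    Expects the fixture layout: columns ``group`` (EC/OC/AH), ``mmr_status``,
    ``loh``, ``second_hits``, ``any_hit_strict``, ``tmb``, ``hypermutated``.
    """
    unknown = set(cohort["group"].dropna()) - {"EC", "OC", "AH"}
    if unknown:
        raise ValueError(f"unknown histology group(s): {sorted(unknown)}")
    out = []
    for name, selector in _GROUP_FILTERS.items():
        sub = cohort[selector(cohort)]
        n = len(sub)
        if n == 0:
            out.append(
                GroupSummary(name, 0, 0, 0, 0, 0, None, None, None, 0)
            )
            continue
        loh = sub["loh"].isin(["LOH", "pLOH"])
        somatic = sub["second_hits"].map(
            lambda hits: any(not h.sub_threshold for h in hits)
        )
        tmb = sub["tmb"].to_numpy(dtype=float)
        out.append(
            GroupSummary(
                group=name,
                n_samples=n,
                n_dmmr=int((sub["mmr_status"] == "dMMR").sum()),
                n_any_second_hit=int(sub["any_hit_strict"].sum()),
                n_loh=int(loh.sum()),
                n_somatic_hit=int(somatic.sum()),
                mean_variants=round_half_up(float(np.mean(tmb * panel_mb)), 1),
                mean_tmb=round_half_up(float(np.mean(tmb)), 1),
                tmb_range=(float(tmb.min()), float(tmb.max())),
                n_hypermutated=int(sub["hypermutated"].sum()),
            )
        )
    return out


def fisher_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p (minimum-likelihood rule: the hypergeometric
    probabilities of all tables at the observed margins that do not exceed
    the observed table's probability are summed).

    A zero margin makes the table degenerate; p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a nonnegative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


@dataclass(frozen=True)
class TestReport:
    test: str
    statistic: float
    p_value: float


def mann_whitney(group_1: Sequence[float], group_2: Sequence[float]) -> TestReport:
    """Two-tailed Mann-Whitney U (normal approximation with tie and
    continuity corrections, the convention of standard statistics suites)."""
    if len(group_1) == 0 or len(group_2) == 0:
        raise ValueError("both groups must be non-empty")
    if list(group_1) == list(group_2):
        # identical samples: no evidence of a shift
        return TestReport("mann_whitney", len(group_1) * len(group_2) / 2, 1.0)
    u, p = sps.mannwhitneyu(
        group_1, group_2, alternative="two-sided", method="asymptotic"
    )
    return TestReport("mann_whitney", float(u), float(p))


@dataclass(frozen=True)
class DunnComparison:
    group_1: int
    group_2: int
    z: float
    p_value: float  # Bonferroni-adjusted when requested


@dataclass(frozen=True)
class KruskalDunnReport:
    kruskal: TestReport
    pairwise: tuple[DunnComparison, ...]


def kruskal_dunn(
    groups: Sequence[Sequence[float]], bonferroni: bool = True
) -> KruskalDunnReport:
    """Kruskal-Wallis followed by Dunn's pairwise post-hoc z tests.

    Dunn's test compares mean ranks from the pooled ranking with the
    tie-corrected normal approximation; Bonferroni multiplies each pairwise
    p by the number of comparisons (capped at 1).
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    h, p = sps.kruskal(*groups)
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    sizes = [len(g) for g in groups]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[offsets[i] : offsets[i + 1]].mean() for i in range(len(groups))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n - 1))
    n_comparisons = len(groups) * (len(groups) - 1) // 2
    pairwise = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(
            (n * (n + 1) / 12 - tie_term) * (1 / sizes[i] + 1 / sizes[j])
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_pair = 2 * sps.norm.sf(abs(z))
        if bonferroni:
            p_pair = min(1.0, p_pair * n_comparisons)
        pairwise.append(DunnComparison(i, j, float(z), float(p_pair)))
    return KruskalDunnReport(
        TestReport("kruskal_wallis", float(h), float(p)), tuple(pairwise)
    )


def stratify_hyperplasia(
    cohort: pd.DataFrame,
) -> tuple[Optional[float], Optional[float], int, int]:
    """Mean AH TMB by timing relative to the carcinoma endpoint.

    Returns (mean_tmb_concurrent, mean_tmb_preceding, n_concurrent,
    n_preceding): concurrent = timepoint 0, preceding = timepoint < 0.
    Means are display-rounded to one decimal; an empty stratum reports None.
    """
    ah = cohort[cohort["group"] == "AH"]
    concurrent = ah[ah["timepoint"] == 0]["tmb"]
    preceding = ah[ah["timepoint"] < 0]["tmb"]
    mean_c = round_half_up(float(concurrent.mean()), 1) if len(concurrent) else None
    mean_p = round_half_up(float(preceding.mean()), 1) if len(preceding) else None
    return mean_c, mean_p, len(concurrent), len(preceding)


def format_p(p: float) -> str:
    """Display convention: three decimals, '< .001' below 0.0005."""
    if p < 0.0005:
        return "< .001"
    return f"{p:.3f}".lstrip("0") or ".000"
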