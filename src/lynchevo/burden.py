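"""Tumor mutational burden and top-mutant-gene summaries.

TMB on a targeted panel is the count of significant non-synonymous somatic
variants divided by the panel footprint (default 6.4 Mb); a lesion is called
hypermutated at TMB >= 10/Mb.  Display values round half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional

from .filtering import FilterPolicy, significant_somatic
from .models import EffectClass, SomaticVariant

DEFAULT_PANEL_MB = 6.4
HYPERMUTATION_TMB = 10.0


def round_half_up(x: float, decimals: int = 1) -> float:
    """Half-up rounding used for all displayed burdens and percentages."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BurdenResult:
    sample_id: str
    n_nonsyn_significant: int
    panel_mb: float = DEFAULT_PANEL_MB
    hypermutation_threshold: float = HYPERMUTATION_TMB

    @property
    def tmb(self) -> float:
        return compute_tmb(self.n_nonsyn_significant, self.panel_mb)

    @property
    def tmb_display(self) -> float:
        return round_half_up(self.tmb, 1)

    @property
    def hypermutated(self) -> bool:
        return classify_hypermutated(self.tmb, self.hypermutation_threshold)


def compute_tmb(n_variants: int, panel_mb: float = DEFAULT_PANEL_MB) -> float:
    """Variants per megabase; full precision (round only for display)."""
    if n_variants < 0:
        raise ValueError(f"variant count must be >= 0, got {n_variants}")
    if panel_mb <= 0:
        raise ValueError(f"panel size must be positive, got {panel_mb}")
    return n_variants / panel_mb


def classify_hypermutated(tmb: float, threshold: float = HYPERMUTATION_TMB) -> bool:
    """Hypermutated at TMB >= threshold (boundary lesions at exactly 10.0/Mb
    are counted as hypermutated)."""
    if tmb < 0:
        raise ValueError(f"tmb must be >= 0, got {tmb}")
    return tmb >= threshold


def burden_for_sample(
    sample_id: str,
    variants: Iterable[SomaticVariant],
    policy: FilterPolicy = FilterPolicy(),
    panel_mb: float = DEFAULT_PANEL_MB,
) -> BurdenResult:
    """Filter a sample's variants under ``policy`` and compute its burden."""
    kept = significant_somatic(variants, policy)
    return BurdenResult(sample_id, len(kept), panel_mb)


def top_mutant_genes(
    sample_variants: Mapping[str, Iterable[SomaticVariant]],
    vaf_cutoff: float = 0.05,
    min_fraction: float = 0.0,
) -> list[tuple[str, float]]:
    """Fraction of samples carrying >= 1 qualifying variant per gene.

    A sample counts once per gene regardless of how many variants hit it.
    Genes are ranked by fraction descending, ties broken alphabetically;
    ``min_fraction`` applies the report-level display threshold (e.g. >50%
    of carcinomas, >40% of hyperplasias).
    """
    n_samples = len(sample_variants)
    if n_samples == 0:
        return []
    counts: dict[str, int] = {}
    for variants in sample_variants.values():
        genes = {
            v.gene for v in variants if v.gene and v.vaf >= vaf_cutoff
        }
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    ranked = sorted(
        ((g, n / n_samples) for g, n in counts.items()),
        key=lambda item: (-item[1], item[0]),
    )
    return [(g, f) for g, f in ranked if f > min_fraction or min_fraction == 0.0]


def frameshift_fraction(
    gene: str, variants: Iterable[SomaticVariant]
) -> Optional[float]:
    """Proportion of frameshift variants among all variants of ``gene``.

    Returns None (reported as missing) when the gene has no variants.
    """
    in_gene = [v for v in variants if v.gene == gene]
    if not in_gene:
        return None
    n_fs = sum(1 for v in in_gene if v.effect_class == EffectClass.frameshift)
    return n_fs / len(in_gene)
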