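"""Packaged per-sample cohort table of the Lynch-syndrome tumor series.

The table carries, for each of the 64 neoplastic specimens (27 endometrial
carcinomas, 15 ovarian carcinomas, 22 atypical hyperplasias) of 33 germline
MMR-variant carriers: the predisposing gene, sampling timepoint (years before
the carcinoma endpoint, 0 = endpoint), MMR status (dMMR/pMMR by MSI and/or
immunohistochemistry), LOH call at the germline MMR variant, somatic
second-hit variants of the same MMR gene with their VAF (bracketed in the
source when below the 5% inclusion cut-off), and tumor mutational burden per
Mb with the hypermutation flag (TMB >= 10/Mb).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .models import CARCINOMA_GROUP, Histology

_FIXTURE_RESOURCE = "table2_cohort.tsv"

#: Effect tokens used by the cohort table (as printed in the source series).
_EFFECT_TOKENS = {
    "nonsense",
    "missense",
    "splice",
    "frameshift",
    "in_frame_deletion",
    "frameshift+splice",
}


@dataclass(frozen=True)
class FixtureSecondHit:
    """One somatic MMR-gene second-hit variant of a fixture row."""

    gene: str
    effect: str
    vaf_pct: int
    sub_threshold: bool  # bracketed in the source: VAF below the 5% cut-off


class FixtureIntegrityError(RuntimeError):
    """The packaged cohort table failed its structural checks."""


def _parse_second_hits(cell: str) -> tuple[FixtureSecondHit, ...]:
    if cell == "None":
        return ()
    hits = []
    for token in cell.split(";"):
        m = re.fullmatch(r"(\[)?([A-Z0-9]+):([a-z_+]+):(\d+)(?(1)\])", token)
        if not m:
            raise FixtureIntegrityError(f"unparseable second-hit entry {token!r}")
        bracketed, gene, effect, vaf = m.groups()
        if effect not in _EFFECT_TOKENS:
            raise FixtureIntegrityError(f"unknown effect token {effect!r}")
        hits.append(
            FixtureSecondHit(
                gene=gene,
                effect=effect,
                vaf_pct=int(vaf),
                sub_threshold=bracketed is not None,
            )
        )
    return tuple(hits)


def _histology_of(sample_id: str) -> str:
    suffix = sample_id.split("_", 1)[1]
    return re.sub(r"\d+$", "", suffix)


def load_cohort_fixture() -> pd.DataFrame:
    """Load the packaged cohort table as a DataFrame (one row per specimen).

    Derived columns: ``patient_id``, ``histology``, ``group`` (EC / OC / AH),
    ``second_hits`` (tuple of :class:`FixtureSecondHit`), and
    ``any_hit_strict`` — LOH/pLOH affecting the wild-type allele or at least
    one somatic second-hit variant at VAF >= 5% (bracketed sub-threshold
    variants do not count here; the cross-sample rescue rule applies only to
    variant-table-level second-hit calling).

    Raises :class:`FixtureIntegrityError` if the packaged data do not pass
    structural checks (64 rows; 27 EC + 15 OC + 22 AH).
    """
    with resources.files("lynchevo.data").joinpath(_FIXTURE_RESOURCE).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"tmb": float}, keep_default_na=False)

    expected_cols = [
        "sample_id", "gene", "timepoint", "mmr_status", "loh",
        "second_hit", "tmb", "hypermutated", "ref_normal",
    ]
    if list(df.columns) != expected_cols:
        raise FixtureIntegrityError(f"unexpected columns {list(df.columns)}")

    df["patient_id"] = df["sample_id"].str.split("_").str[0]
    df["histology"] = df["sample_id"].map(_histology_of)
    df["group"] = df["histology"].map(
        lambda h: CARCINOMA_GROUP.get(Histology(h), "AH" if h == "CAH" else None)
    )
    df["second_hits"] = df["second_hit"].map(_parse_second_hits)
    df["hypermutated"] = df["hypermutated"].astype(bool)
    df["ref_normal"] = df["ref_normal"].astype(bool)
    df["any_hit_strict"] = [
        row.loh in ("LOH", "pLOH")
        or any(not h.sub_threshold for h in row.second_hits)
        for row in df.itertuples()
    ]

    if len(df) != 64:
        raise FixtureIntegrityError(f"expected 64 rows, found {len(df)}")
    counts = df["group"].value_counts()
    if not (counts.get("EC") == 27 and counts.get("OC") == 15 and counts.get("AH") == 22):
        raise FixtureIntegrityError(f"unexpected group sizes: {counts.to_dict()}")
    if df["timepoint"].gt(0).any():
        raise FixtureIntegrityError("timepoints must be <= 0")
    if not df["mmr_status"].isin(["dMMR", "pMMR"]).all():
        raise FixtureIntegrityError("MMR status must be dMMR or pMMR")
    if not df["loh"].isin(["LOH", "pLOH", "No", "N/A"]).all():
        raise FixtureIntegrityError("LOH call must be LOH/pLOH/No/N/A")
    return df
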