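"""Bundled cross-species MAPT region-homology survey values.

A small curated table of percent identities (against the human reference)
and region sizes for the MAPT regions of interest — full protein,
N-terminal exons 1–4, the big exons 4a/4a-L, and the MTBD exons 9–13 —
across primates, other mammals, and non-mammalian vertebrates.  These
values serve as reference *inputs* to the summary statistics in this
module (clade means and region-relative conservation ratios); they are not
computed by this package.

Where a species has analyzed entries for both big-exon variants, summaries
use the identity of the variant actually analyzed for that species: the
big-exon column per species prefers the 4a-L entry when one exists.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .homology import ConservationRatio, conservation_ratio

__all__ = [
    "load_survey",
    "clade_big_exon_identities",
    "clade_region_identities",
    "mammal_big_exon_mean",
    "vertebrate_big_exon_vs_mtbd_ratio",
    "human_big_exon_extension",
]

_BIG_EXON_REGIONS = ("exon4a", "exon4aL")


def load_survey() -> pd.DataFrame:
    """Load the bundled survey as a tidy DataFrame.

    Columns: clade, species, variant, region, identity_pct, size_aa.
    """
    with resources.files("exonevo.data").joinpath("mapt_survey.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    df["identity_pct"] = df["identity_pct"].astype(float)
    return df


def _pick_variant_entries(df: pd.DataFrame) -> pd.DataFrame:
    """One entry per species: the 4a-L entry when present, else the 4a one."""
    chosen = []
    for (_, species), group in df.groupby(["clade", "species"], sort=False):
        variants = set(group["variant"])
        pick = "4a-L" if "4a-L" in variants else "4a"
        chosen.append(group[group["variant"] == pick])
    return pd.concat(chosen, ignore_index=True)


def clade_big_exon_identities(
    clade: str, df: pd.DataFrame | None = None, include_human: bool = False
) -> pd.Series:
    """Per-species big-exon (4a or 4a-L) identity for one clade."""
    df = load_survey() if df is None else df
    sub = df[df["clade"] == clade]
    if not include_human:
        sub = sub[sub["species"] != "human"]
    sub = _pick_variant_entries(sub)
    sub = sub[sub["region"].isin(_BIG_EXON_REGIONS)]
    return sub.set_index("species")["identity_pct"]


def clade_region_identities(
    clade: str, region: str, df: pd.DataFrame | None = None
) -> pd.Series:
    """Per-species identity for one region in one clade (variant-picked)."""
    df = load_survey() if df is None else df
    sub = df[(df["clade"] == clade) & (df["species"] != "human")]
    sub = _pick_variant_entries(sub)
    sub = sub[sub["region"] == region]
    return sub.set_index("species")["identity_pct"]


def mammal_big_exon_mean(df: pd.DataFrame | None = None) -> float:
    """Mean 4a/4a-L identity over the surveyed non-human mammals."""
    return float(clade_big_exon_identities("mammals", df).mean())


def vertebrate_big_exon_vs_mtbd_ratio(
    df: pd.DataFrame | None = None,
) -> ConservationRatio:
    """Conservation of the big exon relative to the MTBD in non-mammalian
    vertebrates: 100 x mean(4a/4a-L identities) / mean(exons 9-13 identities)."""
    df = load_survey() if df is None else df
    big = clade_big_exon_identities("vertebrates", df)
    mtbd = clade_region_identities("vertebrates", "MTBD_9_13", df)
    return conservation_ratio(list(big), list(mtbd))


def human_big_exon_extension(df: pd.DataFrame | None = None) -> int:
    """Length difference (aa) between the human 4a-L and 4a exons."""
    df = load_survey() if df is None else df
    human = df[df["species"] == "human"]
    len_4al = human.loc[human["region"] == "exon4aL", "size_aa"].iloc[0]
    len_4a = human.loc[human["region"] == "exon4a", "size_aa"].iloc[0]
    return int(len_4al - len_4a)
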