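"""Published per-condition genus means from the reference soil experiment.

The shipped table holds the printed mean bait-masked relative abundances
(in percent) of the ten most abundant partner-experiment genera across the
six conditions, as published for the original soil study. "Not present" in
the Binder control is encoded as 0. These numbers serve as desk-scale
inputs: fold-enrichment of the trusted partner genera versus the uncultured
soil source can be computed from them without any sequencing data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .abundance import ConditionSummary, EnrichmentResult, enrichment_factor
from .report_io import Condition, Rank, TaxonKey

__all__ = ["load_published_genus_means", "published_enrichment"]

#: replicates behind each published condition mean
_PUBLISHED_N = 3


def load_published_genus_means() -> pd.DataFrame:
    """The published genus condition means as fractions in [0, 1], genus-indexed."""
    with resources.files("mipner.data").joinpath("published_genus_means.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col="genus")
    return df / 100.0


def published_enrichment(
    genus: str,
    numerator: Condition = Condition.MIPNER,
    denominator: Condition = Condition.SOIL_SOURCE,
    threshold: float = 100.0,
) -> EnrichmentResult:
    """Fold enrichment of one published genus mean between two conditions."""
    df = load_published_genus_means()
    if genus not in df.index:
        raise KeyError(f"genus {genus!r} not in the published table: {list(df.index)}")
    taxon = TaxonKey(taxid=df.index.get_loc(genus) + 1, name=genus, rank=Rank.GENUS)
    num = ConditionSummary(
        taxon=taxon, condition=numerator, mean=float(df.loc[genus, numerator.value]),
        se=0.0, n=_PUBLISHED_N,
    )
    den = ConditionSummary(
        taxon=taxon, condition=denominator, mean=float(df.loc[genus, denominator.value]),
        se=0.0, n=_PUBLISHED_N,
    )
    return enrichment_factor(num, den, threshold=threshold)
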