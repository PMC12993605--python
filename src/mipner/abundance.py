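"""Abundance post-processing: domain filtering, rank views, relative
abundances, bait masking, per-condition means and fold enrichment.

All fractions live in [0, 1] internally; percentages appear only in
rendered reports. Masking the bait genus removes *every* row of that genus
(species-level assignments of a bait genus are typically classifier
artifacts of the bait isolate's reads) and renormalizes the remaining taxa,
which preserves their pairwise ratios exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .report_io import Condition, CountTable, Rank, SampleMetadata, TaxonKey

__all__ = [
    "FilterConfig",
    "RelativeAbundanceTable",
    "ConditionSummary",
    "EnrichmentResult",
    "MissingDomainError",
    "filter_domains",
    "aggregate_to_rank",
    "to_relative",
    "mask_taxa",
    "condition_means",
    "enrichment_factor",
    "summaries_to_frame",
]

#: Tolerance on relative-abundance column sums.
COLUMN_SUM_TOL = 1e-9


class MissingDomainError(ValueError):
    """A taxon lacked a domain annotation during domain filtering."""


@dataclass(frozen=True)
class FilterConfig:
    """Which clades to drop before any abundance work.

    Defaults drop archaeal and viral rows and the Homo sapiens subtree
    (taxid 9606), leaving the bacterial (and any other) community.
    """

    excluded_domains: frozenset[str] = frozenset({"Archaea", "Viruses"})
    excluded_taxid_subtrees: frozenset[int] = frozenset({9606})


@dataclass
class RelativeAbundanceTable:
    """Taxa x samples matrix of per-sample fractions.

    Every column sums to 1 within ``COLUMN_SUM_TOL`` unless flagged in
    ``zero_columns`` (a sample whose retained counts were all zero).
    """

    taxa: list[TaxonKey]
    samples: list[SampleMetadata]
    fractions: np.ndarray
    zero_columns: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float).reshape(
            len(self.taxa), len(self.samples)
        )
        if self.zero_columns is None:
            self.zero_columns = np.zeros(len(self.samples), dtype=bool)
        self.zero_columns = np.asarray(self.zero_columns, dtype=bool).reshape(
            len(self.samples)
        )
        if self.fractions.size:
            if self.fractions.min() < 0 or self.fractions.max() > 1 + COLUMN_SUM_TOL:
                raise ValueError("fractions must lie in [0, 1]")
            sums = self.fractions.sum(axis=0)
            bad = ~self.zero_columns & (np.abs(sums - 1.0) > COLUMN_SUM_TOL) & (
                len(self.taxa) > 0
            )
            if len(self.taxa) and bad.any():
                raise ValueError(
                    f"column sums deviate from 1 beyond {COLUMN_SUM_TOL}: "
                    f"{sums[bad]}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.fractions.shape

    def sample_index(self, condition: Condition) -> list[int]:
        return [i for i, s in enumerate(self.samples) if s.condition is condition]

    def conditions(self) -> set[Condition]:
        return {s.condition for s in self.samples}

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(
            [(t.taxid, t.name, t.rank.name) for t in self.taxa],
            names=["taxid", "name", "rank"],
        )
        return pd.DataFrame(
            self.fractions, index=idx, columns=[s.sample_id for s in self.samples]
        )


@dataclass(frozen=True)
class ConditionSummary:
    """Mean +/- SE of a taxon's relative abundance over one condition's replicates."""

    taxon: TaxonKey
    condition: Condition
    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.se < 0:
            raise ValueError("se must be >= 0")
        if not (0.0 <= self.mean <= 1.0 + COLUMN_SUM_TOL):
            raise ValueError(f"mean must be a fraction in [0, 1], got {self.mean}")


@dataclass(frozen=True)
class EnrichmentResult:
    """Fold change of condition means: numerator mean / denominator mean.

    A positive numerator over a zero denominator is flagged ``infinite``
    (and meets any threshold); both zero gives factor 0.
    """

    taxon: TaxonKey
    numerator_condition: Condition
    denominator_condition: Condition
    factor: float
    infinite: bool
    meets_threshold: bool


# ---------------------------------------------------------------------------


def filter_domains(table: CountTable, cfg: FilterConfig | None = None) -> CountTable:
    """Drop rows from excluded domains or excluded taxid subtrees.

    Every taxon must carry a domain annotation (its own rank or lineage);
    silent retention of unannotated rows is an error.
    """
    cfg = cfg or FilterConfig()

    def keep(t: TaxonKey) -> bool:
        domain = t.domain
        if domain is None:
            raise MissingDomainError(
                f"taxon {t.name!r} (taxid {t.taxid}) has no domain annotation"
            )
        if domain in cfg.excluded_domains:
            return False
        if t.taxid in cfg.excluded_taxid_subtrees:
            return False
        if t.lineage_taxids and set(t.lineage_taxids) & cfg.excluded_taxid_subtrees:
            return False
        return True

    mask = [keep(t) for t in table.taxa]
    return CountTable(
        taxa=[t for t, k in zip(table.taxa, mask) if k],
        samples=list(table.samples),
        counts=table.counts[np.asarray(mask, dtype=bool), :]
        if table.taxa
        else table.counts,
    )


def aggregate_to_rank(table: CountTable, rank: Rank) -> CountTable:
    """Single-rank view: keep only rows of ``rank`` (GENUS or SPECIES).

    Counts are not summed across ranks — the classifier assigns reads per
    rank already, so selecting rows avoids double counting.
    """
    if rank not in (Rank.GENUS, Rank.SPECIES):
        raise ValueError(f"rank view supports GENUS or SPECIES, got {rank}")
    mask = [t.rank is rank for t in table.taxa]
    if not any(mask):
        warnings.warn(f"no rows at rank {rank.name}; returning empty table", stacklevel=2)
    return CountTable(
        taxa=[t for t, k in zip(table.taxa, mask) if k],
        samples=list(table.samples),
        counts=table.counts[np.asarray(mask, dtype=bool), :]
        if table.taxa
        else table.counts,
    )


def to_relative(table: CountTable) -> RelativeAbundanceTable:
    """Divide each column by its total; all-zero columns are flagged, not NaN."""
    totals = table.counts.sum(axis=0)
    zero = totals == 0
    safe = np.where(zero, 1, totals)
    fractions = table.counts / safe
    return RelativeAbundanceTable(
        taxa=list(table.taxa),
        samples=list(table.samples),
        fractions=fractions,
        zero_columns=zero,
    )


def _matches_mask(t: TaxonKey, masked: str) -> bool:
    return t.name == masked or t.genus == masked


def mask_taxa(table: RelativeAbundanceTable, masked: str) -> RelativeAbundanceTable:
    """Remove the bait taxon/genus and renormalize each column to sum to 1.

    ``masked`` matches a row by exact name or by genus (the row's own genus
    rank, a genus lineage entry, or the first token of a species binomial).
    Renormalization preserves pairwise ratios among retained taxa exactly.
    A column left empty by masking (the bait was 100 % of it) is flagged
    all-zero.
    """
    keep = np.array([not _matches_mask(t, masked) for t in table.taxa], dtype=bool)
    sub = table.fractions[keep, :] if len(table.taxa) else table.fractions
    totals = sub.sum(axis=0) if sub.size else np.zeros(len(table.samples))
    zero = table.zero_columns | (totals <= 0)
    safe = np.where(totals <= 0, 1.0, totals)
    fractions = sub / safe
    fractions[:, zero] = 0.0
    return RelativeAbundanceTable(
        taxa=[t for t, k in zip(table.taxa, keep) if k],
        samples=list(table.samples),
        fractions=fractions,
        zero_columns=zero,
    )


def condition_means(
    table: RelativeAbundanceTable, condition: Condition
) -> list[ConditionSummary]:
    """Per-taxon mean and SE (sample SD / sqrt(n)) over one condition's replicates.

    With a single replicate the SE is defined as 0 (with a warning) so the
    summary stays total.
    """
    cols = table.sample_index(condition)
    if not cols:
        raise ValueError(f"condition {condition.value} absent from table metadata")
    n = len(cols)
    if n == 1:
        warnings.warn(
            f"condition {condition.value} has a single replicate; SE set to 0",
            stacklevel=2,
        )
    sub = table.fractions[:, cols]
    means = sub.mean(axis=1)
    if n > 1:
        ses = sub.std(axis=1, ddof=1) / math.sqrt(n)
        # identical replicates have exactly zero spread; suppress float noise
        ses[sub.max(axis=1) == sub.min(axis=1)] = 0.0
    else:
        ses = np.zeros(len(table.taxa))
    return [
        ConditionSummary(taxon=t, condition=condition, mean=float(m), se=float(se), n=n)
        for t, m, se in zip(table.taxa, means, ses)
    ]


def enrichment_factor(
    summary_num: ConditionSummary,
    summary_den: ConditionSummary,
    threshold: float = 100.0,
) -> EnrichmentResult:
    """Fold enrichment of a taxon between two condition means."""
    if summary_num.taxon.key != summary_den.taxon.key:
        raise ValueError(
            f"taxon mismatch: {summary_num.taxon.name!r} vs {summary_den.taxon.name!r}"
        )
    num, den = summary_num.mean, summary_den.mean
    if den == 0.0 and num > 0.0:
        return EnrichmentResult(
            taxon=summary_num.taxon,
            numerator_condition=summary_num.condition,
            denominator_condition=summary_den.condition,
            factor=math.inf,
            infinite=True,
            meets_threshold=True,
        )
    factor = 0.0 if den == 0.0 else num / den
    return EnrichmentResult(
        taxon=summary_num.taxon,
        numerator_condition=summary_num.condition,
        denominator_condition=summary_den.condition,
        factor=factor,
        infinite=False,
        meets_threshold=factor >= threshold,
    )


def summaries_to_frame(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    """Export ConditionSummary rows as a tidy frame (taxid, name, rank, condition, mean, se, n)."""
    return pd.DataFrame(
        {
            "taxid": [s.taxon.taxid for s in summaries],
            "name": [s.taxon.name for s in summaries],
            "rank": [s.taxon.rank.name for s in summaries],
            "condition": [s.condition.value for s in summaries],
            "mean": [s.mean for s in summaries],
            "se": [s.se for s in summaries],
            "n": [s.n for s in summaries],
        }
    )
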