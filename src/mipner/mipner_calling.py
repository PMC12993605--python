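"""Partner calling: the decision procedure at the heart of the pipeline.

A taxon is a *putative microbial partner* of the bait when it shows up in
the bait-coated-applicator (MIPNER) samples but has **zero raw reads in
every stick-only BINDER replicate** — anything present in the Binder
control may simply bind the applicator stick and is unassignable. Calls are
tiered by bait-masked relative abundance: above the high tier (> 1 % in at
least one MIPNER sample) or below it, restricted to the top-N most abundant
species across the MIPNER replicates.

Genus-level trust works the same way: a genus is trusted only if it never
appears in any Binder replicate and is present in the MIPNER samples.

Taxa absent from the uncultured soil source are flagged as possible
environmental contaminants, but the flag never demotes a putative call.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .abundance import (
    ConditionSummary,
    EnrichmentResult,
    RelativeAbundanceTable,
    condition_means,
    enrichment_factor,
)
from .report_io import Condition, CountTable, Rank, TaxonKey

__all__ = [
    "BinderZeroRule",
    "ClassificationConfig",
    "MipnerStatus",
    "MipnerCall",
    "GenusTrustCall",
    "rank_candidate_species",
    "call_species_mipners",
    "call_genus_trust",
    "classification_report",
]


class BinderZeroRule(enum.Enum):
    """How 'absence in the Binder control' is defined."""

    ZERO_READS_ALL_REPLICATES = "ZERO_READS_ALL_REPLICATES"


class MipnerStatus(enum.Enum):
    PUTATIVE_HIGH = "PUTATIVE_HIGH"
    PUTATIVE_LOW = "PUTATIVE_LOW"
    UNASSIGNABLE_BINDER = "UNASSIGNABLE_BINDER"
    NOT_CANDIDATE = "NOT_CANDIDATE"


#: deterministic report ordering of statuses
_STATUS_ORDER = {
    MipnerStatus.PUTATIVE_HIGH: 0,
    MipnerStatus.PUTATIVE_LOW: 1,
    MipnerStatus.UNASSIGNABLE_BINDER: 2,
    MipnerStatus.NOT_CANDIDATE: 3,
}


@dataclass(frozen=True)
class ClassificationConfig:
    bait_genus: str = "Serratia"
    bait_species: str = "Serratia marcescens"
    high_tier_threshold: float = 0.01
    top_n_species: int = 100
    enrichment_threshold: float = 100.0
    binder_zero_rule: BinderZeroRule = BinderZeroRule.ZERO_READS_ALL_REPLICATES

    def __post_init__(self) -> None:
        if not (0.0 < self.high_tier_threshold < 1.0):
            raise ValueError(
                f"high_tier_threshold must lie strictly between 0 and 1, "
                f"got {self.high_tier_threshold}"
            )
        if self.top_n_species < 1:
            raise ValueError(f"top_n_species must be >= 1, got {self.top_n_species}")
        if self.enrichment_threshold <= 0:
            raise ValueError("enrichment_threshold must be positive")


@dataclass(frozen=True)
class MipnerCall:
    taxon: TaxonKey
    status: MipnerStatus
    max_mipner_fraction: float
    mean_mipner_fraction: float
    binder_read_total: int
    enrichment: EnrichmentResult
    contaminant_flag: bool
    in_top_n: bool

    def __post_init__(self) -> None:
        if self.status is MipnerStatus.UNASSIGNABLE_BINDER and self.binder_read_total <= 0:
            raise ValueError("UNASSIGNABLE_BINDER requires binder reads > 0")
        if self.status in (MipnerStatus.PUTATIVE_HIGH, MipnerStatus.PUTATIVE_LOW):
            if self.binder_read_total != 0 or self.max_mipner_fraction <= 0:
                raise ValueError(
                    "putative calls require zero binder reads and a positive "
                    "MIPNER fraction"
                )


@dataclass(frozen=True)
class GenusTrustCall:
    genus: TaxonKey
    trusted: bool
    binder_presence: bool
    mipner_mean: float
    enrichment: EnrichmentResult

    def __post_init__(self) -> None:
        if self.trusted and self.binder_presence:
            raise ValueError("a genus present in the Binder control cannot be trusted")


# ---------------------------------------------------------------------------


def _require_conditions(conditions: set[Condition], needed: Sequence[Condition]) -> None:
    missing = [c.value for c in needed if c not in conditions]
    if missing:
        raise ValueError(f"required condition(s) missing from metadata: {missing}")


def _check_no_bait(table: RelativeAbundanceTable, cfg: ClassificationConfig) -> None:
    offenders = [t.name for t in table.taxa if t.genus == cfg.bait_genus or t.name == cfg.bait_genus]
    if offenders:
        raise ValueError(
            f"bait genus {cfg.bait_genus!r} present in a table that must be "
            f"bait-masked: {offenders[:5]}"
        )


def rank_candidate_species(
    mipner_table: RelativeAbundanceTable, n: int
) -> list[TaxonKey]:
    """Top-``n`` taxa by mean fraction across the MIPNER replicates.

    Ordering: mean descending, ties by max fraction descending, then taxid
    ascending. Only taxa with a nonzero mean are candidates; fewer than
    ``n`` nonzero taxa yields a shorter list.
    """
    cols = mipner_table.sample_index(Condition.MIPNER)
    if not cols:
        raise ValueError("no MIPNER samples in table")
    sub = mipner_table.fractions[:, cols]
    means = sub.mean(axis=1)
    maxes = sub.max(axis=1) if sub.size else means
    order = sorted(
        (i for i in range(len(mipner_table.taxa)) if means[i] > 0),
        key=lambda i: (-means[i], -maxes[i], mipner_table.taxa[i].taxid),
    )
    return [mipner_table.taxa[i] for i in order[:n]]


def call_species_mipners(
    masked_rel: RelativeAbundanceTable,
    raw_counts: CountTable,
    cfg: ClassificationConfig | None = None,
) -> list[MipnerCall]:
    """Classify species-level taxa as putative partners, binder artifacts or neither.

    ``masked_rel`` is the bait-masked species-level relative table over all
    conditions; ``raw_counts`` the unmasked species-level count table used
    for the raw-read Binder-absence and soil-source contaminant checks.

    Per taxon in the top-N candidate list:

    * any raw Binder read (summed over replicates) -> UNASSIGNABLE_BINDER;
    * else max masked MIPNER fraction strictly above the high tier
      threshold -> PUTATIVE_HIGH;
    * else a positive MIPNER fraction -> PUTATIVE_LOW.

    Taxa outside the top-N, or with zero MIPNER fraction, are
    NOT_CANDIDATE, so report totals reconcile with the input taxa universe.
    Every call carries the MIPNER-vs-SOIL_SOURCE fold enrichment and a
    contaminant flag (zero soil-source reads in every replicate).
    """
    cfg = cfg or ClassificationConfig()
    _require_conditions(
        masked_rel.conditions(), (Condition.MIPNER, Condition.BINDER, Condition.SOIL_SOURCE)
    )
    _require_conditions(
        raw_counts.conditions(), (Condition.MIPNER, Condition.BINDER, Condition.SOIL_SOURCE)
    )
    _check_no_bait(masked_rel, cfg)

    raw_rows = raw_counts.row_index()
    missing = [t.name for t in masked_rel.taxa if t.key not in raw_rows]
    if missing:
        raise ValueError(
            f"taxa present in the masked table but absent from raw counts: "
            f"{missing[:5]}"
        )

    binder_cols = raw_counts.sample_index(Condition.BINDER)
    soil_cols = raw_counts.sample_index(Condition.SOIL_SOURCE)
    mipner_cols = masked_rel.sample_index(Condition.MIPNER)

    top = {t.key for t in rank_candidate_species(masked_rel, cfg.top_n_species)}
    mipner_summaries = condition_means(masked_rel, Condition.MIPNER)
    soil_summaries = condition_means(masked_rel, Condition.SOIL_SOURCE)

    calls: list[MipnerCall] = []
    for i, taxon in enumerate(masked_rel.taxa):
        raw_row = raw_counts.counts[raw_rows[taxon.key], :]
        binder_total = int(raw_row[binder_cols].sum())
        fracs = masked_rel.fractions[i, mipner_cols]
        max_frac = float(fracs.max())
        mean_frac = float(fracs.mean())
        in_top_n = taxon.key in top

        if not in_top_n or max_frac == 0.0:
            status = MipnerStatus.NOT_CANDIDATE
        elif binder_total > 0:
            status = MipnerStatus.UNASSIGNABLE_BINDER
        elif max_frac > cfg.high_tier_threshold:
            status = MipnerStatus.PUTATIVE_HIGH
        else:
            status = MipnerStatus.PUTATIVE_LOW

        enrichment = enrichment_factor(
            mipner_summaries[i], soil_summaries[i], cfg.enrichment_threshold
        )
        contaminant = bool((raw_row[soil_cols] == 0).all())
        calls.append(
            MipnerCall(
                taxon=taxon,
                status=status,
                max_mipner_fraction=max_frac,
                mean_mipner_fraction=mean_frac,
                binder_read_total=binder_total,
                enrichment=enrichment,
                contaminant_flag=contaminant,
                in_top_n=in_top_n,
            )
        )

    calls.sort(
        key=lambda c: (
            _STATUS_ORDER[c.status],
            -c.mean_mipner_fraction,
            c.taxon.taxid,
        )
    )
    return calls


def call_genus_trust(
    genus_rel: RelativeAbundanceTable,
    raw_counts: CountTable,
    cfg: ClassificationConfig | None = None,
) -> list[GenusTrustCall]:
    """Genus-level trust calls: trusted iff absent from every Binder replicate
    and present (positive mean masked fraction) in the MIPNER samples."""
    cfg = cfg or ClassificationConfig()
    _require_conditions(
        genus_rel.conditions(), (Condition.MIPNER, Condition.BINDER, Condition.SOIL_SOURCE)
    )
    _require_conditions(
        raw_counts.conditions(), (Condition.MIPNER, Condition.BINDER, Condition.SOIL_SOURCE)
    )
    _check_no_bait(genus_rel, cfg)

    raw_rows = raw_counts.row_index()
    binder_cols = raw_counts.sample_index(Condition.BINDER)
    mipner_summaries = condition_means(genus_rel, Condition.MIPNER)
    soil_summaries = condition_means(genus_rel, Condition.SOIL_SOURCE)

    calls = []
    for i, genus in enumerate(genus_rel.taxa):
        if genus.key not in raw_rows:
            raise ValueError(f"genus {genus.name!r} absent from raw counts")
        binder_presence = bool(
            (raw_counts.counts[raw_rows[genus.key], binder_cols] > 0).any()
        )
        mipner_mean = mipner_summaries[i].mean
        calls.append(
            GenusTrustCall(
                genus=genus,
                trusted=(not binder_presence) and mipner_mean > 0,
                binder_presence=binder_presence,
                mipner_mean=mipner_mean,
                enrichment=enrichment_factor(
                    mipner_summaries[i], soil_summaries[i], cfg.enrichment_threshold
                ),
            )
        )
    calls.sort(key=lambda c: (-c.mipner_mean, c.genus.taxid))
    return calls


# ---------------------------------------------------------------------------


def calls_to_frame(calls: Sequence[MipnerCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxid": [c.taxon.taxid for c in calls],
            "name": [c.taxon.name for c in calls],
            "rank": [c.taxon.rank.name for c in calls],
            "status": [c.status.value for c in calls],
            "max_mipner_fraction": [c.max_mipner_fraction for c in calls],
            "mean_mipner_fraction": [c.mean_mipner_fraction for c in calls],
            "binder_read_total": [c.binder_read_total for c in calls],
            "enrichment_factor": [c.enrichment.factor for c in calls],
            "enrichment_infinite": [c.enrichment.infinite for c in calls],
            "meets_enrichment": [c.enrichment.meets_threshold for c in calls],
            "contaminant_flag": [c.contaminant_flag for c in calls],
            "in_top_n": [c.in_top_n for c in calls],
        }
    )


def trust_to_frame(calls: Sequence[GenusTrustCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxid": [c.genus.taxid for c in calls],
            "name": [c.genus.name for c in calls],
            "trusted": [c.trusted for c in calls],
            "binder_presence": [c.binder_presence for c in calls],
            "mipner_mean": [c.mipner_mean for c in calls],
            "enrichment_factor": [c.enrichment.factor for c in calls],
            "enrichment_infinite": [c.enrichment.infinite for c in calls],
            "meets_enrichment": [c.enrichment.meets_threshold for c in calls],
        }
    )


def classification_report(
    calls: Sequence[MipnerCall],
    trust_calls: Sequence[GenusTrustCall] | None = None,
) -> str:
    """Render calls as a TSV string with a '#'-prefixed tier-count footer.

    Rows are ordered by status then mean MIPNER fraction descending (the
    order :func:`call_species_mipners` already produces).
    """
    ordered = sorted(
        calls,
        key=lambda c: (_STATUS_ORDER[c.status], -c.mean_mipner_fraction, c.taxon.taxid),
    )
    buf = io.StringIO()
    calls_to_frame(ordered).to_csv(buf, sep="\t", index=False)
    tally = {s: 0 for s in MipnerStatus}
    for c in ordered:
        tally[c.status] += 1
    footer = "\t".join(f"{s.value}={tally[s]}" for s in _STATUS_ORDER)
    buf.write(f"# status_counts\t{footer}\n")
    if trust_calls is not None:
        trusted = sum(1 for t in trust_calls if t.trusted)
        buf.write(f"# trusted_genera\t{trusted}/{len(trust_calls)}\n")
    return buf.getvalue()
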