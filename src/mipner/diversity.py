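"""Alpha diversity, group comparisons and shared-taxa set intersections.

Richness counts taxa with at least one read; diversity uses Simpson's index
of diversity, 1 - sum(p_i^2) — the probability that two randomly drawn
reads come from different taxa. Group comparison is a one-way fixed-effects
ANOVA with Tukey HSD post-hoc tests. Shared-taxa analysis reports, for
every combination of conditions, how many taxa occur in exactly that
combination (the disjoint regions an upset plot displays).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .abundance import aggregate_to_rank
from .report_io import Condition, CountTable, Rank

__all__ = [
    "DiversitySummary",
    "AnovaResult",
    "TukeyResult",
    "SharedTaxaSets",
    "alpha_diversity",
    "one_way_anova",
    "tukey_hsd",
    "shared_taxa",
]


@dataclass(frozen=True)
class DiversitySummary:
    """Per-sample richness and Simpson diversity at one rank.

    ``simpson`` is None for an all-zero sample (undefined, not 0).
    """

    sample_id: str
    rank: Rank
    richness: int
    simpson: float | None


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_labels: tuple[Hashable, ...]


@dataclass(frozen=True)
class TukeyResult:
    """All-pairs mean differences with studentized-range adjusted p-values."""

    pairs: tuple[tuple[Hashable, Hashable, float, float], ...]


@dataclass(frozen=True)
class SharedTaxaSets:
    """Per-condition presence sets and the 2^k - 1 disjoint region counts.

    ``region_counts`` maps a frozenset of conditions to the number of taxa
    present in exactly those conditions (and no other).
    """

    rank: Rank
    sets: dict[Condition, frozenset[int]]
    region_counts: dict[frozenset[Condition], int]

    def union_size(self) -> int:
        out: set[int] = set()
        for s in self.sets.values():
            out |= s
        return len(out)

    def lost_from(
        self, source: Condition, cultured: Sequence[Condition] | None = None
    ) -> int:
        """Taxa present in ``source`` but in none of the ``cultured`` conditions.

        Default cultured set: SOIL_CULTURE, MIXNER_A, MIXNER_B (whichever
        are present) — the "lost through culturing" count.
        """
        if cultured is None:
            cultured = [
                c
                for c in (Condition.SOIL_CULTURE, Condition.MIXNER_A, Condition.MIXNER_B)
                if c in self.sets
            ]
        if source not in self.sets:
            raise ValueError(f"source condition {source.value} not in sets")
        union: set[int] = set()
        for c in cultured:
            union |= self.sets[c]
        return len(self.sets[source] - union)


# ---------------------------------------------------------------------------


def alpha_diversity(table: CountTable, rank: Rank) -> list[DiversitySummary]:
    """Richness and Simpson's index of diversity per sample at one rank."""
    view = table if all(t.rank is rank for t in table.taxa) else aggregate_to_rank(table, rank)
    out = []
    for j, sample in enumerate(view.samples):
        col = view.counts[:, j]
        total = col.sum()
        richness = int((col > 0).sum())
        if total == 0:
            simpson = None
        else:
            p = col / total
            simpson = float(1.0 - np.sum(p * p))
        out.append(
            DiversitySummary(
                sample_id=sample.sample_id, rank=rank, richness=richness, simpson=simpson
            )
        )
    return out


def one_way_anova(values: Sequence[float], groups: Sequence[Hashable]) -> AnovaResult:
    """One-way fixed-effects ANOVA.

    Degenerate inputs where every value is identical give F = 0, p = 1
    (scipy would return NaN for the 0/0 mean-square ratio).
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    labels = list(dict.fromkeys(groups))  # first-seen order
    by_group = [values[np.asarray([g == lab for g in groups])] for lab in labels]
    if len(labels) < 2:
        raise ValueError("ANOVA requires at least two groups")
    if any(len(v) == 0 for v in by_group):
        raise ValueError("every group needs at least one value")
    if all(len(v) < 2 for v in by_group):
        raise ValueError("at least one group needs two or more values")

    df_between = len(labels) - 1
    df_within = len(values) - len(labels)
    if np.allclose(values, values[0]):
        return AnovaResult(0.0, df_between, df_within, 1.0, tuple(labels))
    f_stat, p_value = scipy.stats.f_oneway(*by_group)
    return AnovaResult(float(f_stat), df_between, df_within, float(p_value), tuple(labels))


def tukey_hsd(values: Sequence[float], groups: Sequence[Hashable]) -> TukeyResult:
    """Tukey HSD pairwise comparisons (studentized-range adjusted p).

    Every group needs n >= 2: HSD's pooled within-group variance is
    undefined for singleton groups.
    """
    values = np.asarray(values, dtype=float)
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ValueError("Tukey HSD requires at least two groups")
    counts = {lab: sum(1 for g in groups if g == lab) for lab in labels}
    singletons = [lab for lab, n in counts.items() if n < 2]
    if singletons:
        raise ValueError(f"Tukey HSD undefined for singleton group(s): {singletons}")

    res = pairwise_tukeyhsd(values, np.asarray([str(g) for g in groups]))
    by_str = {str(lab): lab for lab in labels}
    uniq = list(res.groupsunique)
    pair_labels = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1 :]]
    pairs = tuple(
        (by_str[a], by_str[b], float(diff), float(p))
        for (a, b), diff, p in zip(pair_labels, res.meandiffs, res.pvalues)
    )
    return TukeyResult(pairs=pairs)


def shared_taxa(table: CountTable, rank: Rank) -> SharedTaxaSets:
    """Per-condition presence sets and exact-region intersection counts.

    A taxon belongs to a condition's set iff any replicate of that
    condition has at least one read. Region counts cover every non-empty
    combination of the conditions present, counting taxa found in exactly
    that combination.
    """
    view = table if all(t.rank is rank for t in table.taxa) else aggregate_to_rank(table, rank)
    conditions = sorted(view.conditions(), key=lambda c: c.value)
    if len(conditions) < 2:
        raise ValueError("shared_taxa requires at least two conditions")

    sets: dict[Condition, frozenset[int]] = {}
    for cond in conditions:
        cols = view.sample_index(cond)
        present = view.counts[:, cols].sum(axis=1) > 0
        sets[cond] = frozenset(t.taxid for t, p in zip(view.taxa, present) if p)

    membership: dict[int, frozenset[Condition]] = {}
    for cond, s in sets.items():
        for taxid in s:
            membership[taxid] = membership.get(taxid, frozenset()) | {cond}

    region_counts: dict[frozenset[Condition], int] = {}
    for r in range(1, len(conditions) + 1):
        for combo in combinations(conditions, r):
            region_counts[frozenset(combo)] = 0
    for combo_set in membership.values():
        region_counts[combo_set] += 1
    return SharedTaxaSets(rank=rank, sets=sets, region_counts=region_counts)


def diversity_to_frame(summaries: Sequence[DiversitySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [d.sample_id for d in summaries],
            "rank": [d.rank.name for d in summaries],
            "richness": [d.richness for d in summaries],
            "simpson": [d.simpson if d.simpson is not None else np.nan for d in summaries],
        }
    )
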