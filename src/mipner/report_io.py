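"""Reading and writing taxonomic count tables.

The pipeline consumes per-sample read-classification reports (Kraken-style
six-column reports, Bracken abundance files) and works internally on a
merged :class:`CountTable`: taxa as rows, samples as columns, raw read
counts as values, with per-sample experimental condition attached.

The merged table round-trips through a strict TSV dialect
(``write_table`` / ``read_combined_table``) whose sample columns encode the
metadata as ``sample_id|CONDITION|replicate``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Rank",
    "Condition",
    "TaxonKey",
    "SampleMetadata",
    "CountTable",
    "ReportParseError",
    "parse_kraken_report",
    "parse_bracken_file",
    "merge_tables",
    "read_combined_table",
    "write_table",
    "read_metadata",
    "write_metadata",
]


class Rank(enum.Enum):
    """Taxonomic rank of a row. Sub-ranks (Kraken G1, S2, ...) map to OTHER."""

    DOMAIN = 1
    PHYLUM = 2
    CLASS = 3
    ORDER = 4
    FAMILY = 5
    GENUS = 6
    SPECIES = 7
    OTHER = 8


class Condition(enum.Enum):
    """Experimental condition of a sample.

    SOIL_SOURCE   uncultured soil-suspension community (reference).
    SOIL_CULTURE  soil suspension plated without the bait.
    MIXNER_A/B    soil suspension co-plated with the bait at two doses.
    BINDER        applicator stick dipped in soil only (stick-binding control).
    MIPNER        bait-coated applicator stick dipped in soil (the experiment).
    """

    SOIL_SOURCE = "SOIL_SOURCE"
    SOIL_CULTURE = "SOIL_CULTURE"
    MIXNER_A = "MIXNER_A"
    MIXNER_B = "MIXNER_B"
    BINDER = "BINDER"
    MIPNER = "MIPNER"


#: Kraken rank codes -> Rank. Codes with a digit suffix (G1, S2, ...) and
#: unknown codes map to OTHER.
_KRAKEN_RANK_CODES = {
    "D": Rank.DOMAIN,
    "P": Rank.PHYLUM,
    "C": Rank.CLASS,
    "O": Rank.ORDER,
    "F": Rank.FAMILY,
    "G": Rank.GENUS,
    "S": Rank.SPECIES,
}


class ReportParseError(ValueError):
    """A report file violated its dialect (bad column count, bad value...)."""


@dataclass(frozen=True)
class TaxonKey:
    """Identity of one taxon row.

    ``lineage`` holds (rank, name) ancestor pairs where known (innermost
    last); ``lineage_taxids`` the matching ancestor taxids, used for
    subtree-based filtering (e.g. removing everything under Homo sapiens).
    """

    taxid: int
    name: str
    rank: Rank
    lineage: tuple[tuple[Rank, str], ...] | None = None
    lineage_taxids: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.taxid <= 0:
            raise ValueError(f"taxid must be positive, got {self.taxid}")
        if not isinstance(self.rank, Rank):
            raise TypeError(f"rank must be a Rank, got {self.rank!r}")

    @property
    def key(self) -> tuple[int, int]:
        """(rank order, taxid) — the unique row key, also the sort key."""
        return (self.rank.value, self.taxid)

    @property
    def domain(self) -> str | None:
        """Domain-level annotation, or None if the lineage does not carry one."""
        if self.rank is Rank.DOMAIN:
            return self.name
        if self.lineage:
            for rank, name in self.lineage:
                if rank is Rank.DOMAIN:
                    return name
        return None

    @property
    def genus(self) -> str | None:
        """Genus name: the row itself, a lineage entry, or the binomial's first token."""
        if self.rank is Rank.GENUS:
            return self.name
        if self.lineage:
            for rank, name in self.lineage:
                if rank is Rank.GENUS:
                    return name
        if self.rank is Rank.SPECIES and " " in self.name:
            return self.name.split()[0]
        return None


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    condition: Condition
    replicate: int

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if not isinstance(self.condition, Condition):
            raise TypeError(f"condition must be a Condition, got {self.condition!r}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")


def _validate_axes(
    taxa: Sequence[TaxonKey], samples: Sequence[SampleMetadata], matrix: np.ndarray
) -> None:
    keys = [t.key for t in taxa]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (rank, taxid) rows: {dupes}")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in sample list")
    if matrix.shape != (len(taxa), len(samples)):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match "
            f"{len(taxa)} taxa x {len(samples)} samples"
        )


@dataclass
class CountTable:
    """Taxa x samples matrix of non-negative integer read counts."""

    taxa: list[TaxonKey]
    samples: list[SampleMetadata]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.size and not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise ValueError("counts must be integers")
            self.counts = as_int
        self.counts = self.counts.astype(np.int64).reshape(
            len(self.taxa), len(self.samples)
        )
        _validate_axes(self.taxa, self.samples, self.counts)
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")

    # -- convenience -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_index(self, condition: Condition) -> list[int]:
        return [i for i, s in enumerate(self.samples) if s.condition is condition]

    def conditions(self) -> set[Condition]:
        return {s.condition for s in self.samples}

    def row_index(self) -> dict[tuple[int, int], int]:
        return {t.key: i for i, t in enumerate(self.taxa)}

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame with (taxid, name, rank) index, sample_id columns."""
        idx = pd.MultiIndex.from_tuples(
            [(t.taxid, t.name, t.rank.name) for t in self.taxa],
            names=["taxid", "name", "rank"],
        )
        return pd.DataFrame(
            self.counts, index=idx, columns=[s.sample_id for s in self.samples]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.samples == other.samples
            and np.array_equal(self.counts, other.counts)
        )


# ---------------------------------------------------------------------------
# Kraken-style report
# ---------------------------------------------------------------------------

def _kraken_rank(code: str) -> Rank:
    return _KRAKEN_RANK_CODES.get(code, Rank.OTHER)


def parse_kraken_report(path: str | Path, sample: SampleMetadata) -> CountTable:
    """Parse a six-column Kraken-style report into a one-sample CountTable.

    Columns: percent, clade reads, direct reads, rank code, taxid, indented
    name. The *direct* read count becomes the taxon count (clade-cumulative
    counts would double-count when genus and species rows coexist).
    Lineage (and ancestor taxids) is reconstructed from the two-space
    indentation of the name column. Unclassified rows (taxid 0) are counted
    and dropped with a warning.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ReportParseError(f"{path}: empty report")

    taxa: list[TaxonKey] = []
    counts: list[int] = []
    # stack of (depth, rank, name, taxid) for lineage reconstruction
    stack: list[tuple[int, Rank, str, int]] = []
    n_unclassified = 0
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) != 6:
            raise ReportParseError(
                f"{path}: line {lineno}: expected 6 tab-separated columns, "
                f"got {len(fields)}"
            )
        _, _, direct_s, rank_code, taxid_s, raw_name = fields
        try:
            direct = int(direct_s)
            taxid = int(taxid_s)
        except ValueError as exc:
            raise ReportParseError(
                f"{path}: line {lineno}: non-integer count or taxid: {exc}"
            ) from None
        if direct < 0:
            raise ReportParseError(f"{path}: line {lineno}: negative count {direct}")
        if rank_code.startswith("U") or taxid == 0:
            n_unclassified += 1
            continue
        name = raw_name.lstrip(" ")
        depth = (len(raw_name) - len(name)) // 2
        rank = _kraken_rank(rank_code)
        while stack and stack[-1][0] >= depth:
            stack.pop()
        lineage = tuple((r, n) for _, r, n, _ in stack) or None
        lineage_taxids = tuple(t for _, _, _, t in stack) or None
        taxa.append(
            TaxonKey(
                taxid=taxid,
                name=name,
                rank=rank,
                lineage=lineage,
                lineage_taxids=lineage_taxids,
            )
        )
        counts.append(direct)
        stack.append((depth, rank, name, taxid))

    if n_unclassified:
        warnings.warn(
            f"{path}: dropped {n_unclassified} unclassified row(s) (taxid 0)",
            stacklevel=2,
        )
    if not taxa:
        raise ReportParseError(f"{path}: no classified rows")
    return CountTable(taxa=taxa, samples=[sample], counts=np.array(counts)[:, None])


# ---------------------------------------------------------------------------
# Bracken file
# ---------------------------------------------------------------------------

_BRACKEN_REQUIRED = ("name", "taxonomy_id", "new_est_reads")


def parse_bracken_file(
    path: str | Path,
    sample: SampleMetadata,
    rank: Rank,
    domain_map: Mapping[int, str] | None = None,
) -> CountTable:
    """Parse a Bracken abundance file (one rank per file).

    ``new_est_reads`` becomes the count; the ``fraction_total_reads``
    column is ignored and recomputed downstream. ``domain_map`` optionally
    attaches a domain name per taxid (Bracken files carry no lineage, and
    domain filtering requires one).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _BRACKEN_REQUIRED if c not in df.columns]
    if missing:
        raise ReportParseError(f"{path}: missing column(s) {missing}")
    if df["taxonomy_id"].duplicated().any():
        dupes = sorted(df.loc[df["taxonomy_id"].duplicated(), "taxonomy_id"])
        raise ReportParseError(f"{path}: duplicate taxid row(s): {dupes}")
    reads = df["new_est_reads"]
    if (reads < 0).any():
        raise ReportParseError(f"{path}: negative new_est_reads value")

    taxa = []
    for _, row in df.iterrows():
        taxid = int(row["taxonomy_id"])
        lineage = None
        if domain_map is not None and taxid in domain_map:
            lineage = ((Rank.DOMAIN, domain_map[taxid]),)
        taxa.append(TaxonKey(taxid=taxid, name=str(row["name"]), rank=rank, lineage=lineage))
    return CountTable(
        taxa=taxa, samples=[sample], counts=reads.to_numpy(dtype=np.int64)[:, None]
    )


# ---------------------------------------------------------------------------
# Merge
# ---------------------------------------------------------------------------

def merge_tables(tables: Sequence[CountTable]) -> CountTable:
    """Merge single- or multi-sample tables into one table.

    Taxa are unioned (absent cells filled with 0), columns keep input
    order, rows are normalized to (rank, taxid) ascending order so output
    is deterministic regardless of input row order.
    """
    if not tables:
        raise ValueError("merge_tables requires at least one table")
    samples: list[SampleMetadata] = []
    seen_ids: set[str] = set()
    for t in tables:
        for s in t.samples:
            if s.sample_id in seen_ids:
                raise ValueError(f"duplicate sample_id across tables: {s.sample_id!r}")
            seen_ids.add(s.sample_id)
            samples.append(s)

    union: dict[tuple[int, int], TaxonKey] = {}
    for t in tables:
        for tax in t.taxa:
            prev = union.get(tax.key)
            if prev is None:
                union[tax.key] = tax
            else:
                if prev.name != tax.name:
                    raise ValueError(
                        f"conflicting names for taxid {tax.taxid} ({prev.rank.name}): "
                        f"{prev.name!r} vs {tax.name!r}"
                    )
                if prev.lineage is None and tax.lineage is not None:
                    union[tax.key] = tax
    taxa = [union[k] for k in sorted(union)]
    row_of = {k: i for i, k in enumerate(sorted(union))}

    counts = np.zeros((len(taxa), len(samples)), dtype=np.int64)
    col = 0
    for t in tables:
        for j in range(len(t.samples)):
            for tax, c in zip(t.taxa, t.counts[:, j]):
                counts[row_of[tax.key], col] = c
            col += 1
    return CountTable(taxa=taxa, samples=samples, counts=counts)


# ---------------------------------------------------------------------------
# Combined-table TSV round trip
# ---------------------------------------------------------------------------

_FIXED_COLUMNS = ["name", "taxid", "rank", "domain"]


def _sample_header(s: SampleMetadata) -> str:
    return f"{s.sample_id}|{s.condition.value}|{s.replicate}"


def _parse_sample_header(col: str) -> SampleMetadata:
    parts = col.split("|")
    if len(parts) != 3:
        raise ReportParseError(
            f"unrecognized column {col!r}: expected fixed columns "
            f"{_FIXED_COLUMNS} or a sample column 'sample_id|CONDITION|replicate'"
        )
    sample_id, cond_s, rep_s = parts
    try:
        condition = Condition(cond_s)
    except ValueError:
        valid = ", ".join(c.value for c in Condition)
        raise ReportParseError(
            f"unknown condition {cond_s!r} in metadata header {col!r}; "
            f"valid conditions: {valid}"
        ) from None
    try:
        replicate = int(rep_s)
    except ValueError:
        raise ReportParseError(f"non-integer replicate in header {col!r}") from None
    return SampleMetadata(sample_id=sample_id, condition=condition, replicate=replicate)


def write_table(table: CountTable, path: str | Path) -> Path:
    """Write the combined-table TSV (columns: name, taxid, rank, domain, samples).

    Lineage detail beyond the domain is not persisted; reading the file
    back yields taxa annotated with a domain-only lineage.
    """
    path = Path(path)
    data = {
        "name": [t.name for t in table.taxa],
        "taxid": [t.taxid for t in table.taxa],
        "rank": [t.rank.name for t in table.taxa],
        "domain": [t.domain or "" for t in table.taxa],
    }
    df = pd.DataFrame(data)
    for j, s in enumerate(table.samples):
        df[_sample_header(s)] = table.counts[:, j]
    df.to_csv(path, sep="\t", index=False)
    return path


def read_combined_table(path: str | Path) -> CountTable:
    """Read a combined-table TSV written by :func:`write_table` (strict dialect)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "domain": str})
    cols = list(df.columns)
    if cols[: len(_FIXED_COLUMNS)] != _FIXED_COLUMNS:
        raise ReportParseError(
            f"{path}: expected leading columns {_FIXED_COLUMNS}, got {cols[:4]}"
        )
    samples = [_parse_sample_header(c) for c in cols[len(_FIXED_COLUMNS):]]

    taxa = []
    for _, row in df.iterrows():
        try:
            rank = Rank[row["rank"]]
        except KeyError:
            raise ReportParseError(
                f"{path}: unknown rank {row['rank']!r} "
                f"(valid: {[r.name for r in Rank]})"
            ) from None
        domain = row["domain"]
        lineage = None
        if isinstance(domain, str) and domain:
            if rank is Rank.DOMAIN:
                lineage = None  # the row itself carries the domain
            else:
                lineage = ((Rank.DOMAIN, domain),)
        taxa.append(TaxonKey(taxid=int(row["taxid"]), name=row["name"], rank=rank, lineage=lineage))

    if samples:
        counts = df[cols[len(_FIXED_COLUMNS):]].to_numpy()
    else:
        counts = np.zeros((len(taxa), 0), dtype=np.int64)
    if counts.size and not np.issubdtype(counts.dtype, np.integer):
        raise ReportParseError(f"{path}: non-integer count values")
    return CountTable(taxa=taxa, samples=samples, counts=counts)


# ---------------------------------------------------------------------------
# Metadata TSV
# ---------------------------------------------------------------------------

def write_metadata(samples: Iterable[SampleMetadata], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "condition": [s.condition.value for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the sample metadata TSV (columns: sample_id, condition, replicate)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    expected = ["sample_id", "condition", "replicate"]
    if list(df.columns) != expected:
        raise ReportParseError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    out = []
    for _, row in df.iterrows():
        try:
            condition = Condition(row["condition"])
        except ValueError:
            valid = ", ".join(c.value for c in Condition)
            raise ReportParseError(
                f"{path}: unknown condition {row['condition']!r}; valid: {valid}"
            ) from None
        out.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                condition=condition,
                replicate=int(row["replicate"]),
            )
        )
    return out
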