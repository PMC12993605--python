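"""Synthetic bait-partner experiments with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* a diverse soil community (symmetric Dirichlet base composition whose low
  concentration yields a long rare tail),
* a culture bottleneck (most taxa cannot grow on the plate; survivors get
  lognormal growth factors),
* a bait spiked at a known fraction of reads wherever bait was added, with
  a few satellite species of the bait genus emulating classifier artifacts
  of the bait's own reads,
* stick-binding taxa that dominate the Binder control, and
* rare soil taxa that bind the bait and are therefore strongly enriched
  only in the MIPNER condition.

Transfer from the applicator stick requires adhesion: taxa without any
stick-binding propensity are simply not plated in the Binder control (the
rinse removes unbound cells), which is why most taxa show literally zero
Binder reads. A configurable subset of background taxa are weak stick
binders; planted binders bind strongly. In the MIPNER condition the bait
coats most of the stick, so stick carry-over is attenuated.

Everything is driven by a single :class:`numpy.random.Generator` seeded
from the config, so equal seeds give byte-identical experiments.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .report_io import (
    Condition,
    CountTable,
    Rank,
    SampleMetadata,
    TaxonKey,
    write_metadata,
    write_table,
)

__all__ = [
    "Role",
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_experiment",
    "write_fixture",
]

_BAIT_GENUS = "Serratia"
_BAIT_SPECIES = "Serratia marcescens"
#: share of bait reads misassigned to satellite species of the bait genus
_SATELLITE_READ_SHARE = 0.015

_SPECIES_TAXID_BASE = 10_000
_GENUS_TAXID_BASE = 1_000_000


class Role(enum.Enum):
    BAIT = "BAIT"
    PLANTED_BINDER = "PLANTED_BINDER"
    PLANTED_MIPNER = "PLANTED_MIPNER"
    BACKGROUND = "BACKGROUND"


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic experiment. ``seed`` is required."""

    seed: int
    n_taxa: int = 800
    n_replicates: int = 3
    depth: int = 1_000_000
    base_concentration: float = 0.3
    culturable_fraction: float = 0.2
    bait_fraction_mixner_a: float = 0.6
    bait_fraction_mixner_b: float = 0.8
    bait_fraction_mipner: float = 0.7
    n_planted_binders: int = 5
    binder_capture_weight: float = 500.0
    n_planted_mipners: int = 8
    mipner_capture_weight: float = 500.0
    binder_carryover_in_mipner: bool = True
    mipner_stick_attenuation: float = 0.02
    weak_binder_fraction: float = 0.15
    weak_binder_sigma: float = 1.0
    growth_sigma: float = 2.5
    n_bait_satellites: int = 3

    def __post_init__(self) -> None:
        problems = []
        if self.depth < 1:
            problems.append(f"depth must be >= 1, got {self.depth}")
        if self.n_replicates < 1:
            problems.append("n_replicates must be >= 1")
        for name in (
            "culturable_fraction",
            "bait_fraction_mixner_a",
            "bait_fraction_mixner_b",
            "bait_fraction_mipner",
            "weak_binder_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                problems.append(f"{name} must lie in [0, 1], got {v}")
        if self.base_concentration <= 0:
            problems.append("base_concentration must be positive")
        if 1 + self.n_planted_binders + self.n_planted_mipners > self.n_taxa:
            problems.append(
                "planted roles plus the bait exceed n_taxa "
                f"({self.n_planted_binders} binders + {self.n_planted_mipners} "
                f"partners + 1 bait > {self.n_taxa})"
            )
        if problems:
            raise ValueError("; ".join(problems))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object], seed: int | None = None) -> "SyntheticConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown SyntheticConfig field(s): {sorted(unknown)}")
        kwargs = dict(mapping)
        if seed is not None:
            kwargs["seed"] = seed
        if "seed" not in kwargs:
            raise ValueError("SyntheticConfig requires an explicit seed")
        return cls(**kwargs)  # type: ignore[arg-type]


@dataclass
class SyntheticTruth:
    """Planted per-taxon roles, culturability and realized base fractions.

    Rows are species-level, aligned with the species rows of the simulated
    table.
    """

    taxa: list[TaxonKey]
    roles: list[Role]
    culturable: list[bool]
    base_fractions: list[float]

    def __post_init__(self) -> None:
        if sum(1 for r in self.roles if r is Role.BAIT) != 1:
            raise ValueError("exactly one BAIT role required")

    @property
    def bait_taxid(self) -> int:
        return next(t.taxid for t, r in zip(self.taxa, self.roles) if r is Role.BAIT)

    def taxids_with_role(self, role: Role) -> frozenset[int]:
        return frozenset(t.taxid for t, r in zip(self.taxa, self.roles) if r is role)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxid": [t.taxid for t in self.taxa],
                "name": [t.name for t in self.taxa],
                "role": [r.value for r in self.roles],
                "culturable": self.culturable,
                "base_fraction": self.base_fractions,
            }
        )


# ---------------------------------------------------------------------------


def _species_taxa(n_background: int, n_satellites: int) -> list[TaxonKey]:
    """Species-level taxa: bait first, background soil species, then satellites."""
    dom = (Rank.DOMAIN, "Bacteria")
    taxa = [
        TaxonKey(
            taxid=_SPECIES_TAXID_BASE,
            name=_BAIT_SPECIES,
            rank=Rank.SPECIES,
            lineage=(dom, (Rank.GENUS, _BAIT_GENUS)),
        )
    ]
    for i in range(1, n_background):
        genus = f"Genus{i:04d}"
        taxa.append(
            TaxonKey(
                taxid=_SPECIES_TAXID_BASE + i,
                name=f"{genus} synthetica",
                rank=Rank.SPECIES,
                lineage=(dom, (Rank.GENUS, genus)),
            )
        )
    for k in range(n_satellites):
        taxa.append(
            TaxonKey(
                taxid=_SPECIES_TAXID_BASE + n_background + k,
                name=f"Serratia sp. SYN{k + 1}",
                rank=Rank.SPECIES,
                lineage=(dom, (Rank.GENUS, _BAIT_GENUS)),
            )
        )
    return taxa


def _genus_of(species_index: int, n_background: int) -> int:
    """Genus group index of a species row: 0 = bait genus (incl. satellites)."""
    return species_index if 0 < species_index < n_background else 0


def simulate_experiment(
    cfg: SyntheticConfig,
) -> tuple[CountTable, list[SampleMetadata], SyntheticTruth]:
    """Simulate one full experiment (all six conditions, both rank views).

    Returns a merged CountTable holding genus rows (species summed by
    genus) and species rows — species counts per sample sum exactly to
    ``cfg.depth`` — plus the sample metadata and the planted truth.
    """
    rng = np.random.default_rng(cfg.seed)
    n_bg = cfg.n_taxa
    n_total = n_bg + cfg.n_bait_satellites
    species = _species_taxa(n_bg, cfg.n_bait_satellites)

    # --- base soil composition (bait and satellites absent from soil) -----
    base = np.zeros(n_total)
    raw = rng.dirichlet(np.full(n_bg, cfg.base_concentration))
    raw[0] = 0.0
    base[:n_bg] = raw / raw.sum()

    # --- roles -------------------------------------------------------------
    roles = np.full(n_total, Role.BACKGROUND, dtype=object)
    roles[0] = Role.BAIT
    positive = base[1:n_bg]
    q10, q25, q75 = np.quantile(positive, [0.10, 0.25, 0.75])
    rare_band = [i for i in range(1, n_bg) if q10 < base[i] <= q25]
    if len(rare_band) < cfg.n_planted_mipners:
        raise ValueError(
            f"rare band too small for {cfg.n_planted_mipners} planted partners"
        )
    mipner_idx = rng.choice(rare_band, size=cfg.n_planted_mipners, replace=False)
    roles[mipner_idx] = Role.PLANTED_MIPNER
    abundant = [
        i
        for i in range(1, n_bg)
        if base[i] >= q75 and roles[i] is Role.BACKGROUND
    ]
    if len(abundant) < cfg.n_planted_binders:
        raise ValueError(
            f"abundant band too small for {cfg.n_planted_binders} planted binders"
        )
    binder_idx = rng.choice(abundant, size=cfg.n_planted_binders, replace=False)
    roles[binder_idx] = Role.PLANTED_BINDER

    # --- culturability and growth ------------------------------------------
    culturable = rng.random(n_total) < cfg.culturable_fraction
    culturable[0] = True
    culturable[n_bg:] = True  # satellites track the bait
    culturable[mipner_idx] = True
    culturable[binder_idx] = True
    growth = rng.lognormal(mean=0.0, sigma=cfg.growth_sigma, size=n_total)

    culture = base * culturable * growth
    culture = culture / culture.sum()

    # --- stick-binding propensity -------------------------------------------
    stick = np.zeros(n_total)
    stick[binder_idx] = cfg.binder_capture_weight
    weak_candidates = np.array(
        [
            i
            for i in range(1, n_bg)
            if culturable[i] and roles[i] is Role.BACKGROUND
        ]
    )
    weak_draw = rng.random(len(weak_candidates)) < cfg.weak_binder_fraction
    weak_idx = weak_candidates[weak_draw]
    stick[weak_idx] = rng.lognormal(0.0, cfg.weak_binder_sigma, size=len(weak_idx))

    # --- per-condition compositions ------------------------------------------
    bait_split = np.zeros(n_total)
    if cfg.n_bait_satellites:
        bait_split[0] = 1.0 - _SATELLITE_READ_SHARE
        bait_split[n_bg:] = _SATELLITE_READ_SHARE / cfg.n_bait_satellites
    else:
        bait_split[0] = 1.0

    def with_bait(community: np.ndarray, bait_fraction: float) -> np.ndarray:
        total = community.sum()
        if total == 0:
            return bait_split.copy()
        return (1.0 - bait_fraction) * community / total + bait_fraction * bait_split

    binder_w = culture * stick
    mipner_w = np.zeros(n_total)
    mipner_w[mipner_idx] = cfg.mipner_capture_weight * culture[mipner_idx]
    if cfg.binder_carryover_in_mipner:
        carry = culture * stick * cfg.mipner_stick_attenuation
        carry[mipner_idx] = 0.0
        mipner_w += carry

    compositions = {
        Condition.SOIL_SOURCE: base,
        Condition.SOIL_CULTURE: culture,
        Condition.MIXNER_A: with_bait(culture, cfg.bait_fraction_mixner_a),
        Condition.MIXNER_B: with_bait(culture, cfg.bait_fraction_mixner_b),
        Condition.BINDER: binder_w / binder_w.sum() if binder_w.sum() else binder_w,
        Condition.MIPNER: with_bait(mipner_w, cfg.bait_fraction_mipner),
    }

    # --- draw reads -----------------------------------------------------------
    samples: list[SampleMetadata] = []
    columns: list[np.ndarray] = []
    for cond in Condition:
        comp = compositions[cond]
        total = comp.sum()
        comp = comp / total if total else comp
        for rep in range(1, cfg.n_replicates + 1):
            samples.append(
                SampleMetadata(
                    sample_id=f"{cond.value.lower()}_r{rep}", condition=cond, replicate=rep
                )
            )
            if total:
                columns.append(rng.multinomial(cfg.depth, comp))
            else:
                columns.append(np.zeros(n_total, dtype=np.int64))
    species_counts = np.column_stack(columns).astype(np.int64)

    # --- genus view (species summed within genus) -----------------------------
    genus_groups: dict[int, list[int]] = {}
    for i in range(n_total):
        genus_groups.setdefault(_genus_of(i, n_bg), []).append(i)
    dom = (Rank.DOMAIN, "Bacteria")
    genus_taxa = []
    genus_rows = []
    for g in sorted(genus_groups):
        name = _BAIT_GENUS if g == 0 else f"Genus{g:04d}"
        genus_taxa.append(
            TaxonKey(taxid=_GENUS_TAXID_BASE + g, name=name, rank=Rank.GENUS, lineage=(dom,))
        )
        genus_rows.append(species_counts[genus_groups[g], :].sum(axis=0))

    taxa = genus_taxa + species
    counts = np.vstack([np.array(genus_rows), species_counts])
    table = CountTable(taxa=taxa, samples=samples, counts=counts)

    truth = SyntheticTruth(
        taxa=species,
        roles=list(roles),
        culturable=[bool(c) for c in culturable],
        base_fractions=[float(b) for b in base],
    )
    return table, samples, truth


def write_fixture(cfg: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate and write counts.tsv + metadata.tsv + truth.tsv to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table, samples, truth = simulate_experiment(cfg)
    paths = {
        "counts": write_table(table, out_dir / "counts.tsv"),
        "metadata": write_metadata(samples, out_dir / "metadata.tsv"),
        "truth": out_dir / "truth.tsv",
    }
    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
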