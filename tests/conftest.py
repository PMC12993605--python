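import numpy as np
import pytest

from mipner.report_io import (
    Condition,
    CountTable,
    Rank,
    SampleMetadata,
    TaxonKey,
)

_DOM = (Rank.DOMAIN, "Bacteria")


def bacterium(taxid, name, rank=Rank.SPECIES, domain="Bacteria", genus=None):
    """Shorthand TaxonKey with a domain (and optional genus) lineage."""
    lineage = [(Rank.DOMAIN, domain)]
    if genus is not None:
        lineage.append((Rank.GENUS, genus))
    return TaxonKey(taxid=taxid, name=name, rank=rank, lineage=tuple(lineage))


def sample(sample_id, condition, replicate=1):
    return SampleMetadata(sample_id=sample_id, condition=condition, replicate=replicate)


def six_condition_samples(n_replicates=1):
    """One (or more) replicate sample(s) per condition, deterministic ids."""
    out = []
    for cond in Condition:
        for rep in range(1, n_replicates + 1):
            out.append(sample(f"{cond.value.lower()}_r{rep}", cond, rep))
    return out


def make_table(taxa, samples, counts):
    return CountTable(taxa=list(taxa), samples=list(samples), counts=np.asarray(counts))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_sim_cfg():
    """Scaled-down synthetic experiment for fast unit tests."""
    from mipner.synthetic_data import SyntheticConfig

    return SyntheticConfig(
        seed=7,
        n_taxa=120,
        depth=30_000,
        n_planted_binders=3,
        n_planted_mipners=4,
    )
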