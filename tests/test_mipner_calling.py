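"""Tests of the partner-calling decision procedure, including an
independent literal transcription of the tiered presence/absence rules
used as an oracle on enumerated and random toy tables."""

import itertools
import warnings

import numpy as np
import pytest

from mipner.abundance import RelativeAbundanceTable, mask_taxa, to_relative
from mipner.mipner_calling import (
    ClassificationConfig,
    MipnerStatus,
    call_genus_trust,
    call_species_mipners,
    classification_report,
    rank_candidate_species,
)
from mipner.report_io import Condition, Rank

from conftest import bacterium, make_table, sample


def six_samples(n_reps=3):
    return [
        sample(f"{c.value.lower()}_r{r}", c, r)
        for c in Condition
        for r in range(1, n_reps + 1)
    ]


def species_scenario(rows, n_reps=3):
    """rows: list of (name, {Condition: [rep counts]}); returns (masked_rel, raw)."""
    samples = six_samples(n_reps)
    taxa = [bacterium(i + 1, name) for i, (name, _) in enumerate(rows)]
    counts = np.zeros((len(rows), len(samples)), dtype=int)
    for i, (_, by_cond) in enumerate(rows):
        for j, s in enumerate(samples):
            reps = by_cond.get(s.condition)
            if reps is not None:
                counts[i, j] = reps[s.replicate - 1]
    raw = make_table(taxa, samples, counts)
    masked = mask_taxa(to_relative(raw), "Serratia")
    return masked, raw


FILLER = {c: [1000, 1000, 1000] for c in Condition}


class TestCallSpeciesMipners:
    @pytest.fixture
    def scenario(self):
        rows = [
            ("Filler f", FILLER),
            # present only in capture samples, no binder reads, absent from soil
            ("High h", {Condition.MIPNER: [30, 0, 0]}),
            # low-level capture presence, present in soil, no binder reads
            ("Low l", {Condition.MIPNER: [5, 5, 5], Condition.SOIL_SOURCE: [10, 10, 10]}),
            # abundant in capture samples but present in the Binder control
            ("Unassignable u", {Condition.MIPNER: [300, 300, 300], Condition.BINDER: [12, 0, 0]}),
            ("Absent z", {}),
        ]
        return species_scenario(rows)

    def test_tier_assignment(self, scenario):
        masked, raw = scenario
        calls = {c.taxon.name: c for c in call_species_mipners(masked, raw)}
        assert calls["High h"].status is MipnerStatus.PUTATIVE_HIGH
        assert calls["Low l"].status is MipnerStatus.PUTATIVE_LOW
        assert calls["Unassignable u"].status is MipnerStatus.UNASSIGNABLE_BINDER
        assert calls["Absent z"].status is MipnerStatus.NOT_CANDIDATE

    def test_evidence_fields(self, scenario):
        masked, raw = scenario
        calls = {c.taxon.name: c for c in call_species_mipners(masked, raw)}
        assert calls["Unassignable u"].binder_read_total == 12
        assert calls["High h"].contaminant_flag is True
        assert calls["Low l"].contaminant_flag is False
        assert calls["High h"].enrichment.infinite
        assert calls["Low l"].enrichment.factor < 100

    def test_exact_threshold_is_low_tier(self):
        # max capture fraction exactly at the high tier bound stays low tier
        rows = [
            ("Filler f", {c: [99, 99, 99] for c in Condition}),
            ("Edge e", {Condition.MIPNER: [1, 1, 1], Condition.SOIL_SOURCE: [1, 1, 1]}),
        ]
        masked, raw = species_scenario(rows)
        call = {c.taxon.name: c for c in call_species_mipners(masked, raw)}["Edge e"]
        assert call.max_mipner_fraction == 0.01
        assert call.status is MipnerStatus.PUTATIVE_LOW

    def test_top_n_restriction(self, scenario):
        masked, raw = scenario
        cfg = ClassificationConfig(top_n_species=1)
        calls = {c.taxon.name: c for c in call_species_mipners(masked, raw, cfg)}
        # only the single top-ranked taxon can receive a non-NOT_CANDIDATE status
        assert sum(1 for c in calls.values() if c.status is not MipnerStatus.NOT_CANDIDATE) == 1

    def test_missing_binder_condition_errors(self):
        rows = [("Filler f", {Condition.MIPNER: [10], Condition.SOIL_SOURCE: [10]})]
        samples = [sample("m1", Condition.MIPNER), sample("s1", Condition.SOIL_SOURCE)]
        taxa = [bacterium(1, "Filler f")]
        raw = make_table(taxa, samples, [[10, 10]])
        masked = mask_taxa(to_relative(raw), "Serratia")
        with pytest.raises(ValueError, match="BINDER"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                call_species_mipners(masked, raw)

    def test_bait_in_masked_table_errors(self):
        rows = [("Serratia marcescens", FILLER), ("Filler f", FILLER)]
        _, raw = species_scenario(rows)
        unmasked = to_relative(raw)
        with pytest.raises(ValueError, match="bait genus"):
            call_species_mipners(unmasked, raw)

    def test_partition_is_exhaustive_and_exclusive(self, scenario):
        masked, raw = scenario
        calls = call_species_mipners(masked, raw)
        assert len(calls) == len(masked.taxa)
        assert {c.taxon.taxid for c in calls} == {t.taxid for t in masked.taxa}

    def test_binder_reads_never_move_status_toward_putative(self, rng):
        masked, raw = _random_scenario(rng, n_taxa=6)
        before = {c.taxon.taxid: c.status for c in _call_quiet(masked, raw)}
        binder_cols = raw.sample_index(Condition.BINDER)
        for i, taxon in enumerate(raw.taxa):
            bumped = raw.counts.copy()
            bumped[i, binder_cols[0]] += 7
            raw2 = make_table(raw.taxa, raw.samples, bumped)
            after = {c.taxon.taxid: c.status for c in _call_quiet(masked, raw2)}
            if before[taxon.taxid] in (MipnerStatus.PUTATIVE_HIGH, MipnerStatus.PUTATIVE_LOW):
                assert after[taxon.taxid] is MipnerStatus.UNASSIGNABLE_BINDER
            elif before[taxon.taxid] is MipnerStatus.NOT_CANDIDATE:
                assert after[taxon.taxid] is MipnerStatus.NOT_CANDIDATE

    def test_replicate_permutation_invariance(self, rng, scenario):
        masked, raw = scenario
        before = {c.taxon.taxid: c.status for c in call_species_mipners(masked, raw)}
        # swap replicates within each condition in both tables
        perm = []
        for c in Condition:
            idx = raw.sample_index(c)
            perm.extend(rng.permutation(idx).tolist())
        raw2 = make_table(raw.taxa, [raw.samples[j] for j in perm], raw.counts[:, perm])
        masked2 = RelativeAbundanceTable(
            taxa=masked.taxa,
            samples=[masked.samples[j] for j in perm],
            fractions=masked.fractions[:, perm],
            zero_columns=masked.zero_columns[perm],
        )
        after = {c.taxon.taxid: c.status for c in call_species_mipners(masked2, raw2)}
        assert after == before


# ---------------------------------------------------------------------------
# literal oracle
# ---------------------------------------------------------------------------


def _call_quiet(masked, raw, cfg=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return call_species_mipners(masked, raw, cfg)


def _random_scenario(rng, n_taxa=3, n_reps=3, values=(0, 1, 50)):
    samples = six_samples(n_reps)
    taxa = [bacterium(i + 1, f"T{i} x") for i in range(n_taxa)]
    counts = rng.choice(values, size=(n_taxa, len(samples)))
    raw = make_table(taxa, samples, counts)
    return mask_taxa(to_relative(raw), "Serratia"), raw


def literal_rule_oracle(masked, raw, top_n=100, high=0.01):
    """Independent transcription of the tiered presence/absence rules."""
    mip = masked.sample_index(Condition.MIPNER)
    binder = raw.sample_index(Condition.BINDER)
    raw_rows = {t.key: i for i, t in enumerate(raw.taxa)}

    stats = {}
    for i, t in enumerate(masked.taxa):
        fr = [masked.fractions[i, j] for j in mip]
        stats[t.taxid] = (sum(fr) / len(fr), max(fr))
    ranked = sorted(
        (tid for tid, (m, _) in stats.items() if m > 0),
        key=lambda tid: (-stats[tid][0], -stats[tid][1], tid),
    )
    top = set(ranked[:top_n])

    expected = {}
    for t in masked.taxa:
        mean, mx = stats[t.taxid]
        binder_total = sum(raw.counts[raw_rows[t.key], j] for j in binder)
        if t.taxid not in top or mx == 0:
            expected[t.taxid] = MipnerStatus.NOT_CANDIDATE
        elif binder_total > 0:
            expected[t.taxid] = MipnerStatus.UNASSIGNABLE_BINDER
        elif mx > high:
            expected[t.taxid] = MipnerStatus.PUTATIVE_HIGH
        else:
            expected[t.taxid] = MipnerStatus.PUTATIVE_LOW
    return expected


def test_oracle_equivalence_exhaustive_single_taxon():
    """Every {0,1,50}^6 single-taxon table agrees with the literal rules."""
    samples = six_samples(n_reps=1)
    taxa = [bacterium(1, "T x")]
    for combo in itertools.product((0, 1, 50), repeat=6):
        raw = make_table(taxa, samples, np.array(combo)[None, :])
        masked = mask_taxa(to_relative(raw), "Serratia")
        got = {c.taxon.taxid: c.status for c in _call_quiet(masked, raw)}
        assert got == literal_rule_oracle(masked, raw), combo


def test_oracle_equivalence_random_tables(rng):
    for trial in range(300):
        n_taxa = int(rng.integers(2, 7))
        n_reps = int(rng.integers(1, 3))
        masked, raw = _random_scenario(rng, n_taxa=n_taxa, n_reps=n_reps)
        top_n = int(rng.integers(1, n_taxa + 2))
        cfg = ClassificationConfig(top_n_species=top_n)
        got = {c.taxon.taxid: c.status for c in _call_quiet(masked, raw, cfg)}
        assert got == literal_rule_oracle(masked, raw, top_n=top_n), trial


# ---------------------------------------------------------------------------
# candidate ranking
# ---------------------------------------------------------------------------


def _mipner_rel(fracs):
    taxa = [bacterium(i + 1, f"T{i} x") for i in range(fracs.shape[0])]
    samples = [sample(f"m{j}", Condition.MIPNER, j + 1) for j in range(fracs.shape[1])]
    zero = fracs.sum(axis=0) == 0
    return RelativeAbundanceTable(taxa=taxa, samples=samples, fractions=fracs, zero_columns=zero)


class TestRankCandidateSpecies:
    def test_mean_ordering(self):
        rel = _mipner_rel(np.array([[0.5], [0.3], [0.2]]))
        top2 = rank_candidate_species(rel, 2)
        assert [t.taxid for t in top2] == [1, 2]

    def test_zero_mean_taxa_excluded(self):
        rel = _mipner_rel(np.array([[0.55, 0.45], [0.45, 0.55], [0.0, 0.0]]))
        assert len(rank_candidate_species(rel, 3)) == 2

    def test_tie_broken_by_max_fraction(self):
        # taxon 1: (0.2, 0.6); taxon 2: (0.4, 0.4) -> equal means, taxon 1 first
        rel = _mipner_rel(np.array([[0.2, 0.6], [0.4, 0.4], [0.4, 0.0]]))
        ranked = rank_candidate_species(rel, 2)
        assert [t.taxid for t in ranked] == [1, 2]

    def test_matches_brute_force_sort(self, rng):
        fr = rng.dirichlet(np.ones(200), size=3).T  # 200 taxa x 3 replicates
        rel = _mipner_rel(fr)
        ranked = [t.taxid for t in rank_candidate_species(rel, 100)]
        means, maxes = fr.mean(axis=1), fr.max(axis=1)
        oracle = sorted(
            (i for i in range(200) if means[i] > 0),
            key=lambda i: (-means[i], -maxes[i], i + 1),
        )
        assert ranked == [i + 1 for i in oracle[:100]]

    def test_no_mipner_samples_errors(self):
        taxa = [bacterium(1, "T x")]
        rel = RelativeAbundanceTable(
            taxa=taxa, samples=[sample("b", Condition.BINDER)], fractions=np.array([[1.0]])
        )
        with pytest.raises(ValueError, match="MIPNER"):
            rank_candidate_species(rel, 5)


# ---------------------------------------------------------------------------
# genus trust
# ---------------------------------------------------------------------------


class TestGenusTrust:
    def _genus_scenario(self):
        rows = [
            # appears in one binder replicate -> never trusted
            ("Binderish", {Condition.MIPNER: [100, 100, 100], Condition.BINDER: [0, 1, 0]}),
            # absent everywhere -> no evidence, not trusted
            ("Ghost", {}),
            # the published partner-genus pattern: 27% capture, 0.26% soil
            (
                "Trusty",
                {Condition.MIPNER: [2700, 2700, 2700], Condition.SOIL_SOURCE: [26, 26, 26]},
            ),
            ("Other", {c: [7200, 7200, 7200] for c in Condition}),
        ]
        samples = six_samples()
        taxa = [bacterium(i + 1, name, rank=Rank.GENUS) for i, (name, _) in enumerate(rows)]
        counts = np.zeros((len(rows), len(samples)), dtype=int)
        for i, (_, by_cond) in enumerate(rows):
            for j, s in enumerate(samples):
                reps = by_cond.get(s.condition)
                if reps is not None:
                    counts[i, j] = reps[s.replicate - 1]
        # pad soil so Trusty's soil fraction is 26/10000
        soil_cols = [j for j, s in enumerate(samples) if s.condition is Condition.SOIL_SOURCE]
        other = [i for i, t in enumerate(taxa) if t.name == "Other"][0]
        counts[other, soil_cols] = 9974
        raw = make_table(taxa, samples, counts)
        return mask_taxa(to_relative(raw), "Serratia"), raw

    def test_binder_presence_blocks_trust(self):
        rel, raw = self._genus_scenario()
        trust = {c.genus.name: c for c in call_genus_trust(rel, raw)}
        assert trust["Binderish"].trusted is False
        assert trust["Binderish"].binder_presence is True

    def test_absent_genus_not_trusted(self):
        rel, raw = self._genus_scenario()
        trust = {c.genus.name: c for c in call_genus_trust(rel, raw)}
        assert trust["Ghost"].trusted is False and trust["Ghost"].binder_presence is False

    def test_partner_genus_trusted_and_enriched(self):
        rel, raw = self._genus_scenario()
        call = {c.genus.name: c for c in call_genus_trust(rel, raw)}["Trusty"]
        assert call.trusted is True
        assert call.enrichment.factor == pytest.approx(0.27 / 0.0026, rel=1e-3)
        assert call.enrichment.meets_threshold


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------


class TestClassificationReport:
    def test_empty_call_list(self):
        text = classification_report([])
        lines = text.strip().splitlines()
        assert lines[0].startswith("taxid\t")
        assert "PUTATIVE_HIGH=0" in lines[-1]

    def test_footer_counts_match_brute_force(self):
        rows = [
            ("Filler f", FILLER),
            ("High h", {Condition.MIPNER: [30, 0, 0]}),
            ("Low l", {Condition.MIPNER: [5, 5, 5]}),
            ("U u", {Condition.MIPNER: [300, 300, 300], Condition.BINDER: [12, 0, 0]}),
            ("Z z", {}),
        ]
        masked, raw = species_scenario(rows)
        calls = call_species_mipners(masked, raw)
        text = classification_report(calls)
        tally = {}
        for c in calls:
            tally[c.status.value] = tally.get(c.status.value, 0) + 1
        footer = [l for l in text.splitlines() if l.startswith("# status_counts")][0]
        for status, n in tally.items():
            assert f"{status}={n}" in footer
        # one data row per call plus header and footer
        assert len(text.strip().splitlines()) == len(calls) + 2
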