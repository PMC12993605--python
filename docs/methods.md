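# Methods

## Input model

The pipeline operates on taxa × samples matrices of non-negative integer
read counts (`CountTable`), where each sample carries an experimental
condition (`SOIL_SOURCE`, `SOIL_CULTURE`, `MIXNER_A`, `MIXNER_B`, `BINDER`,
`MIPNER`) and a replicate index. Counts are the classifier's *direct*
per-rank assignments, not clade-cumulative totals: rank views
(`aggregate_to_rank`) select rows of one rank rather than summing across
ranks, which avoids double counting when genus and species rows coexist in
one report. Archaeal and viral rows and the Homo sapiens subtree (taxid
9606) are removed before any abundance work; a taxon without a domain
annotation is an error rather than silently retained.

Relative abundances are per-sample fractions in [0, 1]; percentages appear
only in rendered outputs. A sample whose retained counts are all zero is
flagged rather than divided by zero, and stays flagged through downstream
transforms.

## Bait masking

All rows whose genus matches the bait genus are removed — the bait species
itself and every congeneric assignment — and each sample is renormalized.
Read classifiers assign a sizable minority of a sequenced isolate's reads
to related species of the same genus (low-information genomic regions), so
congeneric species-level rows in bait-spiked samples are treated as
artifacts of the bait, not as independent observations. Masking is a pure
renormalization: pairwise ratios among retained taxa are preserved exactly
(to 1e-12 in tests). A genus match is the row's own name at genus rank, a
genus lineage entry, or the first token of a species binomial, so masking
works on tables whose lineage annotations were reduced to the domain level
by TSV round-tripping.

## Partner calling

Candidates are the top *N* species (default 100) by mean bait-masked
MIPNER fraction, ties broken by max fraction then ascending taxid. The
status partition for candidates:

1. `UNASSIGNABLE_BINDER` if the taxon has any raw read in any BINDER
   replicate. Absence is defined on raw read counts (zero summed over all
   Binder replicates), the only scale on which "zero" is well defined —
   fractions depend on masking and depth.
2. `PUTATIVE_HIGH` if the max masked MIPNER fraction over replicates is
   strictly greater than the high-tier threshold (default 1 %). The strict
   inequality puts a taxon at exactly the threshold in the low tier.
3. `PUTATIVE_LOW` otherwise (positive MIPNER fraction, zero Binder reads).

Non-candidates get `NOT_CANDIDATE`, so report totals reconcile with the
input taxa universe. The tier test uses the max over replicates ("in at
least one capture sample"), not the mean; the candidate *ranking* uses the
mean. All tiers are restricted to the top-*N* list.

Each call carries the MIPNER-vs-SOIL_SOURCE fold enrichment of condition
means (positive/zero → flagged infinite and counted as meeting any
threshold; zero/zero → 0) and a contaminant flag set when the taxon has
zero soil-source reads in every replicate. The flag never demotes a
putative call — real capture experiments recover taxa below the soil
sample's detection floor — it is reported as a caveat. Genus trust is the
same Binder-absence rule at genus rank: trusted iff zero Binder reads in
every replicate and a positive mean masked MIPNER fraction.

Enrichment compares condition means (not per-replicate ratios), matching
how averaged condition tables are read. Standard error of a condition mean
is sample SD/√n; with a single replicate it is defined as 0 with a warning
so summaries stay total (designed experiments have n = 3).

## Diversity and culture bias

Richness counts taxa with ≥ 1 read (no abundance floor). Diversity is
Simpson's index of diversity `1 − Σ pᵢ²` (the probability two random reads
come from different taxa), the orientation under which a diverse soil
community scores near 1. An all-zero sample has richness 0 and an
*undefined* (flagged) Simpson value, not 0. Both are computed on
domain-filtered, unmasked tables: diversity describes the community as
sequenced, before any bait-specific transformation.

Group comparison is a one-way fixed-effects ANOVA over three groups —
soil source (n = 3), soil culture (n = 3) and the two co-culture doses
pooled (n = 6), giving df = (2, 9) — with Tukey HSD post-hoc tests
(studentized-range adjusted p). A design where every value is identical
returns F = 0, p = 1 rather than the 0/0 NaN. ANOVA is delegated to
`scipy.stats.f_oneway` and Tukey to `statsmodels`' `pairwise_tukeyhsd`;
tests cross-check Tukey p-values against a direct studentized-range tail
computation and ANOVA against F = t² on two groups and hand-computed sums
of squares.

Shared-taxa analysis uses presence = any replicate with ≥ 1 read (the same
rule as Binder presence, for consistency) and reports the count of taxa in
*exactly* each condition combination — the 2^k − 1 disjoint regions an
upset plot displays, which satisfy inclusion–exclusion by construction.
"Genera lost through culturing" is the soil-source set minus the union of
the cultured-condition sets (soil culture and both co-culture doses).

## Synthetic experiments

`simulate_experiment` draws one complete experiment from an explicit seed
(a single `numpy.random.Generator`; equal seeds give byte-identical
output). The generative model:

1. **Soil community.** Base fractions over `n_taxa` (default 800) species
   from a symmetric Dirichlet with concentration 0.3 — low concentration
   produces the long rare tail a capture experiment exploits. The bait's
   base fraction is forced to 0 (the bait is a lab culture, not a member
   of this soil community), and `SOIL_SOURCE` samples are
   Multinomial(depth = 10⁶, base).
2. **Culture bottleneck.** Each taxon survives plating with probability
   0.2 (planted roles and the bait are forced culturable); survivors get
   per-taxon lognormal growth factors (σ = 2.5, chosen so that a handful
   of fast growers dominate the plate, the dominance pattern real plate
   cultures show) and the community is renormalized.
3. **Bait spike.** Where bait was added, the bait block takes a fixed
   fraction of reads (co-culture dose A 0.6, dose B 0.8, capture 0.7),
   of which 1.5 % is misassigned to 3 satellite species of the bait genus
   — emulating classifier artifacts and exercising genus masking.
4. **Stick transfer.** Plating from the applicator requires adhesion: the
   rinse removes unbound cells, so a taxon with no stick-binding
   propensity contributes nothing to the BINDER community. Five planted
   binders (drawn from the abundant, culturable quartile) get capture
   weight 500; a random 15 % of culturable background taxa are weak
   binders with ~1× lognormal weights; everything else — including the
   planted partners — has weight 0. BINDER composition is the culture
   community reweighted by these propensities.
5. **Capture.** Eight planted partners, drawn from a bounded rare band of
   the soil community (10th–25th percentile of positive base fractions),
   get capture weight 500. Stick binders carry over into the capture
   community at their stick weight attenuated ×0.02 (the bait coats most
   of the stick surface). The bait is then added at its spike fraction and
   reads drawn multinomially.

Two generator choices deserve justification. First, sparse stick binding
(rather than a uniform background transfer rate) reflects both the
mechanism — plating from a stick samples only what adheres — and the
observed data pattern in real experiments, where most candidate taxa,
including abundant captured partners, show literally zero Binder reads.
Second, partners are planted in a *bounded* rare band rather than the
unbounded rare tail: a taxon whose soil fraction is below the
capture-and-sequencing detection floor can never be recovered at any
binding strength, so recovery rates over unbounded tail draws measure the
tail shape, not the pipeline. Within the band, the planted partners'
~100-fold-plus enrichment over the soil source emerges from the capture
weight rather than being imposed.

What the generator does **not** emulate: read-level sequence error and
classifier confusion beyond the bait satellites, compositional correlation
between taxa, plate-to-plate growth interactions (replicate variation is
purely multinomial), or variable sequencing depth. Passing recovery tests
therefore show the decision rules are correct and well-calibrated for
communities with this structure, not that any particular real soil will
yield partners.

Per-sample species-level read totals equal `depth` exactly; the merged
output table additionally contains genus rows (species summed within
genus), so both rank views of the pipeline can be exercised from one
fixture.

## Numerical choices and degenerate inputs

* Relative columns must sum to 1 within 1e-9 (flagged all-zero columns
  excepted); masking preserves retained ratios to better than 1e-12.
* Deterministic ordering everywhere: merged rows sort by (rank, taxid);
  candidate ties break by max fraction then taxid; report rows order by
  status then mean fraction descending then taxid. Reruns on identical
  inputs are byte-identical (no timestamps in outputs).
* SE with n = 1 is 0 (warned); identical replicates give exactly 0 rather
  than float noise.
* Kraken-report unclassified rows (taxid 0) are counted and dropped with a
  warning; malformed lines abort with the line number. Bracken fraction
  columns are ignored and recomputed.
* Exit codes of the CLI: 0 success, 2 configuration error (all problems
  reported at once), 3 data error.

## Known limitations

* Species-level conclusions inherit the classifier's limited congeneric
  resolution; genus masking removes bait artifacts but cannot recover true
  congeneric partners of the bait.
* The Binder-absence rule is a hard zero on raw reads and therefore depth
  dependent: deeper sequencing of Binder controls moves borderline taxa
  from putative to unassignable, never the reverse.
* Enrichment versus the soil source is undefined (flagged infinite) for
  taxa below the soil detection floor; such taxa also carry the
  contaminant caveat and deserve isolation follow-up before being treated
  as partners.
* Reproducing the original study's numbers requires its supplementary
  per-sample count tables (see `tests/test_acceptance.py`); the package
  ships only the study's printed genus condition means.
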