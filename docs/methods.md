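# Methods

## Scope and model

`barcodiag` evaluates whether a short mitochondrial fragment can diagnose
a specimen to species. The underlying model of "diagnosis" is the
character-based criterion of population aggregation analysis (PAA):
populations remain aggregated (undiagnosable) unless some character shows
fixed, mutually exclusive states between them. Diagnosis is a
presence/absence property of observed state sets — frequencies play no
role, and a single shared individual at a site destroys that site's
diagnostic value. The combination extension uses *joint* haplotypes: a
k-tuple of positions is diagnostic when the projections of the two
species' joint haplotype sets onto the tuple are disjoint. Projections of
a shared full haplotype overlap on every tuple, so one haplotype shared
between species suffices to defeat every combination; this monotone
structure (diagnostic tuples are upward-closed) is verified as a property
test. The exhaustive search over all tuples up to `kmax` is the defining
computation; it refuses instances with more than 10^6 candidate tuples.

Two assignment modes are exposed. `site_wise` (the default and the one
the headline verdict uses) calls a species compatible when the query's
state at every variable position occurs in that species; it uses all
queries with at least one scored position and is the natural reading of
"could this sequence have come from that population". `exact_haplotype`
demands membership of the query's complete joint haplotype and is
stricter with missing data.

## The bear fragment dataset

The packaged dataset emulates a published comparison of two identical
104-bp 12S rRNA fragments against 49 Brown Bear and 32 Polar Bear
sequences: the fragment occupies positions 451–554 of the complete gene,
exactly four sites vary (gene positions 474, 478, 492 and 550 = fragment
positions 24, 28, 42 and 100), and the per-species state counts at those
sites are fixed constants of the package (e.g. Brown Bear 40 T / 9 C at
474; Polar Bear 31 C / 1 T there).

Only per-site marginal counts are published; the joint haplotypes of the
real individuals are not. The fixture therefore compiles in one canonical
completion of the marginals, chosen so that the two species share a full
haplotype — (T, A, G, T), the haplotype of the focal queries. Any
completion consistent with the published per-site counts in which the one
thymine-bearing Polar Bear matches the focal states yields this overlap,
and the overlap is what the published conclusion (no diagnosis, ambiguous
assignment) requires. Combination-level (k ≥ 2) results on the fixture
are consequently properties of this constructed completion, not a
reproduction of unpublished individual-level data; single-site results
depend only on the published marginals. Background (invariant) sites are
filled with `A` — arbitrary, and invisible to every statistic, which only
ever sees the variable columns.

`generate_from_marginals` generalises the fixture: given any per-site
count specification it emits an alignment whose tabulation reproduces the
counts exactly, randomising only the joint arrangement across individuals
(each column is an independent seeded permutation). This is the main
property-test engine: tabulate(generate(spec)) == spec round-trips by
construction. What the synthetic data deliberately do *not* model:
phylogenetic correlation among sites, indels, sequencing error, or
alignment uncertainty. Passing tests therefore establish the correctness
of the bookkeeping and the search, not robustness to misalignment or
degraded DNA.

## Coordinate mapping

Mapping is ungapped by design: the fragment of interest is short and
contiguous, and the correspondence it needs is a single window on a
complete-gene reference. All coordinates are 1-based inclusive, matching
how gene positions are quoted in practice. Both orientations are scanned;
ties prefer the forward strand and then the leftmost placement. Ambiguity
codes never count as matches (conservative identity). The default
acceptance threshold `min_identity = 0.8` is arbitrary but configurable;
below it the mapper returns an explicit unmapped result rather than
raising, so pipelines can degrade gracefully.

## Variability table conventions

Gaps and ambiguity codes are tallied as missing, and for every species
and position, state counts plus missing equal the sample size (a tested
invariant). Input is case-insensitive and `U` maps to `T`. Queries are
excluded from all species statistics and reported in their own row.

Two species "differ" at a position when their observed state sets differ
**or** their modal states differ. The set-only rule undercounts the case
of a site where both species show both states but with reversed
majorities (as at position 474 of the bear fragment: Brown Bear mostly T,
Polar Bear mostly C, one individual shared each way); the modal clause
counts it, giving the four difference positions the bear comparison
reports. A frequency-distribution-inequality rule is available as a
configurable alternative and agrees on this dataset. Modal ties resolve
alphabetically and are flagged.

`within_species_polymorphic` uses the plain definition — at least two
observed states — under which the Brown Bear is polymorphic at all four
sites of the fixture (the table's own singleton A at 492 included) and
the Polar Bear at one. Summaries that quote "polymorphic at three
positions" for the Brown Bear refer to the three sites where it is
polymorphic *while the other species is fixed* (478, 492, 550); that
private-vs-shared split is exposed separately as
`exclusively_polymorphic`.

## Similarity scoring

Raw scores use reward +1 / penalty −2 and the best ungapped segment over
all diagonals and both strands (maximal-scoring segment per diagonal,
i.e. negative prefixes and suffixes trimmed; never below 0). Bit scores
are `(λS − ln K)/ln 2` with the standard megablast constants λ = 1.28,
K = 0.46, all four configurable; the displayed value rounds
half-away-from-zero to an integer, under which a perfect 104-nt match
displays 193 bits. E-values are the textbook `K·m·n·e^(−λS)` with no
effective-length correction and no masking — deliberate simplifications,
exact and adequate at barcode scale, and documented here rather than
hidden. Note one consequence of segment trimming: a 104-mer with a single
*end* mismatch scores 103 (the trimmed perfect suffix), not 101; only
interior mismatches (both flanks ≤ 100) score 101. Hit rankings sort by
bit score with subject id as tie-break, so ranking is invariant to
database order; subjects with equal displayed bits form tie groups, and
per-group species compositions are reported.

## Tree sanity check

The tree stage is a deliberately lightweight stand-in for full
model-based phylogenetics: uncorrected p-distances (pairs compared over
sites where both are unambiguous), saitou–nei neighbor joining, and a
nonparametric bootstrap that resamples alignment columns with
replacement, rebuilds the tree per pseudoreplicate, and reports for every
split of the original tree the percentage of replicates containing it
(default 1000 replicates; the seed is mandatory). The claim this stage
supports is qualitative — a distance tree of the fragment cannot separate
the two bear species, because a shared haplotype sits at distance zero
from members of both — and that claim is demonstrable at desk scale
without likelihood machinery. Maximum-likelihood and Bayesian inference,
model selection, and any quantitative reproduction of published tree
topologies are out of scope; the posterior-probability support classifier
is included as a pure function for completeness.

Numerical notes: the NJ core is vectorised numpy with ties in the Q
criterion broken by the lowest (row, column) pair, making runs
deterministic; on additive matrices it recovers the generating topology
and branch lengths exactly (tested against construction and
cross-checked against an independent NJ implementation). The pairwise
p-distance step collapses duplicate sequences before the O(n²·L)
comparison, which matters because population alignments — and their
bootstrap replicates — contain many identical haplotypes. Negative NJ
branch lengths are left as computed. Support categories follow the
conventional thresholds: bootstrap ≥ 75% strong, > 50% and < 75%
moderate, ≤ 50% negligible; posterior probability ≥ 0.95 strong,
0.90–0.94 moderate, < 0.90 negligible (boundaries inclusive exactly as
listed).

## Pipeline and reproducibility

The pipeline runs mapping → variability → PAA → similarity → tree on
FASTA inputs, isolates stage failures (a failed or inapplicable stage is
recorded with a reason and the rest still runs), and writes every
artifact plus a single JSON report. Reports contain no timestamps and all
randomness flows from the configured seed, so identical configuration
yields byte-identical reports — a tested property. Species labels travel
in FASTA headers as `species=...`; records without the key are treated as
queries. `scripts/acceptance.py` regenerates the dataset from the
compiled-in per-site counts (seeded joint arrangement, seeded reference
flanks), re-runs the mapper, tabulation and scorer, and writes the
headline numbers; they are properties of the prescribed counts and do not
vary with the seed.

## Known limitations

- Ungapped mapping cannot place fragments whose correspondence to the
  reference requires indels.
- PAA here is pairwise; multi-species panels must be iterated pairwise.
- The similarity stage reproduces score structure, not the contents of
  any external sequence database; tie-tier compositions from public
  databases are version-dependent and out of scope.
- The bootstrap stand-in shows what distance methods can or cannot
  recover on a fragment; it says nothing about likelihood-based support
  on longer alignments.
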