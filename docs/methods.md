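# Methods

`amplitree` bundles two workflows that in practice run back to back in a
multiplexed eDNA metabarcoding study: (1) in-silico evaluation of
"universal" (taxon-wide) primer pairs against a local taxonomy-annotated
reference database, and (2) processing of multiplexed paired-end amplicon
reads down to a per-sample species presence/absence matrix with association
tests.  This note records the models, the defaults and their rationale, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Reference database

The database is a FASTA of marker sequences plus a TSV mapping each record
to a fixed seven-rank lineage (superkingdom, phylum, class, order, family,
genus, species).  A flat rank ladder is used instead of a full taxonomy
graph: every downstream consumer (tree annotation, resolution metrics,
species assignment) only ever needs the taxon name at a standard rank, and
a flat table keeps the artifact self-contained and round-trippable.  Names,
not numeric taxon identifiers, are carried throughout.  Unknown ranks are
explicit empty strings; a species name without a genus is tolerated but
flagged incomplete.  Missing lineages are a hard error by default
(`strict=True`), downgradeable to a logged warning.

`N` is allowed in reference sequences but never counts as a match anywhere
(primer matching, distance columns, identity) — an ambiguous base carries no
evidence, so this is the conservative choice.

## In-silico PCR

Remote primer-search services expose no stable, citable matching semantics,
so a local one is defined and made configurable (`PcrConfig`):

- a primer binds a site iff it has at most `max_mismatch_per_primer`
  (default 2) mismatches in total **and** its final `three_prime_exact`
  (default 2) 3′ bases match exactly — polymerase extension is far more
  sensitive to 3′ mismatches than to internal ones;
- IUPAC-degenerate primer positions match every base of their set at zero
  cost; reference `N` never matches;
- both orientations are searched; every forward × reverse hit combination
  in amplifiable orientation (primers facing inward on opposite strands)
  whose product length lies in the pair's `[min_product, max_product]`
  (default [50, 3000] bp when a panel file does not override) yields an
  amplicon — there is no "shortest product wins" heuristic, mirroring
  exhaustive in-silico PCR;
- if more than `amplicon_cap` (default 500) amplicons result, that many are
  sampled uniformly without replacement from a single seeded generator;
  similarly degenerate primers are expanded to at most `permutation_cap`
  (default 25) concrete sequences, exhaustively and in lexicographic order
  below the cap, sampled without replacement above it.

Matching is implemented as a vectorised bitmask AND over sliding windows
(A=1, C=2, G=4, T=8; degenerate codes are unions; reference `N` is 0), and
is checked in the tests against an independent all-offsets sliding-window
oracle.  Coordinates are 0-based half-open on the + strand throughout; the
amplicon's `insert_seq` is the region strictly between the two primer
binding sites, reverse-complemented into forward-primer orientation for
minus-strand products.

Thermodynamics (melting temperature, dimers) are out of scope: the tool
asks "could this primer pair amplify this reference and what would the
product look like", not "how efficiently".

## Alignment and trees

Amplicons from one assay are short (tens to a few hundred bp) homologous
fragments, so a deterministic center-star multiple alignment under unit
edit cost is sufficient for counting nucleotide differences; a progressive
aligner would add dependencies and nondeterminism without changing the
difference counts that matter here.  The center is the sequence minimising
total pairwise Levenshtein distance (ties → lowest input index); all others
are pairwise-aligned to it (edlib, unit cost) and gaps are merged under
"once a gap, always a gap".  Distances count columns where two rows differ,
including base-vs-gap, skipping gap-vs-gap and any column containing `N`.

Trees are built with the classic Saitou–Nei Neighbor-Joining agglomeration
on that matrix: standard Q criterion, ties broken by the lexicographically
smallest pair of node labels, negative branch-length estimates clamped to
zero.  On additive matrices the implementation recovers the generating tree
exactly (a property the test suite checks against randomly generated trees
and against an independent NJ implementation).  Branch lengths are in plain
nucleotide differences: these trees are a primer-screening device — short
branches flag markers whose amplicons cannot separate species — and are not
species phylogenies.

Output is a Newick string plus a tip annotation table (tip, taxon at the
chosen rank, stable color index cycled over a 12-color palette, unknown →
"unclassified"), with an optional minimal static PNG rendering; polished
interactive graphics are a non-goal.

Resolution metrics per rank: number of distinct taxa amplified, mean
pairwise difference within taxa, and the mean number of distinct taxa at
that rank sharing each unique insert sequence.  At rank species the last is
the species-per-unique-sequence statistic: ~1 means an observed sequence
identifies one species; large values mean the marker cannot discriminate
(the classic failure mode of very short or very conserved inserts, e.g.
plastid trnL fragments or recently radiated genera such as thrushes).  It
is reported per rank rather than species-only because the same question —
"does one sequence pin down one taxon?" — is asked at family or order level
when species resolution is known to be unattainable.

## Read processing

Stages, in order, each filing failures under an explicit reason so that
read counts are conserved end to end:

1. **Demultiplexing** by a 6-nt sample index, exact match only by default:
   the index sets are designed with pairwise Hamming distance ≥ 2, which
   detects single errors but cannot correct them safely (a single error can
   sit at distance 1 from two valid indices), so 1-mismatch rescue is
   opt-in (`policy="1mm"`, only applied when the neighbour is unique).
   Index sets are built by seeded greedy selection over shuffled candidates
   and verified by brute force in the tests.
2. **Primer identification and trimming**: the assay's forward primer is
   sought at offsets 0–5 of mate 1 and the reverse primer at offsets 0–5 of
   mate 2, degenerate-aware, ≤ 2 mismatches each; the assay minimising
   total mismatches wins and an exact tie across assays is rejected as
   ambiguous rather than guessed.  The primer and any bases 5′ of it are
   removed.  Because short amplicons (down to 17 bp inserts for plant-type
   assays) are much shorter than 250 bp reads, each insert is then scanned
   for the reverse complement of the opposite primer (full matches
   anywhere; 3′-terminal partial matches of at least 8 bases) and trimmed
   at the leftmost occurrence — without this, read-through adapter/primer
   sequence would survive into the consensus.
3. **Length filters**: each trimmed insert must reach the per-assay minimum
   (default 50 bp; short-amplicon assays override it in the panel file),
   and the two inserts of a pair may differ by at most 5 bp — a larger
   difference means a primer was missed in one mate.  The minimum-length
   filter is applied to per-mate inserts before merging, i.e. in the order
   trim → length → merge.
4. **Merging**: mate 2 is reverse-complemented and slid along mate 1; among
   offsets with overlap ≥ 10 and overlap identity ≥ 0.8 the one maximising
   a +1/−1 match/mismatch score wins (ties → longer overlap, then smaller
   offset).  Disagreeing overlap positions take the base with the higher
   Phred score (tie → mate 1).  This replaces probabilistic paired-end
   assemblers with a deterministic, unit-testable rule; error-free pairs
   from fragments of 60–400 bp reconstruct the fragment exactly (tested as
   a round-trip property).
5. **Dereplication**: identical (assay, sequence) consensus strings
   collapse into one record with per-sample read counts; output order is by
   descending total count and is independent of input order.  Only exact
   duplicates are collapsed — sub-100%-identity clustering (OTUs) is a
   non-goal.

## Species assignment and statistics

- Unique sequences with fewer than 10 reads total across all samples are
  removed as probable sequencing errors before any comparison.
- Each remaining sequence is compared against **every** reference by glocal
  alignment (query global, free end-gaps on the reference, unit cost);
  identity = matched positions / query length, `N` matching nothing.
  Exhaustive comparison against a desk-scale local database replaces a
  heuristic database search: it is exact, deterministic, and immune to
  database-version drift.  The implementation takes the edlib-optimal
  unit-cost alignment and counts matched columns excluding `N`; in the
  degenerate case of co-optimal paths the identity can differ by at most a
  column or two from an N-aware optimiser, which is far below the decision
  threshold granularity.
- A sequence is assigned iff its best identity **strictly exceeds** 0.90;
  all species tied at the maximum are assigned together (ties are real:
  sister species frequently share short marker sequences, and picking one
  would fabricate precision).
- The presence matrix sums reads per (sample, species) across all sequences
  whose species set contains that species — multi-species ties therefore
  contribute to every tied species, a deliberate, documented over-count —
  and calls presence at ≥ 10 reads per sample.  The per-sample threshold is
  applied to the species-level sum (not per unique sequence) because the
  evidence for a species in a sample is the totality of its reads; both
  thresholds are configurable.
- Species seen above threshold in extraction/PCR control samples are
  flagged in the output but not subtracted: control hits indicate
  contamination pressure, not that every field observation of that species
  is false.
- Association of one species' presence with a sample grouping (river
  region, collection timepoint) uses Fisher's exact test, two-sided: SciPy
  for 2×2 tables, and an in-package exact enumeration of all tables with
  the observed margins (multivariate hypergeometric) for 2×3, since SciPy's
  R×C path is a Monte-Carlo permutation test rather than exact.  Raw
  p-values are reported with no multiplicity correction, matching the
  descriptive use of these tests.  A table with an empty margin yields
  p = 1 with a warning.
- `expected_read_count(abundance, mean_depth)` is the nearest-integer
  product — the sanity arithmetic behind the 10-read floor: a species at 1%
  abundance in an assay averaging 14,211 reads per sample is expected in
  ~142 reads, an order of magnitude above the filter.

## Synthetic data generator

The generator emulates the full input bundle with known ground truth.

*Reference database*: species marker sequences evolve by i.i.d.
substitution down a fixed star-within-level hierarchy (ancestor → family →
genus → species), with per-branch divergences defaulting to 0.12 / 0.05 /
0.02 substitutions per site — giving within-genus < within-family distances
in expectation and realistic ~2–10% species-level divergence for a
mitochondrial-style marker.  Optional rare indels exercise gapped
alignment.  Every record embeds, for each assay in the panel, an exact
concrete realisation of the primer pair flanking the species insert,
separated by random spacers, so in-silico PCR finds exactly one amplicon
per species per assay; configuring more embedded primer-site mismatches
than the matcher tolerates is rejected rather than silently producing an
unamplifiable database.  Species inserts are forced pairwise distinct
within an assay (resampled substitutions on collision) so that an
error-free read identifies a unique species — real markers do collide
(whole genera sharing one sequence), so perfect recovery in these tests
demonstrates pipeline correctness, not real-world resolution.

*Reads*: the default panel has three assays with insert lengths 95, 53 and
48 bp (a mammal-16S-like, bird-12S-like and short plant-trnL-like shape),
read length 250 bp, so every default read runs through the amplicon into
adapter — deliberately forcing the read-through trimming path.  Each read
pair draws a species from the sample's composition and an assay uniformly;
substitution errors are injected at a configurable per-base rate (0–5%),
and error positions receive a Phred dip (12 vs baseline 37).  Tying quality
to error is an idealisation of the real correlation between low quality and
miscalls; it lets quality-resolved merging correct almost all single-mate
errors, leaving consensus errors mainly where both mates err at the same
position.  Real data would retain more error sequences than this model.

*Study layout*: `default_study_config` builds n field samples (default 12)
split over three river regions and two timepoints separated by a rain
event, plus two zero-composition extraction-control blanks, each field
sample holding 2–6 species at fractions ≥ ~5%, at a default depth of 5,000
read pairs per sample.  The full river-survey shape (91 sites + 2 controls)
is reproducible by setting `n_samples=91` with miniature depths.
Everything (database, compositions, reads, FASTQ bytes) is deterministic
per seed.

Not modelled: amplification-efficiency competition between templates (the
reason the assay is non-quantitative), PCR chimeras, quality decay along
the read, cross-talk between indices, and taxon-dependent depth skew.

## Problem sizes in the shipped checks

The acceptance script and test suite run the end-to-end study at 12 samples
× 5,000 read pairs (~60,000 pairs), the NJ exactness property over 100–200
random trees of ≤ 8 tips, the primer-matching oracle over 50–100 random
1 kb references, and the merge round-trip over 200–500 random fragments —
sizes chosen to exercise every code path at desk scale while keeping a full
run in minutes.

## Known limitations

- Center-star alignments can differ from progressive-aligner alignments;
  tree topologies over amplicons are screening aids either way.
- The in-silico PCR stringency is a declared local semantics, not a
  reproduction of any remote service's scoring.
- Best-hit assignment is only as good as the reference database; absent
  taxa surface as high-identity hits to relatives (reported identity makes
  this auditable) and absence from output never proves absence in the
  environment.
- Exhaustive glocal comparison scales as (queries × references); it is
  intended for curated marker databases of up to a few thousand records,
  not whole-nucleotide-archive scale.
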