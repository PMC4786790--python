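# amplitree

**In-silico evaluation of "universal" eDNA primer pairs, and a multiplexed
metabarcoding pipeline from raw indexed paired reads to a per-sample
species presence/absence matrix.**

Environmental DNA (eDNA) surveys amplify a taxonomically informative marker
(e.g. mammalian mitochondrial 16S rRNA, plastid trnL) from mixed-template
water or soil extracts with taxon-wide ("universal") primers, sequence all
products together, and identify the species behind each read.  Two
computational problems dominate such studies, and this package addresses
both for ecologists and molecular biologists designing or analysing them:

1. **Will a candidate primer pair work?**  Before any wet-lab work, a pair
   should amplify broadly within its target taxon, avoid off-target taxa,
   and yield amplicons variable enough to tell species apart.  `amplitree`
   predicts amplicons of a (possibly IUPAC-degenerate) primer pair against
   a local taxonomy-annotated reference database, aligns them, builds a
   Neighbor-Joining tree with branch lengths in nucleotide differences and
   taxon-annotated tips, and reports resolution metrics — number of taxa
   amplified, mean within-taxon pairwise differences, and the mean number
   of species sharing each unique amplicon sequence (≈1 means one sequence
   identifies one species).

2. **From reads to species.**  Given multiplexed 250 bp paired reads with
   6-nt sample indices, the pipeline demultiplexes (indices designed with
   pairwise Hamming distance ≥ 2), finds and trims amplification primers
   (including 3′ read-through of short amplicons), discards inserts < 50 bp
   (configurable per assay) and pairs whose mates differ by > 5 bp, merges
   each pair into a quality-resolved consensus, dereplicates into unique
   sequences with per-sample counts, removes sequences with < 10 reads
   total, assigns species by exhaustive best-hit glocal identity (> 90%
   over the full sequence, all tied species kept), calls presence at ≥ 10
   reads per sample per species, and tests presence against sample
   groupings with Fisher's exact test.

A seeded synthetic-data generator produces complete study bundles
(reference database, primer panel, indexed FASTQs, sample sheet) with known
ground truth, so every stage is testable without downloads.

## Core definitions

For a primer p of length m laid at a reference site, the site is a hit iff

    #mismatches(p, site) ≤ 2   and   the last 2 bases at the 3′ end match exactly,

where a degenerate position matches every base of its IUPAC set at zero
cost and reference `N` never matches.  Amplicons are all inward-facing
forward × reverse hit combinations with product length in the pair's
bounds, down-sampled uniformly to 500 if more are found; degenerate primers
expand to at most 25 concrete sequences (all, if fewer).

Distances between aligned amplicons i, j count columns where rows differ
(base-vs-gap included, gap-vs-gap and N-columns skipped).  Trees use
Saitou–Nei Neighbor-Joining: iteratively join the pair (i,j) minimising
Q(i,j) = (n−2)·d(i,j) − Σₖd(i,k) − Σₖd(j,k), with branch lengths
lᵢ = d(i,j)/2 + (Σₖd(i,k) − Σₖd(j,k))/(2(n−2)) clamped to ≥ 0.

Assignment identity of query q against reference r is
matches/|q| under a unit-cost alignment of q global in q with free end-gaps
in r; a sequence is assigned iff its best identity is strictly > 0.90, to
the set of all species attaining the maximum.

## Worked example

Simulate a small six-sample study, run the pipeline, and check recovery:

```python
import amplitree as at

cfg = at.default_study_config(seed=42, n_samples=6, depth=2000)
pairs, sheet, truth, cfg = at.simulate_study(cfg)          # 12,000 read pairs
result = at.process_pairs(pairs, sheet, cfg.panel)
kept, removed = at.filter_low_count(result.merged)         # 36 kept, 0 removed
assignments = at.assign_all(kept, truth.db)
pm = at.presence_matrix(assignments, sheet)
print(pm.presence.sum(axis=1))
```

prints the number of species detected per sample:

```
CTRL0    0
CTRL1    0
S000     5
S001     4
S002     6
S003     4
S004     3
S005     3
```

The two extraction-control blanks are clean, and each field sample's
species set equals the simulated ground truth (`truth.species_set(s)`).
Association of one species' presence with the collection timepoint:

```python
p, table = at.fisher_association(pm, pm.counts.columns[0], "timepoint")
# p = 0.25 — no evidence this species differs before vs after the rain event
```

Evaluating the bundled mammal-16S-style assay against the simulated
reference database:

```python
from amplitree.pcr import PcrConfig, predict_amplicons, pcr_summary

db, truth = at.simulate_reference_db(at.SimConfig(seed=42))
amps = predict_amplicons(db, cfg.panel[0], PcrConfig(seed=1))
s = pcr_summary(amps)          # 18 amplicons, 18 species, inserts 95 bp
res = at.resolution_summary(amps)
res["mean_species_per_unique_sequence"]   # 1.0 → every sequence → one species
res["per_rank"]["genus"]["mean_within_taxon_pairwise_diff"]   # 6.67 nt
```

Every number above is what the code prints at these seeds: one amplicon per
species, perfectly species-resolving inserts, and ~7 nucleotide differences
between congeneric amplicons.

The same workflows are available from the shell:

```
amplitree simulate --seed 42 --n-samples 6 --depth 2000 --out run/
amplitree db validate run/reference.fasta run/taxonomy.tsv
amplitree pcr --db run/reference.fasta --tax run/taxonomy.tsv \
              --panel run/panel.tsv --assay mam16S --seed 1 --out amplicons.fa
amplitree tree --amplicons amplicons.fa --rank family --out tree.nwk
amplitree pipeline reads --r1 run/r1.fastq --r2 run/r2.fastq \
              --index run/index.fastq --sheet run/samples.tsv \
              --panel run/panel.tsv --out reads_out/
amplitree pipeline assign --db run/reference.fasta --tax run/taxonomy.tsv \
              --counts reads_out/counts.tsv --sheet run/samples.tsv --out assign_out/
```

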