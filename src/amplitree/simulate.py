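"""Synthetic study generator with known ground truth.

Emulates the inputs of a multiplexed eDNA metabarcoding run end to end: a
taxonomy-structured reference marker database (species sequences evolved by
i.i.d. substitution down a fixed family → genus → species star hierarchy, so
within-genus distances are smaller than within-family distances in
expectation), a panel of degenerate primer pairs whose binding sites are
embedded in every record, and indexed paired 250 bp reads simulated from
per-sample species compositions with substitution errors and read-through
of short amplicons.  Everything is deterministic per seed and the ground
truth (who is in which sample, at what expected read count, with which
amplicon) is returned alongside, so every pipeline stage is testable
without downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pcr import Primer, PrimerPair, write_panel
from .readproc import ReadPair, SampleInfo, SampleSheet, design_index_set, write_sample_sheet
from .refdb import ReferenceDB, RefSequence, write_db
from .seq import IUPAC, revcomp
from .taxonomy import TaxonLineage

BASES = "ACGT"
BASE_QUAL = 37      # baseline Phred for a correct call
ERROR_QUAL = 12     # dip at positions where an error was injected
ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCACGTAGATCTCGGTGGTCGCCGTATCATT"

#: Maximum embedded primer-site mismatches before sites stop being findable
#: under the default matching stringency.
MAX_SITE_MISMATCHES = 2


@dataclass
class SampleSpec:
    sample_id: str
    composition: dict[str, float]  # species → fraction, sums to 1 (or empty)
    depth: int
    index: str
    site: str = ""
    region: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        if self.composition:
            total = sum(self.composition.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"sample {self.sample_id}: composition sums to {total}, not 1"
                )
            if any(f < 0 for f in self.composition.values()):
                raise ValueError(f"sample {self.sample_id}: negative fraction")


@dataclass
class SimConfig:
    seed: int = 0
    n_families: int = 3
    n_genera_per_family: int = 2
    n_species_per_genus: int = 3
    family_divergence: float = 0.12   # substitutions per site on the family branch
    genus_divergence: float = 0.05
    species_divergence: float = 0.02
    indel_rate: float = 0.0           # optional, exercises gapped alignment
    primer_site_mismatches: int = 0
    panel: list[PrimerPair] = field(default_factory=list)
    insert_lengths: dict[str, int] = field(default_factory=dict)
    samples: list[SampleSpec] = field(default_factory=list)
    error_rate: float = 0.0
    read_length: int = 250
    spacer_length: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if not self.panel:
            self.panel = default_panel()
        if not self.insert_lengths:
            self.insert_lengths = DEFAULT_INSERT_LENGTHS.copy()
        for p in self.panel:
            if p.assay not in self.insert_lengths:
                raise ValueError(f"no insert length configured for assay {p.assay}")
        if self.primer_site_mismatches > MAX_SITE_MISMATCHES:
            raise ValueError(
                f"primer_site_mismatches={self.primer_site_mismatches} would destroy "
                f"the embedded primer sites (max {MAX_SITE_MISMATCHES})"
            )

    @property
    def n_species(self) -> int:
        return self.n_families * self.n_genera_per_family * self.n_species_per_genus


@dataclass
class GroundTruth:
    db: ReferenceDB
    #: species → assay → true insert sequence
    inserts: dict[str, dict[str, str]]
    #: assay → (concrete forward site, concrete reverse site as embedded)
    primer_sites: dict[str, tuple[str, str]]
    #: sample_id → species → expected read count (composition × depth)
    expected_counts: dict[str, dict[str, float]] = field(default_factory=dict)

    def species_set(self, sample_id: str) -> set[str]:
        return {s for s, c in self.expected_counts.get(sample_id, {}).items() if c > 0}


def default_panel() -> list[PrimerPair]:
    """A miniature three-assay panel shaped like a field panel: a mammal-style
    16S pair (~95 bp inserts), a bird-style 12S pair (~53 bp) and a plant
    trnL-style pair with very short inserts (~48 bp, minimum 17 bp) that
    force read-through handling.  One degenerate base per pair keeps the
    degenerate-matching path exercised."""
    return [
        PrimerPair(
            assay="mam16S",
            forward=Primer("mam16S_F", "CGGTTGGGGTGACCTCGGA"),
            reverse=Primer("mam16S_R", "GCTGTTATCCCTAGGGTARCT"),
            min_product=60, max_product=400, min_read_len=50,
        ),
        PrimerPair(
            assay="bird12S",
            forward=Primer("bird12S_F", "GTCTTGTAAACCGGAGATGA"),
            reverse=Primer("bird12S_R", "CACCTTCACGGGYTTACAGC"),
            min_product=60, max_product=400, min_read_len=50,
        ),
        PrimerPair(
            assay="plantTrnL",
            forward=Primer("plantTrnL_F", "GGGCAATCCTGAGCCAAATC"),
            reverse=Primer("plantTrnL_R", "CCATTGAGTCTCTGCACCTATC"),
            min_product=50, max_product=400, min_read_len=17,
        ),
    ]


DEFAULT_INSERT_LENGTHS = {"mam16S": 95, "bird12S": 53, "plantTrnL": 48}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def _mutate(rng: np.random.Generator, seq: str, rate: float, indel_rate: float = 0.0) -> str:
    """i.i.d. substitutions at ``rate`` per site, optional rare indels."""
    out = []
    for c in seq:
        if indel_rate and rng.random() < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(rng.choice(list(BASES)))  # insertion before c
        if rng.random() < rate:
            out.append(rng.choice([b for b in BASES if b != c]))
        else:
            out.append(c)
    return "".join(out)


def _concrete_site(rng: np.random.Generator, primer_seq: str, n_mismatch: int) -> str:
    """One concrete realisation of a degenerate primer, with ``n_mismatch``
    substitutions away from matchability placed off the 3' anchor."""
    site = [rng.choice(sorted(IUPAC[c])) for c in primer_seq]
    if n_mismatch:
        positions = rng.choice(len(site) - MAX_SITE_MISMATCHES, size=n_mismatch, replace=False)
        for p in positions:
            allowed = IUPAC[primer_seq[p]]
            site[p] = rng.choice([b for b in BASES if b not in allowed] or list(BASES))
    return "".join(site)


def simulate_reference_db(config: SimConfig) -> tuple[ReferenceDB, GroundTruth]:
    """Generate the reference DB and the partial ground truth.

    Each species record concatenates, per assay, an exact (or configurably
    mismatched) forward primer site, a species-specific insert and the
    reverse-complemented reverse primer site, separated by random spacers —
    so in-silico PCR yields exactly one amplicon per species per assay.
    Species inserts are forced pairwise distinct within an assay so that a
    perfect read maps back to a unique species.
    """
    rng = np.random.default_rng(config.seed)
    primer_sites: dict[str, tuple[str, str]] = {}
    ancestors: dict[str, str] = {}
    for p in config.panel:
        fwd = _concrete_site(rng, p.forward.seq, config.primer_site_mismatches)
        rev = _concrete_site(rng, p.reverse.seq, config.primer_site_mismatches)
        primer_sites[p.assay] = (fwd, rev)
        ancestors[p.assay] = _random_seq(rng, config.insert_lengths[p.assay])

    records: list[RefSequence] = []
    inserts: dict[str, dict[str, str]] = {}
    seen_per_assay: dict[str, set[str]] = {p.assay: set() for p in config.panel}
    sp_counter = 0
    for fi in range(config.n_families):
        class_name = f"Simuclassis{fi % max(1, (config.n_families + 1) // 2)}"
        order_name = f"Simuordo{fi}"
        family_name = f"Simufamilia{fi}"
        fam_seq = {a: _mutate(rng, s, config.family_divergence, config.indel_rate)
                   for a, s in ancestors.items()}
        for gi in range(config.n_genera_per_family):
            genus_name = f"Simugenus{fi}{gi}"
            gen_seq = {a: _mutate(rng, s, config.genus_divergence, config.indel_rate)
                       for a, s in fam_seq.items()}
            for si in range(config.n_species_per_genus):
                sp_counter += 1
                species_name = f"{genus_name} species{si}"
                sp_ins: dict[str, str] = {}
                for p in config.panel:
                    ins = _mutate(rng, gen_seq[p.assay], config.species_divergence,
                                  config.indel_rate)
                    while ins in seen_per_assay[p.assay]:
                        pos = int(rng.integers(len(ins)))
                        ins = (ins[:pos]
                               + rng.choice([b for b in BASES if b != ins[pos]])
                               + ins[pos + 1:])
                    seen_per_assay[p.assay].add(ins)
                    sp_ins[p.assay] = ins
                inserts[species_name] = sp_ins
                parts = [_random_seq(rng, config.spacer_length)]
                for p in config.panel:
                    fwd, rev = primer_sites[p.assay]
                    parts.append(fwd + sp_ins[p.assay] + revcomp(rev))
                    parts.append(_random_seq(rng, config.spacer_length))
                lineage = TaxonLineage(
                    {
                        "superkingdom": "Eukaryota",
                        "phylum": "Simuphylum",
                        "class": class_name,
                        "order": order_name,
                        "family": family_name,
                        "genus": genus_name,
                        "species": species_name,
                    }
                )
                records.append(
                    RefSequence(
                        id=f"ref{sp_counter:04d}",
                        description=species_name,
                        seq="".join(parts),
                        lineage=lineage,
                    )
                )
    db = ReferenceDB(records=records)
    return db, GroundTruth(db=db, inserts=inserts, primer_sites=primer_sites)


def _make_read(rng: np.random.Generator, template: str, read_length: int,
               error_rate: float) -> tuple[str, list[int]]:
    """One read off a template: pad with adapter to read length, then apply
    substitution errors whose positions get a Phred dip."""
    fill = template
    while len(fill) < read_length:
        fill += ADAPTER
    seq = np.array(list(fill[:read_length]))
    qual = np.full(read_length, BASE_QUAL, dtype=int)
    if error_rate > 0:
        errs = np.nonzero(rng.random(read_length) < error_rate)[0]
        for i in errs:
            seq[i] = rng.choice([b for b in BASES if b != seq[i]])
            qual[i] = ERROR_QUAL
    return "".join(seq), qual.tolist()


def simulate_sample(
    truth: GroundTruth,
    spec: SampleSpec,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[ReadPair]:
    """Read pairs for one sample: species drawn from the composition, assay
    uniform among assays amplifying it, reads of ``read_length`` with
    read-through where the amplicon is short."""
    if not spec.composition or spec.depth == 0:
        return []
    unknown = [s for s in spec.composition if s not in truth.inserts]
    if unknown:
        raise ValueError(f"sample {spec.sample_id}: species not in DB: {unknown}")
    species = list(spec.composition)
    probs = np.array([spec.composition[s] for s in species])
    assays = [p.assay for p in config.panel]
    sp_draw = rng.choice(len(species), size=spec.depth, p=probs)
    as_draw = rng.choice(len(assays), size=spec.depth)
    pairs: list[ReadPair] = []
    for i in range(spec.depth):
        sp = species[sp_draw[i]]
        assay = assays[as_draw[i]]
        fwd, rev = truth.primer_sites[assay]
        fragment = fwd + truth.inserts[sp][assay] + revcomp(rev)
        r1, q1 = _make_read(rng, fragment, config.read_length, config.error_rate)
        r2, q2 = _make_read(rng, revcomp(fragment), config.read_length, config.error_rate)
        pairs.append(
            ReadPair(
                id=f"{spec.sample_id}_read{i:06d}",
                r1_seq=r1, r1_qual=q1, r2_seq=r2, r2_qual=q2,
                index_seq=spec.index,
            )
        )
    return pairs


def default_study_config(
    seed: int = 0,
    n_samples: int = 12,
    depth: int = 5000,
    error_rate: float = 0.0,
    n_controls: int = 2,
    **kwargs,
) -> SimConfig:
    """A study layout mirroring a river survey: ``n_samples`` field samples
    split over three river regions and two timepoints separated by a rain
    event, plus extraction-control blanks, each field sample holding 2–6
    species at fractions of at least ~5%."""
    config = SimConfig(seed=seed, error_rate=error_rate, **kwargs)
    rng = np.random.default_rng(seed + 1)
    _, truth = simulate_reference_db(config)
    all_species = sorted(truth.inserts)
    indices = design_index_set(n_samples + n_controls, length=6, min_dist=2, seed=seed + 2)
    regions = ["upper", "middle", "lower"]
    samples: list[SampleSpec] = []
    for i in range(n_samples):
        k = int(rng.integers(2, 7))
        chosen = rng.choice(len(all_species), size=min(k, len(all_species)), replace=False)
        weights = rng.uniform(0.5, 1.5, size=len(chosen))
        weights /= weights.sum()
        composition = {all_species[j]: float(w) for j, w in zip(chosen, weights)}
        samples.append(
            SampleSpec(
                sample_id=f"S{i:03d}",
                composition=composition,
                depth=depth,
                index=indices[i],
                site=f"site{i:03d}",
                region=regions[i % 3],
                timepoint="before_rain" if i % 2 == 0 else "after_rain",
            )
        )
    for c in range(n_controls):
        samples.append(
            SampleSpec(
                sample_id=f"CTRL{c}",
                composition={},
                depth=0,
                index=indices[n_samples + c],
                site="lab",
                region="control",
                timepoint="control",
            )
        )
    config.samples = samples
    return config


def simulate_study(config: SimConfig, out_dir: str | Path | None = None):
    """Simulate the whole run; optionally write the bundle to ``out_dir``.

    Returns (pairs, sheet, truth, config).  The bundle on disk holds the
    r1/r2/index FASTQs, sample sheet, panel, reference FASTA + taxonomy and
    a truth manifest JSON.
    """
    if not config.samples:
        raise ValueError("config.samples is empty; use default_study_config or set samples")
    db, truth = simulate_reference_db(config)
    rng = np.random.default_rng(config.seed + 1000)
    pairs: list[ReadPair] = []
    for spec in config.samples:
        pairs.extend(simulate_sample(truth, spec, config, rng))
        truth.expected_counts[spec.sample_id] = {
            s: f * spec.depth for s, f in spec.composition.items()
        }
    sheet = SampleSheet(
        entries={
            s.index: SampleInfo(s.sample_id, s.site, s.region, s.timepoint)
            for s in config.samples
        }
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_db(db, out / "reference.fasta", out / "taxonomy.tsv")
        write_panel(config.panel, out / "panel.tsv")
        write_sample_sheet(sheet, out / "samples.tsv")
        _write_fastqs(pairs, out)
        manifest = {
            "seed": config.seed,
            "n_samples": len(config.samples),
            "read_pairs": len(pairs),
            "files": {
                "r1": "r1.fastq", "r2": "r2.fastq", "index": "index.fastq",
                "reference": "reference.fasta", "taxonomy": "taxonomy.tsv",
                "panel": "panel.tsv", "sheet": "samples.tsv",
            },
            "expected_counts": truth.expected_counts,
            "primer_sites": {a: list(v) for a, v in truth.primer_sites.items()},
            "inserts": truth.inserts,
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return pairs, sheet, truth, config


def _phred33(quals: list[int]) -> str:
    return "".join(chr(q + 33) for q in quals)


def _write_fastqs(pairs: list[ReadPair], out: Path) -> None:
    with open(out / "r1.fastq", "w") as f1, open(out / "r2.fastq", "w") as f2, open(
        out / "index.fastq", "w"
    ) as fi:
        for p in pairs:
            f1.write(f"@{p.id}\n{p.r1_seq}\n+\n{_phred33(p.r1_qual)}\n")
            f2.write(f"@{p.id}\n{p.r2_seq}\n+\n{_phred33(p.r2_qual)}\n")
            fi.write(f"@{p.id}\n{p.index_seq}\n+\n{_phred33([BASE_QUAL] * len(p.index_seq))}\n")
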