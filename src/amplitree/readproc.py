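"""Multiplexed paired-end read processing.

Raw indexed MiSeq-style read pairs are demultiplexed by a 6-nt sample index,
assigned to an assay by locating the amplification primers at the 5′ ends of
both mates, trimmed (including 3′ read-through into the opposite primer for
short amplicons), length-filtered, merged into a single consensus per pair
and dereplicated into unique sequences with per-sample read counts.  Every
read is accounted for: each stage either passes a pair on or files it under
an explicit rejection reason.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .pcr import PrimerPair
from .seq import IUPAC, revcomp

log = logging.getLogger(__name__)

#: Offsets at which the amplification primer is sought at a mate's 5' end.
PRIMER_SEARCH_WINDOW = 6


@dataclass
class ReadPair:
    id: str
    r1_seq: str
    r1_qual: list[int]
    r2_seq: str
    r2_qual: list[int]
    index_seq: str

    def __post_init__(self) -> None:
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(self.r2_qual):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass
class SampleInfo:
    sample_id: str
    site: str = ""
    region: str = ""
    timepoint: str = ""


@dataclass
class SampleSheet:
    """index → sample metadata; indices unique, equal length, pairwise
    Hamming distance >= 2 so a single sequencing error cannot convert one
    valid index into another."""

    entries: dict[str, SampleInfo]

    def __post_init__(self) -> None:
        idxs = list(self.entries)
        if not idxs:
            raise ValueError("sample sheet is empty")
        if len({len(i) for i in idxs}) != 1:
            raise ValueError("indices must all have the same length")
        sids = [e.sample_id for e in self.entries.values()]
        if len(set(sids)) != len(sids):
            raise ValueError("duplicate sample ids in sheet")
        for a, b in itertools.combinations(idxs, 2):
            if hamming(a, b) < 2:
                raise ValueError(f"indices {a} and {b} are fewer than 2 mismatches apart")

    @property
    def samples(self) -> list[str]:
        return [e.sample_id for e in self.entries.values()]

    def info(self, sample_id: str) -> SampleInfo:
        for e in self.entries.values():
            if e.sample_id == sample_id:
                return e
        raise KeyError(sample_id)


@dataclass
class TrimmedPair:
    id: str
    sample_id: str
    assay: str
    r1_insert: str
    r1_qual: list[int]
    r2_insert: str
    r2_qual: list[int]
    fwd_mismatches: int
    rev_mismatches: int


@dataclass
class Rejection:
    id: str
    stage: str
    reason: str


@dataclass
class MergedSequence:
    """Dereplicated consensus with per-sample read counts."""

    seq: str
    assay: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def design_index_set(n: int, length: int = 6, min_dist: int = 2, seed: int = 0) -> list[str]:
    """Greedy randomized set of ``n`` sample indices with pairwise Hamming
    distance >= ``min_dist``; deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if min_dist > length:
        raise ValueError(
            f"min_dist {min_dist} exceeds index length {length}; bound reached at 0 indices"
        )
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    candidates = ["".join(p) for p in itertools.product(bases, repeat=length)]
    order = rng.permutation(len(candidates))
    chosen: list[str] = []
    for k in order:
        cand = candidates[k]
        if all(hamming(cand, c) >= min_dist for c in chosen):
            chosen.append(cand)
            if len(chosen) == n:
                return chosen
    raise ValueError(
        f"cannot construct {n} indices of length {length} with pairwise distance "
        f">= {min_dist}; bound reached at {len(chosen)}"
    )


def demultiplex(
    pairs: list[ReadPair], sheet: SampleSheet, policy: str = "exact"
) -> dict[str, list[ReadPair]]:
    """Assign pairs to samples by index; unmatched pairs go to "unassigned".

    The default exact policy requires the read index to equal a sheet entry:
    with a minimum pairwise index distance of 2, tolerating one mismatch
    could mis-assign reads, so error correction is off unless requested
    (policy="1mm" accepts a unique single-mismatch neighbour).
    """
    if policy not in ("exact", "1mm"):
        raise ValueError(f"unknown demultiplex policy {policy!r}")
    out: dict[str, list[ReadPair]] = {e.sample_id: [] for e in sheet.entries.values()}
    out["unassigned"] = []
    for p in pairs:
        sample = None
        entry = sheet.entries.get(p.index_seq)
        if entry is not None:
            sample = entry.sample_id
        elif policy == "1mm" and len(p.index_seq) == len(next(iter(sheet.entries))):
            near = [e.sample_id for idx, e in sheet.entries.items() if hamming(idx, p.index_seq) == 1]
            if len(near) == 1:
                sample = near[0]
        out[sample if sample is not None else "unassigned"].append(p)
    return out


_PRIMER_SETS_CACHE: dict[str, tuple[frozenset, ...]] = {}


def _primer_sets(primer_seq: str) -> tuple[frozenset, ...]:
    sets = _PRIMER_SETS_CACHE.get(primer_seq)
    if sets is None:
        sets = tuple(frozenset(IUPAC[c]) for c in primer_seq)
        _PRIMER_SETS_CACHE[primer_seq] = sets
    return sets


def _mismatches_at(read: str, primer_seq: str, offset: int) -> int | None:
    """Mismatches of the degenerate primer laid at ``offset``; None if the
    read is too short there.  Read N never matches."""
    sets = _primer_sets(primer_seq)
    if offset + len(sets) > len(read):
        return None
    mm = 0
    for k, allowed in enumerate(sets):
        if read[offset + k] not in allowed:
            mm += 1
    return mm


def _find_primer(read: str, primer_seq: str, max_mismatch: int) -> tuple[int, int] | None:
    """Best (offset, mismatches) of the primer within the 5' search window."""
    best: tuple[int, int] | None = None
    for off in range(PRIMER_SEARCH_WINDOW):
        mm = _mismatches_at(read, primer_seq, off)
        if mm is not None and mm <= max_mismatch and (best is None or mm < best[1]):
            best = (off, mm)
    return best


def _find_readthrough(insert: str, primer_rc: str, max_mismatch: int) -> int | None:
    """Leftmost start of the reverse-complemented opposite primer inside the
    insert (a prefix of it may hang off the 3' end), or None."""
    sets = _primer_sets(primer_rc)
    n, m = len(insert), len(sets)
    for start in range(n):
        span = min(m, n - start)
        if span < min(m, 8):  # require a meaningful anchor for partial hits
            break
        mm = sum(1 for k in range(span) if insert[start + k] not in sets[k])
        if mm <= max_mismatch:
            return start
    return None


def identify_and_trim(
    pair: ReadPair,
    panel: list[PrimerPair],
    max_mismatch: int = 2,
    *,
    sample_id: str = "",
) -> TrimmedPair | Rejection:
    """Locate the assay primers at the 5′ ends of both mates and trim them.

    The forward primer is sought at offsets 0–5 of r1 and the reverse primer
    at offsets 0–5 of r2 (degenerate-aware, at most ``max_mismatch`` each);
    the assay minimising total mismatches wins, with an exact tie across
    assays rejected as ambiguous.  The primer and any preceding bases are
    removed.  If the reverse complement of the opposite primer occurs within
    an insert (read-through of a short amplicon), it and everything after it
    are removed too.
    """
    if not panel:
        raise ValueError("primer panel is empty")
    scored: list[tuple[int, PrimerPair, tuple[int, int], tuple[int, int]]] = []
    for pp in panel:
        f = _find_primer(pair.r1_seq, pp.forward.seq, max_mismatch)
        r = _find_primer(pair.r2_seq, pp.reverse.seq, max_mismatch)
        if f is not None and r is not None:
            scored.append((f[1] + r[1], pp, f, r))
    if not scored:
        return Rejection(pair.id, "trim", "no_primer")
    scored.sort(key=lambda t: t[0])
    if len(scored) > 1 and scored[0][0] == scored[1][0]:
        return Rejection(pair.id, "trim", "ambiguous")
    total_mm, pp, (foff, fmm), (roff, rmm) = scored[0]

    r1_start = foff + len(pp.forward.seq)
    r2_start = roff + len(pp.reverse.seq)
    r1_insert = pair.r1_seq[r1_start:]
    r1_qual = pair.r1_qual[r1_start:]
    r2_insert = pair.r2_seq[r2_start:]
    r2_qual = pair.r2_qual[r2_start:]

    cut = _find_readthrough(r1_insert, revcomp(pp.reverse.seq), max_mismatch)
    if cut is not None:
        r1_insert, r1_qual = r1_insert[:cut], r1_qual[:cut]
    cut = _find_readthrough(r2_insert, revcomp(pp.forward.seq), max_mismatch)
    if cut is not None:
        r2_insert, r2_qual = r2_insert[:cut], r2_qual[:cut]

    if not r1_insert or not r2_insert:
        return Rejection(pair.id, "trim", "empty_insert")
    return TrimmedPair(
        id=pair.id,
        sample_id=sample_id,
        assay=pp.assay,
        r1_insert=r1_insert,
        r1_qual=r1_qual,
        r2_insert=r2_insert,
        r2_qual=r2_qual,
        fwd_mismatches=fmm,
        rev_mismatches=rmm,
    )


def length_filters(
    trimmed: TrimmedPair, panel: list[PrimerPair], max_length_diff: int = 5
) -> TrimmedPair | Rejection:
    """Discard inserts below the per-assay minimum length (default 50 bp;
    short-amplicon assays such as plants/bryophytes override it in the
    panel) and pairs whose two inserts differ in length by more than 5 bp
    (a primer was likely missed in one mate)."""
    by_assay = {p.assay: p for p in panel}
    min_len = by_assay[trimmed.assay].min_read_len
    if len(trimmed.r1_insert) < min_len or len(trimmed.r2_insert) < min_len:
        return Rejection(trimmed.id, "length", "too_short")
    if abs(len(trimmed.r1_insert) - len(trimmed.r2_insert)) > max_length_diff:
        return Rejection(trimmed.id, "length", "length_diff")
    return trimmed


def merge_pair(
    trimmed: TrimmedPair,
    min_overlap: int = 10,
    min_overlap_identity: float = 0.8,
) -> str | Rejection:
    """Merge the two inserts into one consensus sequence.

    r2 is reverse-complemented and slid along r1; among offsets with overlap
    >= ``min_overlap`` and overlap identity >= ``min_overlap_identity`` the
    one maximising (+1 match / −1 mismatch) score wins (ties → longer
    overlap, then smaller offset).  At disagreeing overlap positions the
    base with the higher Phred score is kept (tie → r1's base).
    """
    a = trimmed.r1_insert
    qa = trimmed.r1_qual
    b = revcomp(trimmed.r2_insert)
    qb = trimmed.r2_qual[::-1]
    la, lb = len(a), len(b)

    best: tuple[int, int, int] | None = None  # (score, overlap, offset)
    for off in range(0, la - min_overlap + 1):
        ov = min(la - off, lb)
        if ov < min_overlap:
            continue
        matches = sum(1 for k in range(ov) if a[off + k] == b[k])
        if matches / ov < min_overlap_identity:
            continue
        score = 2 * matches - ov
        key = (score, ov, -off)
        if best is None or key > (best[0], best[1], -best[2]):
            best = (score, ov, off)
    if best is None:
        return Rejection(trimmed.id, "merge", "no_overlap")
    _, ov, off = best

    out: list[str] = list(a[:off])
    for k in range(ov):
        ca, cb = a[off + k], b[k]
        if ca == cb:
            out.append(ca)
        elif qb[k] > qa[off + k]:
            out.append(cb)
        else:
            out.append(ca)
    if off + lb > la:
        out.extend(b[ov:])
    else:
        out.extend(a[off + ov:])
    return "".join(out)


def dereplicate(consensus: list[tuple[str, str, str]]) -> list[MergedSequence]:
    """Collapse (assay, sample_id, sequence) triples into unique sequences.

    One MergedSequence per distinct (assay, sequence), with per-sample read
    counts; the total count equals the number of inputs.  Output order is
    by descending total count, then assay, then sequence — independent of
    input order.
    """
    tally: dict[tuple[str, str], Counter] = {}
    for assay, sample, seq in consensus:
        tally.setdefault((assay, seq), Counter())[sample] += 1
    out = [
        MergedSequence(seq=seq, assay=assay, counts=dict(sorted(c.items())))
        for (assay, seq), c in tally.items()
    ]
    out.sort(key=lambda m: (-m.total_reads, m.assay, m.seq))
    return out


@dataclass
class PipelineResult:
    merged: list[MergedSequence]
    tallies: dict[str, int]
    rejections: list[Rejection]
    consensus: list[tuple[str, str, str]] = field(default_factory=list)


def process_pairs(
    pairs: list[ReadPair],
    sheet: SampleSheet,
    panel: list[PrimerPair],
    *,
    policy: str = "exact",
    max_mismatch: int = 2,
    min_overlap: int = 10,
    min_overlap_identity: float = 0.8,
) -> PipelineResult:
    """Run demultiplex → trim → length filters → merge → dereplicate.

    Read conservation holds at every stage: assigned + unassigned equals the
    input count, and merged + each rejection reason equals the assigned
    count; the per-stage tallies are returned and logged.
    """
    demux = demultiplex(pairs, sheet, policy=policy)
    rejections: list[Rejection] = [
        Rejection(p.id, "demultiplex", "unassigned") for p in demux["unassigned"]
    ]
    consensus: list[tuple[str, str, str]] = []
    n_assigned = 0
    for sample_id, sample_pairs in demux.items():
        if sample_id == "unassigned":
            continue
        n_assigned += len(sample_pairs)
        for p in sample_pairs:
            t = identify_and_trim(p, panel, max_mismatch, sample_id=sample_id)
            if isinstance(t, Rejection):
                rejections.append(t)
                continue
            t = length_filters(t, panel)
            if isinstance(t, Rejection):
                rejections.append(t)
                continue
            m = merge_pair(t, min_overlap, min_overlap_identity)
            if isinstance(m, Rejection):
                rejections.append(m)
                continue
            consensus.append((t.assay, sample_id, m))
    merged = dereplicate(consensus)
    tallies = Counter(f"{r.stage}:{r.reason}" for r in rejections)
    tallies["input_pairs"] = len(pairs)
    tallies["assigned"] = n_assigned
    tallies["merged_reads"] = len(consensus)
    for k, v in sorted(tallies.items()):
        log.info("pipeline tally %s = %d", k, v)
    return PipelineResult(
        merged=merged, tallies=dict(tallies), rejections=rejections, consensus=consensus
    )


# ---------------------------------------------------------------------------
# FASTQ / TSV IO


def read_paired_fastq(r1: str | Path, r2: str | Path, index: str | Path) -> list[ReadPair]:
    """Read mate-1, mate-2 and index FASTQ files (Phred+33) in lockstep."""
    out: list[ReadPair] = []
    it1 = SeqIO.parse(str(r1), "fastq")
    it2 = SeqIO.parse(str(r2), "fastq")
    iti = SeqIO.parse(str(index), "fastq")
    for a, b, i in zip(it1, it2, iti):
        out.append(
            ReadPair(
                id=a.id,
                r1_seq=str(a.seq).upper(),
                r1_qual=list(a.letter_annotations["phred_quality"]),
                r2_seq=str(b.seq).upper(),
                r2_qual=list(b.letter_annotations["phred_quality"]),
                index_seq=str(i.seq).upper(),
            )
        )
    return out


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """TSV with header: index, sample_id, site, region, timepoint."""
    expected = ["index", "sample_id", "site", "region", "timepoint"]
    entries: dict[str, SampleInfo] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip().lower() for h in header] != expected:
            raise ValueError(f"sample sheet must have header {expected!r}, got {header!r}")
        for line in fh:
            if not line.strip():
                continue
            idx, sid, site, region, tp = (c.strip() for c in line.rstrip("\n").split("\t"))
            if idx in entries:
                raise ValueError(f"duplicate index {idx} in sample sheet")
            entries[idx] = SampleInfo(sample_id=sid, site=site, region=region, timepoint=tp)
    return SampleSheet(entries=entries)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("index\tsample_id\tsite\tregion\ttimepoint\n")
        for idx, e in sheet.entries.items():
            fh.write(f"{idx}\t{e.sample_id}\t{e.site}\t{e.region}\t{e.timepoint}\n")


def write_merged(merged: list[MergedSequence], fasta: str | Path, counts_tsv: str | Path) -> None:
    """Dereplicated output: FASTA with count annotations plus a long-format
    sequence × sample count TSV."""
    with open(fasta, "w") as fh:
        for i, m in enumerate(merged):
            fh.write(f">uniq{i}|{m.assay}|total={m.total_reads}\n{m.seq}\n")
    with open(counts_tsv, "w") as fh:
        fh.write("seq_id\tassay\tsample_id\treads\tsequence\n")
        for i, m in enumerate(merged):
            for sample, c in m.counts.items():
                fh.write(f"uniq{i}\t{m.assay}\t{sample}\t{c}\t{m.seq}\n")


def write_rejection_log(rejections: list[Rejection], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstage\treason\n")
        for r in rejections:
            fh.write(f"{r.id}\t{r.stage}\t{r.reason}\n")
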