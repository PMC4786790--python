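"""In-silico PCR: predict amplicons of a degenerate primer pair.

Replaces a remote primer-search service with a local, fully specified
semantics: a primer binds a site iff it has at most ``max_mismatch_per_primer``
mismatches overall and its final ``three_prime_exact`` 3′ bases match exactly.
Degenerate (IUPAC) primer positions match any base in their set at no cost;
an ``N`` in the reference never matches.  Amplicons are every
forward/reverse hit combination in amplifiable orientation whose product
length falls within the pair's bounds; blow-ups are controlled by uniform
seeded sampling down to ``amplicon_cap`` (500 by default, mirroring the
500-random-amplifiable-sequences retrieval cap) and degenerate primers are
expanded to at most ``permutation_cap`` concrete sequences (25 by default).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .refdb import ReferenceDB
from .seq import IUPAC, degeneracy, encode_primer, encode_reference, is_iupac, revcomp
from .taxonomy import RANKS, TaxonLineage

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Primer:
    name: str
    seq: str

    def __post_init__(self) -> None:
        s = self.seq.upper().replace("U", "T")
        object.__setattr__(self, "seq", s)
        if len(s) < 10:
            raise ValueError(f"primer {self.name!r} shorter than 10 nt: {s!r}")
        if not is_iupac(s):
            raise ValueError(f"primer {self.name!r} has non-IUPAC characters: {s!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrimerPair:
    assay: str
    forward: Primer
    reverse: Primer
    min_product: int = 50
    max_product: int = 3000
    min_read_len: int = 50  # per-assay post-trim insert length floor

    def __post_init__(self) -> None:
        if not (0 < self.min_product <= self.max_product):
            raise ValueError(
                f"assay {self.assay!r}: need 0 < min_product <= max_product, "
                f"got [{self.min_product}, {self.max_product}]"
            )


@dataclass(frozen=True)
class PrimerHit:
    """Primer binding site, coordinates 0-based half-open on the + strand."""

    ref_id: str
    strand: str  # '+' or '-'
    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """Predicted product; insert excludes the primer-binding regions."""

    ref_id: str
    insert_seq: str
    product_start: int
    product_end: int
    fwd_mismatches: int
    rev_mismatches: int
    lineage: TaxonLineage = field(default_factory=TaxonLineage.empty)
    strand: str = "+"

    @property
    def product_length(self) -> int:
        return self.product_end - self.product_start


@dataclass(frozen=True)
class PcrConfig:
    max_mismatch_per_primer: int = 2
    three_prime_exact: int = 2
    permutation_cap: int = 25
    amplicon_cap: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_mismatch_per_primer", "three_prime_exact", "permutation_cap", "amplicon_cap", "seed"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def expand_degenerate(primer: Primer | str, cap: int = 25, seed: int = 0) -> list[str]:
    """Concrete sequences for a degenerate primer, at most ``cap`` of them.

    Below the cap all expansions are returned in lexicographic order;
    above it, ``cap`` distinct expansions are sampled uniformly without
    replacement using ``seed``.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    seq = primer.seq if isinstance(primer, Primer) else primer.upper()
    sets = [sorted(IUPAC[c]) for c in seq]
    total = degeneracy(seq)
    if total <= cap:
        return ["".join(p) for p in itertools.product(*sets)]
    rng = np.random.default_rng(seed)
    picks = rng.choice(total, size=cap, replace=False)
    out = []
    for idx in picks:
        chars = []
        for s in reversed(sets):
            idx, r = divmod(idx, len(s))
            chars.append(s[r])
        out.append("".join(reversed(chars)))
    return out


def _scan(ref_bits: np.ndarray, primer: str, max_mm: int, three_prime_exact: int) -> np.ndarray:
    """Offsets and mismatch counts of primer sites on the encoded + strand.

    Returns an (k, 2) int array of (offset, mismatches).  The 3′-exact
    constraint applies to the last ``three_prime_exact`` primer bases as laid
    on the array (caller orients the primer accordingly).
    """
    m = len(primer)
    n = ref_bits.shape[0]
    if n < m:
        return np.empty((0, 2), dtype=int)
    pbits = encode_primer(primer)
    windows = np.lib.stride_tricks.sliding_window_view(ref_bits, m)
    match = (windows & pbits) != 0
    mism = m - match.sum(axis=1)
    ok = mism <= max_mm
    if three_prime_exact > 0:
        k = min(three_prime_exact, m)
        ok &= match[:, -k:].all(axis=1)
    offs = np.nonzero(ok)[0]
    return np.stack([offs, mism[offs]], axis=1)


def match_primer(ref_seq: str, primer: Primer | str, config: PcrConfig = PcrConfig(), *, ref_id: str = "") -> list[PrimerHit]:
    """All binding sites of ``primer`` on both strands of ``ref_seq``.

    ``+`` hits are sites where the primer matches the + strand left-to-right;
    ``-`` hits are sites where its reverse complement matches the + strand
    (primer 3′ end at the leftmost coordinate).
    """
    pseq = primer.seq if isinstance(primer, Primer) else primer.upper()
    ref_bits = encode_reference(ref_seq.upper().replace("U", "T"))
    hits: list[PrimerHit] = []
    m = len(pseq)
    for offs, mm in _scan(ref_bits, pseq, config.max_mismatch_per_primer, config.three_prime_exact):
        hits.append(PrimerHit(ref_id, "+", int(offs), int(offs) + m, int(mm)))
    # minus strand: revcomp(primer) on + strand; its first bases are the primer 3' end,
    # so the exactness window moves to the front of the laid-down sequence.
    rc = revcomp(pseq)
    pbits = encode_primer(rc)
    n = ref_bits.shape[0]
    if n >= m:
        windows = np.lib.stride_tricks.sliding_window_view(ref_bits, m)
        match = (windows & pbits) != 0
        mism = m - match.sum(axis=1)
        ok = mism <= config.max_mismatch_per_primer
        if config.three_prime_exact > 0:
            k = min(config.three_prime_exact, m)
            ok &= match[:, :k].all(axis=1)
        for offs in np.nonzero(ok)[0]:
            hits.append(PrimerHit(ref_id, "-", int(offs), int(offs) + m, int(mism[offs])))
    return hits


def predict_amplicons(
    db: ReferenceDB,
    pair: PrimerPair,
    config: PcrConfig = PcrConfig(),
) -> list[Amplicon]:
    """Every amplifiable forward × reverse hit combination in the DB.

    Orientation: the forward primer extends rightwards from a + hit and the
    reverse primer extends leftwards from a − hit downstream (or the mirror
    image with forward on −).  Products outside the pair's length bounds are
    dropped; if more than ``config.amplicon_cap`` remain, that many are
    sampled uniformly without replacement with ``config.seed``.
    """
    if len(db) == 0:
        raise ValueError("reference database is empty")
    out: list[Amplicon] = []
    for rec in db.records:
        fhits = match_primer(rec.seq, pair.forward, config, ref_id=rec.id)
        rhits = match_primer(rec.seq, pair.reverse, config, ref_id=rec.id)
        for f in fhits:
            for r in rhits:
                if f.strand == "+" and r.strand == "-" and r.start >= f.end:
                    start, end = f.start, r.end
                    insert = rec.seq[f.end:r.start]
                    strand = "+"
                elif f.strand == "-" and r.strand == "+" and f.start >= r.end:
                    start, end = r.start, f.end
                    insert = revcomp(rec.seq[r.end:f.start])
                    strand = "-"
                else:
                    continue
                if pair.min_product <= end - start <= pair.max_product:
                    out.append(
                        Amplicon(
                            ref_id=rec.id,
                            insert_seq=insert,
                            product_start=start,
                            product_end=end,
                            fwd_mismatches=f.mismatches,
                            rev_mismatches=r.mismatches,
                            lineage=rec.lineage,
                            strand=strand,
                        )
                    )
    if not out:
        log.info("assay %s: no amplicons predicted", pair.assay)
    if len(out) > config.amplicon_cap:
        rng = np.random.default_rng(config.seed)
        keep = rng.choice(len(out), size=config.amplicon_cap, replace=False)
        out = [out[i] for i in sorted(keep)]
    return out


def pcr_summary(amplicons: list[Amplicon]) -> dict:
    """Per-rank taxon counts, insert length stats and amplicons per taxon."""
    lengths = [len(a.insert_seq) for a in amplicons]
    per_rank: dict[str, dict] = {}
    for rank in RANKS:
        counts: dict[str, int] = {}
        for a in amplicons:
            name = a.lineage[rank] or "unclassified"
            counts[name] = counts.get(name, 0) + 1
        named = {k: v for k, v in counts.items() if k != "unclassified"}
        per_rank[rank] = {"distinct_taxa": len(named), "amplicons_per_taxon": counts}
    return {
        "n_amplicons": len(amplicons),
        "length_min": min(lengths) if lengths else 0,
        "length_mean": float(np.mean(lengths)) if lengths else 0.0,
        "length_max": max(lengths) if lengths else 0,
        "per_rank": per_rank,
    }


def read_panel(path: str | Path) -> list[PrimerPair]:
    """Read a primer panel TSV: assay, forward, reverse, min_product,
    max_product, min_read_len (header required)."""
    expected = ["assay", "forward", "reverse", "min_product", "max_product", "min_read_len"]
    pairs: list[PrimerPair] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip().lower() for h in header] != expected:
            raise ValueError(f"panel file must have header {expected!r}, got {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(expected):
                raise ValueError(f"{path}:{lineno}: expected {len(expected)} columns")
            assay, fwd, rev, mn, mx, mrl = (c.strip() for c in cells)
            pairs.append(
                PrimerPair(
                    assay=assay,
                    forward=Primer(f"{assay}_F", fwd),
                    reverse=Primer(f"{assay}_R", rev),
                    min_product=int(mn),
                    max_product=int(mx),
                    min_read_len=int(mrl),
                )
            )
    if not pairs:
        raise ValueError(f"no assays in panel file {path}")
    names = [p.assay for p in pairs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate assay names in panel")
    return pairs


def write_panel(pairs: list[PrimerPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("assay\tforward\treverse\tmin_product\tmax_product\tmin_read_len\n")
        for p in pairs:
            fh.write(
                f"{p.assay}\t{p.forward.seq}\t{p.reverse.seq}\t"
                f"{p.min_product}\t{p.max_product}\t{p.min_read_len}\n"
            )


def write_amplicons_fasta(amplicons: list[Amplicon], path: str | Path) -> None:
    """FASTA out, lineage (semicolon-joined) in the header."""
    with open(path, "w") as fh:
        for i, a in enumerate(amplicons):
            lineage = ";".join(a.lineage.as_tuple())
            fh.write(f">amp{i}|{a.ref_id} {lineage}\n{a.insert_seq}\n")
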