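"""Pairwise and multiple alignment over short amplicons.

Amplicons from one assay are short homologous fragments, so a deterministic
center-star MSA under unit edit cost is adequate for counting nucleotide
differences; the underlying pairwise alignments are Levenshtein-optimal
(edlib).  Distances count differing columns, treating base-vs-gap as a
difference, skipping gap-vs-gap and any column containing N.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np


@dataclass
class Msa:
    """Gapped rows over {A,C,G,T,N,-}; ungapping row i reproduces input i."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("MSA rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class DistanceMatrix:
    """Symmetric matrix of nucleotide differences, zero diagonal."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0) or np.any(self.d < 0):
            raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")


def edit_distance(a: str, b: str) -> int:
    """Unit-cost global (Levenshtein) distance."""
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _pairwise_rows(center: str, other: str) -> tuple[str, str]:
    """Optimal unit-cost global alignment of ``other`` against ``center``."""
    res = edlib.align(other, center, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, other, center)
    return nice["target_aligned"], nice["query_aligned"]


def center_star_align(seqs: list[str], ids: list[str] | None = None) -> Msa:
    """Center-star MSA: the sequence minimising total pairwise edit distance
    (ties → lowest input index) anchors pairwise alignments, with gaps merged
    by the "once a gap, always a gap" rule."""
    if ids is None:
        ids = [f"s{i}" for i in range(len(seqs))]
    if len(seqs) == 0:
        raise ValueError("cannot align an empty sequence set")
    seqs = [s.upper() for s in seqs]
    if len(seqs) == 1:
        return Msa(ids=list(ids), rows=[seqs[0]])

    n = len(seqs)
    totals = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = edit_distance(seqs[i], seqs[j])
            totals[i] += d
            totals[j] += d
    c = int(np.argmin(totals))  # argmin takes the first minimum → lowest index on ties
    center = seqs[c]

    # Pairwise-align everyone to the center, then merge: the master alignment
    # inserts before each center position the maximum number of gap columns
    # any pairwise alignment needs there.
    aligned: list[tuple[str, str] | None] = [None] * n
    ins_needed = np.zeros(len(center) + 1, dtype=int)
    for i in range(n):
        if i == c:
            continue
        crow, orow = _pairwise_rows(center, seqs[i])
        aligned[i] = (crow, orow)
        pos = 0
        run = 0
        for ch in crow:
            if ch == "-":
                run += 1
            else:
                ins_needed[pos] = max(ins_needed[pos], run)
                run = 0
                pos += 1
        ins_needed[len(center)] = max(ins_needed[len(center)], run)

    # Gap columns for a center position are placed *before* that position;
    # pairwise insertions are left-padded with '-' to the master width.
    def project(crow: str, orow: str) -> str:
        out: list[str] = []
        pos = 0
        run: list[str] = []
        for cch, och in zip(crow, orow):
            if cch == "-":
                run.append(och)
            else:
                out.append("-" * (ins_needed[pos] - len(run)) + "".join(run))
                run = []
                out.append(och)
                pos += 1
        out.append("-" * (ins_needed[len(center)] - len(run)) + "".join(run))
        return "".join(out)

    rows: list[str] = [""] * n
    center_row_parts: list[str] = []
    for pos, ch in enumerate(center):
        center_row_parts.append("-" * ins_needed[pos] + ch)
    center_row_parts.append("-" * ins_needed[len(center)])
    rows[c] = "".join(center_row_parts)
    for i in range(n):
        if i == c:
            continue
        crow, orow = aligned[i]
        rows[i] = project(crow, orow)
    return Msa(ids=list(ids), rows=rows)


def msa_distance_matrix(msa: Msa) -> DistanceMatrix:
    """Nucleotide-difference matrix over MSA rows.

    A column counts as a difference when the two rows differ there, including
    base-vs-gap; gap-vs-gap columns and columns where either row has N are
    skipped.
    """
    arr = np.array([list(r) for r in msa.rows])
    n = len(msa.rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arr[i], arr[j]
            usable = ~(((a == "-") & (b == "-")) | (a == "N") | (b == "N"))
            d[i, j] = d[j, i] = np.count_nonzero((a != b) & usable)
    return DistanceMatrix(ids=list(msa.ids), d=d)


def glocal_identity(query: str, ref_seq: str) -> float:
    """Identity of ``query`` aligned end-to-end inside ``ref_seq``.

    The query is globally aligned with free end-gaps on the reference
    (unit cost); identity = matched positions / query length, where N never
    counts as a match.
    """
    if not query or not ref_seq:
        raise ValueError("query and reference must be non-empty")
    query = query.upper()
    ref_seq = ref_seq.upper()
    res = edlib.align(query, ref_seq, mode="HW", task="path")
    nice = edlib.getNiceAlignment(res, query, ref_seq)
    matches = 0
    for q, t in zip(nice["query_aligned"], nice["target_aligned"]):
        if q == t and q not in ("-", "N"):
            matches += 1
    return matches / len(query)
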