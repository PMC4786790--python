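"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from amplitree.align import DistanceMatrix
from amplitree.refdb import ReferenceDB, RefSequence, build_db
from amplitree.seq import IUPAC, revcomp
from amplitree.taxonomy import TaxonLineage


# ---------------------------------------------------------------------------
# small taxonomy-annotated reference DB: 4 thrushes, 3 other birds, 2 mammals,
# 1 fish — enough structure to exercise subsetting and rank indexing


def _lineage(cls, order, family, genus, species):
    return TaxonLineage(
        {
            "superkingdom": "Eukaryota",
            "phylum": "Chordata",
            "class": cls,
            "order": order,
            "family": family,
            "genus": genus,
            "species": species,
        }
    )


@pytest.fixture(scope="session")
def bird_db() -> ReferenceDB:
    rng = np.random.default_rng(42)
    specs = [
        ("Aves", "Passeriformes", "Turdidae", "Turdus", "Turdus migratorius"),
        ("Aves", "Passeriformes", "Turdidae", "Turdus", "Turdus merula"),
        ("Aves", "Passeriformes", "Turdidae", "Turdus", "Turdus philomelos"),
        ("Aves", "Passeriformes", "Turdidae", "Catharus", "Catharus guttatus"),
        ("Aves", "Passeriformes", "Passeridae", "Passer", "Passer domesticus"),
        ("Aves", "Galliformes", "Phasianidae", "Gallus", "Gallus gallus"),
        ("Aves", "Anseriformes", "Anatidae", "Cygnus", "Cygnus olor"),
        ("Mammalia", "Rodentia", "Castoridae", "Castor", "Castor canadensis"),
        ("Mammalia", "Rodentia", "Cricetidae", "Ondatra", "Ondatra zibethicus"),
        ("Actinopterygii", "Cypriniformes", "Cyprinidae", "Cyprinus", "Cyprinus carpio"),
    ]
    records, lineages = [], {}
    for i, spec in enumerate(specs):
        rid = f"acc{i:03d}"
        seq = "".join(rng.choice(list("ACGT"), size=300))
        records.append(RefSequence(id=rid, description=spec[-1], seq=seq))
        lineages[rid] = _lineage(*spec)
    return build_db(records, lineages)


# ---------------------------------------------------------------------------
# oracles


def brute_force_primer_hits(ref: str, primer: str, max_mm: int, three_prime_exact: int):
    """All-offsets sliding comparison, independent of the vectorised path.

    Returns a set of (strand, start, mismatches); reference N never matches.
    """
    hits = set()
    m = len(primer)

    def mismatch_vector(laid: str, off: int) -> list[bool]:
        out = []
        for k, pc in enumerate(laid):
            rc = ref[off + k]
            out.append(rc == "N" or rc not in IUPAC[pc])
        return out

    for off in range(len(ref) - m + 1):
        mmv = mismatch_vector(primer, off)
        if sum(mmv) <= max_mm and not any(mmv[m - three_prime_exact:]):
            hits.add(("+", off, sum(mmv)))
        mmv = mismatch_vector(revcomp(primer), off)
        if sum(mmv) <= max_mm and not any(mmv[:three_prime_exact]):
            hits.add(("-", off, sum(mmv)))
    return hits


def random_additive_matrix(rng: np.random.Generator, ntips: int) -> DistanceMatrix:
    """Path-length distances of a random unrooted binary tree with positive
    integer-ish branch lengths (oracle for NJ exact recovery)."""
    import networkx as nx

    G = nx.Graph()
    for t in range(3):
        G.add_edge(f"t{t}", "x0", weight=float(rng.integers(1, 20)))
    nxt = 1
    for k in range(3, ntips):
        edges = list(G.edges(data=True))
        u, v, d = edges[rng.integers(len(edges))]
        G.remove_edge(u, v)
        mid = f"x{nxt}"
        nxt += 1
        a = float(rng.uniform(0.2, 0.8)) * d["weight"]
        G.add_edge(u, mid, weight=a)
        G.add_edge(mid, v, weight=d["weight"] - a)
        G.add_edge(f"t{k}", mid, weight=float(rng.integers(1, 20)))
    tips = [f"t{i}" for i in range(ntips)]
    sp = dict(nx.all_pairs_dijkstra_path_length(G))
    d = np.array([[sp[a][b] for b in tips] for a in tips])
    d = (d + d.T) / 2  # remove float dust from path-summation order
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tips, d)


def fisher_2xk_enumeration(table: np.ndarray) -> float:
    """Exact two-sided Fisher p for a 2×k table by hypergeometric enumeration."""
    from math import comb

    table = np.asarray(table, dtype=int)
    r1 = table[0].sum()
    cols = table.sum(axis=0)
    N = table.sum()

    def prob(row):
        num = 1
        for a, c in zip(row, cols):
            num *= comb(int(c), int(a))
        return num / comb(int(N), int(r1))

    def rows(remaining_cols, remaining_r1):
        if len(remaining_cols) == 1:
            if 0 <= remaining_r1 <= remaining_cols[0]:
                yield (remaining_r1,)
            return
        for a in range(0, min(remaining_cols[0], remaining_r1) + 1):
            for rest in rows(remaining_cols[1:], remaining_r1 - a):
                yield (a,) + rest

    p_obs = prob(table[0])
    total = 0.0
    for row in rows(list(cols), r1):
        p = prob(row)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)
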