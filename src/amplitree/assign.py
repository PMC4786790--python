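"""Species assignment and presence/absence statistics.

Dereplicated consensus sequences are filtered (sequences seen in fewer than
10 reads total are treated as sequencing errors and dropped), assigned to
species by exhaustive best-hit glocal identity against the local reference
database (matches must exceed 90% identity over the entire query; all tied
best species are retained), summed into a sample × species read-count
matrix, thresholded into presence calls at 10 reads per sample, and tested
for association with sample groupings by Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .align import glocal_identity
from .readproc import MergedSequence, SampleSheet
from .refdb import ReferenceDB

log = logging.getLogger(__name__)


@dataclass
class Assignment:
    sequence: MergedSequence
    best_identity: float
    species: frozenset[str]
    status: str  # "assigned" | "unassigned"


@dataclass
class PresenceMatrix:
    """Sample × species read counts with thresholded presence calls."""

    counts: pd.DataFrame  # rows: samples, cols: species
    min_reads_per_sample: int
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts >= self.min_reads_per_sample


def filter_low_count(
    merged: list[MergedSequence], min_total: int = 10
) -> tuple[list[MergedSequence], list[MergedSequence]]:
    """Split unique sequences into (kept, removed) by total read count.

    A sequence is kept iff its reads summed across all samples reach
    ``min_total`` (default 10); rare sequences overwhelmingly arise from
    sequencing error.  The removed read fraction is logged.
    """
    kept = [m for m in merged if m.total_reads >= min_total]
    removed = [m for m in merged if m.total_reads < min_total]
    total = sum(m.total_reads for m in merged)
    lost = sum(m.total_reads for m in removed)
    if total:
        log.info(
            "low-count filter: removed %d/%d unique sequences (%.2f%% of reads)",
            len(removed), len(merged), 100 * lost / total,
        )
    return kept, removed


def assign_best_hit(
    merged: MergedSequence, db: ReferenceDB, identity_threshold: float = 0.90
) -> Assignment:
    """Best-hit species assignment by exhaustive glocal identity.

    The best identity over all references decides: strictly above the
    threshold the sequence receives the species of *all* references attaining
    the maximum (multi-species ties keep every name), otherwise it stays
    unassigned.
    """
    if len(db) == 0:
        raise ValueError("reference database is empty")
    best = -1.0
    best_species: set[str] = set()
    for rec in db.records:
        ident = glocal_identity(merged.seq, rec.seq)
        if ident > best + 1e-12:
            best = ident
            best_species = {rec.lineage.species} if rec.lineage.species else set()
        elif abs(ident - best) <= 1e-12 and rec.lineage.species:
            best_species.add(rec.lineage.species)
    if best > identity_threshold and best_species:
        return Assignment(merged, best, frozenset(best_species), "assigned")
    return Assignment(merged, max(best, 0.0), frozenset(), "unassigned")


def assign_all(
    merged: list[MergedSequence], db: ReferenceDB, identity_threshold: float = 0.90
) -> list[Assignment]:
    return [assign_best_hit(m, db, identity_threshold) for m in merged]


def presence_matrix(
    assignments: list[Assignment],
    sheet: SampleSheet | None = None,
    min_reads_per_sample: int = 10,
) -> PresenceMatrix:
    """Sample × species read counts with presence thresholding.

    Counts for a species sum over every sequence whose species set contains
    it, so a multi-species tie contributes its reads to each tied species
    (a deliberate over-count: the reads support each candidate equally).
    """
    cells: dict[tuple[str, str], int] = {}
    samples: set[str] = set()
    species: set[str] = set()
    for a in assignments:
        if a.status != "assigned":
            continue
        for sp in a.species:
            species.add(sp)
            for sample, c in a.sequence.counts.items():
                samples.add(sample)
                cells[(sample, sp)] = cells.get((sample, sp), 0) + c
    if sheet is not None:
        samples.update(sheet.samples)
    counts = pd.DataFrame(
        0, index=sorted(samples), columns=sorted(species), dtype=int
    )
    for (sample, sp), c in cells.items():
        counts.loc[sample, sp] = c
    meta = pd.DataFrame()
    if sheet is not None:
        meta = pd.DataFrame(
            [
                {
                    "sample_id": e.sample_id,
                    "site": e.site,
                    "region": e.region,
                    "timepoint": e.timepoint,
                }
                for e in sheet.entries.values()
            ]
        ).set_index("sample_id")
        meta = meta.reindex(counts.index)
    return PresenceMatrix(counts=counts, min_reads_per_sample=min_reads_per_sample, metadata=meta)


def flag_control_species(
    pm: PresenceMatrix, control_samples: list[str]
) -> list[str]:
    """Species present (above threshold) in any control sample.

    Controls monitor contamination; flagged species are reported, not
    removed — sequences in real samples may still be genuine.
    """
    present = pm.presence
    flagged: set[str] = set()
    for s in control_samples:
        if s in present.index:
            flagged.update(present.columns[present.loc[s]])
    return sorted(flagged)


def expected_read_count(abundance: float, mean_depth: float) -> int:
    """Expected reads for a template at a given abundance fraction, e.g. a
    species at 1% of the DNA in an amplification averaging 14,211 reads per
    sample is expected in ~142 reads — far above a 10-read detection floor."""
    if not 0 <= abundance <= 1:
        raise ValueError("abundance must be within [0, 1]")
    return int(np.floor(abundance * mean_depth + 0.5))


def fisher_association(
    pm: PresenceMatrix, species: str, grouping: str
) -> tuple[float, pd.DataFrame]:
    """Two-sided Fisher's exact test of one species' presence against a
    sample grouping (``region`` or ``timepoint``; 2 or 3 groups).

    Returns (p, contingency table).  A table with an empty margin carries no
    information: p = 1 with a warning.
    """
    if pm.metadata.empty or grouping not in pm.metadata.columns:
        raise ValueError(f"no metadata column {grouping!r} for grouping")
    if species not in pm.counts.columns:
        raise ValueError(f"species {species!r} not in matrix")
    present = pm.presence[species]
    groups = pm.metadata[grouping]
    levels = sorted(g for g in groups.dropna().unique() if g != "")
    if not 2 <= len(levels) <= 3:
        raise ValueError(f"grouping {grouping!r} has {len(levels)} levels; need 2 or 3")
    table = pd.DataFrame(
        [
            [int(((groups == g) & present).sum()) for g in levels],
            [int(((groups == g) & ~present).sum()) for g in levels],
        ],
        index=["present", "absent"],
        columns=levels,
    )
    arr = table.to_numpy()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        log.warning("fisher_association(%s, %s): zero margin, p = 1", species, grouping)
        return 1.0, table
    if arr.shape[1] == 2:
        p = float(stats.fisher_exact(arr).pvalue)
    else:
        p = _exact_fisher_2xk(arr)
    return min(p, 1.0), table


def _exact_fisher_2xk(arr: np.ndarray) -> float:
    """Exact two-sided p for a 2×k table: enumerate all tables with the
    observed margins and sum the multivariate-hypergeometric probabilities
    not exceeding that of the observed table."""
    from itertools import product
    from math import comb

    cols = arr.sum(axis=0)
    r1 = int(arr[0].sum())
    denom = comb(int(cols.sum()), r1)

    def prob(top: tuple[int, ...]) -> float:
        num = 1
        for a, c in zip(top, cols):
            num *= comb(int(c), a)
        return num / denom

    p_obs = prob(tuple(int(x) for x in arr[0]))
    total = 0.0
    ranges = [range(int(c) + 1) for c in cols[:-1]]
    for head in product(*ranges):
        last = r1 - sum(head)
        if 0 <= last <= cols[-1]:
            p = prob(head + (last,))
            if p <= p_obs * (1 + 1e-9):
                total += p
    return total


def association_table(pm: PresenceMatrix, grouping: str) -> pd.DataFrame:
    """Fisher p-value for every species against one grouping (raw p-values,
    no multiplicity correction)."""
    rows = []
    for sp in pm.counts.columns:
        p, _ = fisher_association(pm, sp, grouping)
        rows.append({"species": sp, "grouping": grouping, "p_value": p})
    return pd.DataFrame(rows)


def write_assignments(assignments: list[Assignment], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tassay\ttotal_reads\tbest_identity\tstatus\tspecies\n")
        for a in assignments:
            fh.write(
                f"{a.sequence.seq}\t{a.sequence.assay}\t{a.sequence.total_reads}\t"
                f"{a.best_identity:.4f}\t{a.status}\t{';'.join(sorted(a.species))}\n"
            )
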