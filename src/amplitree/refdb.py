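"""Taxonomy-annotated reference marker database.

A local FASTA + TSV stand-in for a remote nucleotide database: marker
sequences with a ranked lineage per record, indexed by taxon name at every
rank so primer panels can be evaluated within an arbitrary taxon (e.g. only
Turdidae) without re-reading anything.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .seq import validate_reference
from .taxonomy import RANKS, TaxonLineage, check_rank

log = logging.getLogger(__name__)


@dataclass
class RefSequence:
    """One reference marker sequence with its lineage."""

    id: str
    description: str
    seq: str
    lineage: TaxonLineage = field(default_factory=TaxonLineage.empty)


@dataclass
class ReferenceDB:
    """Records plus a per-rank taxon-name → record-id index."""

    records: list[RefSequence]
    index: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = _build_index(self.records)
        self._by_id = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, ref_id: str) -> RefSequence:
        return self._by_id[ref_id]

    def ids_at(self, rank: str, taxon: str) -> list[str]:
        """Record ids whose lineage carries ``taxon`` at ``rank``."""
        check_rank(rank)
        return list(self.index.get(rank, {}).get(taxon, []))


def _build_index(records: list[RefSequence]) -> dict[str, dict[str, list[str]]]:
    index: dict[str, dict[str, list[str]]] = {r: {} for r in RANKS}
    for rec in records:
        for rank in RANKS:
            name = rec.lineage[rank]
            if name:
                index[rank].setdefault(name, []).append(rec.id)
    return index


def read_reference_fasta(path: str | Path) -> list[RefSequence]:
    """Read reference sequences (lineages unset).

    Sequences are uppercased and U→T normalised; the record id is the first
    whitespace-delimited header token.  Duplicate ids, an empty file and
    non-IUPAC characters are hard errors.
    """
    path = Path(path)
    records: list[RefSequence] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate sequence id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = validate_reference(str(entry.seq), where=entry.id)
        if not seq:
            raise ValueError(f"empty sequence for id {entry.id!r} in {path}")
        desc = entry.description
        if desc.startswith(entry.id):
            desc = desc[len(entry.id):].strip()
        records.append(RefSequence(id=entry.id, description=desc, seq=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_taxonomy_table(path: str | Path) -> dict[str, TaxonLineage]:
    """Read the id → lineage table (TSV, header ``id`` + the 7 rank columns)."""
    path = Path(path)
    expected = ["id", *RANKS]
    lineages: dict[str, TaxonLineage] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip().lower() for h in header] != expected:
            raise ValueError(
                f"taxonomy table {path} must have header {expected!r}, got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(expected):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(expected)} columns, got {len(cells)}"
                )
            rid = cells[0].strip()
            if rid in lineages:
                raise ValueError(f"{path}:{lineno}: duplicate id {rid!r}")
            lineages[rid] = TaxonLineage(dict(zip(RANKS, (c.strip() for c in cells[1:]))))
    return lineages


def build_db(
    records: list[RefSequence],
    lineages: dict[str, TaxonLineage],
    *,
    strict: bool = True,
) -> ReferenceDB:
    """Attach lineages to records and build the rank index.

    With ``strict`` (default) every record must have a lineage entry; with
    ``strict=False`` missing lineages become empty and are logged.
    """
    missing = [r.id for r in records if r.id not in lineages]
    if missing and strict:
        raise ValueError(f"records missing a lineage entry: {missing}")
    for rid in missing:
        log.warning("no lineage for record %s; storing empty lineage", rid)
    out = [
        RefSequence(r.id, r.description, r.seq, lineages.get(r.id, TaxonLineage.empty()))
        for r in records
    ]
    return ReferenceDB(records=out)


def load_db(fasta: str | Path, taxonomy: str | Path, *, strict: bool = True) -> ReferenceDB:
    """Convenience: read FASTA + taxonomy TSV and build the DB."""
    return build_db(read_reference_fasta(fasta), read_taxonomy_table(taxonomy), strict=strict)


def subset_by_taxon(db: ReferenceDB, rank: str, taxon: str) -> ReferenceDB:
    """DB restricted to records carrying ``taxon`` at ``rank`` (may be empty)."""
    check_rank(rank)
    keep = set(db.index.get(rank, {}).get(taxon, []))
    records = [r for r in db.records if r.id in keep]
    if not records:
        log.info("subset %s=%s matched no records", rank, taxon)
    return ReferenceDB(records=records)


def write_db(db: ReferenceDB, fasta: str | Path, taxonomy: str | Path) -> None:
    """Write the DB back out as FASTA + taxonomy TSV (round-trip safe)."""
    with open(fasta, "w") as fh:
        for r in db.records:
            header = f">{r.id} {r.description}".rstrip()
            fh.write(f"{header}\n{r.seq}\n")
    with open(taxonomy, "w") as fh:
        fh.write("\t".join(["id", *RANKS]) + "\n")
        for r in db.records:
            fh.write("\t".join([r.id, *r.lineage.as_tuple()]) + "\n")
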