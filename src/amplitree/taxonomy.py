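"""Ranked taxonomic lineages.

Every reference sequence carries a lineage over a fixed seven-rank ladder
(superkingdom → species).  Lineages are propagated unchanged to predicted
amplicons, tree tips and species assignments, so a single flat representation
is enough — the full taxonomy DAG is never needed for labelling trees or
matching at standard ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Fixed rank ladder, most to least inclusive.
RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


@dataclass(frozen=True)
class TaxonLineage:
    """Ordered rank → taxon-name mapping over the fixed ladder.

    Unknown ranks are explicitly empty strings.  ``incomplete`` marks records
    where a species name is present without a genus (tolerated but flagged).
    """

    ranks: dict[str, str] = field(default_factory=dict)
    incomplete: bool = False

    def __post_init__(self) -> None:
        full = {r: str(self.ranks.get(r, "") or "") for r in RANKS}
        object.__setattr__(self, "ranks", full)
        if full["species"] and not full["genus"] and not self.incomplete:
            object.__setattr__(self, "incomplete", True)

    def __getitem__(self, rank: str) -> str:
        if rank not in self.ranks:
            raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.ranks[rank]

    @property
    def species(self) -> str:
        return self.ranks["species"]

    def name_at(self, rank: str) -> str:
        """Taxon name at ``rank`` or '' if unknown."""
        return self[rank]

    def is_empty(self) -> bool:
        return not any(self.ranks.values())

    def as_tuple(self) -> tuple[str, ...]:
        return tuple(self.ranks[r] for r in RANKS)

    @classmethod
    def empty(cls) -> "TaxonLineage":
        return cls({})

    @classmethod
    def from_names(cls, *names: str) -> "TaxonLineage":
        """Build from up to seven names in ladder order."""
        if len(names) > len(RANKS):
            raise ValueError(f"at most {len(RANKS)} rank names, got {len(names)}")
        return cls(dict(zip(RANKS, names)))


def check_rank(rank: str) -> str:
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    return rank
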