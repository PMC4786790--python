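"""Neighbor-Joining trees with taxonomic tip annotation.

Trees here are a screening device for primer panels, not species phylogenies:
branch lengths are in plain nucleotide differences so short branches flag
poor discriminating power (risk of misassignment from sequencing error) and
off-target taxa are visible from tip labels.  The classic agglomerative
algorithm of Saitou & Nei is implemented directly, with deterministic
tie-breaking and negative branch estimates clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import DistanceMatrix, center_star_align, msa_distance_matrix
from .pcr import Amplicon
from .taxonomy import RANKS, TaxonLineage, check_rank

#: Number of distinct color indices cycled over taxa when annotating.
PALETTE_SIZE = 12


@dataclass
class TreeNode:
    name: str
    length: float = 0.0  # branch length to parent
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, *, precision: int = 6) -> str:
        return self._newick_inner(precision) + ";"

    def _newick_inner(self, precision: int, top: bool = True) -> str:
        if self.is_leaf():
            body = self.name
        else:
            body = "(" + ",".join(c._newick_inner(precision, top=False) for c in self.children) + ")"
        if top:
            return body
        return f"{body}:{self.length:.{precision}f}"


@dataclass
class PhyloTree:
    """Unrooted binary tree serialised with a trifurcating root node."""

    root: TreeNode
    tip_ids: list[str]

    def tip_distances(self) -> DistanceMatrix:
        """Patristic (path-length) distances between tips."""
        idx = {t: i for i, t in enumerate(self.tip_ids)}
        n = len(self.tip_ids)
        d = np.zeros((n, n))

        def walk(node: TreeNode, dists: dict[str, float]) -> dict[str, float]:
            if node.is_leaf():
                return {node.name: 0.0}
            below: dict[str, float] = {}
            groups = []
            for c in node.children:
                sub = {k: v + c.length for k, v in walk(c, dists).items()}
                groups.append(sub)
                below.update(sub)
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for ta, da in groups[a].items():
                        for tb, db in groups[b].items():
                            d[idx[ta], idx[tb]] = d[idx[tb], idx[ta]] = da + db
            return below

        walk(self.root, {})
        return DistanceMatrix(ids=list(self.tip_ids), d=d)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei Neighbor-Joining under the standard Q criterion.

    Agglomeration ties are broken by the lexicographically smallest pair of
    node labels; negative branch-length estimates are clamped to 0.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("Neighbor-Joining needs at least 3 taxa")
    if len(set(dm.ids)) != n:
        raise ValueError("duplicate ids in distance matrix")

    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.ids]
    labels: list[str] = list(dm.ids)
    d = dm.d.astype(float).copy()
    next_internal = 0

    while len(nodes) > 2:
        m = len(nodes)
        r = d.sum(axis=1)
        best: tuple[float, str, str, int, int] | None = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                lab = tuple(sorted((labels[i], labels[j])))
                key = (q, lab[0], lab[1])
                if best is None or key < best[:3]:
                    best = (q, lab[0], lab[1], i, j)
        _, _, _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(li, 0.0)
        child_j.length = max(lj, 0.0)
        parent = TreeNode(name=f"_nj{next_internal}", children=[child_i, child_j])
        next_internal += 1

        newd = np.zeros((m - 1, m - 1))
        keep = [k for k in range(m) if k not in (i, j)]
        for a, ka in enumerate(keep):
            for b, kb in enumerate(keep):
                newd[a, b] = d[ka, kb]
        for a, ka in enumerate(keep):
            du = (d[i, ka] + d[j, ka] - d[i, j]) / 2
            newd[a, m - 2] = newd[m - 2, a] = du
        d = newd
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [parent.name]

    a, b = nodes
    # attach the remaining node to the other across the final edge
    if a.is_leaf() and not b.is_leaf():
        a, b = b, a
    b.length = max(d[0, 1], 0.0)
    a.children.append(b)
    a.length = 0.0
    return PhyloTree(root=a, tip_ids=list(dm.ids))


def annotate_and_write(
    tree: PhyloTree,
    lineages: dict[str, TaxonLineage],
    rank: str,
) -> tuple[str, pd.DataFrame]:
    """Newick string plus a tip annotation table at the chosen rank.

    The table maps tip_id → taxon-at-rank → color index; taxa are sorted and
    color indices cycled over a fixed palette so the assignment is stable.
    Tips whose lineage is empty at the rank are labelled "unclassified".
    """
    check_rank(rank)
    missing = [t for t in tree.tip_ids if t not in lineages]
    if missing:
        raise ValueError(f"tips without a lineage: {missing}")
    taxa = {t: (lineages[t][rank] or "unclassified") for t in tree.tip_ids}
    order = sorted(set(taxa.values()))
    color = {name: i % PALETTE_SIZE for i, name in enumerate(order)}
    table = pd.DataFrame(
        {
            "tip_id": tree.tip_ids,
            "taxon": [taxa[t] for t in tree.tip_ids],
            "color_index": [color[taxa[t]] for t in tree.tip_ids],
        }
    )
    return tree.root.newick(), table


def resolution_summary(amplicons: list[Amplicon]) -> dict:
    """Per-rank resolution metrics for a predicted amplicon set.

    For each rank: number of distinct taxa amplified, mean pairwise
    nucleotide difference within taxa (over all within-taxon pairs), and the
    mean number of distinct taxa at that rank exhibiting each unique insert
    sequence.  At rank species the last metric is the species-per-unique-
    sequence statistic used to judge a marker's identification power (a value
    near 1 means most amplicon sequences pin down a single species).
    """
    out: dict = {"n_amplicons": len(amplicons), "per_rank": {}}
    if not amplicons:
        for rank in RANKS:
            out["per_rank"][rank] = {
                "distinct_taxa": 0,
                "mean_within_taxon_pairwise_diff": float("nan"),
                "mean_taxa_per_unique_sequence": float("nan"),
            }
        out["mean_species_per_unique_sequence"] = float("nan")
        return out

    ids = [f"a{i}" for i in range(len(amplicons))]
    msa = center_star_align([a.insert_seq for a in amplicons], ids)
    dm = msa_distance_matrix(msa)

    by_seq: dict[str, list[Amplicon]] = {}
    for a in amplicons:
        by_seq.setdefault(a.insert_seq, []).append(a)

    for rank in RANKS:
        names = [a.lineage[rank] for a in amplicons]
        distinct = {n for n in names if n}
        diffs: list[float] = []
        for taxon in distinct:
            members = [i for i, n in enumerate(names) if n == taxon]
            for x in range(len(members)):
                for y in range(x + 1, len(members)):
                    diffs.append(dm.d[members[x], members[y]])
        per_seq = [
            len({a.lineage[rank] for a in group if a.lineage[rank]})
            for group in by_seq.values()
        ]
        per_seq = [c for c in per_seq if c > 0]
        out["per_rank"][rank] = {
            "distinct_taxa": len(distinct),
            "mean_within_taxon_pairwise_diff": float(np.mean(diffs)) if diffs else float("nan"),
            "mean_taxa_per_unique_sequence": float(np.mean(per_seq)) if per_seq else float("nan"),
        }
    out["mean_species_per_unique_sequence"] = out["per_rank"]["species"][
        "mean_taxa_per_unique_sequence"
    ]
    return out


def plot_tree(tree: PhyloTree, annotation: pd.DataFrame, path: str) -> None:
    """Minimal static rendering: tips on a line, colored by taxon."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dm = tree.tip_distances()
    colors = dict(zip(annotation["tip_id"], annotation["color_index"]))
    taxa = dict(zip(annotation["tip_id"], annotation["taxon"]))
    # order tips by a root-to-tip traversal for a readable layout
    order = [leaf.name for leaf in tree.root.leaves()]
    root_dist = {}

    def walk(node: TreeNode, acc: float) -> None:
        if node.is_leaf():
            root_dist[node.name] = acc
        for c in node.children:
            walk(c, acc + c.length)

    walk(tree.root, 0.0)
    fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(order))))
    cmap = plt.get_cmap("tab20")
    for y, tip in enumerate(order):
        x = root_dist[tip]
        ax.plot([0, x], [y, y], color="0.7", lw=0.8, zorder=1)
        ax.scatter([x], [y], color=cmap(colors[tip] % 20), zorder=2)
        ax.text(x, y, f" {tip} [{taxa[tip]}]", va="center", fontsize=7)
    ax.set_yticks([])
    ax.set_xlabel("nucleotide differences from root")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
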