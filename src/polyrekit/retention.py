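"""Retention-group classification: build the Ks-filtered paralog graph,
label one/two/three-copy groups, anchor them to outgroup orthologs, and
intersect groups with external gene lists.

Connected components of the retained-pair graph define the groups:
size 1 -> one-copy, 2 -> two-copy, 3 -> three-copy; components larger
than 3 (tandem arrays or older duplicates leaking through the Ks filter)
are flagged ``oversized`` and excluded from class counts rather than
force-split.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = [
    "RetentionGroup",
    "build_retention_graph",
    "classify_retention_groups",
    "class_counts",
    "anchor_ortholog_groups",
    "intersect_groups_with_gene_list",
]


@dataclass
class RetentionGroup:
    group_id: int
    species: str
    members: tuple[str, ...]
    copy_class: int | None  # 1, 2, 3, or None when oversized
    anchor_ortholog: str | None = None

    @property
    def oversized(self) -> bool:
        return self.copy_class is None


def build_retention_graph(retained_pairs, all_genes=None) -> nx.Graph:
    """Undirected simple graph over genes; edges are retained WGT-era
    paralog pairs; ``all_genes`` (optional iterable) adds isolated nodes
    for genes with no retained paralog."""
    g = nx.Graph()
    if all_genes is not None:
        g.add_nodes_from(all_genes)
    for a, b in retained_pairs:
        if a == b:
            raise ValueError(f"self-loop pair for gene {a!r}")
        g.add_edge(a, b)
    return g


def classify_retention_groups(graph: nx.Graph,
                              species: str = "?") -> list[RetentionGroup]:
    """Connected components as retention groups, ordered by their
    smallest member for determinism."""
    groups = []
    comps = sorted((sorted(c) for c in nx.connected_components(graph)),
                   key=lambda c: c[0])
    for i, comp in enumerate(comps, start=1):
        size = len(comp)
        groups.append(RetentionGroup(
            group_id=i, species=species, members=tuple(comp),
            copy_class=size if size <= 3 else None))
    return groups


def class_counts(groups) -> dict:
    """Counts of groups by copy class; oversized components counted
    separately under ``'oversized'``."""
    out = {1: 0, 2: 0, 3: 0, "oversized": 0}
    for g in groups:
        out[g.copy_class if g.copy_class is not None else "oversized"] += 1
    return out


def groups_to_frame(groups) -> pd.DataFrame:
    return pd.DataFrame(
        [(g.group_id, g.species,
          g.copy_class if g.copy_class is not None else "oversized",
          ";".join(g.members), g.anchor_ortholog or "")
         for g in groups],
        columns=["group_id", "species", "copy_class", "members",
                 "anchor_ortholog"])


def anchor_ortholog_groups(groups_a, groups_b, orthologs_to_outgroup,
                           pattern: tuple[int, int] = (3, 3)
                           ) -> pd.DataFrame:
    """Join outgroup genes to their retention groups in both ingroup
    species and filter to a copy-class pattern.

    ``orthologs_to_outgroup`` maps outgroup gene -> {species_label:
    [ingroup genes]} with species labels 'a' and 'b'. A row is flagged
    ambiguous when one outgroup gene's orthologs span two groups of one
    species. Rows are kept when both group classes match ``pattern``.
    """
    member_to_group = {}
    by_id = {}
    for tag, groups in (("a", groups_a), ("b", groups_b)):
        for g in groups:
            by_id[(tag, g.group_id)] = g
            for m in g.members:
                member_to_group[(tag, m)] = g.group_id
    rows = []
    for og in sorted(orthologs_to_outgroup):
        spmap = orthologs_to_outgroup[og]
        found = {}
        ambiguous = False
        for tag in ("a", "b"):
            hits = {member_to_group.get((tag, m))
                    for m in spmap.get(tag, ())} - {None}
            if len(hits) > 1:
                ambiguous = True
            found[tag] = by_id[(tag, hits.pop())] if len(hits) == 1 \
                else None
        ga, gb = found["a"], found["b"]
        match = (not ambiguous and ga is not None and gb is not None
                 and ga.copy_class == pattern[0]
                 and gb.copy_class == pattern[1])
        rows.append((og,
                     ga.group_id if ga else None,
                     gb.group_id if gb else None,
                     ambiguous, match))
    df = pd.DataFrame(rows, columns=["outgroup_gene", "group_a", "group_b",
                                     "ambiguous", "matches_pattern"])
    return df


def intersect_groups_with_gene_list(groups, gene_list) -> dict:
    """Groups with >= 1 member in ``gene_list``, counted by copy class."""
    wanted = set(gene_list)
    counts = {1: 0, 2: 0, 3: 0, "oversized": 0}
    hit_groups = []
    for g in groups:
        if wanted.intersection(g.members):
            counts[g.copy_class if g.copy_class is not None
                   else "oversized"] += 1
            hit_groups.append(g)
    return {"counts": counts, "groups": hit_groups}
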