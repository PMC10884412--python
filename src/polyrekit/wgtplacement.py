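"""Phylogenetic placement of the WGT relative to speciation: NJ gene-tree
building, duplicate-topology scenario classification, and MAPS-style
per-node shared-duplication percentages compared against simulated null
and positive gene-tree sets.

Gene-tree leaves are labeled ``species|geneid``; duplication nodes are
called by species overlap (a gene-tree node whose two child subtrees
share at least one species), which on binary, complete-taxon trees is
equivalent to reconciliation-based duplication calling.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioCount",
    "MapsResult",
    "leaf_species",
    "build_nj_tree",
    "classify_wgt_topology",
    "classify_scenarios",
    "maps_percentages",
    "compare_maps_to_simulations",
]

SCENARIOS = ("shared_wgt", "lineage_specific", "unresolved")


@dataclass
class ScenarioCount:
    shared_wgt: int = 0
    lineage_specific: int = 0
    unresolved: int = 0

    @property
    def total(self) -> int:
        return self.shared_wgt + self.lineage_specific + self.unresolved


@dataclass
class MapsResult:
    """Per species-tree internal node: subtrees examined, subtrees with a
    duplication shared by all descendant species, percentage."""

    table: pd.DataFrame  # index: node label; columns n_examined,
    # n_with_shared_duplication, percentage


def leaf_species(label: str) -> str:
    return label.split("|", 1)[0]


def build_nj_tree(distances: pd.DataFrame, outgroup: str):
    """Neighbor-joining tree from a symmetric distance matrix
    (DataFrame, labels on both axes), rooted on the outgroup leaf.
    Deterministic given input order."""
    import dendropy

    if distances.isna().any().any() or \
            not np.isfinite(distances.values).all():
        raise ValueError("non-finite distance")
    if distances.shape[0] < 3:
        raise ValueError("need >= 3 taxa")
    labels = list(distances.index)
    if outgroup not in labels:
        raise ValueError(f"outgroup {outgroup!r} not among taxa")
    csv = io.StringIO()
    distances.to_csv(csv)
    csv.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        csv, delimiter=",")
    tree = pdm.nj_tree()
    node = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == outgroup:
            node = leaf
            break
    if node is None:  # dendropy may normalize label whitespace
        raise ValueError(f"outgroup {outgroup!r} missing from NJ tree")
    tree.reroot_at_edge(node.edge, update_bipartitions=True,
                        suppress_unifurcations=False)
    return tree


def _species_under(node) -> set[str]:
    return {leaf_species(l.taxon.label) for l in node.leaf_iter()}


def classify_wgt_topology(tree, ingroup_species: tuple[str, str],
                          outgroup_species: str) -> str:
    """Three-way scenario for a rooted tree with two duplicate leaves per
    ingroup species plus outgroup leaves.

    shared_wgt: each duplicate clade mixes the two ingroup species
    (((S1,L1),(S2,L2)),O) — the duplication predates speciation.
    lineage_specific: duplicates are species-monophyletic
    (((S1,S2),(L1,L2)),O). Anything else (missing leaves,
    multifurcations, other resolutions) is unresolved.
    """
    s, l = ingroup_species
    known = {s, l, outgroup_species}
    ingroup_leaves = []
    for leaf in tree.leaf_node_iter():
        sp = leaf_species(leaf.taxon.label)
        if sp not in known:
            raise ValueError(f"leaf species {sp!r} not in "
                             f"{sorted(known)}")
        if sp in (s, l):
            ingroup_leaves.append(leaf)
    by_sp = {s: 0, l: 0}
    for leaf in ingroup_leaves:
        by_sp[leaf_species(leaf.taxon.label)] += 1
    if by_sp[s] != 2 or by_sp[l] != 2:
        return "unresolved"
    tree.is_rooted = True  # rooted semantics required for the MRCA
    mrca = tree.mrca(taxa=[lf.taxon for lf in ingroup_leaves])
    children = mrca.child_nodes()
    if len(children) != 2:
        return "unresolved"
    sets = []
    for ch in children:
        leaves = [lf for lf in ch.leaf_iter()
                  if leaf_species(lf.taxon.label) in (s, l)]
        sets.append(sorted(leaf_species(lf.taxon.label) for lf in leaves))
    if sorted(sets) == sorted([sorted([s, l]), sorted([s, l])]):
        return "shared_wgt"
    if sorted(sets) == sorted([[s, s], [l, l]]):
        return "lineage_specific"
    return "unresolved"


def classify_scenarios(trees, ingroup_species, outgroup_species
                       ) -> ScenarioCount:
    out = ScenarioCount()
    for t in trees:
        label = classify_wgt_topology(t, ingroup_species, outgroup_species)
        setattr(out, label, getattr(out, label) + 1)
    return out


# --------------------------------------------------------------------------
# MAPS


def _species_tree_clades(species_tree) -> dict[str, frozenset]:
    clades = {}
    for i, nd in enumerate(species_tree.preorder_internal_node_iter()):
        label = (nd.label or f"N{i}").replace(" ", "_")
        clades[label] = frozenset(
            l.taxon.label for l in nd.leaf_iter())
    return clades


def maps_percentages(gene_trees, species_tree) -> MapsResult:
    """Percentage of gene-tree subtrees with a duplication shared by all
    species descended from each species-tree internal node.

    A gene tree is examined for node N when its species set covers N's
    clade; it supports N when some gene-tree node is a species-overlap
    duplication whose total species set equals the clade and whose two
    children each cover the whole clade. Nodes with zero examined
    subtrees are reported as absent.
    """
    clades = _species_tree_clades(species_tree)
    sp_in_tree = {l.taxon.label
                  for l in species_tree.leaf_node_iter()}
    n_exam = {k: 0 for k in clades}
    n_supp = {k: 0 for k in clades}
    for gt in gene_trees:
        tree_species = {leaf_species(l.taxon.label)
                        for l in gt.leaf_node_iter()}
        unknown = tree_species - sp_in_tree
        if unknown:
            raise ValueError(f"gene-tree species {sorted(unknown)} absent "
                             f"from species tree")
        # collect duplication nodes once per tree
        dup_hits: dict[str, bool] = {}
        for nd in gt.preorder_internal_node_iter():
            children = nd.child_nodes()
            if len(children) < 2:
                continue
            child_sets = [_species_under(c) for c in children]
            overlap = False
            for i in range(len(child_sets)):
                for j in range(i + 1, len(child_sets)):
                    if child_sets[i] & child_sets[j]:
                        overlap = True
            if not overlap:
                continue
            total = frozenset().union(*child_sets)
            for label, clade in clades.items():
                if total == clade and \
                        sum(1 for cs in child_sets if clade <= cs) >= 2:
                    dup_hits[label] = True
        for label, clade in clades.items():
            if clade <= tree_species:
                n_exam[label] += 1
                if dup_hits.get(label):
                    n_supp[label] += 1
    rows = {}
    for label in clades:
        if n_exam[label] == 0:
            continue
        rows[label] = (n_exam[label], n_supp[label],
                       100.0 * n_supp[label] / n_exam[label])
    table = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["n_examined", "n_with_shared_duplication", "percentage"])
    table.index.name = "node"
    return MapsResult(table)


def compare_maps_to_simulations(observed: MapsResult, null_sims,
                                positive_sims,
                                band: tuple[float, float] = (0.025, 0.975)
                                ) -> pd.DataFrame:
    """Per-node verdict from observed percentage vs simulated bands.

    supports_wgd: observed above the null band and inside (or above the
    low edge of) the positive band; no_support: observed within the null
    band; ambiguous otherwise. Node sets must match across inputs.
    """
    nodes = set(observed.table.index)
    for sims, name in ((null_sims, "null"), (positive_sims, "positive")):
        for s in sims:
            if set(s.table.index) != nodes:
                raise ValueError(f"{name} simulation nodes do not match "
                                 f"observed nodes")
    rows = []
    for node in observed.table.index:
        obs = observed.table.loc[node, "percentage"]
        nullv = np.array([s.table.loc[node, "percentage"]
                          for s in null_sims])
        posv = np.array([s.table.loc[node, "percentage"]
                         for s in positive_sims])
        n_lo, n_hi = np.quantile(nullv, band)
        p_lo, p_hi = np.quantile(posv, band)
        if obs > n_hi and obs >= p_lo:
            verdict = "supports_wgd"
        elif obs <= n_hi:
            verdict = "no_support"
        else:
            verdict = "ambiguous"
        rows.append((node, obs, n_lo, n_hi, p_lo, p_hi, verdict))
    return pd.DataFrame(rows, columns=["node", "observed", "null_low",
                                       "null_high", "positive_low",
                                       "positive_high", "verdict"])
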