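"""Homology filtering, collinear-block chaining, synteny-depth ratios and
karyotype arithmetic (ploidy ladders, fusion/fission/inversion counting).

Chaining is a weighted longest-increasing-chain dynamic program over
anchor pairs sorted by rank, gap-penalized, run per chromosome pair and
per orientation; blocks are extracted iteratively (best chain first, its
anchors removed, repeat), which yields maximal non-overlapping chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntenicBlock",
    "KaryotypeMap",
    "filter_homology_hits",
    "chain_collinear_blocks",
    "best_chain",
    "synteny_depth_ratio",
    "expected_ploidy_ladder",
    "count_rearrangement_events",
    "karyotype_map_from_layout",
]


@dataclass
class SyntenicBlock:
    block_id: int
    species_a: str
    species_b: str
    chrom_a: str
    chrom_b: str
    orientation: str  # "same" | "inverted"
    anchors: list[tuple[str, str]]  # ordered (gene_a, gene_b)
    ranks_a: list[int]
    ranks_b: list[int]
    score: float  # sum of anchor bitscores

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def filter_homology_hits(hits: pd.DataFrame, min_identity: float = 30.0,
                         max_evalue: float = 1e-10,
                         min_coverage: float = 0.30,
                         drop_self: bool = True) -> pd.DataFrame:
    """Keep hits with identity >= min_identity, e-value strictly below
    max_evalue, and both coverages >= min_coverage."""
    keep = ((hits["identity"] >= min_identity)
            & (hits["evalue"] < max_evalue)
            & (hits["coverage_q"] >= min_coverage)
            & (hits["coverage_s"] >= min_coverage))
    if drop_self:
        keep &= hits["query"] != hits["subject"]
    return hits.loc[keep].reset_index(drop=True)


# --------------------------------------------------------------------------
# chaining


def _collapse_tandem(anchors: list[tuple]) -> list[tuple]:
    """Collapse tandem-duplicate anchors: within a run of consecutive
    ranks on one genome all hitting the same gene on the other genome,
    keep only the highest-bitscore anchor."""
    for key_rank, key_gene in ((0, 4), (1, 3)):  # (ra, gene_b), (rb, gene_a)
        anchors = sorted(anchors, key=lambda a: (a[key_gene], a[key_rank]))
        out, run = [], []
        for a in anchors:
            if run and a[key_gene] == run[-1][key_gene] \
                    and a[key_rank] == run[-1][key_rank] + 1:
                run.append(a)
            else:
                if run:
                    out.append(max(run, key=lambda x: x[2]))
                run = [a]
        if run:
            out.append(max(run, key=lambda x: x[2]))
        anchors = out
    return anchors


def _chain_key(chain: list[tuple]) -> tuple:
    """Deterministic ordering of equal-length chains: higher total score,
    then higher bitscore sum, then lexicographically smaller anchor
    coordinates."""
    coords = tuple((a[0], a[1]) for a in chain)
    return coords


def best_chain(anchors: list[tuple], max_gap: int, gap_penalty: float,
               orientation: str) -> tuple[float, float, list[tuple]]:
    """Maximum-score collinear chain by dynamic programming.

    ``anchors`` are tuples (rank_a, rank_b, bitscore, gene_a, gene_b).
    A chain is strictly increasing in rank_a and strictly increasing
    (same) or strictly decreasing (inverted) in rank_b, with successive
    rank differences at most ``max_gap`` on both genomes. The score is
    the bitscore sum minus ``gap_penalty`` per skipped rank unit
    ((da-1) + (db-1) per join). Ties break toward higher bitscore sum
    then lexicographically smallest anchor coordinates.

    Returns (score, bitscore_sum, chain).
    """
    if not anchors:
        return (-np.inf, 0.0, [])
    sign = 1 if orientation == "same" else -1
    pts = sorted(anchors, key=lambda a: (a[0], sign * a[1]))
    n = len(pts)
    score = [0.0] * n
    bits = [0.0] * n
    parent: list[int | None] = [None] * n

    def chain_of(i: int) -> list[tuple]:
        out = []
        while i is not None:
            out.append(pts[i])
            i = parent[i]
        out.reverse()
        return out

    for i, a in enumerate(pts):
        score[i], bits[i], parent[i] = a[2], a[2], None
        for j in range(i):
            b = pts[j]
            da = a[0] - b[0]
            db = sign * (a[1] - b[1])
            if da < 1 or db < 1 or da > max_gap or db > max_gap:
                continue
            cand_sc = score[j] + a[2] - gap_penalty * ((da - 1) + (db - 1))
            cand = (cand_sc, bits[j] + a[2])
            cur = (score[i], bits[i])
            take = cand > cur
            if not take and cand == cur:
                # exact tie: lexicographically smaller chain wins
                alt = chain_of(j) + [a]
                ref = (chain_of(parent[i]) + [a]) if parent[i] is not None \
                    else [a]
                take = _chain_key(alt) < _chain_key(ref)
            if take:
                score[i], bits[i], parent[i] = cand_sc, cand[1], j
    best_i = 0
    for i in range(1, n):
        cand = (score[i], bits[i])
        cur = (score[best_i], bits[best_i])
        if cand > cur or (cand == cur and
                          _chain_key(chain_of(i))
                          < _chain_key(chain_of(best_i))):
            best_i = i
    return score[best_i], bits[best_i], chain_of(best_i)


def chain_collinear_blocks(hits: pd.DataFrame, genes_a: pd.DataFrame,
                           genes_b: pd.DataFrame, min_genes: int = 5,
                           max_gap: int = 25, gap_penalty: float = 1.0,
                           collapse_tandem: bool = True
                           ) -> list[SyntenicBlock]:
    """Chain filtered homology hits into syntenic blocks.

    ``genes_a``/``genes_b`` are ranked gene tables (see
    :func:`polyrekit.ioformats.add_ranks`). Blocks need at least
    ``min_genes`` anchors; each anchor is used in at most one block per
    chromosome pair.
    """
    loc_a = genes_a.set_index("gene_id")[["chromosome", "rank"]]
    loc_b = genes_b.set_index("gene_id")[["chromosome", "rank"]]
    species_a = genes_a["species"].iat[0] if len(genes_a) else "?"
    species_b = genes_b["species"].iat[0] if len(genes_b) else "?"

    by_pair: dict[tuple[str, str], list[tuple]] = {}
    for q, s, bits in hits[["query", "subject", "bitscore"]].itertuples(
            index=False):
        if q not in loc_a.index or s not in loc_b.index:
            continue
        ca, ra = loc_a.loc[q]
        cb, rb = loc_b.loc[s]
        by_pair.setdefault((ca, cb), []).append(
            (int(ra), int(rb), float(bits), q, s))

    blocks: list[SyntenicBlock] = []
    bid = 0
    for (ca, cb) in sorted(by_pair):
        anchors = by_pair[(ca, cb)]
        if collapse_tandem:
            anchors = _collapse_tandem(anchors)
        pool = list(anchors)
        while True:
            cands = []
            for orient in ("same", "inverted"):
                sc, bits, chain = best_chain(pool, max_gap, gap_penalty,
                                             orient)
                if len(chain) >= min_genes:
                    cands.append((sc, bits, orient, chain))
            if not cands:
                break
            cands.sort(key=lambda c: (-c[0], -c[1], c[2],
                                      _chain_key(c[3])))
            sc, bits, orient, chain = cands[0]
            bid += 1
            blocks.append(SyntenicBlock(
                block_id=bid, species_a=species_a, species_b=species_b,
                chrom_a=ca, chrom_b=cb, orientation=orient,
                anchors=[(a[3], a[4]) for a in chain],
                ranks_a=[a[0] for a in chain],
                ranks_b=[a[1] for a in chain],
                score=bits))
            chain_set = {(a[0], a[1]) for a in chain}
            pool = [a for a in pool if (a[0], a[1]) not in chain_set]
    return blocks


def blocks_to_frame(blocks: list[SyntenicBlock]) -> pd.DataFrame:
    rows = []
    for b in blocks:
        for (ga, gb), ra, rb in zip(b.anchors, b.ranks_a, b.ranks_b):
            rows.append((b.block_id, b.species_a, b.species_b, b.chrom_a,
                         b.chrom_b, b.orientation, b.score, ga, gb, ra, rb))
    return pd.DataFrame(rows, columns=[
        "block_id", "species_a", "species_b", "chrom_a", "chrom_b",
        "orientation", "score", "gene_a", "gene_b", "rank_a", "rank_b"])


def write_collinearity(blocks: list[SyntenicBlock], path) -> None:
    """Write blocks in a documented MCScanX-inspired dialect: one header
    line per block, then tab-indented anchor rows."""
    with open(path, "wt") as fh:
        for b in blocks:
            fh.write(f"## block {b.block_id}: {b.species_a} {b.chrom_a} x "
                     f"{b.species_b} {b.chrom_b} orientation={b.orientation} "
                     f"score={b.score:.1f} n={b.n_anchors}\n")
            for (ga, gb), ra, rb in zip(b.anchors, b.ranks_a, b.ranks_b):
                fh.write(f"\t{ga}\t{gb}\t{ra}\t{rb}\n")


# --------------------------------------------------------------------------
# depth


def synteny_depth_ratio(blocks: list[SyntenicBlock], genes_ref: pd.DataFrame,
                        reference_species: str, query_species: str
                        ) -> tuple[pd.Series, int]:
    """Per-reference-gene coverage depth and the modal depth.

    Depth of a reference gene is the number of distinct query blocks in
    which it occurs as an anchor — i.e. the number of homoeologous
    copies the query genome retains for it.
    """
    depth = pd.Series(0, index=genes_ref["gene_id"], dtype=int)
    for b in blocks:
        if b.species_a == reference_species and \
                b.species_b == query_species:
            ref_genes = {ga for ga, _ in b.anchors}
        elif b.species_b == reference_species and \
                b.species_a == query_species:
            ref_genes = {gb for _, gb in b.anchors}
        else:
            continue
        hit = depth.index.isin(ref_genes)
        depth[hit] += 1
    mode = int(depth.mode().iloc[0]) if len(depth) else 0
    return depth, mode


# --------------------------------------------------------------------------
# karyotype arithmetic


def expected_ploidy_ladder(n_base: int, multipliers: list[int]) -> int:
    """Expected haploid chromosome number after successive whole-genome
    multiplications with no rearrangement: n_base * prod(multipliers)."""
    if not isinstance(n_base, (int, np.integer)) or n_base < 1:
        raise ValueError("n_base must be an integer >= 1")
    out = int(n_base)
    for m in multipliers:
        if not isinstance(m, (int, np.integer)) or m < 1:
            raise ValueError("multipliers must be integers >= 1")
        out *= int(m)
    return out


@dataclass
class KaryotypeMap:
    """For each descendant chromosome, the ordered signed segment list
    covering it: {chrom: [(segment_id, sign), ...]}. A segment id names
    one ancestral chromosome copy (post-WGT copies are distinct ids)."""

    segments: dict[str, list]


def karyotype_map_from_layout(layout, by_copy: bool = True) -> KaryotypeMap:
    """Collapse a simulated layout into maximal (ancestral-chromosome
    copy, sign) runs per descendant chromosome.

    With ``by_copy`` (default) the segment id is (anc_chrom, subgenome),
    distinguishing the post-WGT copies; otherwise it is the bare
    ancestral chromosome.
    """
    segs = {}
    for ci, chrom in enumerate(layout.chromosomes):
        runs = []
        for g in chrom:
            seg = (g.anc_chrom, g.subgenome) if by_copy else g.anc_chrom
            key = (seg, g.sign)
            if runs and runs[-1] == key:
                continue
            runs.append(key)
        segs[f"chr{ci + 1}"] = runs
    return KaryotypeMap(segs)


def count_rearrangement_events(kmap: KaryotypeMap, ancestral_n: int,
                               multiplier: int = 1) -> dict[str, int]:
    """Lower-bound rearrangement counts from segment adjacencies.

    A descendant chromosome carrying r maximal segment runs (runs of one
    ancestral-chromosome copy, sign flips within a run allowed)
    contributes (r - 1) fusions; a copy split into m runs across all
    descendants contributes (m - 1) fissions; each adjacency of two runs
    of the same copy with opposite sign counts one inversion breakpoint.
    With run-based counting, fusions - fissions always equals (number of
    ancestral copies observed) - (number of descendant chromosomes).

    This is a surrogate lower bound on the true event history, not a
    rearrangement-distance solver.
    """
    fusions = fissions = inversions = 0
    runs_per_copy: dict = {}
    for chrom, segs in kmap.segments.items():
        if not segs:
            continue
        copy_runs = []
        for seg, sign in segs:
            if copy_runs and copy_runs[-1] == seg:
                inversions += 1  # same copy adjacent again: sign flip
                continue
            copy_runs.append(seg)
        fusions += len(copy_runs) - 1
        for seg in copy_runs:
            runs_per_copy[seg] = runs_per_copy.get(seg, 0) + 1
    for seg in runs_per_copy:
        anc = seg[0] if isinstance(seg, tuple) else seg
        if not 0 <= anc < ancestral_n:
            raise ValueError(f"segment maps to unknown ancestral "
                             f"chromosome {anc!r}")
    for m in runs_per_copy.values():
        fissions += m - 1
    return {"fusion": fusions, "fission": fissions,
            "inversion_breakpoints": inversions}
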