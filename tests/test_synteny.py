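"""Homology filtering thresholds, chaining against exhaustive search,
synteny depth on simulated triplications, and karyotype arithmetic."""

import numpy as np
import pandas as pd
import pytest

from polyrekit import ioformats as io
from polyrekit import simgenome as sg
from polyrekit import synteny as syn


def _hits(rows):
    return pd.DataFrame(rows, columns=io.HOMOLOGY_COLUMNS)


def make_gene_table(species, chrom_sizes):
    rows = []
    for ci, n in enumerate(chrom_sizes):
        for r in range(n):
            rows.append((f"{species}_c{ci}_{r}", species, f"chr{ci + 1}",
                         1000 * r + 1, 1000 * r + 600, "+"))
    return io.add_ranks(pd.DataFrame(rows, columns=io.GENE_TABLE_COLUMNS))


class TestFilter:
    @pytest.mark.parametrize("identity,evalue,cov,kept", [
        (29.9, 1e-20, 1.0, False),   # below identity floor
        (30.0, 1e-20, 1.0, True),    # floor is inclusive
        (50.0, 1e-10, 1.0, False),   # e-value bound is strict
        (50.0, 9.9e-11, 1.0, True),
        (50.0, 1e-20, 0.29, False),  # both coverages tested
        (100.0, 0.0, 1.0, True),
    ])
    def test_thresholds(self, identity, evalue, cov, kept):
        hits = _hits([("q", "s", identity, evalue, cov, cov, 100.0)])
        out = syn.filter_homology_hits(hits)
        assert (len(out) == 1) == kept

    def test_asymmetric_coverage_tested_both_sides(self):
        hits = _hits([("q", "s", 50.0, 1e-20, 0.9, 0.1, 100.0)])
        assert len(syn.filter_homology_hits(hits)) == 0


def brute_force_best_chain(anchors, max_gap, gap_penalty, orientation):
    """Exhaustive enumeration oracle over all anchor subsets."""
    sign = 1 if orientation == "same" else -1
    best = None
    n = len(anchors)
    for mask in range(1, 1 << n):
        sub = [anchors[i] for i in range(n) if mask >> i & 1]
        sub.sort(key=lambda a: (a[0], sign * a[1]))
        score = bits = 0.0
        ok = True
        for i, a in enumerate(sub):
            bits += a[2]
            score += a[2]
            if i:
                da = a[0] - sub[i - 1][0]
                db = sign * (a[1] - sub[i - 1][1])
                if da < 1 or db < 1 or da > max_gap or db > max_gap:
                    ok = False
                    break
                score -= gap_penalty * ((da - 1) + (db - 1))
        if not ok:
            continue
        key = (score, bits)
        if best is None or key > (best[0], best[1]) or (
                key == (best[0], best[1])
                and syn._chain_key(sub) < syn._chain_key(best[2])):
            best = (score, bits, sub)
    return best


def random_anchor_instance(rng, n_max=12, rank_range=15):
    n = int(rng.integers(1, n_max + 1))
    seen, anchors = set(), []
    for i in range(n):
        ra, rb = int(rng.integers(rank_range)), int(rng.integers(rank_range))
        if (ra, rb) in seen:
            continue
        seen.add((ra, rb))
        anchors.append((ra, rb, float(np.round(rng.uniform(1, 100), 3)),
                        f"a{i}", f"b{i}"))
    return anchors


class TestChaining:
    def test_four_anchors_no_block(self):
        genes = make_gene_table("x", [10])
        hits = _hits([(f"x_c0_{i}", f"x_c0_{i + 5}", 80, 0.0, 1, 1, 100.0)
                      for i in range(4)])
        # map hits onto one genome used as both sides via another species
        genes_b = make_gene_table("x", [10])
        blocks = syn.chain_collinear_blocks(hits, genes, genes_b,
                                            min_genes=5)
        assert blocks == []

    def test_five_anchors_one_block_same_orientation(self):
        genes_a = make_gene_table("a", [6])
        genes_b = make_gene_table("b", [6])
        hits = _hits([(f"a_c0_{i}", f"b_c0_{i}", 80, 0.0, 1, 1, 100.0)
                      for i in range(5)])
        blocks = syn.chain_collinear_blocks(hits, genes_a, genes_b,
                                            min_genes=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == "same"
        assert blocks[0].n_anchors == 5

    def test_inverted_block_detected(self):
        genes_a = make_gene_table("a", [8])
        genes_b = make_gene_table("b", [8])
        hits = _hits([(f"a_c0_{i}", f"b_c0_{7 - i}", 80, 0.0, 1, 1, 100.0)
                      for i in range(6)])
        blocks = syn.chain_collinear_blocks(hits, genes_a, genes_b,
                                            min_genes=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"

    def test_block_anchors_strictly_monotone(self, rng):
        genes_a = make_gene_table("a", [30])
        genes_b = make_gene_table("b", [30])
        rows = [(f"a_c0_{int(rng.integers(30))}",
                 f"b_c0_{int(rng.integers(30))}", 80, 0.0, 1, 1,
                 float(rng.uniform(50, 150))) for _ in range(120)]
        blocks = syn.chain_collinear_blocks(_hits(rows), genes_a, genes_b,
                                            min_genes=3)
        for b in blocks:
            da = np.diff(b.ranks_a)
            db = np.diff(b.ranks_b)
            assert (da > 0).all()
            assert ((db > 0).all() if b.orientation == "same"
                    else (db < 0).all())

    def test_dp_equals_exhaustive_search(self, rng):
        for _ in range(150):
            anchors = random_anchor_instance(rng)
            for orient in ("same", "inverted"):
                want = brute_force_best_chain(anchors, 5, 1.0, orient)
                got = syn.best_chain(anchors, 5, 1.0, orient)
                assert want is not None
                assert got[0] == pytest.approx(want[0])
                assert [(a[0], a[1]) for a in got[2]] \
                    == [(a[0], a[1]) for a in want[2]]


class TestDepth:
    def test_no_loss_triplication_modal_depth_three(self):
        cfg = sg.SimConfig(seed=9, n_anc_chromosomes=4, n_anc_genes=200,
                           loss_prob=0.0, inv_rate=0, fus_rate=0,
                           fis_rate=0)
        anc, (a, _), _ = sg.simulate_wgt_genomes(cfg)
        genes_anc = io.add_ranks(anc.to_gene_table())
        genes_a = io.add_ranks(a.to_gene_table())
        hits = sg.ancestor_descendant_hits(anc, a)
        blocks = syn.chain_collinear_blocks(hits, genes_anc, genes_a,
                                            min_genes=5)
        depth, mode = syn.synteny_depth_ratio(blocks, genes_anc, "anc",
                                              "spA")
        assert mode == 3

    def test_depth_matches_truth_under_loss(self):
        cfg = sg.SimConfig(seed=10, n_anc_chromosomes=4, n_anc_genes=400,
                           loss_prob=0.5, inv_rate=0, fus_rate=0,
                           fis_rate=0)
        anc, (a, _), truth = sg.simulate_wgt_genomes(cfg)
        genes_anc = io.add_ranks(anc.to_gene_table())
        genes_a = io.add_ranks(a.to_gene_table())
        hits = sg.ancestor_descendant_hits(anc, a)
        blocks = syn.chain_collinear_blocks(hits, genes_anc, genes_a,
                                            min_genes=3, max_gap=50)
        depth, _ = syn.synteny_depth_ratio(blocks, genes_anc, "anc", "spA")
        truth_depth = truth.copy_class["spA"]
        anc_ids = {g.anc_gene: g.gene_id for g in anc.genes()}
        for i in range(cfg.n_anc_genes):
            assert depth[anc_ids[i]] == truth_depth[i]


class TestKaryotype:
    @pytest.mark.parametrize("n_base,mult,expected", [
        (7, [3, 2, 2, 2], 168),
        (8, [3], 24),
        (13, [], 13),
    ])
    def test_ploidy_ladder(self, n_base, mult, expected):
        assert syn.expected_ploidy_ladder(n_base, mult) == expected

    @pytest.mark.parametrize("n_base,mult", [(0, []), (2, [0]),
                                             (2.5, []), (2, [1.5])])
    def test_ploidy_ladder_rejects(self, n_base, mult):
        with pytest.raises(ValueError):
            syn.expected_ploidy_ladder(n_base, mult)

    def test_identity_painting_zero_events(self):
        kmap = syn.KaryotypeMap({"chr1": [((0, 0), 1)],
                                 "chr2": [((1, 0), 1)]})
        out = syn.count_rearrangement_events(kmap, 2)
        assert out == {"fusion": 0, "fission": 0,
                       "inversion_breakpoints": 0}

    def test_single_fusion(self):
        kmap = syn.KaryotypeMap({"chr1": [((0, 0), 1), ((1, 0), 1)]})
        out = syn.count_rearrangement_events(kmap, 2)
        assert out["fusion"] == 1 and out["fission"] == 0

    def test_hand_enumerated_toy(self):
        # chrA = A+ B+ A-  (2 fusions; A split in 2 runs on this chrom)
        # chrB = B+        (B split across 2 chroms -> 1 fission)
        # chrC = C+ C-     (inversion breakpoint, no fusion)
        A, B, C = (0, 0), (1, 0), (2, 0)
        kmap = syn.KaryotypeMap({
            "chr1": [(A, 1), (B, 1), (A, -1)],
            "chr2": [(B, 1)],
            "chr3": [(C, 1), (C, -1)],
        })
        out = syn.count_rearrangement_events(kmap, 3)
        assert out["fusion"] == 2
        assert out["fission"] == 2  # A in 2 runs, B in 2 runs
        assert out["inversion_breakpoints"] == 1

    def test_conservation_on_rearrangement_only_simulation(self):
        cfg = sg.SimConfig(seed=12, n_anc_chromosomes=6, n_anc_genes=600,
                           loss_prob=0.0, inv_rate=4, fus_rate=3,
                           fis_rate=3)
        _, (a, b), _ = sg.simulate_wgt_genomes(cfg)
        for layout in (a, b):
            kmap = syn.karyotype_map_from_layout(layout)
            ev = syn.count_rearrangement_events(kmap, 6, multiplier=3)
            assert ev["fusion"] - ev["fission"] \
                == 6 * 3 - layout.n_chromosomes

    def test_unknown_ancestor_rejected(self):
        kmap = syn.KaryotypeMap({"chr1": [((9, 0), 1)]})
        with pytest.raises(ValueError, match="unknown ancestral"):
            syn.count_rearrangement_events(kmap, 2)
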