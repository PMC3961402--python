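"""Anchor chaining, block construction, completion and breakpoints."""

import numpy as np
import pytest

from helpers import (build_genome, chain_closure_oracle, components_as_sets,
                     make_pair, mutate, random_protein)
from syntenic.homology import AlignmentParams
from syntenic.homology import test_nonrbh_homology as nonrbh_test
from syntenic.simul import SimParams, simulate_pair
from syntenic.synteny import (SyntenyParams, block_orientation, build_blocks,
                              chain_anchors, complete_block,
                              extract_breakpoints, reconstruct_blocks)
from syntenic.homology import find_rbh


def _paired_genomes(rng, order_b, n=None, chrom_b=None):
    """Genomes where A holds genes 0..n-1 in order and B holds ``order_b``."""
    n = n if n is not None else len(order_b)
    prots = [random_protein(rng, 30) for _ in range(n)]
    ga = build_genome("A", {"c1": [(f"a{i}", prots[i]) for i in range(n)]})
    layout_b = [(f"b{i}", prots[i]) for i in order_b]
    gb = build_genome("B", {chrom_b or "c1": layout_b})
    rbh = [make_pair(ga, gb, f"a{i}", f"b{i}") for i in range(n)]
    return ga, gb, rbh


class TestChainAnchors:
    def test_consecutive_rbh_form_one_component(self, rng):
        ga, gb, rbh = _paired_genomes(rng, [0, 1, 2])
        comps = chain_anchors(rbh, ga, gb, delta1=1)
        assert len(comps) == 1 and len(comps[0]) == 3

    def test_intervening_rbh_boundary_is_strict(self, rng):
        # B chr c1 order: b0, b2, b3, b4, b1 -> 3 intervening RBH-genes
        # between (a0,b0) and (a1,b1); the intervening genes pair with a
        # different A chromosome so they cannot bridge the chain.
        prots = [random_protein(rng, 30) for _ in range(5)]
        ga = build_genome("A", {"c1": [("a0", prots[0]), ("a1", prots[1])],
                                "c2": [(f"a{i}", prots[i]) for i in (2, 3, 4)]})
        gb = build_genome("B", {"c1": [(f"b{i}", prots[i])
                                       for i in (0, 2, 3, 4, 1)]})
        rbh = [make_pair(ga, gb, f"a{i}", f"b{i}") for i in range(5)]

        for delta, expect_linked in [(3, False), (4, True)]:
            comps = components_as_sets(chain_anchors(rbh, ga, gb, delta))
            linked = any({("a0", "b0"), ("a1", "b1")} <= c for c in comps)
            assert linked == expect_linked
            assert comps == chain_closure_oracle(rbh, ga, gb, delta)

    def test_different_b_chromosomes_never_linked(self, rng):
        prots = [random_protein(rng, 30) for _ in range(2)]
        ga = build_genome("A", {"c1": [("a0", prots[0]), ("a1", prots[1])]})
        gb = build_genome("B", {"c1": [("b0", prots[0])],
                                "c2": [("b1", prots[1])]})
        rbh = [make_pair(ga, gb, "a0", "b0"), make_pair(ga, gb, "a1", "b1")]
        comps = chain_anchors(rbh, ga, gb, delta1=100)
        assert len(comps) == 2

    def test_matches_transitive_closure_on_random_instances(self, rng):
        """Union-find chaining equals the brute-force closure oracle."""
        for _ in range(40):
            n = int(rng.integers(5, 30))
            order = list(rng.permutation(n))
            ga, gb, rbh = _paired_genomes(rng, order, n=n)
            delta = int(rng.integers(1, 6))
            assert components_as_sets(chain_anchors(rbh, ga, gb, delta)) == \
                chain_closure_oracle(rbh, ga, gb, delta)

    def test_unknown_gene_rejected(self, rng):
        ga, gb, rbh = _paired_genomes(rng, [0, 1])
        ga2 = build_genome("A", {"c1": [("other", "MKV")]})
        with pytest.raises(ValueError):
            chain_anchors(rbh, ga2, gb, 1)


class TestBuildBlocks:
    def test_single_anchor_component_dropped(self, rng):
        ga, gb, rbh = _paired_genomes(rng, [0])
        blocks = build_blocks(chain_anchors(rbh, ga, gb, 1), SyntenyParams())
        assert blocks == []
        assert rbh[0].syntenic is False

    def test_two_anchor_component_becomes_block(self, rng):
        ga, gb, rbh = _paired_genomes(rng, [0, 1])
        blocks = build_blocks(chain_anchors(rbh, ga, gb, 1), SyntenyParams())
        assert len(blocks) == 1
        assert len(blocks[0].anchors) == 2
        assert all(p.syntenic for p in rbh)

    def test_unrearranged_pair_gives_one_block_per_chromosome(self):
        params = SimParams(n_chromosomes=4, genes_per_chromosome=30,
                           divergence=0.1, n_inversions=0, n_translocations=0,
                           protein_length=(80, 150), seed=11)
        ga, gb, truth = simulate_pair(params)
        rbh = find_rbh(ga, gb, AlignmentParams())
        blocks = build_blocks(chain_anchors(rbh, ga, gb, 5),
                              SyntenyParams.single_delta(5))
        assert len(blocks) == 4
        assert sorted(b.chrom_a for b in blocks) == [f"chr{i}" for i in range(1, 5)]


class TestBlockOrientation:
    def _block(self, rng, order_b):
        ga, gb, rbh = _paired_genomes(rng, order_b)
        blocks = build_blocks(chain_anchors(rbh, ga, gb, len(order_b)),
                              SyntenyParams(delta1=len(order_b)))
        assert len(blocks) == 1
        return blocks[0]

    def test_collinear_is_forward(self, rng):
        assert self._block(rng, [0, 1, 2]).orientation == 1

    def test_reversed_is_backward(self, rng):
        assert self._block(rng, [2, 1, 0]).orientation == -1

    def test_transposed_pair_matches_pair_count_oracle(self, rng):
        order = [0, 1, 3, 2, 4]
        block = self._block(rng, order)
        conc = disc = 0
        ranks_b = {g: r for r, g in enumerate(order)}
        for i in range(5):
            for j in range(i + 1, 5):
                d = ranks_b[j] - ranks_b[i]
                conc += d > 0
                disc += d < 0
        expected = 1 if conc > disc else (-1 if disc > conc else 0)
        assert block.orientation == expected

    def test_balanced_order_is_zero(self, rng):
        # 2 concordant vs 2 discordant anchor pairs (with ties absent)
        block = self._block(rng, [1, 0, 3, 2])
        assert block.orientation in (-1, 0, 1)
        conc = disc = 0
        ranks_b = {g: r for r, g in enumerate([1, 0, 3, 2])}
        for i in range(4):
            for j in range(i + 1, 4):
                d = ranks_b[j] - ranks_b[i]
                conc += d > 0
                disc += d < 0
        assert (conc == disc) == (block.orientation == 0)


class TestCompleteBlock:
    def _setup(self, rng, gap_a, gap_b, chrom_b_planted="c1"):
        """Two identical-protein anchors at ranks 0,1 plus a planted diverged
        homolog pair ``gap`` genes downstream of anchor 1 in each genome."""
        anchor_prots = [random_protein(rng, 60) for _ in range(2)]
        planted = random_protein(rng, 60)
        fill = lambda: random_protein(rng, 60)
        a_genes = [("a0", anchor_prots[0]), ("a1", anchor_prots[1])]
        b_genes = [("b0", anchor_prots[0]), ("b1", anchor_prots[1])]
        for k in range(1, gap_a):
            a_genes.append((f"af{k}", fill()))
        a_genes.append(("ap", planted))
        for k in range(1, gap_b):
            b_genes.append((f"bf{k}", fill()))
        bp_entry = ("bp", mutate(rng, planted, 0.1))
        ga = build_genome("A", {"c1": a_genes})
        if chrom_b_planted == "c1":
            b_genes.append(bp_entry)
            gb = build_genome("B", {"c1": b_genes})
        else:
            gb = build_genome("B", {"c1": b_genes, "c2": [bp_entry]})
        rbh = [make_pair(ga, gb, "a0", "b0"), make_pair(ga, gb, "a1", "b1")]
        blocks = build_blocks(chain_anchors(rbh, ga, gb, 2), SyntenyParams())
        params = AlignmentParams()
        tester = lambda pa, pb: nonrbh_test(pa, pb, params)
        return ga, gb, blocks[0], tester

    def test_planted_pair_within_reach_added(self, rng):
        delta2 = 3  # planted gene at distance delta2 - 1 from anchor a1/b1
        ga, gb, block, tester = self._setup(rng, delta2 - 1, delta2 - 1)
        complete_block(block, ga, gb, delta2, tester, {"a0", "a1"}, {"b0", "b1"})
        assert ("ap", "bp") in {(c.gene_a.id, c.gene_b.id)
                                for c in block.completions}
        assert block.span_a[1] >= ga["ap"].rank  # span extended

    def test_distance_bound_is_strict(self, rng):
        delta2 = 3  # planted gene at exactly delta2 genes -> excluded
        ga, gb, block, tester = self._setup(rng, delta2, delta2)
        complete_block(block, ga, gb, delta2, tester, {"a0", "a1"}, {"b0", "b1"})
        assert ("ap", "bp") not in {(c.gene_a.id, c.gene_b.id)
                                    for c in block.completions}

    def test_wrong_partner_chromosome_never_added(self, rng):
        ga, gb, block, tester = self._setup(rng, 2, 2, chrom_b_planted="c2")
        complete_block(block, ga, gb, 5, tester, {"a0", "a1"}, {"b0", "b1"})
        assert "bp" not in {c.gene_b.id for c in block.completions}

    def test_no_passing_candidate_leaves_block_unchanged(self, rng):
        delta2 = 3
        ga, gb, block, tester = self._setup(rng, delta2 - 1, delta2 - 1)
        span_before = block.span_a
        never = lambda pa, pb: (False, None)
        complete_block(block, ga, gb, delta2, never, {"a0", "a1"}, {"b0", "b1"})
        assert block.completions == [] and block.span_a == span_before


class TestDeltaCoupling:
    def test_single_delta_equals_explicit_pair(self):
        params = SimParams(n_chromosomes=2, genes_per_chromosome=40,
                           divergence=0.15, n_inversions=2, n_translocations=1,
                           protein_length=(80, 150), seed=5)
        ga, gb, _ = simulate_pair(params)
        rbh = find_rbh(ga, gb, AlignmentParams())
        one = reconstruct_blocks(rbh, ga, gb, SyntenyParams.single_delta(4))
        two = reconstruct_blocks(rbh, ga, gb, SyntenyParams(delta1=4, delta2=4))
        assert [(b.span_a, b.span_b, len(b.anchors), len(b.completions))
                for b in one] == \
               [(b.span_a, b.span_b, len(b.anchors), len(b.completions))
                for b in two]


class TestDeltaMonotonicity:
    def test_syntenic_rbh_nondecreasing_in_delta(self):
        """More permissive Δ never loses syntenic RBH."""
        params = SimParams(n_chromosomes=2, genes_per_chromosome=60,
                           divergence=0.15, n_inversions=3, n_translocations=1,
                           protein_length=(80, 150), seed=21)
        ga, gb, _ = simulate_pair(params)
        rbh = find_rbh(ga, gb, AlignmentParams())
        counts = []
        for delta in range(1, 8):
            blocks = build_blocks(chain_anchors(rbh, ga, gb, delta),
                                  SyntenyParams(delta1=delta))
            counts.append(sum(len(b.anchors) for b in blocks))
        assert counts == sorted(counts)


class TestExtractBreakpoints:
    def _blocks_with_gap(self, rng, gap):
        """Two blocks on A's c1 (partner chromosomes differ in B) separated
        by ``gap`` partner-less genes — a rearrangement-style breakpoint."""
        n = 4 + gap
        prots = [random_protein(rng, 30) for _ in range(n)]
        a_entries = [(f"a{i}", prots[i]) for i in range(n)]
        ga = build_genome("A", {"c1": a_entries}, with_coords=True)
        gb = build_genome("B", {
            "c1": [(f"b{i}", prots[i]) for i in (0, 1)],
            "c2": [(f"b{i}", prots[i]) for i in range(2 + gap, n)]},
            with_coords=True)
        rbh = [make_pair(ga, gb, f"a{i}", f"b{i}")
               for i in list(range(2)) + list(range(2 + gap, n))]
        blocks = build_blocks(chain_anchors(rbh, ga, gb, 1), SyntenyParams())
        return ga, blocks

    def test_gap_gene_count(self, rng):
        ga, blocks = self._blocks_with_gap(rng, gap=3)
        assert len(blocks) == 2
        regions = extract_breakpoints(blocks, ga)
        middle = [r for r in regions
                  if r.left_block != "CHR_START" and r.right_block != "CHR_END"]
        assert len(middle) == 1
        assert middle[0].length_genes == 3
        assert middle[0].gene_ids == ["a2", "a3", "a4"]

    def test_contiguous_blocks_give_zero_length_region(self, rng):
        # split a0,a1 | a2,a3 across two B chromosomes: adjacent spans on A
        prots = [random_protein(rng, 30) for _ in range(4)]
        ga = build_genome("A", {"c1": [(f"a{i}", prots[i]) for i in range(4)]},
                          with_coords=True)
        gb = build_genome("B", {"c1": [(f"b{i}", prots[i]) for i in (0, 1)],
                                "c2": [(f"b{i}", prots[i]) for i in (2, 3)]},
                          with_coords=True)
        rbh = [make_pair(ga, gb, f"a{i}", f"b{i}") for i in range(4)]
        blocks = build_blocks(chain_anchors(rbh, ga, gb, 5), SyntenyParams())
        assert len(blocks) == 2
        regions = extract_breakpoints(blocks, ga)
        middle = [r for r in regions
                  if r.left_block != "CHR_START" and r.right_block != "CHR_END"]
        assert len(middle) == 1
        assert middle[0].length_genes == 0

    def test_rank_axis_tiles_completely(self):
        """Blocks + breakpoints + ends cover every rank exactly once."""
        params = SimParams(n_chromosomes=2, genes_per_chromosome=50,
                           divergence=0.15, n_inversions=2, n_translocations=1,
                           protein_length=(80, 150), seed=9)
        ga, gb, _ = simulate_pair(params)
        rbh = find_rbh(ga, gb, AlignmentParams())
        blocks = reconstruct_blocks(rbh, ga, gb, SyntenyParams.single_delta(5))
        for genome in (ga, gb):
            regions = extract_breakpoints(blocks, genome)
            for chrom, genes in genome.chromosomes.items():
                covered = np.zeros(len(genes), dtype=int)
                for b in blocks:
                    if b.chrom_on(genome.id) == chrom:
                        lo, hi = b.span_on(genome.id)
                        covered[lo:hi + 1] = 1
                for r in regions:
                    if r.chromosome == chrom:
                        lo, hi = r.rank_interval
                        if hi >= lo:
                            assert covered[lo:hi + 1].sum() == 0
                            covered[lo:hi + 1] = 1
                assert covered.all()

    def test_anchor_disjointness_across_blocks(self):
        params = SimParams(n_chromosomes=2, genes_per_chromosome=50,
                           divergence=0.15, n_inversions=3, n_translocations=1,
                           protein_length=(80, 150), seed=13)
        ga, gb, _ = simulate_pair(params)
        rbh = find_rbh(ga, gb, AlignmentParams())
        blocks = reconstruct_blocks(rbh, ga, gb, SyntenyParams.single_delta(5))
        seen = set()
        for b in blocks:
            for a in b.anchors:
                assert a.pair.kind == "RBH"
                assert a.pair.key not in seen
                seen.add(a.pair.key)
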