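"""Block chaining vs exhaustive search, duplication classes, Ks peaks,
fusion counting."""

import itertools

import numpy as np
import pytest

from camgen.simulate import GenomeSimSpec, gen_genome_layout
from camgen.synteny import (AnchorPair, PaintedBlock, anchors_from_hits,
                            best_chain, chain_collinear_blocks,
                            classify_duplications, count_fusions,
                            ks_distribution)


def _anchor(ra, rb, score=1.0, ca="c1", cb="c2"):
    return AnchorPair(f"a{ra}", f"b{rb}", ca, cb, ra, rb, score)


def exhaustive_best_score(anchors, max_gap, gap_penalty, direction):
    """Max chain score over every ordered subset of anchors."""
    best = 0.0
    n = len(anchors)
    for r in range(1, n + 1):
        for subset in itertools.combinations(range(n), r):
            chain = sorted((anchors[i] for i in subset),
                           key=lambda a: a.rank_a)
            ok = True
            score = chain[0].score
            for prev, cur in zip(chain, chain[1:]):
                da = cur.rank_a - prev.rank_a
                db = (cur.rank_b - prev.rank_b) * direction
                if da <= 0 or db <= 0:
                    ok = False
                    break
                g = max(da, db) - 1
                if g > max_gap:
                    ok = False
                    break
                score += cur.score - gap_penalty * g
            if ok:
                best = max(best, score)
    return best


class TestBestChain:
    def test_perfect_diagonal(self):
        anchors = [_anchor(i, i) for i in range(12)]
        blocks = chain_collinear_blocks(anchors, min_block_genes=10, max_gap=4)
        assert len(blocks) == 1
        assert blocks[0].n_genes == 12 and blocks[0].orientation == "same"

    def test_inverted_diagonal(self):
        anchors = [_anchor(i, 11 - i) for i in range(12)]
        blocks = chain_collinear_blocks(anchors, min_block_genes=10, max_gap=4)
        assert len(blocks) == 1 and blocks[0].orientation == "inverted"

    def test_gap_limit_splits_chain(self):
        anchors = [_anchor(i, i) for i in range(5)] + \
                  [_anchor(i + 20, i + 20) for i in range(5)]
        blocks = chain_collinear_blocks(anchors, min_block_genes=4, max_gap=4)
        assert [b.n_genes for b in blocks] == [5, 5]

    def test_empty_input(self):
        assert chain_collinear_blocks([], 5, 4) == []

    @pytest.mark.parametrize("direction", [1, -1])
    def test_matches_exhaustive_search(self, rng, direction):
        for _ in range(60):
            n = int(rng.integers(2, 13))
            coords = set()
            while len(coords) < n:
                coords.add((int(rng.integers(0, 15)),
                            int(rng.integers(0, 15))))
            anchors = [_anchor(ra, rb, float(rng.integers(1, 5)))
                       for ra, rb in coords]
            max_gap = int(rng.integers(0, 5))
            got, chain = best_chain(anchors, max_gap, 1.0, direction)
            want = exhaustive_best_score(anchors, max_gap, 1.0, direction)
            assert got == pytest.approx(want)

    def test_planted_blocks_recovered_at_zero_noise(self):
        spec = GenomeSimSpec(n_tandem_arrays=0, n_collinear_blocks=3,
                             block_length_range=(12, 15),
                             hit_noise_rate=0.0, seed=5)
        layout = gen_genome_layout(spec)
        anchors = anchors_from_hits(layout["annot_a"], layout["annot_b"],
                                    layout["cross_hits"])
        blocks = chain_collinear_blocks(anchors, min_block_genes=11,
                                        max_gap=4)
        got = {frozenset((a.gene_a, a.gene_b) for a in b.anchors)
               for b in blocks}
        want = {frozenset(map(tuple, b["pairs"]))
                for b in layout["truth"]["blocks"]}
        assert got == want  # recall 1.0
        orient = {frozenset(map(tuple, b["pairs"])): b["orientation"]
                  for b in layout["truth"]["blocks"]}
        for b in blocks:
            key = frozenset((a.gene_a, a.gene_b) for a in b.anchors)
            assert b.orientation == orient[key]


class TestClassifyDuplications:
    def _block(self, pairs, ca, cb):
        anchors = tuple(AnchorPair(a, b, ca, cb, i, i)
                        for i, (a, b) in enumerate(pairs))
        from camgen.synteny import CollinearBlock
        return CollinearBlock(anchors, "same")

    def test_intra_chromosomal_is_segmental(self):
        b = self._block([("g1", "g9"), ("g2", "g10")], "c1", "c1")
        classes = classify_duplications([b], tandem_genes=set())
        assert set(classes.values()) == {"segmental"}

    def test_cross_chromosomal_is_interchromosomal(self):
        b = self._block([("g1", "h1")], "c1", "c2")
        assert set(classify_duplications([b], set()).values()) == \
            {"interchromosomal"}

    def test_tandem_pairs_excluded_from_segmental(self):
        b = self._block([("g1", "g2"), ("g3", "g9")], "c1", "c1")
        classes = classify_duplications([b], tandem_genes={"g1", "g2"})
        assert classes[("g1", "g2")] == "tandem"
        assert classes[("g3", "g9")] == "segmental"

    def test_self_diagonal_dropped(self):
        b = self._block([("g1", "g1")], "c1", "c1")
        assert classify_duplications([b], set()) == {}

    def test_matches_rule_oracle_on_random_layouts(self, rng):
        tandem = {f"g{i}" for i in rng.integers(0, 30, size=10)}
        blocks = []
        for _ in range(10):
            ca, cb = f"c{rng.integers(1, 3)}", f"c{rng.integers(1, 3)}"
            pairs = [(f"g{rng.integers(0, 30)}", f"g{rng.integers(0, 30)}")
                     for _ in range(4)]
            blocks.append(self._block(pairs, ca, cb))
        classes = classify_duplications(blocks, tandem)
        for b in blocks:
            for anc in b.anchors:
                if anc.gene_a == anc.gene_b:
                    continue
                key = tuple(sorted((anc.gene_a, anc.gene_b)))
                if anc.chrom_a != anc.chrom_b:
                    want = "interchromosomal"
                elif anc.gene_a in tandem and anc.gene_b in tandem:
                    want = "tandem"
                else:
                    want = "segmental"
                assert classes[key] == want


class TestKsDistribution:
    def test_single_point_mass(self):
        d = ks_distribution([0.1] * 50)
        assert d["modes"][0] == pytest.approx(0.1)

    def test_histogram_mass_conserved(self, rng):
        vals = rng.uniform(0.01, 2.9, size=400)
        d = ks_distribution(vals)
        assert d["counts"].sum() == d["n"] == 400

    def test_bimodal_mixture_mode_recovery(self, rng):
        vals = np.concatenate([rng.normal(0.10, 0.02, 500),
                               rng.normal(0.33, 0.02, 500)])
        d = ks_distribution(vals, bin_width=0.01, ks_max=1.0)
        top2 = sorted(d["modes"][:2])
        assert abs(top2[0] - 0.10) <= 0.02
        assert abs(top2[1] - 0.33) <= 0.02

    def test_saturated_and_out_of_range_excluded(self):
        d = ks_distribution([np.nan, -0.5, 0.2, 5.0], ks_max=3.0)
        assert d["n"] == 1

    def test_empty_input(self):
        d = ks_distribution([])
        assert d["n"] == 0 and d["modes"] == []


class TestCountFusions:
    def _paint(self, labels_per_chrom, n_genes=10):
        return {f"chr{i}": [PaintedBlock((j * 10, j * 10 + 9), lab, n_genes)
                            for j, lab in enumerate(labels)]
                for i, labels in enumerate(labels_per_chrom)}

    def test_one_label_per_chromosome_means_zero(self):
        assert count_fusions(self._paint([["A"], ["B"], ["C"]])) == 0

    def test_two_labels_one_fusion(self):
        assert count_fusions(self._paint([["A", "B"]])) == 1

    def test_counting_identity_21_labels_12_chromosomes(self):
        # 21 ancestral groups on 12 modern chromosomes, one-to-one blocks:
        # sum(d_i - 1) = 21 - 12 = 9
        labels = [f"L{i}" for i in range(21)]
        per_chrom, i = [], 0
        sizes = [2, 2, 2, 2, 2, 2, 2, 2, 2, 1, 1, 1]
        for s in sizes:
            per_chrom.append(labels[i:i + s])
            i += s
        assert sum(sizes) == 21
        assert count_fusions(self._paint(per_chrom)) == 9

    def test_small_blocks_filtered(self):
        paint = {"chr1": [PaintedBlock((0, 9), "A", 10),
                          PaintedBlock((10, 12), "B", 3)]}
        assert count_fusions(paint, min_block_genes=5) == 0
        assert count_fusions(paint, min_block_genes=1) == 1

    def test_empty_chromosome_contributes_zero(self):
        paint = {"chr1": [PaintedBlock((0, 1), "A", 2)],
                 "chr2": []}
        assert count_fusions(paint, min_block_genes=5) == 0
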