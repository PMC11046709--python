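"""Gene ranking, collinear-block chaining, duplicate-gene categories."""

import itertools

import numpy as np
import pytest

from polyfam.duplication_classify import (
    HomologyPair,
    classify_duplicates,
    find_collinear_blocks,
    gene_ranks,
)
from polyfam.io_formats import GeneModel


def make_gene(gid, chrom, start, end=None):
    return GeneModel(variant_id=f"{gid}.1", chrom=chrom, start=start, end=end or start + 100)


# ---------------------------------------------------------------- gene_ranks

def test_gene_ranks_basic_and_ties():
    genes = [
        make_gene("a", "1A", 100),
        make_gene("b", "1A", 500),
        make_gene("c", "1A", 900),
        make_gene("d", "1B", 500, 700),
        make_gene("e", "1B", 500, 600),  # same start, earlier end -> lower rank
    ]
    ranks = gene_ranks(genes)
    assert ranks["a"] == ("1A", 0) and ranks["b"] == ("1A", 1) and ranks["c"] == ("1A", 2)
    assert ranks["e"][1] < ranks["d"][1]


def test_gene_ranks_order_invariant():
    rng = np.random.default_rng(3)
    genes = [make_gene(f"g{i}", "2A", int(s)) for i, s in enumerate(rng.choice(10**6, 50, replace=False))]
    ref = gene_ranks(genes)
    shuffled = list(genes)
    rng.shuffle(shuffled)
    assert gene_ranks(shuffled) == ref


# --------------------------------------------------------------------- blocks

def _linear_instance(n, chrom_a="1A", chrom_b="1B", invert=False):
    genes, pairs = [], []
    for i in range(n):
        genes.append(make_gene(f"a{i}", chrom_a, 1000 * (i + 1)))
        genes.append(make_gene(f"b{i}", chrom_b, 1000 * (i + 1)))
    order = range(n - 1, -1, -1) if invert else range(n)
    for i, j in zip(range(n), order):
        pairs.append((f"a{i}", f"b{j}", 1.0))
    return genes, pairs


def test_monotone_chain_forms_one_block():
    genes, pairs = _linear_instance(6)
    blocks = find_collinear_blocks(gene_ranks(genes), pairs, min_block=5)
    assert len(blocks) == 1
    assert len(blocks[0].anchor_pairs) == 6
    assert blocks[0].orientation == "same"


def test_reversed_ranks_give_inverted_block():
    genes, pairs = _linear_instance(6, invert=True)
    blocks = find_collinear_blocks(gene_ranks(genes), pairs, min_block=5)
    assert len(blocks) == 1 and blocks[0].orientation == "inverted"


def test_short_chain_discarded():
    genes, pairs = _linear_instance(4)
    assert find_collinear_blocks(gene_ranks(genes), pairs, min_block=5) == []


def test_unknown_gene_in_pairs_errors():
    genes, pairs = _linear_instance(6)
    pairs.append(("a0", "ghost", 1.0))
    with pytest.raises(KeyError, match="ghost"):
        find_collinear_blocks(gene_ranks(genes), pairs)


def _bruteforce_best_chain(anchors, max_gap):
    """Max-score chain by exhaustive enumeration over all anchor subsets."""
    best = 0.0
    idx = range(len(anchors))
    for r in range(1, len(anchors) + 1):
        for combo in itertools.combinations(idx, r):
            chosen = sorted((anchors[i] for i in combo), key=lambda a: a[0])
            if any(
                not (0 < ra2 - ra1 <= max_gap)
                for (ra1, _, _), (ra2, _, _) in zip(chosen, chosen[1:])
            ):
                continue
            diffs = [b2 - b1 for (_, b1, _), (_, b2, _) in zip(chosen, chosen[1:])]
            if diffs and not (
                all(0 < d <= max_gap for d in diffs)
                or all(-max_gap <= d < 0 for d in diffs)
            ):
                continue
            best = max(best, sum(a[2] for a in chosen))
    return best


def test_chain_dp_matches_bruteforce_on_random_instances():
    from polyfam.duplication_classify import _chain_anchors

    rng = np.random.default_rng(11)
    for _ in range(200):
        n = int(rng.integers(2, 9))
        max_gap = int(rng.integers(2, 8))
        anchors = [
            (int(rng.integers(0, 12)), int(rng.integers(0, 12)), float(rng.integers(1, 4)))
            for _ in range(n)
        ]
        # deduplicate identical (ra, rb) anchors to keep the instance well-posed
        anchors = [(ra, rb, s, HomologyPair(f"x{ra}", f"y{rb}", s)) for ra, rb, s in
                   {(ra, rb): (ra, rb, s) for ra, rb, s in anchors}.values()]
        score, chain, _ = _chain_anchors(anchors, min_block=1, max_gap=max_gap)
        brute = _bruteforce_best_chain([(a[0], a[1], a[2]) for a in anchors], max_gap)
        assert score == pytest.approx(brute)


# ---------------------------------------------------------------- categories

def test_tandem_and_proximal_examples():
    genes = [make_gene(f"g{i}", "5B", 1000 * (i + 1)) for i in range(8)]
    pairs = [("g0", "g1", 1.0), ("g2", "g7", 1.0)]
    cats = {d.gene_id: d.category for d in classify_duplicates(gene_ranks(genes), pairs, [])}
    assert cats["g0"] == cats["g1"] == "tandem"
    assert cats["g2"] == cats["g7"] == "proximal"  # 5 ranks apart, gap 10
    assert cats["g3"] == "singleton"


def test_dispersed_and_block_precedence():
    genes, pairs = _linear_instance(6)
    genes.append(make_gene("far", "7D", 50))
    pairs.append(("a0", "far", 1.0))
    ranks = gene_ranks(genes)
    blocks = find_collinear_blocks(ranks, pairs, min_block=5)
    cats = {d.gene_id: d.category for d in classify_duplicates(ranks, pairs, blocks)}
    assert cats["a0"] == "wgd_segmental"  # block membership wins
    assert cats["far"] == "dispersed"


def test_category_partition_and_order_invariance():
    genes, pairs = _linear_instance(6)
    genes += [make_gene("t0", "1A", 1100), make_gene("lone", "3D", 9)]
    pairs.append(("a0", "t0", 1.0))
    ranks = gene_ranks(genes)
    blocks = find_collinear_blocks(ranks, pairs, min_block=5)
    ref = classify_duplicates(ranks, pairs, blocks)
    assert len(ref) == len(ranks)
    rng = np.random.default_rng(0)
    shuffled = list(pairs)
    rng.shuffle(shuffled)
    blocks2 = find_collinear_blocks(ranks, shuffled, min_block=5)
    assert classify_duplicates(ranks, shuffled, blocks2) == ref


def test_planted_categories_recovered(small_sim):
    from polyfam.duplication_classify import gene_ranks as gr

    truth = small_sim.truth_by_gene()
    ranks = gr(small_sim.genes)
    blocks = find_collinear_blocks(ranks, small_sim.pairs)
    for d in classify_duplicates(ranks, small_sim.pairs, blocks):
        assert d.category == truth[d.gene_id].dup_category
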