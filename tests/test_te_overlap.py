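"""TE insertion / spanning / flanking classification and summaries."""

import numpy as np
import pytest

from polyfam.io_formats import GeneModel, TEFeature
from polyfam.te_overlap import classify_te, merge_intervals, summarize_te


def make_gene(start=10_000, end=14_000, strand="+", chrom="2B"):
    mid = (start + end) // 2
    return GeneModel(
        variant_id="g.1",
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        exons=[(start, mid - 500), (mid + 500, end)],
        cds=[(start + 100, mid - 500), (mid + 500, end - 200)],
        utr5=[(start, start + 99)],
        utr3=[(end - 199, end)],
    )


def te(start, end, chrom="2B"):
    return TEFeature(chrom=chrom, start=start, end=end)


def test_te_inside_intron():
    g = make_gene()
    st = classify_te(g, [te(11_600, 12_300)])  # intron is (11501, 12499)
    assert st.inside and st.inside_where == {"intron"}
    assert not (st.spanning or st.flank5 or st.flank3)


def test_te_touching_exon_and_utr():
    g = make_gene()
    st = classify_te(g, [te(10_050, 10_200)])
    assert st.inside and {"exon", "utr5"} <= st.inside_where


def test_spanning_excludes_inside():
    g = make_gene()
    st = classify_te(g, [te(9_000, 15_000)])
    assert st.spanning and not st.inside
    assert not st.flank_any


def test_window_boundary_exclusive():
    g = make_gene()
    just_in = classify_te(g, [te(7_500, 8_000)])  # 2000 bp upstream exactly
    just_out = classify_te(g, [te(7_400, 7_999)])  # 2001 bp upstream
    assert just_in.flank5
    assert not just_out.flank5


def test_strand_swaps_flanks():
    plus = classify_te(make_gene(strand="+"), [te(8_500, 9_000)])
    minus = classify_te(make_gene(strand="-"), [te(8_500, 9_000)])
    assert plus.flank5 and not plus.flank3
    assert minus.flank3 and not minus.flank5


def test_boundary_te_counts_inside_only():
    g = make_gene()
    st = classify_te(g, [te(9_500, 10_500)])  # crosses the gene start
    assert st.inside and not st.flank5


def test_window_must_be_positive():
    with pytest.raises(ValueError):
        classify_te(make_gene(), [], window=0)


def test_translation_invariance():
    g = make_gene()
    tes = [te(8_500, 9_000), te(11_600, 12_300), te(14_500, 15_000)]
    ref = classify_te(g, tes)
    shift = 123_456
    g2 = GeneModel(
        variant_id=g.variant_id, chrom=g.chrom,
        start=g.start + shift, end=g.end + shift, strand=g.strand,
        exons=[(s + shift, e) for s, e in ((s, e + shift) for s, e in g.exons)],
        cds=[(s + shift, e + shift) for s, e in g.cds],
        utr5=[(s + shift, e + shift) for s, e in g.utr5],
        utr3=[(s + shift, e + shift) for s, e in g.utr3],
    )
    moved = classify_te(g2, [te(s + shift, e + shift) for _, s, e in ((0, t.start, t.end) for t in tes)])
    assert (ref.inside, ref.spanning, ref.flank5, ref.flank3, ref.inside_where) == (
        moved.inside, moved.spanning, moved.flank5, moved.flank3, moved.inside_where
    )


def test_mirroring_genome_swaps_flanks():
    genome_len = 1_000_000
    g = make_gene()
    tes = [te(8_500, 9_000), te(14_200, 14_600)]
    ref = classify_te(g, tes)

    def mirror(s, e):
        return genome_len - e + 1, genome_len - s + 1

    g_m = GeneModel(
        variant_id=g.variant_id, chrom=g.chrom,
        start=mirror(g.start, g.end)[0], end=mirror(g.start, g.end)[1],
        strand="-" if g.strand == "+" else "+",
        exons=sorted(mirror(s, e) for s, e in g.exons),
        cds=sorted(mirror(s, e) for s, e in g.cds),
        utr5=sorted(mirror(s, e) for s, e in g.utr5),
        utr3=sorted(mirror(s, e) for s, e in g.utr3),
    )
    mirrored = classify_te(g_m, [te(*mirror(t.start, t.end)) for t in tes])
    assert (mirrored.flank5, mirrored.flank3) == (ref.flank5, ref.flank3)
    assert (mirrored.inside, mirrored.spanning) == (ref.inside, ref.spanning)


def test_adding_te_is_monotone():
    """Adding TEs never withdraws an (inside-or-spanning) or any-proximity call."""
    rng = np.random.default_rng(9)
    g = make_gene()
    for _ in range(100):
        base = [te(int(s), int(s) + int(l)) for s, l in zip(
            rng.integers(5_000, 18_000, size=3), rng.integers(50, 3_000, size=3))]
        extra = te(int(rng.integers(5_000, 18_000)), int(rng.integers(5_000, 18_000)) + 500)
        before = classify_te(g, base)
        after = classify_te(g, base + [extra])
        assert (before.inside or before.spanning) <= (after.inside or after.spanning)
        assert (before.inside or before.spanning or before.flank_any) <= (
            after.inside or after.spanning or after.flank_any
        )


def test_merge_intervals():
    assert merge_intervals([(5, 10), (8, 12), (20, 30)]) == [(5, 12), (20, 30)]
    assert merge_intervals([(1, 2), (3, 4)]) == [(1, 4)]  # bookended intervals fuse


# ------------------------------------------------------------------- summary

def test_summary_derived_counts():
    genes = [make_gene(start=100_000 * i + 10_000, end=100_000 * i + 14_000) for i in range(10)]
    for i, g in enumerate(genes):
        g.variant_id = f"g{i}.1"
    tes = []
    for i in range(4):  # planted inside
        tes.append(te(genes[i].start + 1_650, genes[i].start + 2_100))
    for i in range(9):  # planted flanking (gene 9 left bare)
        tes.append(te(genes[i].start - 900, genes[i].start - 400))
    statuses = [classify_te(g, tes) for g in genes]
    (summary,) = summarize_te(statuses)
    assert summary.pct_inside == 40.0
    assert summary.pct_flanking == 90.0


def test_summary_no_tes():
    statuses = [classify_te(make_gene(), [])]
    (summary,) = summarize_te(statuses)
    assert (summary.pct_inside, summary.pct_flanking) == (0.0, 0.0)


def test_summary_saturated_flanking():
    genes = [make_gene(start=100_000 * i + 10_000, end=100_000 * i + 14_000) for i in range(5)]
    for i, g in enumerate(genes):
        g.variant_id = f"g{i}.1"
    tes = [te(g.start - 500, g.start - 100) for g in genes] + [
        te(g.end + 100, g.end + 500) for g in genes
    ]
    (summary,) = summarize_te([classify_te(g, tes) for g in genes])
    assert summary.pct_flanking == 100.0


def test_planted_te_statuses_recovered(small_sim):
    truth = small_sim.truth_by_gene()
    by_chrom = {}
    for t in small_sim.tes:
        by_chrom.setdefault(t.chrom, []).append(t)
    for g in small_sim.genes:
        st = classify_te(g, by_chrom.get(g.chrom, []))
        tr = truth[g.gene_id]
        assert (st.inside, st.spanning, st.flank5, st.flank3) == (
            tr.te_inside, tr.te_spanning, tr.te_flank5, tr.te_flank3
        )
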