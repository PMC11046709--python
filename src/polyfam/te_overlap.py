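"""Transposable-element proximity classification for gene models.

Each gene is placed into mutually exclusive display classes with respect to
the merged TE annotation: a TE *spanning* the whole gene, a TE insertion
*inside* the gene body, or TEs *flanking* the gene within a window (2 kb by
default) upstream and/or downstream.  Nested or fragmented TE models are
flattened by merging overlapping intervals of any class before
classification, and a TE that crosses a gene boundary counts as inside
only, never as flanking.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import GeneModel, TEFeature

__all__ = ["TEStatus", "TESummary", "merge_intervals", "classify_te", "summarize_te"]


@dataclass
class TEStatus:
    gene_id: str
    inside: bool
    inside_where: frozenset[str]  # subset of {intron, exon, utr5, utr3}
    spanning: bool
    flank5: bool
    flank3: bool

    @property
    def flank_any(self) -> bool:
        return self.flank5 or self.flank3


@dataclass
class TESummary:
    clade: str
    n_genes: int
    pct_inside: float
    pct_flanking: float


def merge_intervals(intervals):
    """Union of 1-based inclusive intervals (sorted, non-overlapping)."""
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(i) for i in merged]


def _overlaps(a, b) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def classify_te(
    gene: GeneModel,
    te_features: list[TEFeature],
    window: int = 2000,
    anchor: str = "gene",
) -> TEStatus:
    """Classify one gene's TE relationship.

    ``anchor`` selects the reference bounds for the flanking windows: the
    gene body (``gene``, default) or the CDS span (``cds``).  Windows are
    strand-aware: the 5' window sits upstream of the gene start on plus
    strand and upstream of the gene end on minus strand.  Overlap means one
    or more shared bases; the flanking window excludes the gene body.
    """
    if window <= 0:
        raise ValueError(f"flanking window must be positive, got {window}")
    if anchor == "cds" and gene.cds:
        lo, hi = gene.cds[0][0], gene.cds[-1][1]
    else:
        lo, hi = gene.start, gene.end
    body = (gene.start, gene.end)
    tes = merge_intervals(
        [(t.start, t.end) for t in te_features if t.chrom == gene.chrom]
    )

    spanning = any(s <= body[0] and e >= body[1] for s, e in tes)
    body_hits = [iv for iv in tes if _overlaps(iv, body)]
    inside = bool(body_hits) and not spanning

    where = set()
    if inside:
        feature_sets = {
            "exon": gene.exons,
            "utr5": gene.utr5,
            "utr3": gene.utr3,
            "intron": gene.introns(),
        }
        for iv in body_hits:
            for name, ivals in feature_sets.items():
                if any(_overlaps(iv, f) for f in ivals):
                    where.add(name)

    left = (lo - window, lo - 1)
    right = (hi + 1, hi + window)
    flank_left = any(
        _overlaps(iv, left) and not _overlaps(iv, body) for iv in tes
    )
    flank_right = any(
        _overlaps(iv, right) and not _overlaps(iv, body) for iv in tes
    )
    if gene.strand == "-":
        flank5, flank3 = flank_right, flank_left
    else:
        flank5, flank3 = flank_left, flank_right

    return TEStatus(
        gene_id=gene.gene_id,
        inside=inside,
        inside_where=frozenset(where),
        spanning=spanning,
        flank5=flank5,
        flank3=flank3,
    )


def summarize_te(
    statuses: list[TEStatus],
    clades: dict[str, str] | None = None,
    flanking_includes_spanning: bool = True,
) -> list[TESummary]:
    """Per-clade percentage of genes with a TE inside and with flanking TEs
    (1-decimal rounding), plus an ``all`` row over every gene.

    With ``flanking_includes_spanning`` (default) a gene entirely contained
    in a TE counts toward the flanking share as well.
    """
    clades = clades or {}
    buckets: dict[str, list[TEStatus]] = {"all": list(statuses)}
    for st in statuses:
        clade = clades.get(st.gene_id)
        if clade is not None:
            buckets.setdefault(clade, []).append(st)
    out = []
    for clade in sorted(buckets):
        members = buckets[clade]
        n = len(members)
        if n == 0:
            continue
        n_inside = sum(st.inside for st in members)
        n_flank = sum(
            st.flank_any or (flanking_includes_spanning and st.spanning)
            for st in members
        )
        out.append(
            TESummary(
                clade=clade,
                n_genes=n,
                pct_inside=round(100.0 * n_inside / n, 1),
                pct_flanking=round(100.0 * n_flank / n, 1),
            )
        )
    return out
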