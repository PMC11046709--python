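"""Collinear-block detection and duplicate-gene classification.

A dialect of the MCScanX procedure: homologous gene pairs are chained by a
weighted dynamic program over gene ranks (order on the chromosome), maximal
chains with bounded rank gaps become collinear blocks, and every gene is
then assigned one duplication category by precedence

    wgd_segmental > tandem > proximal > dispersed > singleton.

Anchors are restricted to inter-chromosomal pairs; same-chromosome pairs
within the tandem rank distance are stripped before chaining, as MCScanX
does, so tandem arrays do not masquerade as segmental blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "HomologyPair",
    "CollinearBlock",
    "DupClass",
    "gene_ranks",
    "find_collinear_blocks",
    "classify_duplicates",
    "CATEGORY_ORDER",
]

CATEGORY_ORDER = ("wgd_segmental", "tandem", "proximal", "dispersed", "singleton")


@dataclass(frozen=True)
class HomologyPair:
    gene_a: str
    gene_b: str
    score: float = 1.0

    def key(self) -> frozenset:
        return frozenset((self.gene_a, self.gene_b))


@dataclass
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    anchor_pairs: list[HomologyPair]
    orientation: str  # "same" | "inverted"
    score: float = 0.0

    def genes(self) -> set[str]:
        out = set()
        for p in self.anchor_pairs:
            out.add(p.gene_a)
            out.add(p.gene_b)
        return out


@dataclass(frozen=True)
class DupClass:
    gene_id: str
    category: str


def gene_ranks(genes) -> dict[str, tuple[str, int]]:
    """Rank = 0-based ordinal of the gene start on its chromosome.

    ``genes`` yields objects with gene_id/chrom/start/end (GeneModel works);
    ties on start are broken by end, then id, so ranks are deterministic
    under any input order.  Splice variants of one gene collapse to a single
    ranked entry (leftmost variant wins).
    """
    per_gene: dict[str, tuple[str, int, int]] = {}
    for g in genes:
        gid = g.gene_id
        rec = (g.chrom, g.start, g.end)
        if gid not in per_gene or rec < per_gene[gid]:
            per_gene[gid] = rec
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gid, (chrom, start, end) in per_gene.items():
        by_chrom.setdefault(chrom, []).append((start, end, gid))
    ranks = {}
    for chrom, entries in by_chrom.items():
        for rank, (_s, _e, gid) in enumerate(sorted(entries)):
            ranks[gid] = (chrom, rank)
    return ranks


def _normalize_pairs(pairs) -> list[HomologyPair]:
    out = []
    seen = set()
    for p in pairs:
        if not isinstance(p, HomologyPair):
            a, b, *rest = p
            p = HomologyPair(a, b, rest[0] if rest else 1.0)
        if p.gene_a == p.gene_b:
            continue
        k = p.key()
        if k in seen:
            continue
        seen.add(k)
        out.append(p)
    return out


def _chain_anchors(anchors, min_block, max_gap):
    """Best chain (max total score) of anchors with strictly increasing rank
    on the first chromosome, strictly monotone rank on the second, and rank
    gaps <= max_gap on both.  ``anchors`` are (ra, rb, score, pair) tuples.
    Returns (score, [indices]) of the best chain for each orientation.
    """
    best = (0.0, [], "same")
    for direction in (+1, -1):
        order = sorted(
            range(len(anchors)), key=lambda i: (anchors[i][0], direction * anchors[i][1])
        )
        dp = [anchors[i][2] for i in order]
        back = [-1] * len(order)
        for j in range(len(order)):
            ra_j, rb_j, s_j, _ = anchors[order[j]]
            for i in range(j):
                ra_i, rb_i, _, _ = anchors[order[i]]
                if ra_j <= ra_i or ra_j - ra_i > max_gap:
                    continue
                if direction * (rb_j - rb_i) <= 0 or abs(rb_j - rb_i) > max_gap:
                    continue
                if dp[i] + s_j > dp[j]:
                    dp[j] = dp[i] + s_j
                    back[j] = i
        if dp:
            j = max(range(len(order)), key=lambda k: dp[k])
            chain = []
            while j != -1:
                chain.append(order[j])
                j = back[j]
            chain.reverse()
            score = sum(anchors[i][2] for i in chain)
            if len(chain) >= min_block and (
                score > best[0]
                or (score == best[0] and direction == +1 and not best[1])
            ):
                best = (score, chain, "same" if direction == +1 else "inverted")
    return best


def find_collinear_blocks(
    ranks: dict[str, tuple[str, int]],
    pairs,
    min_block: int = 5,
    max_gap: int = 25,
    tandem_gap: int = 1,
) -> list[CollinearBlock]:
    """Chain homology pairs into collinear blocks per chromosome pair.

    Each anchor is assigned to at most one block: chains are extracted
    greedily best-score-first (ties to the leftmost start) until no chain of
    ``min_block`` anchors remains.  Intra-chromosomal pairs are not anchors
    in this dialect.
    """
    unknown = {
        g for p in _normalize_pairs(pairs) for g in (p.gene_a, p.gene_b)
    } - set(ranks)
    if unknown:
        raise KeyError(
            f"genes in homology pairs but absent from ranks: {sorted(unknown)[:5]}"
        )
    by_cpair: dict[tuple[str, str], list] = {}
    for p in _normalize_pairs(pairs):
        ca, ra = ranks[p.gene_a]
        cb, rb = ranks[p.gene_b]
        if ca == cb:
            continue  # intra-chromosomal pairs feed tandem/proximal calls only
        if (ca, p.gene_a) > (cb, p.gene_b):
            ca, cb, ra, rb = cb, ca, rb, ra
            p = HomologyPair(p.gene_b, p.gene_a, p.score)
        by_cpair.setdefault((ca, cb), []).append((ra, rb, p.score, p))

    blocks: list[CollinearBlock] = []
    for (ca, cb), anchors in sorted(by_cpair.items()):
        pool = sorted(anchors)
        while True:
            score, chain_idx, orientation = _chain_anchors(pool, min_block, max_gap)
            if not chain_idx:
                break
            chain = [pool[i] for i in chain_idx]
            blocks.append(
                CollinearBlock(
                    chrom_a=ca,
                    chrom_b=cb,
                    anchor_pairs=[c[3] for c in chain],
                    orientation=orientation,
                    score=score,
                )
            )
            used = set(chain_idx)
            pool = [a for i, a in enumerate(pool) if i not in used]
    blocks.sort(key=lambda b: (-b.score, b.chrom_a, b.chrom_b))
    return blocks


def classify_duplicates(
    ranks: dict[str, tuple[str, int]],
    pairs,
    blocks: list[CollinearBlock],
    proximal_gap: int = 10,
    tandem_gap: int = 1,
) -> list[DupClass]:
    """One duplication category per ranked gene, by precedence.

    Block anchors are whole-genome/segmental duplicates; otherwise a
    same-chromosome homolog within ``tandem_gap`` ranks makes a tandem, within
    ``proximal_gap`` a proximal, any remaining homolog a dispersed duplicate,
    and a gene without relatives is a singleton (the survey's "orphan").
    """
    pairs = _normalize_pairs(pairs)
    unknown = {g for p in pairs for g in (p.gene_a, p.gene_b)} - set(ranks)
    if unknown:
        raise KeyError(f"gene {sorted(unknown)[0]!r} appears in pairs but not in ranks")
    anchor_genes = set()
    for b in blocks:
        anchor_genes |= b.genes()
    neighbors: dict[str, list[str]] = {g: [] for g in ranks}
    for p in pairs:
        neighbors[p.gene_a].append(p.gene_b)
        neighbors[p.gene_b].append(p.gene_a)

    out = []
    for gene in sorted(ranks):
        chrom, rank = ranks[gene]
        if gene in anchor_genes:
            category = "wgd_segmental"
        else:
            homs = neighbors[gene]
            same = [
                abs(ranks[h][1] - rank)
                for h in homs
                if ranks[h][0] == chrom
            ]
            if any(d <= tandem_gap for d in same):
                category = "tandem"
            elif any(d <= proximal_gap for d in same):
                category = "proximal"
            elif homs:
                category = "dispersed"
            else:
                category = "singleton"
        out.append(DupClass(gene_id=gene, category=category))
    return out
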