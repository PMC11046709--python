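"""Homeolog group construction and A:B:D triad-ratio classification.

In hexaploid wheat every gene has potential homeologous copies on the A, B
and D subgenomes.  A homeolog group is the connected component of genes
linked by collinear-block anchors and by tandem/proximal duplication pairs;
its A:B:D copy counts (distinct genes per subgenome, unplaced-chromosome
members excluded) classify the group into the standard ratio categories:

=================  =====================================================
balanced_111       equal non-zero copy number in all three subgenomes
                   (1:1:1, or k:k:k for a stack of k complete triads)
expanded_n11       exactly one subgenome expanded (n:1:1 family)
missing_110        exactly one subgenome copy lost (1:1:0 family)
orphan_singleton   only one subgenome represented
other              any other non-zero pattern
not_categorized    no placeable member, or unresolvable clade mix
=================  =====================================================

The k:k:k reading of "balanced" follows the survey's own accounting, where
a pair of complete triads duplicated in tandem is still an even group.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import networkx as nx

from .io_formats import CatalogueRow, parse_subgenome, strip_splice_suffix

__all__ = [
    "HomeologGroup",
    "TriadSummary",
    "CATEGORIES",
    "GENOME_WIDE_REFERENCE",
    "classify_ratio",
    "counts_from_triad_cell",
    "build_groups",
    "groups_from_catalogue",
    "summarize",
]

CATEGORIES = (
    "balanced_111",
    "expanded_n11",
    "missing_110",
    "orphan_singleton",
    "other",
    "not_categorized",
)

#: genome-wide shares (%) of wheat homeolog groups per category (IWGSC 2018),
#: emitted as the static comparison column of the summary table.
GENOME_WIDE_REFERENCE = {
    "balanced_111": 35.8,
    "expanded_n11": 5.7,
    "missing_110": 13.2,
    "orphan_singleton": 37.1,
    "other": 8.0,
    "not_categorized": None,
}


@dataclass
class HomeologGroup:
    group_id: str
    member_genes: set[str]
    counts: tuple[int, int, int]  # distinct genes on A, B, D (U excluded)
    clade: str | None = None
    u_members: set[str] = field(default_factory=set)
    mixed_clade: bool = False

    @property
    def category(self) -> str:
        if self.mixed_clade:
            return "not_categorized"
        return classify_ratio(self.counts)


@dataclass
class TriadSummary:
    clade: str
    counts: dict[str, int]
    percentages: dict[str, float]
    total: int


def classify_ratio(counts: tuple[int, int, int]) -> str:
    """Total classification of a non-negative A:B:D copy-count triple."""
    a, b, d = counts
    if min(counts) < 0:
        raise ValueError(f"negative copy count in {counts}")
    present = sum(c > 0 for c in counts)
    if present == 0:
        return "not_categorized"
    if present == 1:
        return "orphan_singleton"
    if a == b == d:
        return "balanced_111"
    if present == 2 and sorted(counts) == [0, 1, 1]:
        return "missing_110"
    if present == 3 and sorted(counts)[:2] == [1, 1]:
        return "expanded_n11"
    return "other"


# ---------------------------------------------------------------------------
# parsing the catalogue's per-subgenome layout cell
# ---------------------------------------------------------------------------

_SUFFIXES = ("tan", "dis", "prox")


def counts_from_triad_cell(cell: str) -> tuple[int, int, int] | None:
    """A:B:D copy counts from a subgenome-layout cell like
    ``A(Adis)/b(Btan)(Btan)(Bdis)/-``.

    The three slash-separated slots are the A, B and D subgenomes in order
    (slot position, not chromosome letter, decides the subgenome — homeologs
    translocated to another subgenome's chromosome still occupy their slot).
    Inside a slot, the bare text and every parenthesised token each
    contribute their subgenome letters as copies; tokens containing U/u are
    unplaced-chromosome members and are excluded.  Returns None when the
    cell is empty or marked not-categorizable.
    """
    text = cell.strip()
    if not text or text.lower().startswith("not categorized"):
        return None
    text = text.split(";")[0]  # drop trailing annotations such as translocation notes
    slots = [s.strip() for s in text.split("/")]
    if len(slots) != 3:
        return None
    counts = []
    for slot in slots:
        n = 0
        for tok in re.findall(r"\(([^)]*)\)", slot):
            n += _slot_token_copies(tok)
        outside = re.sub(r"\([^)]*\)", "", slot)
        n += _slot_token_copies(outside)
        counts.append(n)
    return tuple(counts)


def _slot_token_copies(token: str) -> int:
    """Copies encoded by one layout token: ``Btan`` -> 1, ``bBbB`` -> 4,
    ``4D`` -> 1, ``DUn`` -> 1 (the Un member is unplaced), ``udis`` -> 0.

    The tandem/dispersed/proximal suffix is stripped before counting because
    its letters ('a', 'd') collide with subgenome letters; U/u members are
    simply never counted.
    """
    t = token.strip().strip(".")
    if not t or t == "-":
        return 0
    for suf in _SUFFIXES:
        if t.lower().endswith(suf):
            t = t[: -len(suf)]
    t = re.sub(r"\d", "", t)
    return sum(1 for c in t if c in "ABDabd")


# ---------------------------------------------------------------------------
# group construction
# ---------------------------------------------------------------------------

def build_groups(
    genes,
    pairs,
    blocks,
    clades: dict[str, str] | None = None,
    proximal_gap: int = 10,
) -> list[HomeologGroup]:
    """Connected-component homeolog groups.

    Edges are collinear-block anchor pairs plus homology pairs lying within
    ``proximal_gap`` ranks on one chromosome (tandem/proximal duplicates).
    Genes without edges form singleton groups.  A group's clade is the
    majority member clade; an exact tie marks the group unresolvable
    (``not_categorized``).  Copy counts are distinct genes per subgenome;
    unplaced (U) members are listed but never counted.
    """
    from .duplication_classify import gene_ranks, _normalize_pairs

    gene_list = list(genes)
    ranks = gene_ranks(gene_list)
    subgenome = {}
    for g in gene_list:
        subgenome[g.gene_id] = parse_subgenome(g.chrom)
    clades = clades or {}

    graph = nx.Graph()
    graph.add_nodes_from(ranks)
    for b in blocks:
        for p in b.anchor_pairs:
            graph.add_edge(p.gene_a, p.gene_b)
    for p in _normalize_pairs(pairs):
        if p.gene_a not in ranks or p.gene_b not in ranks:
            continue
        ca, ra = ranks[p.gene_a]
        cb, rb = ranks[p.gene_b]
        if ca == cb and abs(ra - rb) <= proximal_gap:
            graph.add_edge(p.gene_a, p.gene_b)

    groups = []
    for i, comp in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0]), 1
    ):
        counts = {"A": 0, "B": 0, "D": 0}
        u_members = set()
        for gid in comp:
            sg = subgenome.get(gid, "U")
            if sg == "U":
                u_members.add(gid)
            else:
                counts[sg] += 1
        member_clades = [clades[g] for g in comp if g in clades]
        clade, mixed = None, False
        if member_clades:
            tally: dict[str, int] = {}
            for c in member_clades:
                tally[c] = tally.get(c, 0) + 1
            top = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
            clade = top[0][0]
            mixed = len(top) > 1 and top[0][1] == top[1][1]
        groups.append(
            HomeologGroup(
                group_id=f"HG{i:04d}",
                member_genes=set(comp),
                counts=(counts["A"], counts["B"], counts["D"]),
                clade=None if mixed else clade,
                u_members=u_members,
                mixed_clade=mixed,
            )
        )
    return groups


def groups_from_catalogue(rows: list[CatalogueRow]) -> list[HomeologGroup]:
    """Homeolog groups straight from the packaged catalogue: the group index
    supplies the grouping and the subgenome-layout cell supplies the copy
    counts, bypassing synteny computation."""
    by_index: dict[int, list[CatalogueRow]] = {}
    for r in rows:
        by_index.setdefault(r.group_index, []).append(r)
    groups = []
    for idx in sorted(by_index):
        members = by_index[idx]
        counts = counts_from_triad_cell(members[0].triad_abd)
        genes = {r.gene_id for r in members}
        u_members = {
            strip_splice_suffix(r.variant_id)
            for r in members
            if r.variant_id.startswith("TraesCSU")
        }
        groups.append(
            HomeologGroup(
                group_id=f"T2G{idx:03d}",
                member_genes=genes,
                counts=counts if counts is not None else (0, 0, 0),
                clade=members[0].clade,
                u_members=u_members,
            )
        )
    return groups


# ---------------------------------------------------------------------------
# per-clade summary
# ---------------------------------------------------------------------------

def _round2(x: float) -> float:
    return float(Decimal(str(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize(groups: list[HomeologGroup]) -> list[TriadSummary]:
    """Per-clade category counts and percentages (half-up, 2 decimals).

    Groups without a clade label are pooled under clade ``"?"``.  Clades
    with zero groups are omitted.
    """
    by_clade: dict[str, list[HomeologGroup]] = {}
    for g in groups:
        by_clade.setdefault(g.clade or "?", []).append(g)
    out = []
    for clade in sorted(by_clade):
        members = by_clade[clade]
        counts = {c: 0 for c in CATEGORIES}
        for g in members:
            counts[g.category] += 1
        total = len(members)
        pct = {c: _round2(100.0 * n / total) for c, n in counts.items()}
        out.append(TriadSummary(clade=clade, counts=counts, percentages=pct, total=total))
    return out
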