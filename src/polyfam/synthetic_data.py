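"""Synthetic allopolyploid genome generator with planted ground truth.

Emulates the structure the survey assumes in a hexaploid genome: three
subgenomes (A, B, D) of up to seven chromosomes, ancestral homeolog groups
instantiated at collinear positions across subgenomes, tandem/proximal/
dispersed duplicate copies, motif-ablated ("nc") proteins, transposable
elements planted inside or flanking genes, and cis-elements planted in
promoters.  Every emitted file is mutually consistent: the CDS extracted
from the genome per the GFF3 translates to the emitted protein, and the
homology pairs are the generating truth.

Planted truth is derived analytically from the layout (anchor runs, rank
distances) rather than by running the analysis pipeline, so end-to-end
recovery tests compare two independent routes to the same answer.

Protein scaffold: a 420-residue template with the FAD-binding GxGxxG at
residue 15, the FMO-identifying motif at 170, the NAD(P)H-binding GxGxxG at
190 and an ATG-containing pentamer at 330; background residues are drawn
from an alphabet without G so no motif can arise by chance.  Non-canonical
copies have the first residue of one required motif substituted by alanine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import GeneModel, TEFeature, write_fasta, write_gff3, write_pairs_tsv, write_tsv
from .promoter_care import DEFAULT_CARES, revcomp
from .triad_classify import classify_ratio

__all__ = ["SimConfig", "GeneTruth", "SimResult", "simulate", "write_outputs", "corrupt"]

# background alphabet deliberately omits G (and F/H/W/Y) so the four motif
# grammars cannot match outside the planted sites
BACKGROUND_AA = "ACDEIKLMNPQRSTV"
SCAFFOLD_LEN = 420
FAD_POS, IDENT_POS, NADPH_POS, ATG_POS = 15, 170, 190, 330
ATG_PLANT_CHOICES = ("FATGY", "LATGY", "MATGY", "HCTGY", "YCTGY", "LATGF", "FGTGF")

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"], "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SimConfig:
    """Study conditions for one synthetic genome.

    Defaults emulate a moderately expanded gene family: ~42 ancestral
    groups spread over 7 homoeologous chromosome triples, 15% per-subgenome
    copy loss, 20% tandem expansion, 20% non-canonical members and the TE
    rates reported for wheat gene neighbourhoods (roughly 45% of genes with
    an insertion, ~90% flanked within 2 kb).
    """

    seed: int
    n_groups: int = 42
    n_chrom_numbers: int = 7
    p_loss: float | dict[str, float] = 0.15
    p_tandem: float = 0.2
    tandem_geom_p: float = 0.5
    max_tandem: int = 3
    p_proximal: float = 0.05
    p_dispersed: float = 0.05
    n_singletons: int = 2
    p_nc: float = 0.2
    p_te_inside: float = 0.45
    p_te_flank: float = 0.7
    p_te_span: float = 0.02
    intergenic_range: tuple[int, int] = (5000, 9000)
    care_rate: float = 2.0
    promoter_len: int = 1500
    min_block: int = 5
    max_gap: int = 25

    def loss_prob(self, subgenome: str) -> float:
        if isinstance(self.p_loss, dict):
            return float(self.p_loss.get(subgenome, 0.0))
        return float(self.p_loss)


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    clade: str
    group_id: int  # -1 for genes outside any planted group
    dup_category: str
    triad_category: str
    nc: bool
    ablated_motif: str
    te_inside: bool
    te_spanning: bool
    te_flank5: bool
    te_flank3: bool
    care_plants: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class SimResult:
    config: SimConfig
    chrom_seqs: dict[str, str]
    genes: list[GeneModel]
    proteins: list[tuple[str, str]]
    tes: list[TEFeature]
    pairs: list[tuple[str, str, float]]
    clades: dict[str, str]
    truth: list[GeneTruth]

    def truth_by_gene(self) -> dict[str, GeneTruth]:
        return {t.gene_id: t for t in self.truth}


# ---------------------------------------------------------------------------
# protein scaffold
# ---------------------------------------------------------------------------

def _scaffold_protein(rng, ablate: str | None = None) -> tuple[str, str]:
    """(protein sequence, planted ATG-variant).  ``ablate`` names a required
    motif whose first residue is replaced by alanine."""
    bg = rng.choice(list(BACKGROUND_AA), size=SCAFFOLD_LEN)
    seq = list(bg)
    seq[0] = "M"
    for off in (0, 2, 5):
        seq[FAD_POS - 1 + off] = "G"
    seq[IDENT_POS - 1] = "F"
    seq[IDENT_POS + 1] = "G"
    seq[IDENT_POS + 5] = "H"
    seq[IDENT_POS + 9] = "Y"
    for off in (0, 2, 5):
        seq[NADPH_POS - 1 + off] = "G"
    atg = ATG_PLANT_CHOICES[rng.integers(len(ATG_PLANT_CHOICES))]
    seq[ATG_POS - 1 : ATG_POS - 1 + 5] = list(atg)
    if ablate == "FAD_binding":
        seq[FAD_POS - 1] = "A"
    elif ablate == "NADPH_binding":
        seq[NADPH_POS - 1] = "A"
    elif ablate == "FMO_identifying":
        seq[IDENT_POS - 1] = "A"
    return "".join(seq), atg


def _backtranslate(rng, protein: str) -> str:
    return "".join(
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein
    )


def _random_dna(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# gene segment assembly
# ---------------------------------------------------------------------------

def _build_segment(rng, protein: str):
    """Return (segment_seq, exons, cds, utr5, utr3) with 1-based intervals
    local to the segment, already oriented for the chosen strand."""
    strand = "+" if rng.random() < 0.5 else "-"
    u5 = int(rng.integers(50, 150))
    u3 = int(rng.integers(100, 250))
    cds_nt = _backtranslate(rng, protein)
    stop = _STOPS[rng.integers(3)]
    k = int(rng.integers(1, 4))
    cuts = sorted(rng.choice(np.arange(1, len(cds_nt) // 3), size=k - 1, replace=False)) if k > 1 else []
    chunks = []
    prev = 0
    for c in cuts:
        chunks.append(cds_nt[prev * 3 : c * 3])
        prev = c
    chunks.append(cds_nt[prev * 3 :])

    parts = []
    pos = 1
    utr5 = [(1, u5)]
    parts.append(_random_dna(rng, u5))
    pos += u5
    cds, exon_bounds = [], []
    exon_start = 1
    for i, chunk in enumerate(chunks):
        cds.append((pos, pos + len(chunk) - 1))
        parts.append(chunk)
        pos += len(chunk)
        if i < len(chunks) - 1:
            exon_bounds.append((exon_start, pos - 1))
            ilen = int(rng.integers(200, 801))
            parts.append(_random_dna(rng, ilen))
            pos += ilen
            exon_start = pos
    parts.append(stop)
    pos += 3
    utr3 = [(pos, pos + u3 - 1)]
    parts.append(_random_dna(rng, u3))
    pos += u3
    exon_bounds.append((exon_start, pos - 1))
    seg = "".join(parts)
    L = len(seg)
    assert L == pos - 1

    if strand == "-":
        seg = revcomp(seg)
        mirror = lambda iv: (L - iv[1] + 1, L - iv[0] + 1)
        exon_bounds = sorted(mirror(iv) for iv in exon_bounds)
        cds = sorted(mirror(iv) for iv in cds)
        utr5 = sorted(mirror(iv) for iv in utr5)
        utr3 = sorted(mirror(iv) for iv in utr3)
    return seg, strand, exon_bounds, cds, utr5, utr3


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

_REQUIRED = ("FAD_binding", "NADPH_binding", "FMO_identifying")


def simulate(config: SimConfig) -> SimResult:
    """Generate one synthetic genome with full planted truth.

    Deterministic for a given config (byte-identical outputs when written).
    """
    if config.n_groups < 1:
        raise ValueError("configuration yields zero homeolog groups")
    rng = np.random.default_rng(config.seed)
    numbers = [i % config.n_chrom_numbers + 1 for i in range(config.n_groups)]
    clade_of_group = [str(rng.choice(list("ABC"))) for _ in range(config.n_groups)]

    # subgenome presence per group
    presence: list[list[str]] = []
    for _ in range(config.n_groups):
        kept = [sg for sg in "ABD" if rng.random() >= config.loss_prob(sg)]
        if not kept:
            kept = [str(rng.choice(list("ABD")))]
        presence.append(kept)

    # --- plan gene entries per chromosome -------------------------------
    # entry: dict(kind, group, source, name assigned later)
    chrom_names = [
        f"{num}{sg}" for num in range(1, config.n_chrom_numbers + 1) for sg in "ABD"
    ]
    core_lists: dict[str, list[dict]] = {c: [] for c in chrom_names}
    entries_all: list[dict] = []

    def new_entry(kind, group, chrom, source=None):
        e = {"kind": kind, "group": group, "chrom": chrom, "source": source}
        entries_all.append(e)
        return e

    for gi in range(config.n_groups):
        num = numbers[gi]
        for sg in presence[gi]:
            chrom = f"{num}{sg}"
            core_lists[chrom].append(new_entry("core", gi, chrom))

    # tandem / proximal / dispersed plans (decided core by core, in order)
    dispersed_per_cpair: dict[frozenset, int] = {}
    plans: dict[int, dict] = {}
    for chrom in chrom_names:
        for idx, core in enumerate(core_lists[chrom]):
            plan = {"tandem": 0, "proximal": False, "dispersed": None}
            if rng.random() < config.p_tandem:
                plan["tandem"] = int(
                    min(config.max_tandem, 1 + rng.geometric(config.tandem_geom_p) - 1)
                )
                plan["tandem"] = max(1, plan["tandem"])
            if rng.random() < config.p_proximal and idx < len(core_lists[chrom]) - 1:
                plan["proximal"] = True
            if rng.random() < config.p_dispersed:
                num = int(chrom[:-1])
                for _ in range(10):
                    tgt = str(
                        rng.choice([c for c in chrom_names if int(c[:-1]) != num])
                    )
                    key = frozenset((chrom, tgt))
                    if dispersed_per_cpair.get(key, 0) < config.min_block - 1:
                        dispersed_per_cpair[key] = dispersed_per_cpair.get(key, 0) + 1
                        plan["dispersed"] = tgt
                        break
            plans[id(core)] = plan

    # assemble ordered gene lists per chromosome
    chrom_entries: dict[str, list[dict]] = {c: [] for c in chrom_names}
    deferred: dict[str, list[dict]] = {c: [] for c in chrom_names}
    for chrom in chrom_names:
        pending_proximal: list[dict] = []
        for core in core_lists[chrom]:
            chrom_entries[chrom].append(core)
            plan = plans[id(core)]
            prev = core
            for _ in range(plan["tandem"]):
                copy = new_entry("tandem", core["group"], chrom, source=prev)
                chrom_entries[chrom].append(copy)
                prev = copy
            for p in pending_proximal:
                chrom_entries[chrom].append(p)
            pending_proximal = []
            if plan["proximal"]:
                pending_proximal.append(
                    new_entry("proximal", core["group"], chrom, source=core)
                )
            if plan["dispersed"]:
                deferred[plan["dispersed"]].append(
                    new_entry("dispersed", core["group"], plan["dispersed"], source=core)
                )
        # sources flagged proximal despite being last are dropped by design
    for _ in range(config.n_singletons):
        chrom = str(rng.choice(chrom_names))
        deferred[chrom].append(new_entry("singleton", -1, chrom))
    for chrom in chrom_names:
        chrom_entries[chrom].extend(deferred[chrom])

    # --- name genes, make proteins -------------------------------------
    counter = 0
    for chrom in chrom_names:
        for e in chrom_entries[chrom]:
            counter += 1
            e["gene_id"] = f"Syn{chrom}G{counter:04d}"
            e["variant_id"] = e["gene_id"] + ".1"
            if e["kind"] == "singleton":
                e["clade"] = str(rng.choice(list("ABC")))
            else:
                e["clade"] = clade_of_group[e["group"]]
            ablate = None
            if rng.random() < config.p_nc:
                ablate = _REQUIRED[rng.integers(3)]
            e["ablate"] = ablate or ""
            e["protein"], e["atg_variant"] = _scaffold_protein(rng, ablate or None)

    # --- assemble chromosomes, plant CAREs and TEs ----------------------
    chrom_seqs: dict[str, str] = {}
    genes: list[GeneModel] = []
    tes: list[TEFeature] = []
    lo_gap, hi_gap = config.intergenic_range
    for chrom in chrom_names:
        buf = bytearray()
        for e in chrom_entries[chrom]:
            gap = int(rng.integers(lo_gap, hi_gap + 1))
            buf.extend(_random_dna(rng, gap).encode())
            seg, strand, exons, cds, utr5, utr3 = _build_segment(rng, e["protein"])
            off = len(buf)  # 0-based offset of segment start
            shift = lambda ivs: [(off + s, off + e_) for s, e_ in ivs]
            model = GeneModel(
                variant_id=e["variant_id"],
                chrom=chrom,
                start=off + 1,
                end=off + len(seg),
                strand=strand,
                exons=shift(exons),
                cds=shift(cds),
                utr5=shift(utr5),
                utr3=shift(utr3),
                clade=e["clade"],
            )
            buf.extend(seg.encode())
            e["model"] = model
            genes.append(model)
        buf.extend(_random_dna(rng, lo_gap).encode())
        chrom_seqs[chrom] = buf.decode()

    # CARE planting (writes into the chromosome sequence upstream of the ATG)
    seq_arrays = {c: bytearray(s.encode()) for c, s in chrom_seqs.items()}
    n_strata = config.promoter_len // 60
    for chrom in chrom_names:
        for e in chrom_entries[chrom]:
            model = e["model"]
            k = int(min(rng.poisson(config.care_rate), n_strata))
            plants: list[tuple[str, int]] = []
            if k > 0:
                strata = rng.choice(n_strata, size=k, replace=False)
                for st in sorted(int(s) for s in strata):
                    care = DEFAULT_CARES[rng.integers(len(DEFAULT_CARES))]
                    L = len(care.iupac)
                    offset = st * 60 + int(rng.integers(1, 60 - L))
                    arr = seq_arrays[chrom]
                    if model.strand == "+":
                        c0 = model.cds[0][0]  # 1-based first codon base
                        start = c0 - offset - L  # 0-based slice start
                        arr[start : start + L] = care.iupac.encode()
                    else:
                        h = model.cds[-1][1]
                        start = h + offset - 1
                        arr[start : start + L] = revcomp(care.iupac).encode()
                    plants.append((care.name, offset))
            e["care_plants"] = plants
    chrom_seqs = {c: a.decode() for c, a in seq_arrays.items()}

    # TE planting
    te_count = 0
    for chrom in chrom_names:
        for e in chrom_entries[chrom]:
            model = e["model"]
            flags = {"inside": False, "spanning": False, "flank5": False, "flank3": False}
            ivals: list[tuple[int, int]] = []
            if rng.random() < config.p_te_span:
                flags["spanning"] = True
                ivals.append((model.start - 50, model.end + 50))
            else:
                if rng.random() < config.p_te_inside:
                    introns = model.introns()
                    host = max(introns, key=lambda iv: iv[1] - iv[0]) if introns else max(
                        model.cds, key=lambda iv: iv[1] - iv[0]
                    )
                    s, t = host
                    width = t - s + 1
                    pad = max(1, width // 4)
                    if width >= 8:
                        flags["inside"] = True
                        ivals.append((s + pad, t - pad))
                for side in ("flank5", "flank3"):
                    if rng.random() < config.p_te_flank:
                        flags[side] = True
                        d = int(rng.integers(100, 1701))
                        left = (side == "flank5") == (model.strand == "+")
                        if left:
                            ivals.append((model.start - d - 299, model.start - d))
                        else:
                            ivals.append((model.end + d, model.end + d + 299))
            for s, t in ivals:
                te_count += 1
                tes.append(TEFeature(chrom=chrom, start=s, end=t, te_class="RLX"))
            e["te_flags"] = flags

    # --- homology pairs --------------------------------------------------
    pairs: list[tuple[str, str, float]] = []
    cores_by_group: dict[int, list[dict]] = {}
    for e in entries_all:
        if e["kind"] == "core":
            cores_by_group.setdefault(e["group"], []).append(e)
    for gi in sorted(cores_by_group):
        cores = cores_by_group[gi]
        for i in range(len(cores)):
            for j in range(i + 1, len(cores)):
                pairs.append((cores[i]["gene_id"], cores[j]["gene_id"], 1.0))
    for e in entries_all:
        if e["kind"] in ("tandem", "proximal", "dispersed"):
            pairs.append((e["source"]["gene_id"], e["gene_id"], 1.0))

    # --- analytic truth --------------------------------------------------
    rank_of = {}
    for chrom in chrom_names:
        for r, e in enumerate(chrom_entries[chrom]):
            rank_of[e["gene_id"]] = (chrom, r)

    # anchor runs per chromosome pair (core-core pairs only, monotone by
    # construction); a run of >= min_block anchors is a collinear block
    wgd_genes: set[str] = set()
    block_edges: list[tuple[str, str]] = []
    anchors_by_cpair: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for gi, cores in cores_by_group.items():
        for i in range(len(cores)):
            for j in range(i + 1, len(cores)):
                a, b = cores[i], cores[j]
                (ca, ra), (cb, rb) = rank_of[a["gene_id"]], rank_of[b["gene_id"]]
                if ca > cb:
                    ca, cb, ra, rb = cb, ca, rb, ra
                    a, b = b, a
                anchors_by_cpair.setdefault((ca, cb), []).append(
                    (ra, rb, a["gene_id"], b["gene_id"])
                )
    for cpair, anchors in anchors_by_cpair.items():
        anchors.sort()
        run: list[tuple[int, int, str, str]] = []
        runs = [run]
        for anc in anchors:
            if run and (
                anc[0] - run[-1][0] > config.max_gap
                or abs(anc[1] - run[-1][1]) > config.max_gap
            ):
                run = []
                runs.append(run)
            run.append(anc)
        for run in runs:
            if len(run) >= config.min_block:
                for _, _, ga, gb in run:
                    wgd_genes.update((ga, gb))
                    block_edges.append((ga, gb))

    neighbors: dict[str, list[str]] = {}
    for a, b, _ in pairs:
        neighbors.setdefault(a, []).append(b)
        neighbors.setdefault(b, []).append(a)

    def dup_category(gene_id: str) -> str:
        if gene_id in wgd_genes:
            return "wgd_segmental"
        chrom, rank = rank_of[gene_id]
        homs = neighbors.get(gene_id, [])
        same = [abs(rank_of[h][1] - rank) for h in homs if rank_of[h][0] == chrom]
        if any(d <= 1 for d in same):
            return "tandem"
        if any(d <= 10 for d in same):
            return "proximal"
        if homs:
            return "dispersed"
        return "singleton"

    # truth homeolog groups: union-find over block edges + close same-chrom pairs
    parent: dict[str, str] = {e["gene_id"]: e["gene_id"] for e in entries_all}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for ga, gb in block_edges:
        union(ga, gb)
    for a, b, _ in pairs:
        (ca, ra), (cb, rb) = rank_of[a], rank_of[b]
        if ca == cb and abs(ra - rb) <= 10:
            union(a, b)

    comp_members: dict[str, list[dict]] = {}
    for e in entries_all:
        comp_members.setdefault(find(e["gene_id"]), []).append(e)
    triad_of_gene: dict[str, str] = {}
    comp_index: dict[str, int] = {}
    for ci, (root, members) in enumerate(sorted(comp_members.items()), 1):
        counts = {"A": 0, "B": 0, "D": 0}
        for m in members:
            sg = m["chrom"][-1]
            if sg in counts:
                counts[sg] += 1
        cat = classify_ratio((counts["A"], counts["B"], counts["D"]))
        for m in members:
            triad_of_gene[m["gene_id"]] = cat
            comp_index[m["gene_id"]] = ci

    truth = []
    clades_map = {}
    proteins = []
    for chrom in chrom_names:
        for e in chrom_entries[chrom]:
            gid = e["gene_id"]
            clades_map[gid] = e["clade"]
            proteins.append((e["variant_id"], e["protein"]))
            flags = e["te_flags"]
            truth.append(
                GeneTruth(
                    gene_id=gid,
                    chrom=chrom,
                    clade=e["clade"],
                    group_id=e["group"],
                    dup_category=dup_category(gid),
                    triad_category=triad_of_gene[gid],
                    nc=bool(e["ablate"]),
                    ablated_motif=e["ablate"],
                    te_inside=flags["inside"],
                    te_spanning=flags["spanning"],
                    te_flank5=flags["flank5"],
                    te_flank3=flags["flank3"],
                    care_plants=e["care_plants"],
                )
            )
    return SimResult(
        config=config,
        chrom_seqs=chrom_seqs,
        genes=genes,
        proteins=proteins,
        tes=tes,
        pairs=pairs,
        clades=clades_map,
        truth=truth,
    )


def corrupt(pairs, dropout_p: float, seed: int):
    """Remove each homology pair independently with probability dropout_p."""
    if not 0.0 <= dropout_p <= 1.0:
        raise ValueError("dropout probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(pairs)) >= dropout_p
    return [p for p, k in zip(pairs, keep) if k]


def write_outputs(sim: SimResult, outdir) -> dict[str, Path]:
    """Write every simulator product in its standard format; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.gff3",
        "proteins": outdir / "proteins.faa",
        "te": outdir / "te.gff3",
        "pairs": outdir / "pairs.tsv",
        "clades": outdir / "clades.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(paths["genome"], sorted(sim.chrom_seqs.items()))
    write_gff3(paths["genes"], sim.genes)
    write_fasta(paths["proteins"], sim.proteins)
    with open(paths["te"], "w") as fh:
        fh.write("##gff-version 3\n")
        for i, t in enumerate(sim.tes, 1):
            fh.write(
                f"{t.chrom}\tpolyfam_sim\t{t.te_class}\t{t.start}\t{t.end}\t.\t+\t.\tID=TE{i:05d}\n"
            )
    write_pairs_tsv(paths["pairs"], sim.pairs)
    with open(paths["clades"], "w") as fh:
        fh.write("# gene_id\tclade\n")
        for gid in sorted(sim.clades):
            fh.write(f"{gid}\t{sim.clades[gid]}\n")
    write_tsv(
        paths["truth"],
        [
            "gene_id", "chrom", "clade", "group_id", "dup_category",
            "triad_category", "nc", "ablated_motif", "te_inside",
            "te_spanning", "te_flank5", "te_flank3", "care_plants",
        ],
        [
            [
                t.gene_id, t.chrom, t.clade, t.group_id, t.dup_category,
                t.triad_category, int(t.nc), t.ablated_motif, int(t.te_inside),
                int(t.te_spanning), int(t.te_flank5), int(t.te_flank3),
                ";".join(f"{n}:{o}" for n, o in t.care_plants),
            ]
            for t in sim.truth
        ],
        comment="planted ground truth, one row per gene",
    )
    return paths
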