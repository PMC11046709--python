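"""Readers and writers for the external formats the survey touches.

All genomic coordinates are kept 1-based inclusive (GFF3 native) throughout
the package; BED input is converted at the boundary (+1 to start).  The
module also ships the packaged homeolog catalogue (``table2_catalogue.tsv``)
transcribed from the wheat FMO survey it reproduces.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "GeneModel",
    "DomainHit",
    "TEFeature",
    "CatalogueRow",
    "FormatError",
    "parse_subgenome",
    "strip_splice_suffix",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_domtblout",
    "read_te_bed",
    "read_te_gff3",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "read_clades_tsv",
    "load_catalogue",
    "write_tsv",
]


class FormatError(ValueError):
    """Malformed input file (carries the offending line number if known)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

_SPLICE_RE = re.compile(r"\.\d+$")
_NC_RE = re.compile(r"-nc$")


def strip_splice_suffix(variant_id: str) -> str:
    """Gene id = variant id minus an optional ``-nc`` marker and a trailing
    ``.<digits>`` splice suffix; ids without the suffix are their own gene."""
    return _SPLICE_RE.sub("", _NC_RE.sub("", variant_id))


def parse_subgenome(chrom: str) -> str:
    """Map a chromosome name to a subgenome letter: A, B, D, or U.

    The subgenome is the letter of the first ``<number><letter>`` token
    (``Chr5B``, ``5B``, ``1A`` ...); unplaced chromosomes (``Un``, ``ChrUn``,
    ``U``) and anything unrecognized map to U, so the mapping is total.
    """
    name = chrom.strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if name.upper() in ("U", "UN") or name.upper().startswith("UN"):
        return "U"
    m = re.match(r"^(\d+)([ABDabd])", name)
    if m:
        return m.group(2).upper()
    return "U"


@dataclass
class GeneModel:
    """One gene / splice variant with its exon-CDS-UTR structure.

    Intervals are (start, end) pairs, 1-based inclusive, sorted ascending
    regardless of strand.
    """

    variant_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    clade: str | None = None

    @property
    def gene_id(self) -> str:
        return strip_splice_suffix(self.variant_id)

    @property
    def subgenome(self) -> str:
        return parse_subgenome(self.chrom)

    @property
    def has_cds(self) -> bool:
        return bool(self.cds)

    def introns(self) -> list[tuple[int, int]]:
        """Gene-body gaps between consecutive exons."""
        out = []
        for (s1, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    domain_name: str
    env_start: int
    env_end: int
    score: float
    evalue: float


@dataclass(frozen=True)
class TEFeature:
    chrom: str
    start: int
    end: int
    te_class: str = "TE"


@dataclass(frozen=True)
class CatalogueRow:
    variant_id: str
    clade: str
    subclade: str
    nc: bool
    synteny_status: str
    chrom_label: str
    triad_abd: str
    triad_cell: str
    group_index: int

    @property
    def gene_id(self) -> str:
        return strip_splice_suffix(self.variant_id)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, SEQUENCE), ...]`` preserving order.

    Ids are the first whitespace-delimited header token; sequences are
    uppercased.  Duplicate ids raise :class:`FormatError`; an empty file
    yields an empty list.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (restricted gene/mRNA/exon/CDS/UTR dialect)
# ---------------------------------------------------------------------------

_UTR5_TYPES = {"five_prime_UTR", "5UTR"}
_UTR3_TYPES = {"three_prime_UTR", "3UTR"}


def _gff_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path) -> list[GeneModel]:
    """Parse gene models from GFF3: one :class:`GeneModel` per mRNA.

    Features are linked by ID/Parent.  mRNAs lacking CDS are kept (their
    ``has_cds`` is False).  A child whose Parent is unknown, or a line with
    the wrong column count, raises :class:`FormatError` with the line number.
    """
    mrnas: dict[str, GeneModel] = {}
    gene_strands: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from None
            attrs = _gff_attrs(attr_s)
            if ftype == "gene":
                gene_strands[attrs.get("ID", "")] = strand
            elif ftype == "mRNA":
                parent = attrs.get("Parent")
                if parent is not None and parent not in gene_strands:
                    raise FormatError(
                        f"{path}:{lineno}: mRNA Parent {parent!r} not seen as a gene"
                    )
                mid = attrs.get("ID")
                if mid is None:
                    raise FormatError(f"{path}:{lineno}: mRNA feature lacks ID")
                mrnas[mid] = GeneModel(
                    variant_id=mid, chrom=chrom, start=start, end=end, strand=strand
                )
                order.append(mid)
            elif ftype in ("exon", "CDS") or ftype in _UTR5_TYPES | _UTR3_TYPES:
                parent = attrs.get("Parent")
                if parent is None or parent not in mrnas:
                    raise FormatError(
                        f"{path}:{lineno}: {ftype} Parent {parent!r} not a known mRNA"
                    )
                model = mrnas[parent]
                if ftype == "exon":
                    model.exons.append((start, end))
                elif ftype == "CDS":
                    model.cds.append((start, end))
                elif ftype in _UTR5_TYPES:
                    model.utr5.append((start, end))
                else:
                    model.utr3.append((start, end))
            # other feature types are ignored
    for model in mrnas.values():
        for name in ("exons", "cds", "utr5", "utr3"):
            setattr(model, name, sorted(getattr(model, name)))
    return [mrnas[m] for m in order]


def write_gff3(path, genes: Sequence[GeneModel]) -> None:
    """Write gene models as GFF3 (one gene wrapping each mRNA)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gid = g.gene_id
            fh.write(
                f"{g.chrom}\tpolyfam\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{g.chrom}\tpolyfam\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.variant_id};Parent={gid}\n"
            )
            for ftype, ivals in (
                ("exon", g.exons),
                ("five_prime_UTR", g.utr5),
                ("CDS", g.cds),
                ("three_prime_UTR", g.utr3),
            ):
                for s, e in ivals:
                    fh.write(
                        f"{g.chrom}\tpolyfam\t{ftype}\t{s}\t{e}\t.\t{g.strand}\t.\t"
                        f"Parent={g.variant_id}\n"
                    )


# ---------------------------------------------------------------------------
# HMMER domtblout
# ---------------------------------------------------------------------------

def read_domtblout(path, evalue_threshold: float = 1e-2) -> list[DomainHit]:
    """Parse a HMMER ``--domtblout`` table into per-domain hits.

    The per-domain independent E-value (column 13) is compared against
    ``evalue_threshold``; hits with E-value >= threshold are excluded.
    Hits are returned grouped per protein, sorted by envelope start.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 22:
                raise FormatError(
                    f"{path}:{lineno}: domtblout line has {len(cols)} columns, expected >=22"
                )
            try:
                evalue = float(cols[12])
                score = float(cols[13])
                env_start, env_end = int(cols[19]), int(cols[20])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinate or score field"
                ) from None
            if evalue >= evalue_threshold:
                continue
            hits.append(
                DomainHit(
                    protein_id=cols[0],
                    domain_name=cols[3],
                    env_start=env_start,
                    env_end=env_end,
                    score=score,
                    evalue=evalue,
                )
            )
    hits.sort(key=lambda h: (h.protein_id, h.env_start, h.env_end))
    return hits


# ---------------------------------------------------------------------------
# TE annotations (BED3+ or GFF3)
# ---------------------------------------------------------------------------

def read_te_bed(path) -> list[TEFeature]:
    """BED3+ transposable-element intervals; 0-based half-open converted to
    1-based inclusive on read."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: BED line needs >=3 columns")
            try:
                start, end = int(cols[1]) + 1, int(cols[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric BED coordinate") from None
            te_class = cols[3] if len(cols) > 3 else "TE"
            out.append(TEFeature(chrom=cols[0], start=start, end=end, te_class=te_class))
    return out


def read_te_gff3(path) -> list[TEFeature]:
    """Any GFF3 feature line becomes a TE interval (class = type column)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from None
            out.append(TEFeature(chrom=cols[0], start=start, end=end, te_class=cols[2]))
    return out


# ---------------------------------------------------------------------------
# homology pairs and clade assignments
# ---------------------------------------------------------------------------

def read_pairs_tsv(path) -> list[tuple[str, str, float]]:
    """Two-column (optionally three: score) TSV of homologous gene pairs."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(f"{path}:{lineno}: pair line needs >=2 columns")
            score = float(cols[2]) if len(cols) > 2 and cols[2] else 1.0
            if cols[0] == cols[1]:
                raise FormatError(f"{path}:{lineno}: self-pair {cols[0]!r}")
            pairs.append((cols[0], cols[1], score))
    return pairs


def write_pairs_tsv(path, pairs: Iterable[tuple[str, str, float]]) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_a\tgene_b\tscore\n")
        for a, b, s in pairs:
            fh.write(f"{a}\t{b}\t{s:g}\n")


def read_clades_tsv(path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) >= 2:
                out[cols[0]] = cols[1]
    return out


# ---------------------------------------------------------------------------
# packaged homeolog catalogue
# ---------------------------------------------------------------------------

def default_catalogue_path() -> Path:
    return Path(resources.files("polyfam").joinpath("data/table2_catalogue.tsv"))


def load_catalogue(path=None) -> list[CatalogueRow]:
    """Load the packaged homeolog catalogue (or a user-supplied TSV of the
    same layout).  Rows are grouped into homeolog groups by ``group_index``;
    the ``-nc`` marker on a variant id sets the non-canonical flag.
    """
    if path is None:
        path = default_catalogue_path()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"catalogue fixture not found at {path}; the packaged copy lives in "
            "the polyfam/data directory of the installed package"
        )
    rows: list[CatalogueRow] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (l for l in fh if not l.startswith("#")), delimiter="\t"
        )
        for rec in reader:
            vid = rec["variant_id"].strip()
            rows.append(
                CatalogueRow(
                    variant_id=vid,
                    clade=rec["clade"].strip(),
                    subclade=rec["subclade"].strip(),
                    nc=vid.endswith("-nc"),
                    synteny_status=rec["synteny_status"].strip(),
                    chrom_label=rec["chrom_label"].strip(),
                    triad_abd=rec["triad_abd"].strip(),
                    triad_cell=rec["triad_cell"].strip(),
                    group_index=int(rec["group_index"]),
                )
            )
    return rows


# ---------------------------------------------------------------------------
# generic TSV output
# ---------------------------------------------------------------------------

def write_tsv(path, header: Sequence[str], rows: Iterable[Sequence], comment: str | None = None) -> None:
    """TSV writer used by every stage: a commented line naming the column
    semantics, then a header row, then the data."""
    with open(path, "w", newline="") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for row in rows:
            writer.writerow(row)
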