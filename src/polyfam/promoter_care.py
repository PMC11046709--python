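"""Promoter extraction and cis-acting regulatory element (CARE) scanning.

Promoters are the 1.5 kb of genomic sequence immediately upstream of the
start codon (strand-aware, clipped at contig edges).  They are scanned on
both strands against a small editable catalogue of cis-element consensus
patterns (IUPAC nucleotide codes) covering the hormone-, stress-, tissue-
and light-responsive element families commonly reported for plant
promoters.  The shipped catalogue is a compact dialect of the public
PlantCARE vocabulary, not a clone of it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .io_formats import GeneModel

__all__ = [
    "CAREModel",
    "CAREHit",
    "PromoterRegion",
    "DEFAULT_CARES",
    "iupac_to_regex",
    "revcomp",
    "extract_promoter",
    "scan_cares",
    "utr_lengths",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def iupac_to_regex(pattern: str) -> re.Pattern:
    if not pattern or any(c not in IUPAC for c in pattern):
        raise ValueError(f"invalid IUPAC pattern {pattern!r}")
    return re.compile("".join(IUPAC[c] for c in pattern))


@dataclass(frozen=True)
class CAREModel:
    name: str
    iupac: str
    category: str  # e.g. hormone:MeJA, stress:drought, tissue, light, core


@dataclass(frozen=True)
class CAREHit:
    gene_id: str
    care_name: str
    offset: int  # bp upstream of the ATG; 1 = immediately adjacent
    strand: str
    matched_text: str


@dataclass
class PromoterRegion:
    gene_id: str
    sequence: str
    length: int
    clipped: bool


#: shipped catalogue: consensus strings for the element families the survey
#: reports (jasmonate TGACG/CGTCA pair, salicylate, gibberellin, ethylene,
#: auxin, abscisate, drought MBS, low-temperature, anaerobic, tissue, light
#: and core elements).  Users can extend or replace it.
DEFAULT_CARES = (
    CAREModel("TGACG-motif", "TGACG", "hormone:MeJA"),
    CAREModel("CGTCA-motif", "CGTCA", "hormone:MeJA"),
    CAREModel("TCA-element", "CCATCTTTTT", "hormone:SA"),
    CAREModel("P-box", "CCTTTTG", "hormone:GA"),
    CAREModel("GARE-motif", "TCTGTTG", "hormone:GA"),
    CAREModel("TATC-box", "TATCCCA", "hormone:GA"),
    CAREModel("ERE", "ATTTTAAA", "hormone:ethylene"),
    CAREModel("AuxRR-core", "GGTCCAT", "hormone:auxin"),
    CAREModel("TGA-element", "AACGAC", "hormone:auxin"),
    CAREModel("ABRE", "ACGTGGC", "hormone:ABA"),
    CAREModel("MBS", "CAACTG", "stress:drought"),
    CAREModel("LTR", "CCGAAA", "stress:cold"),
    CAREModel("ARE", "AAACCA", "stress:anaerobic"),
    CAREModel("W-box", "TTGACC", "stress:defense"),
    CAREModel("TC-rich", "GTTTTCTTAC", "stress:defense"),
    CAREModel("CAT-box", "GCCACT", "tissue"),
    CAREModel("GCN4-motif", "TGAGTCA", "tissue"),
    CAREModel("RY-element", "CATGCATG", "tissue"),
    CAREModel("G-box", "CACGTG", "light"),
    CAREModel("Box4", "ATTAAT", "light"),
    CAREModel("CAAT-box", "CCAAT", "core"),
    CAREModel("TATA-box", "TATAAA", "core"),
)


def extract_promoter(
    gene: GeneModel,
    chrom_seq: str,
    length: int = 1500,
    anchor: str = "atg",
) -> PromoterRegion:
    """Strand-aware upstream region of the start codon.

    For a plus-strand gene with CDS starting at c the promoter is bases
    [c-length, c-1]; for a minus-strand gene it is the ``length`` bases to
    the right of the rightmost CDS base, reverse-complemented.  With
    ``anchor="tss"`` the gene bounds are used instead of the CDS.  Regions
    truncated by a contig edge are flagged clipped with their actual length.
    """
    if anchor == "atg":
        if not gene.cds:
            raise ValueError(f"gene {gene.variant_id} has no CDS; start codon undefined")
        lo, hi = gene.cds[0][0], gene.cds[-1][1]
    elif anchor == "tss":
        lo, hi = gene.start, gene.end
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    n = len(chrom_seq)
    if gene.strand == "-":
        start = hi + 1
        end = min(n, hi + length)
        seq = revcomp(chrom_seq[start - 1 : end].upper())
    else:
        start = max(1, lo - length)
        end = lo - 1
        seq = chrom_seq[start - 1 : end].upper()
    return PromoterRegion(
        gene_id=gene.gene_id,
        sequence=seq,
        length=len(seq),
        clipped=len(seq) < length,
    )


def scan_cares(
    promoter: PromoterRegion | str,
    care_models=DEFAULT_CARES,
    gene_id: str | None = None,
) -> list[CAREHit]:
    """All cis-element matches on both strands of a promoter.

    The promoter sequence is oriented 5'→3' ending immediately before the
    ATG; offsets count upstream base pairs from the ATG, measured at the
    ATG-proximal end of the match (offset 1 = the match ends on the last
    promoter base).  Overlapping matches of one model are all reported;
    hits come back sorted by offset, then name.
    """
    if isinstance(promoter, PromoterRegion):
        seq, gid = promoter.sequence, promoter.gene_id
    else:
        seq, gid = promoter, gene_id or ""
    seq = seq.upper()
    n = len(seq)
    hits = []
    for model in care_models:
        regex = iupac_to_regex(model.iupac)
        L = len(model.iupac)
        for strand, text in (("+", seq), ("-", revcomp(seq))):
            pos = 0
            while True:
                m = regex.search(text, pos)
                if m is None:
                    break
                i = m.start()
                # nearest-to-ATG base of the match, in forward coordinates
                offset = (n - i - L + 1) if strand == "+" else (i + 1)
                hits.append(
                    CAREHit(
                        gene_id=gid,
                        care_name=model.name,
                        offset=offset,
                        strand=strand,
                        matched_text=m.group(0),
                    )
                )
                pos = i + 1
    hits.sort(key=lambda h: (h.offset, h.care_name, h.strand))
    return hits


def utr_lengths(gene: GeneModel) -> tuple[int, int]:
    """Total 5'- and 3'-UTR lengths of a gene model (0 when absent)."""
    u5 = sum(e - s + 1 for s, e in gene.utr5)
    u3 = sum(e - s + 1 for s, e in gene.utr3)
    return u5, u3
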