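# Methods

This note documents the models, conventions and design choices behind
`polyfam`, in the order the pipeline runs them.

## Coordinates and identifiers

All genomic coordinates are 1-based inclusive (GFF3 native) everywhere in
the package; BED input is converted at the boundary (+1 to the start).
A splice variant id maps to its gene id by removing an optional `-nc`
marker and a trailing `.<digits>` suffix; ids without the suffix are their
own gene.  Subgenomes are parsed from chromosome names as the letter of
the first `<number><letter>` token (`Chr5B` → B); unplaced chromosomes
(`Un`, `ChrUn`) and unrecognized names map to U, so the mapping is total.
U genes are carried through every analysis but never enter A:B:D ratio
arithmetic.

## Motif scanning

The survey treats four motifs as diagnostic of canonical FMO function:

| motif            | grammar            | default window                      |
|------------------|--------------------|-------------------------------------|
| FAD-binding      | `GxGxxG`           | residues 1–60                       |
| NAD(P)H-binding  | `GxGxxG`           | ≥ 60 residues after the FAD hit     |
| FMO-identifying  | `FxGxxxHxxx(Y/F)`  | between the FAD and NAD(P)H hits    |
| ATG-containing   | `(F/L/M/H/Y)(A/C/G)TG(Y/F)` | downstream of the NAD(P)H hit |

Published surveys assess these by eye on a multiple sequence alignment;
`polyfam` must run alignment-free, so it uses windowed grammar matching
instead, with the windows above (all configurable).  When an anchor motif
is missing, the dependent window falls back to the whole sequence, so
ablating one motif never hides another.  The leftmost hit in a window is
the canonical one; all hits are reported.  A protein is canonical iff every
*required* motif has a hit; the required set defaults to
{FAD, NAD(P)H, FMO-identifying}.  The ATG-containing motif is recorded but
not required by default, because the literature describes it as less
universal; a strict mode adds it to the required set.  Known variant
spellings (W-for-F in the identifying motif; `FATGY`, `LATGY`, `LATGF`,
`FLATGF`, `FGTGF`, `MATGY`, `HCTGY`, `YCTGY` for the ATG motif) are
labelled, counted as present.  Only the first glycine of the NAD(P)H
Rossmann motif is strongly conserved in this family, so a relaxed mode
accepts any glycine-led hexamer with at least two hydrophobic residues in
context; strict `GxGxxG` is the default.  Sequences shorter than 300
residues are additionally tagged truncated.

Domain architectures come from HMMER `domtblout` tables filtered at
independent E-value < 1e-2 (column 13).  Same-domain envelopes overlapping
by more than half of the shorter envelope are merged before counting; a
kinase domain anywhere labels the protein a kinase fusion, otherwise ≥ 2
FMO-like domains give `FMO_like_x2`, one gives `FMO_like`, a pyridine-redox
domain alone gives `Pyr_redox_like`, and anything else is `other`.

## Collinearity and duplicate-gene categories

Homology pairs are an input (two-column TSV), not computed by alignment.
Genes are ranked by start position per chromosome (ties by end, then id).
For each chromosome pair, anchors are chained by a weighted dynamic
program requiring strictly increasing ranks on one chromosome, strictly
monotone ranks (either orientation) on the other, and rank gaps ≤ 25 on
both; chains shorter than 5 anchors are discarded, and anchors are
assigned greedily to at most one block, best score first.  The defaults
(min_block 5, max_gap 25, proximal_gap 10, tandem_gap 1) follow MCScanX
conventions; the implementation is a dialect of MCScanX, not a clone.  Two
deliberate restrictions keep tandem arrays from masquerading as segmental
blocks: same-chromosome pairs within the tandem rank distance are never
anchors (as in MCScanX), and this dialect chains only inter-chromosomal
pairs — the duplication events of interest here (whole-genome/segmental
homeology) are cross-chromosomal.

Every gene then receives exactly one category by precedence: block anchor →
`wgd_segmental`; else a same-chromosome homolog within 1 rank → `tandem`;
within 10 ranks → `proximal`; any homolog at all → `dispersed`; none →
`singleton`.  Splice variants collapse to one gene before ranking, so a
pair of splice variants can never be called a tandem duplication.

## Homeolog groups and triad ratios

Groups are connected components over block-anchor pairs plus
tandem/proximal homology pairs.  A group's clade is the majority clade of
its members; an exact tie marks the group unresolvable.  Copy counts are
distinct genes per subgenome (U members listed but excluded).  Ratio
classes:

- **balanced** — equal non-zero counts in all three subgenomes.  This
  includes k:k:k with k > 1: a group holding k complete triads duplicated
  in tandem is still an even group.  This generalization is required to
  reproduce the packaged catalogue's own accounting, which prints such
  groups as 1:1:1.
- **expanded (n:1:1 family)** — exactly one subgenome with ≥ 2 copies, the
  other two with one each.
- **one-missing (1:1:0 family)** — exactly one subgenome absent, the other
  two with one copy each.
- **orphan/singleton** — a single subgenome represented.
- **other** — any remaining non-zero pattern.
- **not categorized** — no placeable member, or an unresolvable clade mix.

Percentages are per homeolog group within a clade, rounded half-up to two
decimals, with the genome-wide shares of all wheat genes
(35.8/5.7/13.2/37.1/8.0) attached as a static reference column.

### The packaged catalogue

`polyfam/data/table2_catalogue.tsv` transcribes the wheat FMO homeolog
catalogue: 198 splice variants (clades A/B/C: 55/63/80) over 170 genes in
39 groups (12/11/16).  Group A:B:D counts are parsed from the catalogue's
per-subgenome layout cell (`A(Adis)/b(Btan)(Btan)(Bdis)/-`): the three
slash-separated slots are the A, B and D subgenomes *by position*, each
subgenome letter inside a slot is one copy, the tandem/dispersed/proximal
suffixes are stripped before counting, and tokens containing U/u are
unplaced members that never count.  Slot position rather than chromosome
letter decides the subgenome because translocated homeologs (e.g. a group
laid out `4A / 7A / 7D`) occupy their ancestral slot while residing on
another subgenome's chromosome.

Two documented discrepancies of the source table are preserved rather than
absorbed: clade A's balanced share computes to 1/12 = 8.33% while the
published table prints 8.20% (no integer ratio of 12 groups yields 8.20),
and clade C carries 17 `-nc` variants while the published total says 16.
`polyfam reproduce-paper` prints the first as an annotated discrepancy;
neither is treated as a pass/fail target.

## TE proximity

TE annotations (GFF3 or BED) are flattened by merging overlapping
intervals of any class, since nested/fragmented TE models are common.
Display classes are mutually exclusive: a TE containing the whole gene
marks it *spanning*; otherwise any TE overlapping ≥ 1 bp of the gene body
marks it *inside*, with the overlapped feature classes (intron, exon,
5'/3' UTR; introns are the gene span minus exons) listed; TEs lying
entirely outside the body but within the 2 kb strand-aware windows mark
*flank5*/*flank3*.  A TE crossing a gene boundary counts as inside only.
The flanking window anchors at the gene-body bounds by default
(`anchor="cds"` switches to the CDS span); the summary's flanking
percentage includes spanning genes by default, both choices configurable
because published totals cannot adjudicate them without the original
annotation.  Because the display classes are exclusive, adding a TE is
monotone only up the class hierarchy: it can promote a flanking gene to
inside or an inside gene to spanning, but never withdraws
inside-or-spanning, nor any-proximity.

## Promoters and cis-elements

Promoters are the 1.5 kb of genomic sequence immediately upstream of the
start codon (ATG-anchored; `anchor="tss"` uses the gene bounds instead),
reverse-complemented for minus-strand genes and clipped at contig edges
with the actual length flagged.  Scanning matches IUPAC consensus patterns
on both strands; offsets count base pairs upstream of the ATG at the
ATG-proximal end of the match (offset 1 = adjacent to the start codon).
Overlapping hits are all reported.  The shipped ~22-element catalogue
covers the hormone (MeJA, SA, GA, ethylene, auxin, ABA), stress (drought
MBS, low-temperature LTR, anaerobic ARE, defense), tissue, light and core
element families; it is a compact dialect of the public PlantCARE
vocabulary, editable by the user, and results are not PlantCARE output.

## Synthetic genomes and what they do (not) show

The generator emulates the statistical structure the analysis assumes:
ancestral homeolog groups instantiated at collinear positions across three
subgenomes of up to seven chromosomes; per-subgenome copy loss
(default 0.15); tandem expansion (p 0.2, geometric copy counts, max 3);
proximal, dispersed and singleton copies; motif-ablated proteins
(p 0.2, matching the roughly one-in-five nc rate of the wheat family);
TE planting at the rates reported for wheat gene neighbourhoods (inside
0.45, flanking 0.7 per side, spanning 0.02); and one to a few cis-elements
planted per promoter.  Default size is 42 groups (≈ 170–200 genes), the
scale of the family that motivated the package; recovery tests use 200
groups (≈ 700 genes), which runs in seconds.

Proteins follow a fixed 420-residue scaffold (FAD motif at residue 15,
identifying motif at 170, NAD(P)H at 190, ATG motif at 330 — spacings
loosely follow the family's domain layout, not a claim about real FMO
geometry).  Background residues are drawn from an alphabet without
glycine, so no motif can arise by chance and planted coordinates are exact
oracles.  Non-canonical copies have the first residue of one required
motif replaced by alanine.  CDS sequences are back-translations with
uniformly random synonymous codons; genes carry 1–3 exons, UTRs and random
intergenic spacing of 5–9 kb, wide enough that planted TEs and promoter
elements of one gene can never fall into a neighbour's windows.  Planted
truth is derived *analytically* from the layout (monotone anchor runs,
rank distances, union-find over planted edges), not by running the
analysis pipeline, so end-to-end recovery compares two independent routes.

What passing recovery tests show: the chaining DP, the precedence
classifier, the grouping closure, the interval logic and the scanners
recover planted structure exactly under noise-free homology, and degrade
gracefully (≥ 80% balanced-triad recovery at 10% homology dropout).  What
they do not show: behaviour on real annotation noise — fragmented gene
models, alignment-derived homology with paralog confusion, nested TE
models beyond simple overlap, promoter elements in repetitive context.
The generator has no substitution model or indel process; sequence realism
is out of scope.

## Numerical and degenerate-input choices

- Chain DP ties are broken toward the leftmost chain; anchor-to-block
  exclusivity is resolved best-score-first.
- Percentages round half-up (decimal arithmetic, not binary float
  rounding); per-clade percentages sum to 100 ± 0.02 by construction.
- Empty protein sequences profile as all-missing, non-canonical.  Empty
  domain-hit lists yield architecture `other`.  Genes without CDS are kept
  by the GFF3 reader and rejected with a named error only where a start
  codon is required (promoter extraction).
- The E-value filter excludes hits at exactly the threshold (strict `<`).
- `corrupt` (homology dropout) is an independent Bernoulli per pair under
  its own seed.

## Testing strategy

Every operation has an independent oracle: planted coordinates from the
generator, brute-force enumeration for the chain DP (all chains on ≤ 8
anchors), position-by-position regex/IUPAC matching for both scanners,
exhaustive triples for the ratio classifier, and binomial bounds for the
dropout. Properties (subgenome totality, rank order-invariance, TE
translation/mirror invariance, classifier symmetry) are exercised with
hypothesis or seeded sweeps.  Determinism is asserted byte-for-byte on
simulator outputs and survey reports.
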