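"""Grammar-based scanning of the conserved FMO protein motifs.

Flavin-containing monooxygenases carry two Rossmann-fold dinucleotide
binding motifs (FAD-binding GxGxxG near the N-terminus and NAD(P)H-binding
GxGxxG further downstream), the linker "FMO-identifying" motif
FxGxxxHxxx(Y/F) between them, and the ATG-containing ((F/L)ATGY family)
motif implicated in N-hydroxylation.  Proteins missing any required motif
are flagged non-canonical ("nc").

Scanning is windowed, alignment-free grammar matching: the FAD motif is
searched near the N-terminus, the NAD(P)H motif a minimum spacing downstream
of the FAD hit, the identifying motif between them, and the ATG motif
downstream of the NAD(P)H site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "MotifModel",
    "MotifHit",
    "MotifProfile",
    "Architecture",
    "default_motif_models",
    "compile_pattern",
    "scan_motif",
    "profile_protein",
    "assign_architecture",
]

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")

FAD_BINDING = "FAD_binding"
NADPH_BINDING = "NADPH_binding"
FMO_IDENTIFYING = "FMO_identifying"
ATG_CONTAINING = "ATG_containing"

REQUIRED_DEFAULT = frozenset({FAD_BINDING, NADPH_BINDING, FMO_IDENTIFYING})

#: literal variants of the ATG-containing motif shipped by default; the
#: canonical forms FATGY/LATGY plus the variants seen across grass FMO
#: subclades and the HCTGY/YCTGY forms typical of the S-oxygenase clade.
ATG_VARIANTS = (
    "FATGY",
    "LATGY",
    "LATGF",
    "FLATGF",
    "FGTGF",
    "MATGY",
    "HCTGY",
    "YCTGY",
)


def compile_pattern(pattern: str) -> re.Pattern:
    """Compile a motif grammar string into a regex.

    Grammar: ``x``/``X`` matches any residue; ``A/B`` (optionally
    parenthesised, any number of alternatives) is a single-position residue
    class; every other letter is literal.  ``FxGxxxHxxxY/F`` therefore has
    fixed length 11 and ``(F/L)ATGY`` length 5.
    """
    out = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == "(":
            j = pattern.index(")", i)
            letters = [p for p in pattern[i + 1 : j].split("/") if p]
            out.append("[" + "".join(letters) + "]")
            i = j + 1
        elif c in "xX":
            out.append(".")
            i += 1
        elif i + 1 < len(pattern) and pattern[i + 1] == "/":
            # bare alternation: consume letters separated by '/'
            letters = [c]
            i += 1
            while i < len(pattern) and pattern[i] == "/":
                letters.append(pattern[i + 1])
                i += 2
            out.append("[" + "".join(letters) + "]")
        else:
            out.append(re.escape(c))
            i += 1
    return re.compile("".join(out))


@dataclass
class MotifModel:
    """One motif grammar plus its search window and variant vocabulary.

    ``window`` is (lo, hi) in 1-based residue positions relative to the
    protein start, or None for anchored windows resolved by
    :func:`profile_protein`.  ``variant_vocabulary`` maps literal matched
    text to a variant label; ``variant_rules`` are (regex, label) fallbacks
    applied to the matched text.
    """

    name: str
    pattern: str
    window: tuple[int, int] | None = None
    variant_vocabulary: dict[str, str] = field(default_factory=dict)
    variant_rules: list[tuple[str, str]] = field(default_factory=list)

    def regex(self) -> re.Pattern:
        return compile_pattern(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    start: int  # 1-based residue position
    matched_text: str
    variant_label: str | None = None


@dataclass
class MotifProfile:
    protein_id: str
    hits: dict[str, list[MotifHit]]
    canonical: bool
    missing: frozenset[str]
    truncated: bool = False
    nadph_relaxed: bool = False  # NAD(P)H site found only under relaxed grammar


@dataclass(frozen=True)
class Architecture:
    protein_id: str
    label: str  # FMO_like | FMO_like_x2 | Pyr_redox_like | kinase_fusion | other
    n_fmo_domains: int


def default_motif_models(
    fad_window: tuple[int, int] = (1, 60),
    nadph_min_spacing: int = 60,
) -> dict[str, MotifModel]:
    """The four FMO motif models with their default windows.

    The NAD(P)H and downstream windows are anchored at the FAD hit and are
    resolved by :func:`profile_protein`; ``nadph_min_spacing`` is recorded on
    the model as the anchored offset.
    """
    atg_vocab = {v: v for v in ATG_VARIANTS}
    return {
        FAD_BINDING: MotifModel(FAD_BINDING, "GxGxxG", window=fad_window),
        NADPH_BINDING: MotifModel(
            NADPH_BINDING, "GxGxxG", window=(nadph_min_spacing, None)
        ),
        FMO_IDENTIFYING: MotifModel(
            FMO_IDENTIFYING,
            "(F/W)xGxxxHxxx(Y/F)",
            variant_rules=[("^W", "W-variant")],
        ),
        ATG_CONTAINING: MotifModel(
            ATG_CONTAINING,
            "(F/L/M/H/Y)(A/C/G)TG(Y/F)",
            variant_vocabulary=atg_vocab,
        ),
    }


RELAXED_NADPH = re.compile("G.....")
_HYDROPHOBIC = set("AVILMFWC")


def _validate_sequence(sequence: str) -> None:
    for pos, residue in enumerate(sequence, 1):
        if residue not in VALID_RESIDUES:
            raise ValueError(
                f"unknown residue {residue!r} at position {pos}"
            )


def _label(model: MotifModel, text: str) -> str | None:
    if text in model.variant_vocabulary:
        return model.variant_vocabulary[text]
    for pat, label in model.variant_rules:
        if re.search(pat, text):
            return label
    return None


def scan_motif(
    sequence: str,
    model: MotifModel,
    window: tuple[int, int | None] | None = None,
) -> list[MotifHit]:
    """All (possibly overlapping) matches of ``model`` inside the window.

    ``window`` overrides the model's own window; bounds are 1-based and
    clipped to the sequence.  Hits come back sorted by start position.
    """
    _validate_sequence(sequence)
    lo, hi = window or model.window or (1, None)
    lo = max(1, lo)
    hi = len(sequence) if hi is None else min(hi, len(sequence))
    regex = model.regex()
    hits = []
    pos = lo - 1
    while True:
        m = regex.search(sequence, pos)
        if m is None or m.start() > hi - 1:
            break
        text = m.group(0)
        hits.append(
            MotifHit(
                motif_name=model.name,
                start=m.start() + 1,
                matched_text=text,
                variant_label=_label(model, text),
            )
        )
        pos = m.start() + 1  # overlapping matches allowed
    return hits


def profile_protein(
    protein_id: str,
    sequence: str,
    motif_models: dict[str, MotifModel] | None = None,
    required: frozenset[str] = REQUIRED_DEFAULT,
    nadph_mode: str = "strict",
    truncated_below: int = 300,
) -> MotifProfile:
    """Scan the four motifs in their canonical order and judge canonicality.

    The FAD motif is searched first (N-terminal window); the NAD(P)H motif
    only downstream of the first FAD hit (minimum spacing from the model
    window); the identifying motif between the two; the ATG-containing motif
    downstream of the NAD(P)H site.  When an anchor motif is missing the
    dependent window falls back to the whole sequence, so ablating one motif
    never hides another.  ``canonical`` is True iff every required motif has
    at least one hit.  ``nadph_mode="relaxed"`` accepts any G-led hexamer
    with hydrophobic context at the NAD(P)H position (only the first glycine
    of this Rossmann motif is strongly conserved in the family).
    """
    models = motif_models or default_motif_models()
    hits: dict[str, list[MotifHit]] = {}
    if not sequence:
        missing = frozenset(models)
        return MotifProfile(protein_id, {m: [] for m in models}, False, missing)
    _validate_sequence(sequence)
    n = len(sequence)

    fad = models[FAD_BINDING]
    hits[FAD_BINDING] = scan_motif(sequence, fad)
    fad_hit = hits[FAD_BINDING][0] if hits[FAD_BINDING] else None

    nadph = models[NADPH_BINDING]
    spacing = (nadph.window or (60, None))[0]
    if fad_hit is not None:
        nadph_window = (fad_hit.start + spacing, None)
    else:
        nadph_window = (1, None)
    hits[NADPH_BINDING] = scan_motif(sequence, nadph, window=nadph_window)
    nadph_relaxed = False
    if not hits[NADPH_BINDING] and nadph_mode == "relaxed":
        lo = nadph_window[0]
        for m in RELAXED_NADPH.finditer(sequence, max(0, lo - 1)):
            context = m.group(0)[1:]
            if sum(c in _HYDROPHOBIC for c in context) >= 2:
                hits[NADPH_BINDING].append(
                    MotifHit(NADPH_BINDING, m.start() + 1, m.group(0), "relaxed")
                )
        nadph_relaxed = bool(hits[NADPH_BINDING])
    nadph_hit = hits[NADPH_BINDING][0] if hits[NADPH_BINDING] else None

    ident = models[FMO_IDENTIFYING]
    lo = fad_hit.start + len(fad.pattern) if fad_hit else 1
    hi = nadph_hit.start - 1 if nadph_hit else None
    hits[FMO_IDENTIFYING] = scan_motif(sequence, ident, window=(lo, hi))
    if not hits[FMO_IDENTIFYING] and (fad_hit or nadph_hit):
        hits[FMO_IDENTIFYING] = scan_motif(sequence, ident, window=(1, None))

    atg = models[ATG_CONTAINING]
    lo = nadph_hit.start + 6 if nadph_hit else 1
    hits[ATG_CONTAINING] = scan_motif(sequence, atg, window=(lo, None))
    if not hits[ATG_CONTAINING] and nadph_hit:
        hits[ATG_CONTAINING] = scan_motif(sequence, atg, window=(1, None))

    missing = frozenset(name for name, hs in hits.items() if not hs)
    canonical = not (missing & required)
    return MotifProfile(
        protein_id=protein_id,
        hits=hits,
        canonical=canonical,
        missing=missing,
        truncated=n < truncated_below,
        nadph_relaxed=nadph_relaxed,
    )


# ---------------------------------------------------------------------------
# domain architecture from HMM domain hits
# ---------------------------------------------------------------------------

FMO_DOMAIN_LABELS = frozenset({"FMO-like", "FMO_like", "Flavin_mOase"})
KINASE_DOMAIN_LABELS = frozenset({"Pkinase", "Pkinase_Tyr", "kinase"})
REDOX_DOMAIN_LABELS = frozenset({"Pyr_redox", "Pyr_redox_2", "Pyr_redox_3"})


def _merge_hits(hits):
    """Merge same-domain hits whose envelope overlap exceeds half of the
    shorter envelope, keeping the union interval."""
    merged: list[list] = []
    for h in sorted(hits, key=lambda h: (h.env_start, h.env_end)):
        if merged:
            s, e = merged[-1]
            ov = min(e, h.env_end) - max(s, h.env_start) + 1
            shorter = min(e - s + 1, h.env_end - h.env_start + 1)
            if ov > 0.5 * shorter:
                merged[-1][1] = max(e, h.env_end)
                continue
        merged.append([h.env_start, h.env_end])
    return merged


def assign_architecture(
    protein_id: str,
    domain_hits,
    fmo_labels: frozenset[str] = FMO_DOMAIN_LABELS,
    kinase_labels: frozenset[str] = KINASE_DOMAIN_LABELS,
    redox_labels: frozenset[str] = REDOX_DOMAIN_LABELS,
) -> Architecture:
    """Label a protein's domain architecture from E-value-filtered hits.

    Overlapping same-domain hits are merged before counting.  A kinase
    domain anywhere wins (FMO-kinase fusion proteins); otherwise two or more
    FMO-like domains give the tandem-domain label, one gives the single
    label, a pyridine-redox domain alone gives the redox label, and an empty
    hit list is ``other``.
    """
    by_name: dict[str, list] = {}
    for h in domain_hits:
        by_name.setdefault(h.domain_name, []).append(h)
    n_fmo = sum(
        len(_merge_hits(hs)) for name, hs in by_name.items() if name in fmo_labels
    )
    has_kinase = any(name in kinase_labels for name in by_name)
    has_redox = any(name in redox_labels for name in by_name)
    if has_kinase:
        label = "kinase_fusion"
    elif n_fmo >= 2:
        label = "FMO_like_x2"
    elif n_fmo == 1:
        label = "FMO_like"
    elif has_redox:
        label = "Pyr_redox_like"
    else:
        label = "other"
    return Architecture(protein_id=protein_id, label=label, n_fmo_domains=n_fmo)
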