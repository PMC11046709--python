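"""Motif grammar scanning, canonicality profiling, domain architectures."""

import re

import numpy as np
import pytest

from polyfam.io_formats import DomainHit
from polyfam import motif_scan as ms


def make_protein(fad=15, ident=170, nadph=190, atg=330, atg_text="FATGY", length=420):
    """Background without G/F/H/W/Y so only planted motifs can match."""
    rng = np.random.default_rng(2024)
    seq = list(rng.choice(list("ACDEIKLMNPQRSTV"), size=length))
    seq[0] = "M"
    if fad:
        for off in (0, 2, 5):
            seq[fad - 1 + off] = "G"
    if ident:
        seq[ident - 1], seq[ident + 1], seq[ident + 5], seq[ident + 9] = "F", "G", "H", "Y"
    if nadph:
        for off in (0, 2, 5):
            seq[nadph - 1 + off] = "G"
    if atg:
        seq[atg - 1 : atg - 1 + len(atg_text)] = list(atg_text)
    return "".join(seq)


# ------------------------------------------------------------------- patterns

@pytest.mark.parametrize(
    "pattern,text,matches",
    [
        ("GxGxxG", "GAGTTG", True),
        ("GxGxxG", "GAGTTA", False),
        ("FxGxxxHxxxY/F", "FAGAAAHAAAY", True),
        ("FxGxxxHxxxY/F", "FAGAAAHAAAF", True),
        ("FxGxxxHxxxY/F", "FAGAAAHAAAA", False),
        ("(F/L)ATGY", "LATGY", True),
        ("(F/L)ATGY", "MATGY", False),
    ],
)
def test_compile_pattern(pattern, text, matches):
    assert bool(ms.compile_pattern(pattern).fullmatch(text)) is matches


# ----------------------------------------------------------------- scan_motif

def test_planted_fad_coordinate():
    seq = make_protein(fad=12, ident=170, nadph=190)
    hits = ms.scan_motif(seq, ms.default_motif_models()[ms.FAD_BINDING])
    assert hits and hits[0].start == 12


def test_no_hits_without_glycine():
    model = ms.default_motif_models()[ms.FAD_BINDING]
    assert ms.scan_motif("AAAAAA", model) == []


def test_atg_variant_label():
    seq = make_protein(atg_text="FATGY")
    hits = ms.scan_motif(seq, ms.default_motif_models()[ms.ATG_CONTAINING], window=(1, None))
    assert any(h.variant_label == "FATGY" for h in hits)


def test_unknown_residue_rejected():
    with pytest.raises(ValueError, match="position 3"):
        ms.scan_motif("MA*G", ms.default_motif_models()[ms.FAD_BINDING])


def test_scanner_agrees_with_bruteforce_oracle():
    """Windowed scanning equals scanning every position with a plain regex."""
    rng = np.random.default_rng(42)
    models = ms.default_motif_models()
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(300):
        n = int(rng.integers(30, 200))
        seq = "".join(rng.choice(alphabet, size=n))
        for model in models.values():
            regex = ms.compile_pattern(model.pattern)
            L_lo, L_hi = 10, max(11, n - 5)
            got = {h.start for h in ms.scan_motif(seq, model, window=(L_lo, L_hi))}
            want = {
                i + 1
                for i in range(L_lo - 1, L_hi)
                if regex.match(seq, i) and regex.match(seq, i).start() == i
            }
            assert got == want


# ------------------------------------------------------------ profile_protein

def test_full_complement_is_canonical():
    p = ms.profile_protein("p", make_protein())
    assert p.canonical and not p.missing and not p.truncated


def test_w_variant_counts_as_present():
    seq = list(make_protein())
    seq[169] = "W"  # canonical F swapped for W at the identifying motif
    p = ms.profile_protein("p", "".join(seq))
    assert p.canonical
    assert p.hits[ms.FMO_IDENTIFYING][0].variant_label == "W-variant"


def test_planted_ablation_detected_exactly():
    rng = np.random.default_rng(1)
    ablated = sorted(rng.choice(20, size=6, replace=False))
    required = [ms.FAD_BINDING, ms.NADPH_BINDING, ms.FMO_IDENTIFYING]
    flagged = []
    for i in range(20):
        kwargs = {}
        if i in ablated:
            kwargs[("fad", "nadph", "ident")[i % 3]] = 0
        seq = make_protein(**{**dict(fad=15, ident=170, nadph=190), **kwargs})
        p = ms.profile_protein(f"p{i}", seq)
        if not p.canonical:
            flagged.append(i)
        if i in ablated:
            assert p.missing & set(required)
    assert flagged == ablated


def test_empty_sequence_profile():
    p = ms.profile_protein("p", "")
    assert not p.canonical and p.missing == frozenset(ms.default_motif_models())


def test_truncated_flag():
    p = ms.profile_protein("p", make_protein(length=280, atg=None))
    assert p.truncated


def test_atg_absence_not_required_by_default():
    p = ms.profile_protein("p", make_protein(atg=None))
    assert p.canonical and ms.ATG_CONTAINING in p.missing
    strict = ms.profile_protein(
        "p", make_protein(atg=None),
        required=frozenset({*ms.REQUIRED_DEFAULT, ms.ATG_CONTAINING}),
    )
    assert not strict.canonical


def test_relaxed_nadph_mode():
    seq = list(make_protein())
    seq[191] = "A"  # kill the second glycine: strict GxGxxG fails
    seq[190] = "V"  # hydrophobic context after the conserved first G
    seq[193] = "L"
    strict = ms.profile_protein("p", "".join(seq))
    relaxed = ms.profile_protein("p", "".join(seq), nadph_mode="relaxed")
    assert ms.NADPH_BINDING in strict.missing
    assert relaxed.canonical and relaxed.nadph_relaxed


def test_monotone_ablation_and_extension():
    seq = make_protein()
    base = ms.profile_protein("p", seq)
    assert base.canonical
    # removing the first FAD glycine flips canonical off
    ablated = seq[:14] + "A" + seq[15:]
    assert not ms.profile_protein("p", ablated).canonical
    # appending residues never removes existing hits
    extended = ms.profile_protein("p", seq + "ACDE" * 10)
    for name in base.hits:
        got = {h.start for h in extended.hits[name]}
        assert {h.start for h in base.hits[name]} <= got


# --------------------------------------------------------------- architecture

def _hit(domain, s, e):
    return DomainHit("p", domain, s, e, 50.0, 1e-10)


@pytest.mark.parametrize(
    "hits,label,n_fmo",
    [
        ([_hit("FMO-like", 10, 200), _hit("FMO-like", 220, 400)], "FMO_like_x2", 2),
        ([_hit("FMO-like", 10, 200)], "FMO_like", 1),
        ([_hit("FMO-like", 10, 200), _hit("Pkinase", 250, 400)], "kinase_fusion", 1),
        ([_hit("Pyr_redox_3", 10, 200)], "Pyr_redox_like", 0),
        ([], "other", 0),
    ],
)
def test_assign_architecture(hits, label, n_fmo):
    arch = ms.assign_architecture("p", hits)
    assert (arch.label, arch.n_fmo_domains) == (label, n_fmo)


def test_overlapping_hits_merge_before_counting():
    # two heavily overlapping envelopes are one domain, not two
    hits = [_hit("FMO-like", 10, 200), _hit("FMO-like", 50, 210)]
    assert ms.assign_architecture("p", hits).label == "FMO_like"
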