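"""Worked-example clone panel.

A bundled panel of ELISA-characterized scFv phage clones selected from a
multiple-sclerosis patient antibody library by biopanning on LMP-1 (Epstein-Barr
virus latent membrane protein 1) alone or sequentially on LMP-1 and myelin basic
protein (MBP).  Each entry records the germline V/(D)/J assignments and the
heavy- and/or light-chain CDR3 amino-acid sequences, plus semi-quantitative
ELISA binding symbols.  The panel drives worked examples and round-trip tests:
fixture reads are rebuilt from the toy germline reference and must annotate back
to these germline names and CDR3 strings.

Binding symbols: signal over the M13K07 negative-control phage background —
"±" >1.5-fold, "+" >3-fold, "++" >6-fold, "+++" >9-fold, "ND" not determined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "PaperCloneFixture",
    "load_paper_fixtures",
    "build_fixture_read",
    "SELECTED_BUT_UNCLONED_H_CDR3",
]

#: H-CDR3 that showed strong quantitative selection on both MBP and LMP-1 in the
#: sequencing analysis but was never recovered by monoclonal phage ELISA.  The
#: source table typesets it with spaces ("ARGATSTR LLSRR GHAFDV"); the
#: concatenated form is used here and the original layout recorded alongside.
SELECTED_BUT_UNCLONED_H_CDR3 = "ARGATSTRLLSRRGHAFDV"
SELECTED_BUT_UNCLONED_H_CDR3_PRINTED = "ARGATSTR LLSRR GHAFDV"


@dataclass(frozen=True)
class PaperCloneFixture:
    """One row of the ELISA panel.

    Light-chain-only clones (selected as free light chains) carry ``None`` in
    every heavy-chain field.  ``printed_l_cdr3`` / ``printed_h_cdr3`` keep the
    original typesetting when it contained spaces; the canonical fields are
    space-normalized.
    """

    code: str
    selection: str  # "LMP1/MBP" or "LMP1"
    v_h: Optional[str] = None
    d_h: Optional[str] = None
    j_h: Optional[str] = None
    h_cdr3: Optional[str] = None
    v_l: Optional[str] = None
    j_l: Optional[str] = None
    l_cdr3: Optional[str] = None
    binding_lmp1: str = "ND"
    binding_mbp: str = "ND"
    aliases: tuple[str, ...] = field(default_factory=tuple)
    printed_h_cdr3: Optional[str] = None
    printed_l_cdr3: Optional[str] = None


_PANEL: tuple[PaperCloneFixture, ...] = (
    PaperCloneFixture("b7", "LMP1/MBP", "IGHV1-2*04", "IGHD1-26*01", "IGHJ4*02",
                      "VRGSTYSPSGYFEY", "IGKV5-2*01", "IGKJ2*01", "LQHDNFP", "+", "++"),
    PaperCloneFixture("g10", "LMP1/MBP", "IGHV1-3*01", "IGHD6-13*01", "IGHJ4*02",
                      "ARIFEGLSGIAAPFDY", "IGKV4-1*01", "IGKJ4*01", "QQYFSSPLT", "+", "±"),
    PaperCloneFixture("h1", "LMP1/MBP", "IGHV1-8*01", "IGHD4-17*01", "IGHJ6*03",
                      "AREVSDYSDYGDVYYMDV", "IGKV3-20*01", "IGKJ5*01", "QQYCCSPIT",
                      "±", "±", printed_l_cdr3="QQYCC SPIT"),
    PaperCloneFixture("e11", "LMP1/MBP", "IGHV1-8*01", "IGHD4-17*01", "IGHJ6*03",
                      "AREVSDYSDYGDVYYMDV", "IGLV1-44*01", "IGLJ3*02", "AAWDGSLNGP", "±", "±"),
    PaperCloneFixture("h11", "LMP1/MBP", "IGHV1-18*04", "IGHD3-3*02", "IGHJ2*01",
                      "ARREEGLYTTSPGYFGV", "IGLV3-21*03", "IGLJ7*02", "RVWDKQTVSRSG", "±", "+"),
    PaperCloneFixture("e12", "LMP1/MBP", "IGHV1-46*01", "IGHD4-11*01", "IGHJ6*02",
                      "ARRGFDY", "IGKV1-33*01", "IGKJ1*01", "LQFYEFPYT", "±", "±"),
    PaperCloneFixture("c11", "LMP1/MBP", "IGHV1-46*03", "IGHD5-12*01", "IGHJ6*03",
                      "AKDLRPRDIGDMDV", "IGKV1-39*01", "IGKJ5*01", "QQSYSSP", "±", "+"),
    PaperCloneFixture("c12", "LMP1/MBP", "IGHV1-69*06", "IGHD1-26*01", "IGHJ6*02",
                      "ARCGILRSHYFYGMDV", "IGLV1-47*01", "IGLJ7*01", "AAWDDSLSG", "±", "+"),
    PaperCloneFixture("a6", "LMP1/MBP", "IGHV3-7*01", "IGHD4-11*01", "IGHJ6*02",
                      "VRGGLGAGADY", "IGLV4-69*01", "IGLJ7*01", "QTWGTGI", "+", "++"),
    PaperCloneFixture("c3", "LMP1/MBP", "IGHV4-b*01", "IGHD2-21*01", "IGHJ5*01",
                      "AGLTQSSHNDAN", "IGKV2-30*01", "IGKJ1*01", "MQATHWP", "±", "+"),
    PaperCloneFixture("f11", "LMP1/MBP", v_l="IGLV1-47*01", j_l="IGLJ3*02",
                      l_cdr3="VAWDDNLSG", binding_lmp1="±", binding_mbp="±",
                      aliases=("e1 LL",)),
    PaperCloneFixture("c2", "LMP1/MBP", v_l="IGLV3-1*01", j_l="IGLJ7*01",
                      l_cdr3="AAWDDSLNGPV", binding_lmp1="±", binding_mbp="±"),
    PaperCloneFixture("d1", "LMP1/MBP", v_l="IGLV6-57*01", j_l="IGLJ7*01",
                      l_cdr3="QSYNTSTLI", binding_lmp1="±", binding_mbp="±"),
    PaperCloneFixture("a1", "LMP1/MBP", v_l="IGLV10-54*01", j_l="IGLJ3*02",
                      l_cdr3="SVWDSSLSA", binding_lmp1="±", binding_mbp="±"),
    PaperCloneFixture("h4 LL", "LMP1", "IGHV3-23*01", "IGHD6-13*01", "IGHJ2*01",
                      "AKDIAAAATTPEY", "IGKV3-11*01", "IGKJ5*01", "QQRSNWPPT", "+++", "ND"),
    PaperCloneFixture("c12 LL", "LMP1", "IGHV5-51*01", "IGHD4-17*01", "IGHJ4*03",
                      "ARFYDSTGSCDY", "IGKV1D-33*01", "IGKJ2*02", "SIIQXKFPLXC", "+++", "ND"),
    PaperCloneFixture("d4 LL", "LMP1", v_l="IGLV1-47*01", j_l="IGLJ7*01",
                      l_cdr3="AAWDDSLSG", binding_lmp1="+++", binding_mbp="ND",
                      aliases=("g3 LL", "b3 LL")),
    PaperCloneFixture("e1 LL", "LMP1", v_l="IGLV1-47*01", j_l="IGLJ3*02",
                      l_cdr3="VAWDDNLSG", binding_lmp1="+++", binding_mbp="ND",
                      aliases=("f11",)),
    PaperCloneFixture("d2 LL", "LMP1", v_l="IGLV10-54*01", j_l="IGLJ3*02",
                      l_cdr3="SVWDSSLSA", binding_lmp1="+++", binding_mbp="ND",
                      aliases=("a1",)),
)


def load_paper_fixtures() -> tuple[PaperCloneFixture, ...]:
    """Return the full ELISA clone panel, in table order."""
    return _PANEL


def get_fixture(code: str) -> PaperCloneFixture:
    for fx in _PANEL:  # exact codes win over aliases (f11 vs "e1 LL")
        if fx.code == code:
            return fx
    for fx in _PANEL:
        if code in fx.aliases:
            return fx
    raise KeyError(f"no fixture clone named {code!r}")


def build_fixture_read(clone_code: str, chain: str, germline=None) -> str:
    """Rebuild a plausible error-free variable-region read for a panel clone.

    The read is the toy germline V (through its CDR3 Cys anchor), a junction
    interior re-encoded from the panel CDR3 amino acids, and the toy germline J
    from its F/W anchor onward.  Where the clone's D allele translates to a
    substring of the CDR3 interior, the D's own codons are used there, so the
    annotator can recover the D call from an exact nucleotide match.

    Parameters
    ----------
    clone_code : panel code, e.g. ``"b7"``.
    chain : ``"heavy"`` or ``"light"``.
    germline : a :class:`~repsel.germline.GermlineSet`; defaults to
        ``build_toy_germline()``.
    """
    from .germline import build_toy_germline, encode_aa

    fx = get_fixture(clone_code)
    if germline is None:
        germline = build_toy_germline()
    if chain == "heavy":
        v_name, j_name, d_name, cdr3 = fx.v_h, fx.j_h, fx.d_h, fx.h_cdr3
    elif chain == "light":
        v_name, j_name, d_name, cdr3 = fx.v_l, fx.j_l, None, fx.l_cdr3
    else:
        raise ValueError(f"chain must be 'heavy' or 'light', got {chain!r}")
    if v_name is None or cdr3 is None:
        raise ValueError(f"clone {clone_code!r} has no {chain}-chain entry")

    v = germline.get(v_name)
    j = germline.get(j_name)
    interior_nt = encode_aa(cdr3)
    if d_name is not None:
        d = germline.get(d_name)
        interior_nt = _substitute_d_codons(cdr3, interior_nt, d.nt_seq)
    return v.nt_seq[: v.anchor_pos + 3] + interior_nt + j.nt_seq[j.anchor_pos:]


def _substitute_d_codons(cdr3_aa: str, interior_nt: str, d_nt: str) -> str:
    """Overwrite the codon-aligned window of ``interior_nt`` where the D segment
    translates (in some frame) to a substring of the CDR3, using the D's own
    nucleotides.  Returns ``interior_nt`` unchanged when no ≥2-aa window exists.
    """
    from .germline import translate_nt

    best: tuple[int, int, str] | None = None  # (aa_len, cdr3_pos, d_window_nt)
    for frame in range(3):
        prot = translate_nt(d_nt[frame:])
        for length in range(len(prot), 1, -1):
            for start in range(0, len(prot) - length + 1):
                window = prot[start : start + length]
                if "*" in window or "X" in window:
                    continue
                pos = cdr3_aa.find(window)
                if pos >= 0 and (best is None or length > best[0]):
                    best = (length, pos, d_nt[frame + 3 * start : frame + 3 * (start + length)])
            if best is not None and best[0] >= length:
                break
    if best is None:
        return interior_nt
    _, pos, window_nt = best
    return interior_nt[: 3 * pos] + window_nt + interior_nt[3 * pos + len(window_nt):]
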