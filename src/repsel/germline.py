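"""Toy germline V/(D)/J reference with CDR3 anchor annotations.

The reference is fully synthetic: segment *names* reuse the allele labels of the
bundled worked-example clone panel (so annotations of fixture reads are
comparable to the panel), but every nucleotide sequence is generated from a
seed.  The construction guarantees the two landmarks that IMGT-style CDR3
extraction relies on:

* every V segment carries a conserved Cys codon (the 2nd-CYS, "Cys-104")
  ``anchor_pos`` nucleotides into the segment, followed by two junction-spare
  codons that exonuclease trimming may remove;
* every J segment carries a Phe/Trp codon ("J-Phe/Trp-118") that begins a
  [FW]-G-X-G motif, preceded by two trimmable codons.

Heavy-chain J anchors are Trp and light-chain J anchors Phe, mirroring the
locus convention of real immunoglobulin J genes.

D segments whose allele name appears in the clone panel embed a codon-aligned
encoding of a short window of the host clone's H-CDR3 interior; this makes the
panel's printed CDR3s constructible over this reference with a recoverable
exact D match, while leaving the segments random everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "GermlineSegment",
    "GermlineSet",
    "GermlineConfig",
    "build_toy_germline",
    "write_germline_fasta",
    "read_germline_fasta",
    "translate_nt",
    "encode_aa",
]

LOCI = ("IGH", "IGK", "IGL")
HEAVY_LOCI = ("IGH",)
LIGHT_LOCI = ("IGK", "IGL")

SENSE_CODONS: tuple[str, ...] = tuple(sorted(standard_dna_table.forward_table))

# deterministic amino-acid -> codon encoding: lexicographically smallest codon
_AA_TO_CODON: dict[str, str] = {}
for _codon in SENSE_CODONS:
    _aa = standard_dna_table.forward_table[_codon]
    if _aa not in _AA_TO_CODON:
        _AA_TO_CODON[_aa] = _codon
_AA_TO_CODON["X"] = "NNN"


def translate_nt(nt: str) -> str:
    """Translate ``nt`` in frame 0, ignoring a trailing partial codon.

    Stop codons appear as ``*``; codons containing ambiguity characters that do
    not resolve to one amino acid appear as ``X``.
    """
    usable = len(nt) - len(nt) % 3
    if usable == 0:
        return ""
    return str(Seq(nt[:usable]).translate())


def encode_aa(aa: str) -> str:
    """Deterministically reverse-translate ``aa`` (X allowed, encoded as NNN)."""
    try:
        return "".join(_AA_TO_CODON[a] for a in aa)
    except KeyError as exc:
        raise ValueError(f"cannot encode amino acid {exc.args[0]!r}") from None


@dataclass(frozen=True)
class GermlineSegment:
    """A single germline gene segment.

    ``anchor_pos`` is the 0-based nucleotide start of the conserved CDR3 anchor
    codon — the 2nd-CYS for V segments, the J-Phe/Trp for J segments — and is
    ``None`` for D segments.  ``frame`` is the reading-frame offset of
    ``nt_seq`` (0 for all toy segments).
    """

    name: str
    locus: str
    segment_class: str  # "V", "D" or "J"
    nt_seq: str
    anchor_pos: Optional[int] = None
    frame: int = 0

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise ValueError(f"unknown locus {self.locus!r}")
        if self.segment_class not in ("V", "D", "J"):
            raise ValueError(f"unknown segment class {self.segment_class!r}")
        if not self.nt_seq or set(self.nt_seq) - set("ACGTN"):
            raise ValueError(f"{self.name}: nt_seq must be non-empty over ACGT")
        if self.segment_class in ("V", "J"):
            if self.anchor_pos is None:
                raise ValueError(f"{self.name}: {self.segment_class} needs an anchor")
            codon = self.anchor_codon
            if self.segment_class == "V" and translate_nt(codon) != "C":
                raise ValueError(f"{self.name}: V anchor codon {codon} is not Cys")
            if self.segment_class == "J":
                motif = translate_nt(self.nt_seq[self.anchor_pos : self.anchor_pos + 12])
                if not (len(motif) == 4 and motif[0] in "FW"
                        and motif[1] == "G" and motif[3] == "G"):
                    raise ValueError(f"{self.name}: J anchor does not start [FW]GXG")

    @property
    def anchor_codon(self) -> str:
        if self.anchor_pos is None:
            raise ValueError(f"{self.name}: D segments have no anchor")
        return self.nt_seq[self.anchor_pos : self.anchor_pos + 3]


@dataclass
class GermlineSet:
    """A named collection of germline segments with fast by-name lookup."""

    segments: list[GermlineSegment]
    version: str = "toy-1"
    _by_name: dict[str, GermlineSegment] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_name = {}
        for seg in self.segments:
            if seg.name in self._by_name:
                raise ValueError(f"duplicate segment name {seg.name!r}")
            self._by_name[seg.name] = seg
        for locus in sorted({s.locus for s in self.segments}):
            for cls in ("V", "J"):
                if not self.select(locus=locus, segment_class=cls):
                    raise ValueError(f"locus {locus} lacks a {cls} segment")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def get(self, name: str) -> GermlineSegment:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no germline segment named {name!r}") from None

    def select(self, locus: str | tuple[str, ...] | None = None,
               segment_class: str | None = None) -> list[GermlineSegment]:
        loci = (locus,) if isinstance(locus, str) else locus
        return [s for s in self.segments
                if (loci is None or s.locus in loci)
                and (segment_class is None or s.segment_class == segment_class)]


@dataclass(frozen=True)
class GermlineConfig:
    """Sizes of the toy reference.

    ``v_codons`` / ``j_codons`` are segment lengths in codons; V needs at least
    13 codons to host an alignable body plus the Cys anchor and two spare
    codons, J at least 7 for two trimmable codons, the [FW]GXG motif and a
    downstream body.  ``extra_*`` add unnamed random alleles per locus on top
    of the named panel alleles.
    """

    v_codons: int = 88
    j_codons: int = 16
    d_len_range: tuple[int, int] = (12, 18)
    extra_v: int = 0
    extra_d: int = 0
    extra_j: int = 0

    def validate(self) -> None:
        if self.v_codons < 13:
            raise ValueError(
                f"v_codons={self.v_codons}: V segment too short to contain an "
                "alignable body and the Cys-104 anchor (need >= 13 codons)")
        if self.j_codons < 7:
            raise ValueError(
                f"j_codons={self.j_codons}: J segment too short to contain the "
                "[FW]GXG anchor motif (need >= 7 codons)")
        lo, hi = self.d_len_range
        if not (5 <= lo <= hi):
            raise ValueError(f"d_len_range={self.d_len_range}: need 5 <= lo <= hi")


def _panel_allele_names() -> dict[tuple[str, str], list[str]]:
    """Allele names of the worked-example panel, keyed by (locus, class)."""
    from .fixtures import load_paper_fixtures

    names: dict[tuple[str, str], list[str]] = {}

    def add(name: Optional[str], cls: str) -> None:
        if name is None:
            return
        locus = name[:3]
        key = (locus, cls)
        names.setdefault(key, [])
        if name not in names[key]:
            names[key].append(name)

    for fx in load_paper_fixtures():
        add(fx.v_h, "V"); add(fx.d_h, "D"); add(fx.j_h, "J")
        add(fx.v_l, "V"); add(fx.j_l, "J")
    return names


def _d_host_windows() -> dict[str, list[str]]:
    """For each panel D allele, the 3-aa CDR3-interior windows it should encode."""
    from .fixtures import load_paper_fixtures

    windows: dict[str, list[str]] = {}
    for fx in load_paper_fixtures():
        if fx.d_h is None or fx.h_cdr3 is None:
            continue
        interior = fx.h_cdr3[2:-2]
        size = min(3, len(interior))
        start = (len(interior) - size) // 2
        window = interior[start : start + size]
        windows.setdefault(fx.d_h, [])
        if window and window not in windows[fx.d_h]:
            windows[fx.d_h].append(window)
    return windows


def _random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n))


def _make_v(rng: np.random.Generator, name: str, locus: str, cfg: GermlineConfig) -> GermlineSegment:
    anchor_codon_idx = cfg.v_codons - 3  # Cys + 2 junction-spare codons
    body = _random_codons(rng, anchor_codon_idx)
    cys = "TGT" if rng.integers(2) == 0 else "TGC"
    spare = _random_codons(rng, 2)
    return GermlineSegment(name, locus, "V", body + cys + spare,
                           anchor_pos=3 * anchor_codon_idx)


def _make_j(rng: np.random.Generator, name: str, locus: str, cfg: GermlineConfig) -> GermlineSegment:
    lead = _random_codons(rng, 2)  # trimmable 5' codons
    if locus == "IGH":
        anchor = "TGG"  # Trp-118
    else:
        anchor = "TTT" if rng.integers(2) == 0 else "TTC"  # Phe-118
    g1 = "GG" + "ACGT"[rng.integers(4)]
    x = _random_codons(rng, 1)
    g2 = "GG" + "ACGT"[rng.integers(4)]
    tail = _random_codons(rng, cfg.j_codons - 6)
    return GermlineSegment(name, locus, "J", lead + anchor + g1 + x + g2 + tail,
                           anchor_pos=6)


def _make_d(rng: np.random.Generator, name: str, cfg: GermlineConfig,
            host_windows: list[str]) -> GermlineSegment:
    lo, hi = cfg.d_len_range
    planted = "".join(encode_aa(w) for w in host_windows)
    if len(planted) < lo:
        pad = rng.integers(lo - len(planted), hi - len(planted) + 1)
        planted = planted + "".join("ACGT"[i] for i in rng.integers(0, 4, pad))
    return GermlineSegment(name, "IGH", "D", planted)


def build_toy_germline(config: GermlineConfig | None = None, seed: int = 0) -> GermlineSet:
    """Generate the synthetic germline reference.

    Deterministic for a fixed ``(config, seed)``.  Always contains every V/D/J
    allele name used by the worked-example clone panel; ``config.extra_*`` add
    further random alleles named ``IG{locus}{class}X-<i>*01``.
    """
    config = config or GermlineConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE9]))

    panel = _panel_allele_names()
    d_windows = _d_host_windows()
    segments: list[GermlineSegment] = []

    for locus in LOCI:
        for name in panel.get((locus, "V"), []):
            segments.append(_make_v(rng, name, locus, config))
        for i in range(config.extra_v):
            segments.append(_make_v(rng, f"{locus}VX-{i + 1}*01", locus, config))
        if locus == "IGH":
            for name in panel.get((locus, "D"), []):
                segments.append(_make_d(rng, name, config, d_windows.get(name, [])))
            for i in range(config.extra_d):
                segments.append(_make_d(rng, f"{locus}DX-{i + 1}*01", config, []))
        for name in panel.get((locus, "J"), []):
            segments.append(_make_j(rng, name, locus, config))
        for i in range(config.extra_j):
            segments.append(_make_j(rng, f"{locus}JX-{i + 1}*01", locus, config))

    return GermlineSet(segments)


# ---------------------------------------------------------------------------
# FASTA + anchor-sidecar round trip

_SIDECAR_HEADER = "name\tlocus\tsegment_class\tanchor_pos\tframe"


def write_germline_fasta(germline: GermlineSet, fasta_path: str | Path,
                         sidecar_path: str | Path | None = None) -> Path:
    """Write segments as FASTA plus a tab-separated anchor sidecar.

    The sidecar defaults to ``<fasta>.anchors.tsv`` and lists, per segment:
    name, locus, class, 0-based anchor position (empty for D), frame.
    Output is byte-stable for a fixed set.
    """
    fasta_path = Path(fasta_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else fasta_path.with_suffix(
        fasta_path.suffix + ".anchors.tsv")
    with open(fasta_path, "w", newline="\n") as fh:
        for seg in germline:
            fh.write(f">{seg.name}\n{seg.nt_seq}\n")
    with open(sidecar_path, "w", newline="\n") as fh:
        fh.write(f"# germline_version={germline.version}\n{_SIDECAR_HEADER}\n")
        for seg in germline:
            anchor = "" if seg.anchor_pos is None else str(seg.anchor_pos)
            fh.write(f"{seg.name}\t{seg.locus}\t{seg.segment_class}\t{anchor}\t{seg.frame}\n")
    return sidecar_path


def read_germline_fasta(fasta_path: str | Path,
                        sidecar_path: str | Path | None = None) -> GermlineSet:
    """Inverse of :func:`write_germline_fasta`."""
    from .io import read_fasta

    fasta_path = Path(fasta_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else fasta_path.with_suffix(
        fasta_path.suffix + ".anchors.tsv")
    seqs = dict(read_fasta(fasta_path))
    version = "unknown"
    meta: dict[str, tuple[str, str, Optional[int], int]] = {}
    with open(sidecar_path) as fh:
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            if line.startswith("#"):
                if "germline_version=" in line:
                    version = line.split("germline_version=", 1)[1].strip()
                continue
            if line == _SIDECAR_HEADER:
                continue
            name, locus, cls, anchor, frame = line.split("\t")
            meta[name] = (locus, cls, int(anchor) if anchor else None, int(frame))
    segments = []
    for name, nt in seqs.items():
        if name not in meta:
            raise ValueError(f"segment {name!r} missing from anchor sidecar")
        locus, cls, anchor, frame = meta[name]
        segments.append(GermlineSegment(name, locus, cls, nt, anchor, frame))
    return GermlineSet(segments, version=version)
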