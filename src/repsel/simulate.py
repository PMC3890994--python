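"""Synthetic scFv repertoire and biopanning-selection simulator.

Emulates the data-generating process behind a phage-display selection
experiment: an initial patient-derived library of heavy- and light-chain
clonotypes with a long-tailed (Zipf) abundance law, V(D)J junctional diversity
(exonuclease trimming + N insertions), light somatic point mutation, rounds of
multiplicative per-clone selection on an antigen, and paired-end amplicon
sequencing with per-base substitution errors.  Every generated read is linked
to its ground-truth clone so downstream annotation and enrichment calls can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .germline import GermlineSegment, GermlineSet, translate_nt

__all__ = [
    "CloneTruth",
    "Repertoire",
    "ReadPair",
    "ReadBatch",
    "simulate_repertoire",
    "assign_fitness",
    "apply_selection",
    "emit_reads",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(nt: str) -> str:
    return nt.translate(_COMP)[::-1]


@dataclass
class CloneTruth:
    """Ground truth for one simulated clonotype.

    ``baseline_freq`` is the clone's frequency in the unselected library;
    current (post-selection) frequencies live on the :class:`Repertoire`.
    ``fitness`` maps an antigen condition name to the clone's multiplicative
    per-round selection weight; missing conditions default to 1.0.
    """

    clone_id: str
    locus: str
    v_name: str
    j_name: str
    full_nt: str
    d_name: Optional[str] = None
    junction_nt: str = ""
    cdr3_aa: Optional[str] = None
    productive: bool = True
    baseline_freq: float = 0.0
    fitness: dict[str, float] = field(default_factory=dict)

    def fitness_for(self, condition: str) -> float:
        return self.fitness.get(condition, 1.0)


@dataclass
class Repertoire:
    """A clonotype collection plus its current frequency vector."""

    clones: list[CloneTruth]
    frequencies: np.ndarray
    chain: str  # "heavy" or "light"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.frequencies) != len(self.clones):
            raise ValueError("frequency vector length != clone count")
        total = self.frequencies.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"frequencies sum to {total}, not 1")

    def __len__(self) -> int:
        return len(self.clones)

    def by_id(self, clone_id: str) -> CloneTruth:
        for clone in self.clones:
            if clone.clone_id == clone_id:
                return clone
        raise KeyError(clone_id)

    def truth_cdr3_counts(self, read_counts: np.ndarray) -> dict[str, int]:
        """Aggregate per-clone read counts by true CDR3 (productive clones)."""
        out: dict[str, int] = {}
        for clone, n in zip(self.clones, read_counts):
            if n and clone.productive and clone.cdr3_aa:
                out[clone.cdr3_aa] = out.get(clone.cdr3_aa, 0) + int(n)
        return out


@dataclass
class ReadPair:
    """One paired-end read with its truth link."""

    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    clone_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass
class ReadBatch:
    """Reads emitted for one (library, chain) with their truth table."""

    library_id: str
    chain: str
    pairs: list[ReadPair]
    clone_read_counts: np.ndarray  # aligned with the source repertoire
    seed: int

    @property
    def truth(self) -> pd.DataFrame:
        return pd.DataFrame({"read_id": [p.read_id for p in self.pairs],
                             "clone_id": [p.clone_id for p in self.pairs]})


# ---------------------------------------------------------------------------
# repertoire generation

def _zipf_frequencies(n: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks ** (-exponent)
    return w / w.sum()


def _geometric_trim(rng: np.random.Generator, mean: float, cap: int) -> int:
    if mean <= 0 or cap <= 0:
        return 0
    # geometric on {0,1,...} with the requested mean, truncated at cap
    return int(min(rng.geometric(1.0 / (1.0 + mean)) - 1, cap))


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _recombine(rng: np.random.Generator, v: GermlineSegment,
               d: Optional[GermlineSegment], j: GermlineSegment,
               trim_mean: float, max_n_insert: int,
               in_frame: bool) -> tuple[str, int, int, Optional[str]]:
    """One V(D)J joining event.  Returns (full_nt, junction_start,
    junction_end, cdr3_aa); cdr3_aa is None for out-of-frame or
    stop-containing junctions.  The junction spans Cys-104 through Phe/Trp-118
    inclusive and always starts at the V anchor position."""
    v_spare = len(v.nt_seq) - v.anchor_pos - 3
    v_trim = _geometric_trim(rng, trim_mean, v_spare)
    j_trim = _geometric_trim(rng, trim_mean, j.anchor_pos)
    v_part = v.nt_seq[: len(v.nt_seq) - v_trim]
    j_part = j.nt_seq[j_trim:]
    d_part = ""
    if d is not None:
        d_left = _geometric_trim(rng, trim_mean, len(d.nt_seq))
        d_right = _geometric_trim(rng, trim_mean, len(d.nt_seq) - d_left)
        d_part = d.nt_seq[d_left : len(d.nt_seq) - d_right]
    n1 = _random_nt(rng, int(rng.integers(0, max_n_insert + 1)))
    n2 = _random_nt(rng, int(rng.integers(0, max_n_insert + 1)))

    junction_len = ((len(v_part) - v.anchor_pos) + len(n1) + len(d_part)
                    + len(n2) + (j.anchor_pos - j_trim + 3))
    shift = (-junction_len) % 3
    if in_frame:
        n2 += _random_nt(rng, shift)
    elif shift == 0:  # force out-of-frame
        n2 += _random_nt(rng, int(rng.integers(1, 3)))

    full = v_part + n1 + d_part + n2 + j_part
    j_end = (len(v_part) + len(n1) + len(d_part) + len(n2)
             + (j.anchor_pos - j_trim) + 3)
    junction = full[v.anchor_pos : j_end]
    cdr3 = None
    if len(junction) % 3 == 0:
        aa = translate_nt(junction)
        if "*" not in aa:
            cdr3 = aa[1:-1]
    return full, v.anchor_pos, j_end, cdr3


def _apply_shm(rng: np.random.Generator, full: str, junction_start: int,
               junction_end: int, rate: float) -> str:
    """Point mutations outside the junction; mutations creating an in-frame
    stop are skipped so productivity is controlled by the junction alone."""
    if rate <= 0:
        return full
    seq = list(full)
    n_pos = rng.binomial(len(full), rate)
    positions = rng.choice(len(full), size=n_pos, replace=False) if n_pos else []
    for pos in sorted(int(p) for p in positions):
        if junction_start <= pos < junction_end:
            continue
        old = seq[pos]
        new = "ACGT"[int(rng.integers(0, 4))]
        if new == old:
            continue
        codon_start = pos - pos % 3
        codon = "".join(seq[codon_start : codon_start + 3])
        mutated = codon[: pos % 3] + new + codon[pos % 3 + 1 :]
        if len(mutated) == 3 and translate_nt(mutated) == "*":
            continue
        seq[pos] = new
    return "".join(seq)


def simulate_repertoire(germline: GermlineSet, n_clones: int, rng_seed: int = 0,
                        chain: str = "heavy", zipf_exponent: float = 1.1,
                        trim_mean: float = 2.0, max_n_insert: int = 10,
                        productive_fraction: float = 0.95,
                        shm_rate: float = 0.005,
                        max_retries: int = 50) -> Repertoire:
    """Simulate ``n_clones`` clonotypes for one chain.

    Heavy-chain clones recombine V-D-J over the IGH locus; light-chain clones
    recombine V-J over IGK/IGL (locus drawn per clone).  Abundances follow a
    Zipf law with the given exponent, rank 1 being clone ``C000001``.  A
    ``productive_fraction`` of clones is forced in-frame and stop-free in the
    junction; the rest are out-of-frame.  Point mutations at ``shm_rate`` per
    base are applied outside the junction.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if chain not in ("heavy", "light"):
        raise ValueError(f"chain must be 'heavy' or 'light', got {chain!r}")
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 0x51]))
    loci = ("IGH",) if chain == "heavy" else ("IGK", "IGL")

    freqs = _zipf_frequencies(n_clones, zipf_exponent)
    clones: list[CloneTruth] = []
    for i in range(n_clones):
        locus = loci[int(rng.integers(len(loci)))]
        vs = germline.select(locus, "V")
        js = germline.select(locus, "J")
        ds = germline.select(locus, "D") if locus == "IGH" else []
        in_frame = bool(rng.random() < productive_fraction)
        for attempt in range(max_retries + 1):
            v = vs[int(rng.integers(len(vs)))]
            j = js[int(rng.integers(len(js)))]
            d = ds[int(rng.integers(len(ds)))] if ds else None
            full, j_start, j_end, cdr3 = _recombine(rng, v, d, j, trim_mean,
                                                    max_n_insert, in_frame)
            if not in_frame or cdr3:
                break
        else:
            raise RuntimeError(
                f"clone {i}: could not build a productive junction in "
                f"{max_retries} retries")
        junction = full[j_start:j_end]
        # protect the junction plus the conserved FR4 [FW]GXG motif (the three
        # codons after the J anchor), mirroring their conservation in vivo
        full = _apply_shm(rng, full, j_start, j_end + 9, shm_rate)
        clones.append(CloneTruth(
            clone_id=f"C{i + 1:06d}", locus=locus, v_name=v.name,
            j_name=j.name, d_name=d.name if d else None, full_nt=full,
            junction_nt=junction, cdr3_aa=cdr3 if in_frame else None,
            productive=in_frame and cdr3 is not None, baseline_freq=freqs[i]))
    return Repertoire(clones, freqs.copy(), chain=chain, seed=rng_seed)


# ---------------------------------------------------------------------------
# selection

def assign_fitness(repertoire: Repertoire, condition: str,
                   clone_ids: Sequence[str] = (), value: float = 20.0,
                   background_sigma: float = 0.0, rng_seed: int = 0,
                   predicate: Callable[[CloneTruth], bool] | None = None) -> list[str]:
    """Set per-clone fitness for one antigen condition (in place).

    Background clones get lognormal(0, ``background_sigma``) weights (exactly
    1.0 when sigma is 0); clones in ``clone_ids`` — or matching ``predicate`` —
    are planted binders with fitness ``value``.  Returns the planted ids.
    """
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 0xF1]))
    planted: list[str] = []
    wanted = set(clone_ids)
    for clone in repertoire.clones:
        if background_sigma > 0:
            clone.fitness[condition] = float(np.exp(rng.normal(0.0, background_sigma)))
        else:
            clone.fitness[condition] = 1.0
        if clone.clone_id in wanted or (predicate is not None and predicate(clone)):
            clone.fitness[condition] = float(value)
            planted.append(clone.clone_id)
    missing = wanted - set(planted)
    if missing:
        raise KeyError(f"unknown clone ids: {sorted(missing)}")
    return planted


def apply_selection(repertoire: Repertoire, antigen_condition: str,
                    n_rounds: int = 1) -> Repertoire:
    """Multiplicative per-round selection: f'_i ∝ f_i · w_i^n_rounds.

    ``n_rounds = 0`` is the identity.  Raises if selection extinguishes the
    library (all weighted frequencies zero).
    """
    if n_rounds < 0:
        raise ValueError("n_rounds must be >= 0")
    w = np.array([c.fitness_for(antigen_condition) for c in repertoire.clones])
    if np.any(w < 0):
        raise ValueError("fitness values must be >= 0")
    new = repertoire.frequencies * w ** n_rounds
    total = new.sum()
    if total <= 0:
        raise ValueError(
            f"selection on {antigen_condition!r} extinguished the library "
            "(all-zero fitness)")
    return Repertoire(repertoire.clones, new / total, chain=repertoire.chain,
                      seed=repertoire.seed)


# ---------------------------------------------------------------------------
# read emission

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate_batch(rng: np.random.Generator, template: str, count: int,
                  error_rate: float) -> list[str]:
    """``count`` noisy copies of ``template`` with iid substitution errors."""
    base = np.array([_BASE_IDX[b] for b in template], dtype=np.uint8)
    mat = np.tile(base, (count, 1))
    if error_rate > 0:
        err = rng.random(mat.shape) < error_rate
        n_err = int(err.sum())
        if n_err:
            mat[err] = (mat[err] + rng.integers(1, 4, n_err).astype(np.uint8)) % 4
    chars = _BASES[mat]
    return [row.tobytes().decode("ascii") for row in chars]


def _qual_batch(rng: np.random.Generator, length: int, count: int) -> list[str]:
    q = rng.integers(30, 41, (count, length)).astype(np.uint8) + 33
    return [row.tobytes().decode("ascii") for row in q]


def emit_reads(repertoire: Repertoire, n_reads: int, error_rate: float = 0.001,
               read_len: int = 250, rng_seed: int = 0,
               library_id: str = "lib", min_overlap: int = 30) -> ReadBatch:
    """Draw paired-end reads multinomially from the current frequencies.

    Mate 1 covers the amplicon 5'→3', mate 2 is the reverse complement of the
    amplicon's last ``read_len`` bases; ``read_len`` must guarantee at least
    ``min_overlap`` overlapping bases on the longest amplicon.  Substitution
    errors are iid per base at ``error_rate``; qualities are uniform Q30–Q40.
    Reads are emitted grouped by clone rank, ids sequential per batch.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    longest = max(len(c.full_nt) for c in repertoire.clones)
    if 2 * read_len - longest < min_overlap:
        raise ValueError(
            f"read_len={read_len} cannot guarantee a {min_overlap}-nt overlap "
            f"on a {longest}-nt amplicon")
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 0xEE]))
    counts = rng.multinomial(n_reads, repertoire.frequencies)

    pairs: list[ReadPair] = []
    idx = 0
    for clone, count in zip(repertoire.clones, counts):
        if count == 0:
            continue
        amplicon = clone.full_nt
        m1 = amplicon[:read_len]
        m2 = revcomp(amplicon[-read_len:])
        seqs1 = _mutate_batch(rng, m1, count, error_rate)
        seqs2 = _mutate_batch(rng, m2, count, error_rate)
        quals1 = _qual_batch(rng, len(m1), count)
        quals2 = _qual_batch(rng, len(m2), count)
        for k in range(count):
            pairs.append(ReadPair(
                read_id=f"{library_id}:{repertoire.chain}:{idx:07d}",
                seq1=seqs1[k], qual1=quals1[k], seq2=seqs2[k], qual2=quals2[k],
                clone_id=clone.clone_id))
            idx += 1
    return ReadBatch(library_id=library_id, chain=repertoire.chain,
                     pairs=pairs, clone_read_counts=counts, seed=rng_seed)
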