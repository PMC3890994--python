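"""File formats: FASTA, FASTQ (Phred+33) and the rearrangement table.

The rearrangement table is an AIRR-flavoured tab-separated file, one row per
read, with a fixed mandatory column set; junction coordinates are 1-based
closed in-file (0-based half-open in memory).  Leading ``#`` lines carry run
metadata (``# key=value``) and are preserved by the reader.  Unknown extra
columns round-trip untouched.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .annotate import AnnotatedRearrangement
from .simulate import ReadPair

__all__ = [
    "read_fasta", "write_fasta", "read_fastq", "write_fastq",
    "write_fastq_pairs", "read_fastq_pairs",
    "REARRANGEMENT_COLUMNS", "annotations_to_frame", "frame_to_annotations",
    "write_rearrangements", "read_rearrangements",
]


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as (name, sequence) pairs; name is the first header token.
    CRLF input is accepted (normalized by universal newlines)."""
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            out.append((title.split()[0], seq.upper()))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTQ (Phred+33) as (id, sequence, quality) tuples.

    Malformed records raise ``ValueError`` reporting the file line at which
    the offending record starts.
    """
    out: list[tuple[str, str, str]] = []
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return out
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed FASTQ record near line "
                    f"{4 * len(out) + 1}: {exc}") from exc
            out.append((title.split()[0], seq.upper(), qual))


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for rid, seq, qual in records:
            if len(seq) != len(qual):
                raise ValueError(f"{rid}: sequence/quality length mismatch")
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_fastq_pairs(pairs: Iterable[ReadPair], path_r1: str | Path,
                      path_r2: str | Path) -> None:
    """Write mates to R1/R2 files with ``/1`` and ``/2`` id suffixes."""
    with open(path_r1, "w", newline="\n") as f1, \
         open(path_r2, "w", newline="\n") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def read_fastq_pairs(path_r1: str | Path, path_r2: str | Path) -> list[ReadPair]:
    r1 = read_fastq(path_r1)
    r2 = read_fastq(path_r2)
    if len(r1) != len(r2):
        raise ValueError(f"mate files differ in record count: "
                         f"{len(r1)} vs {len(r2)}")
    pairs = []
    for (id1, s1, q1), (id2, s2, q2) in zip(r1, r2):
        base1 = id1.rsplit("/", 1)[0]
        base2 = id2.rsplit("/", 1)[0]
        if base1 != base2:
            raise ValueError(f"mate id mismatch: {id1!r} vs {id2!r}")
        pairs.append(ReadPair(base1, s1, q1, s2, q2))
    return pairs


# ---------------------------------------------------------------------------
# rearrangement table

REARRANGEMENT_COLUMNS = (
    "sequence_id", "locus", "v_call", "d_call", "j_call",
    "v_identity", "junction", "junction_start", "junction_end", "cdr3_aa",
    "productive", "pass_filter", "fail_reason", "expected_chain",
)


def annotations_to_frame(records: Iterable[AnnotatedRearrangement],
                         include_sequence: bool = True) -> pd.DataFrame:
    """Tabular view with 1-based closed junction coordinates.

    ``include_sequence`` adds the full merged read as an extra ``sequence``
    column (not part of the mandatory set; large at scale)."""
    rows = []
    for r in records:
        rows.append({
            "sequence_id": r.read_id,
            **({"sequence": r.sequence} if include_sequence else {}),
            "locus": r.locus or "",
            "v_call": r.v_call or "",
            "d_call": r.d_call or "",
            "j_call": r.j_call or "",
            "v_identity": "" if r.v_identity is None else round(r.v_identity, 4),
            "junction": r.junction or "",
            "junction_start": "" if r.junction_start is None else r.junction_start + 1,
            "junction_end": "" if r.junction_end is None else r.junction_end,
            "cdr3_aa": r.cdr3_aa or "",
            "productive": "T" if r.productive else "F",
            "pass_filter": "" if r.pass_filter is None else ("T" if r.pass_filter else "F"),
            "fail_reason": r.fail_reason or "",
            "expected_chain": r.expected_chain,
        })
    columns = list(REARRANGEMENT_COLUMNS)
    if include_sequence:
        columns.insert(1, "sequence")
    return pd.DataFrame(rows, columns=columns)


def frame_to_annotations(frame: pd.DataFrame) -> list[AnnotatedRearrangement]:
    records = []
    has_sequence = "sequence" in frame.columns
    for row in frame.itertuples(index=False):
        js = getattr(row, "junction_start")
        je = getattr(row, "junction_end")
        vi = getattr(row, "v_identity")
        pf = getattr(row, "pass_filter")
        records.append(AnnotatedRearrangement(
            read_id=str(row.sequence_id),
            sequence=str(row.sequence) if has_sequence else "",
            expected_chain=str(row.expected_chain),
            locus=str(row.locus) or None,
            v_call=str(row.v_call) or None,
            d_call=str(row.d_call) or None,
            j_call=str(row.j_call) or None,
            v_identity=None if vi == "" else float(vi),
            junction=str(row.junction) or None,
            junction_start=None if js == "" else int(js) - 1,
            junction_end=None if je == "" else int(je),
            cdr3_aa=str(row.cdr3_aa) or None,
            productive=row.productive == "T",
            pass_filter=None if pf == "" else pf == "T",
            fail_reason=str(row.fail_reason) or None))
    return records


def write_rearrangements(frame: pd.DataFrame, path: str | Path,
                         metadata: Optional[dict] = None) -> None:
    """Write a rearrangement table (or any report table) with ``#`` metadata
    header lines.  Raises if a mandatory column is missing."""
    missing = [c for c in REARRANGEMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"rearrangement frame lacks mandatory columns {missing}")
    write_report_table(frame, path, metadata)


def write_report_table(frame: pd.DataFrame, path: str | Path,
                       metadata: Optional[dict] = None) -> None:
    with open(path, "w", newline="\n") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_rearrangements(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a rearrangement table; returns (frame, metadata).

    Unknown extra columns are preserved untouched; a missing mandatory column
    raises ``ValueError`` naming it.  A header-only file yields an empty
    frame without error.
    """
    frame, metadata = read_report_table(path)
    missing = [c for c in REARRANGEMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    return frame, metadata


def read_report_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    metadata: dict[str, str] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if "=" in body:
                key, value = body.split("=", 1)
                metadata[key.strip()] = value.strip()
    frame = pd.read_csv(path, sep="\t", skiprows=header_lines, dtype=str,
                        keep_default_na=False)
    return frame, metadata
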