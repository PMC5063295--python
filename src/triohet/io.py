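"""Readers and writers for the formats the pipeline touches.

FASTA and FASTQ go through Bio.SeqIO; SAM is parsed line-by-line because the
pipeline only interprets flag 0x4 and CIGAR ops M,=,X,I,D,S and must accept
headerless bodies. Coordinates are 1-based inclusive throughout (SAM
convention). Quality encoding is fixed to Phred+33.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("triohet")

VARIETY_DELIM = "|"
_REF_ALPHABET = frozenset("ACGTN")

#: CIGAR ops that consume the query / the reference, respectively.
QUERY_OPS = frozenset("M=XIS")
REF_OPS = frozenset("M=XD")
_SUPPORTED_OPS = QUERY_OPS | REF_OPS
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class TranscriptSet:
    """An ordered map of transcript_id -> uppercase A/C/G/T/N sequence."""

    def __init__(self, records: Mapping[str, str]):
        clean: dict[str, str] = {}
        for tid, seq in records.items():
            if not tid:
                raise ValueError("empty transcript id")
            if tid in clean:
                raise ValueError(f"duplicate transcript id: {tid!r}")
            seq = str(seq).upper()
            if not seq:
                raise ValueError(f"empty sequence for transcript {tid!r}")
            bad = set(seq) - _REF_ALPHABET
            if bad:
                raise ValueError(
                    f"transcript {tid!r} contains invalid characters: {sorted(bad)}"
                )
            clean[tid] = seq
        self.records = clean

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, tid: str) -> bool:
        return tid in self.records

    def __getitem__(self, tid: str) -> str:
        return self.records[tid]

    def __iter__(self) -> Iterator[str]:
        return iter(self.records)

    def items(self):
        return self.records.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, TranscriptSet) and self.records == other.records


def read_fasta(path) -> TranscriptSet:
    """Load a FASTA file; the first whitespace-delimited header token is the id."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate transcript id: {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return TranscriptSet(records)


def write_fasta(transcripts: TranscriptSet, path) -> None:
    recs = (SeqRecord(Seq(seq), id=tid, description="") for tid, seq in transcripts.items())
    SeqIO.write(recs, str(path), "fasta")


@dataclass
class ReadRecord:
    """A sequencing read with Phred qualities and an optional variety tag.

    The tag convention is ``read_id + "|" + VARIETY``: the pipe survives SAM
    and is rare in instrument read names.
    """

    read_id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )

    @property
    def variety_tag(self) -> str | None:
        if VARIETY_DELIM in self.read_id:
            return self.read_id.rsplit(VARIETY_DELIM, 1)[1]
        return None


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream 4-line Phred+33 FASTQ records."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(
            read_id=rec.id,
            sequence=str(rec.seq).upper(),
            qualities=list(rec.letter_annotations["phred_quality"]),
        )


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if not ops or "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return ops


@dataclass
class AlignmentRecord:
    read_id: str
    transcript_id: str
    pos: int  # 1-based leftmost reference position
    cigar: list[tuple[int, str]]
    sequence: str
    qualities: list[int]
    is_unmapped: bool = False

    def query_length(self) -> int:
        return sum(n for n, op in self.cigar if op in QUERY_OPS)

    def reference_length(self) -> int:
        return sum(n for n, op in self.cigar if op in REF_OPS)


def read_sam(path, stats: dict | None = None) -> Iterator[AlignmentRecord]:
    """Stream SAM body lines as AlignmentRecords.

    Header lines (``@``) are ignored, so headerless bodies parse too. Records
    whose CIGAR uses ops outside M,=,X,I,D,S (i.e. N/H/P) are skipped with a
    logged warning; the count lands in ``stats["skipped_unsupported_cigar"]``
    when a stats dict is supplied.
    """
    if stats is not None:
        stats.setdefault("skipped_unsupported_cigar", 0)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: SAM line has {len(fields)} fields")
            qname, flag, rname, pos, _mapq, cigar, _rn, _pn, _tl, seq, qual = fields[:11]
            unmapped = bool(int(flag) & 0x4)
            if unmapped:
                yield AlignmentRecord(qname, rname, max(int(pos), 1), [], seq,
                                      _decode_qual(qual, seq), is_unmapped=True)
                continue
            ops = parse_cigar(cigar)
            unsupported = {op for _, op in ops} - _SUPPORTED_OPS
            if unsupported:
                log.warning("skipping %s: unsupported CIGAR op(s) %s", qname,
                            "".join(sorted(unsupported)))
                if stats is not None:
                    stats["skipped_unsupported_cigar"] += 1
                continue
            rec = AlignmentRecord(qname, rname, int(pos), ops, seq.upper(),
                                  _decode_qual(qual, seq))
            if rec.sequence != "*" and rec.query_length() != len(rec.sequence):
                raise ValueError(
                    f"{path}:{lineno}: CIGAR consumes {rec.query_length()} query "
                    f"bases but read {qname!r} has {len(rec.sequence)}"
                )
            yield rec


def _decode_qual(qual: str, seq: str) -> list[int]:
    if qual == "*":
        return [0] * (0 if seq == "*" else len(seq))
    return [ord(c) - 33 for c in qual]


def write_sam(alignments: Iterable[AlignmentRecord], reference: TranscriptSet, path) -> None:
    """Write alignments with a minimal @HD/@SQ header."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for tid, seq in reference.items():
            fh.write(f"@SQ\tSN:{tid}\tLN:{len(seq)}\n")
        for a in alignments:
            flag = 4 if a.is_unmapped else 0
            cigar = "".join(f"{n}{op}" for n, op in a.cigar) if a.cigar else "*"
            qual = "".join(chr(q + 33) for q in a.qualities) if a.qualities else "*"
            fh.write(
                f"{a.read_id}\t{flag}\t{a.transcript_id}\t{a.pos}\t60\t{cigar}"
                f"\t*\t0\t0\t{a.sequence}\t{qual}\n"
            )


def write_table(rows: Sequence[Mapping], path, columns: Sequence[str] | None = None) -> None:
    """Write rows as a tab-separated table with a header line.

    Column order follows ``columns`` when given, else the key order of the
    first row; all rows must share the same keys.
    """
    rows = list(rows)
    if columns is None:
        if not rows:
            raise ValueError("cannot infer columns from zero rows; pass columns=")
        columns = list(rows[0].keys())
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=list(columns), delimiter="\t")
        w.writeheader()
        for row in rows:
            w.writerow(row)


def read_table(path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
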