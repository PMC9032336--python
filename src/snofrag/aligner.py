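"""Perfect-match placement of trimmed reads on snoRNA precursors.

Reads are counted only when the entire trimmed read matches a precursor
subsequence exactly (100% identity, ungapped) and is at least 20 nt long.
Under this regime, seed-and-extend from an indexed 6-mer word map is exactly
equivalent to exhaustive substring search: every full-read match begins with
the read's first word, so looking up that word's occurrences enumerates all
candidate placements. The e-value parameter of the original BLAST-based
protocol is vestigial here (a whole-read exact match of >=20 nt is always
reported) and is deliberately not modelled.

Alignment only on the sense strand by default: small RNA libraries are
stranded and sdRNAs are subsequences of the precursor transcript. Pass
``search_reverse_complement=True`` to also scan the reverse complement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from snofrag.ingest import NcRNARecord, SmallRNARead

logger = logging.getLogger(__name__)

DEFAULT_WORD_SIZE = 6
DEFAULT_MIN_ALIGN_LEN = 20
DEFAULT_BOUNDARY_SLOP = 3

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True, slots=True)
class Alignment:
    """A perfect ungapped placement of a whole trimmed read on a precursor.

    Coordinates are 0-based half-open internally; rendered reports use
    1-based inclusive.
    """

    read_id: str
    ncrna_id: str
    start: int
    end: int
    library_id: str = ""
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReferenceIndex:
    """Word map over a precursor set: every length-``word_size`` substring of
    every precursor maps to its (ncrna_id, position) occurrences."""

    word_size: int
    words: dict[str, list[tuple[str, int]]]
    sequences: dict[str, str]
    records: dict[str, NcRNARecord] = field(default_factory=dict)


def build_reference_index(
    records: Iterable[NcRNARecord],
    word_size: int = DEFAULT_WORD_SIZE,
) -> ReferenceIndex:
    """Index every ``word_size``-mer of every precursor.

    Records shorter than ``word_size`` are skipped with a warning.
    Occurrence lists are ordered by (ncrna_id, position).
    """
    if word_size < 4:
        raise ValueError("word_size must be >= 4")
    words: dict[str, list[tuple[str, int]]] = {}
    sequences: dict[str, str] = {}
    record_map: dict[str, NcRNARecord] = {}
    for rec in sorted(records, key=lambda r: r.id):
        if len(rec.sequence) < word_size:
            logger.warning(
                "skipping record %s: length %d < word_size %d",
                rec.id,
                len(rec.sequence),
                word_size,
            )
            continue
        sequences[rec.id] = rec.sequence
        record_map[rec.id] = rec
        seq = rec.sequence
        for pos in range(len(seq) - word_size + 1):
            words.setdefault(seq[pos : pos + word_size], []).append((rec.id, pos))
    return ReferenceIndex(
        word_size=word_size, words=words, sequences=sequences, records=record_map
    )


def find_perfect_alignments(
    read: SmallRNARead | str,
    index: ReferenceIndex,
    min_align_len: int = DEFAULT_MIN_ALIGN_LEN,
    library_id: str | None = None,
    search_reverse_complement: bool = False,
) -> list[Alignment]:
    """All placements where the whole trimmed read equals a precursor
    subsequence exactly.

    Reads shorter than ``min_align_len`` or containing N return no
    alignments (N never matches). Multi-mapping reads yield one Alignment
    per placement, ordered by (ncrna_id, start).
    """
    if isinstance(read, str):
        seq, read_id, lib = read, "", library_id or ""
    else:
        seq, read_id = read.sequence, read.read_id
        lib = library_id if library_id is not None else read.library_id
    if min_align_len < index.word_size:
        raise ValueError("min_align_len must be >= word_size")
    n = len(seq)
    if n < min_align_len or "N" in seq:
        return []

    out: list[Alignment] = []
    queries = [(seq, "+")]
    if search_reverse_complement:
        queries.append((reverse_complement(seq), "-"))
    sequences = index.sequences
    for query, strand in queries:
        for rid, pos in index.words.get(query[: index.word_size], ()):
            if sequences[rid][pos : pos + n] == query:
                out.append(
                    Alignment(
                        read_id=read_id,
                        ncrna_id=rid,
                        start=pos,
                        end=pos + n,
                        library_id=lib,
                        strand=strand,
                    )
                )
    out.sort(key=lambda a: (a.ncrna_id, a.start, a.strand))
    return out


def align_library(
    library,
    index: ReferenceIndex,
    min_align_len: int = DEFAULT_MIN_ALIGN_LEN,
) -> list[Alignment]:
    """Align all surviving (trimmed, non-failed) reads of a library."""
    word_size = index.word_size
    words_get = index.words.get
    sequences = index.sequences
    lib_id = library.library_id
    out: list[Alignment] = []
    for read in library.reads:
        if read.failed:
            continue
        seq = read.sequence
        n = len(seq)
        if n < min_align_len or "N" in seq:
            continue
        hits = words_get(seq[:word_size])
        if not hits:
            continue
        for rid, pos in hits:
            if sequences[rid][pos : pos + n] == seq:
                out.append(
                    Alignment(
                        read_id=read.read_id,
                        ncrna_id=rid,
                        start=pos,
                        end=pos + n,
                        library_id=lib_id,
                    )
                )
    return out


def count_locus_hits(
    alignments: Sequence[Alignment],
    ncrna_id: str,
    interval: tuple[int, int],
    index: ReferenceIndex | None = None,
    boundary_slop: int = DEFAULT_BOUNDARY_SLOP,
) -> tuple[int, int]:
    """Count alignments attributed to a locus on one precursor.

    Returns ``(in_locus, total)`` where ``total`` counts all alignments to
    ``ncrna_id`` and ``in_locus`` those contained within the locus interval
    extended by ``boundary_slop`` on both sides (strict containment, no
    partial credit).
    """
    if index is not None and ncrna_id not in index.sequences:
        raise KeyError(f"unknown ncrna_id {ncrna_id!r}")
    start, end = interval
    if start < 0 or end <= start:
        raise ValueError(f"bad locus interval {interval}")
    lo, hi = start - boundary_slop, end + boundary_slop
    total = 0
    in_locus = 0
    for aln in alignments:
        if aln.ncrna_id != ncrna_id:
            continue
        total += 1
        if aln.start >= lo and aln.end <= hi:
            in_locus += 1
    return in_locus, total


def write_alignments_tsv(alignments: Iterable[Alignment], path) -> None:
    """Headered TSV dump (1-based inclusive coordinates in `start_1based`)."""
    with open(path, "w") as fh:
        fh.write("read_id\tncrna_id\tstart_1based\tend\tlength\tlibrary_id\n")
        for a in alignments:
            fh.write(
                f"{a.read_id}\t{a.ncrna_id}\t{a.start + 1}\t{a.end}\t"
                f"{a.length}\t{a.library_id}\n"
            )


def write_alignments_bed(alignments: Iterable[Alignment], path) -> None:
    """BED6 export: name=read_id, score=alignment length, strand=+."""
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(
                f"{a.ncrna_id}\t{a.start}\t{a.end}\t{a.read_id}\t"
                f"{a.length}\t{a.strand}\n"
            )
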