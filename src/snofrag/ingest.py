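"""Reference and small RNA library ingest: FASTA/FASTQ reading, 3' adapter
trimming, and read-level QC.

Sequences are normalized to the DNA alphabet (U -> T, uppercase) on input.
Adapter trimming is exact-match only: the longest read suffix equal to a
prefix of the adapter (at least ``min_overlap`` nt) is removed, matching the
all-perfect-match regime used for alignment downstream. Reads whose insert is
shorter than ``min_length`` after trimming are flagged as failed, never
silently dropped, and are excluded from the library's reads-per-million
denominator.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

#: Illumina TruSeq Small RNA RA3 3' adapter. A config default, never baked
#: into trimming logic; any adapter sequence may be passed instead.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

DEFAULT_MIN_OVERLAP = 6
DEFAULT_MIN_LENGTH = 15

_VALID_BASES = frozenset("ACGTN")

_NORMALIZE = str.maketrans("acgtunU", "ACGTTTT")


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T) alphabet."""
    return str(seq).translate(_NORMALIZE)


class RnaClass(Enum):
    """snoRNA class: C/D box (methylation guides), H/ACA box
    (pseudouridylation guides), or other/unknown."""

    CD_BOX = "CD_box"
    HACA_BOX = "HACA_box"
    OTHER = "other"


class Condition(Enum):
    TUMOR = "tumor"
    NORMAL = "normal"
    AGO_IP = "ago_ip"
    OTHER = "other"


@dataclass(frozen=True)
class NcRNARecord:
    """One snoRNA precursor."""

    id: str
    name: str
    rna_class: RnaClass
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(slots=True)
class SmallRNARead:
    """A single small RNA-seq read, before or after adapter trimming.

    ``failed`` marks reads whose post-trim insert fell below the minimum
    retained length; they stay in the object model for accounting but do not
    enter the RPM denominator.
    """

    read_id: str
    sequence: str
    trimmed: bool = False
    original_length: int = 0
    library_id: str = ""
    failed: bool = False

    def __post_init__(self) -> None:
        if self.original_length == 0:
            self.original_length = len(self.sequence)


@dataclass
class Library:
    """A small RNA library: reads plus the per-sample RPM denominator."""

    library_id: str
    condition: Condition
    reads: list[SmallRNARead] = field(default_factory=list)
    total_reads_post_trim: int = 0


def load_ncrna_reference(
    fasta_source,
    metadata_source=None,
) -> list[NcRNARecord]:
    """Read snoRNA precursors from FASTA, optionally joining a metadata table.

    Parameters
    ----------
    fasta_source
        Path or handle of a FASTA file of precursor sequences.
    metadata_source
        Optional path/handle of a TSV with columns ``id``, ``name``,
        ``class`` (values ``CD_box`` / ``HACA_box`` / ``other``), or a
        mapping ``id -> (name, RnaClass)``. Rows are keyed by FASTA record
        ID; records without metadata default to class ``other``.

    Raises
    ------
    ValueError
        On duplicate record IDs or malformed sequences.
    """
    meta: dict[str, tuple[str, RnaClass]] = {}
    if metadata_source is not None:
        if isinstance(metadata_source, Mapping):
            meta = dict(metadata_source)
        else:
            table = pd.read_csv(metadata_source, sep="\t", dtype=str)
            for _, row in table.iterrows():
                meta[row["id"]] = (
                    row.get("name", row["id"]),
                    RnaClass(row["class"]),
                )

    records: list[NcRNARecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(fasta_source, "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate record ID in reference: {entry.id!r}")
        seen.add(entry.id)
        name, rna_class = meta.get(entry.id, (entry.id, RnaClass.OTHER))
        records.append(
            NcRNARecord(
                id=entry.id,
                name=name,
                rna_class=rna_class,
                sequence=normalize_sequence(str(entry.seq)),
            )
        )
    logger.info("loaded %d ncRNA records", len(records))
    return records


def write_ncrna_fasta(records: Iterable[NcRNARecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def trim_adapter(
    read: SmallRNARead,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> SmallRNARead:
    """Remove the longest read suffix matching a prefix of ``adapter``.

    Exact-match only; the matched overlap must be at least ``min_overlap``
    nt. Reads without such an overlap are returned unmodified with
    ``trimmed=False``. Trimmed reads shorter than ``min_length`` are marked
    ``failed``.
    """
    if not read.sequence:
        raise ValueError(f"read {read.read_id!r}: empty sequence")
    if min_overlap < 1 or len(adapter) < min_overlap:
        raise ValueError("require adapter length >= min_overlap >= 1")
    if read.trimmed:
        return read

    seq = read.sequence
    n = len(seq)
    probe = adapter[:min_overlap]
    # The longest suffix-of-read == prefix-of-adapter match starts at the
    # leftmost occurrence of the adapter's first min_overlap bases that
    # extends to the read end.
    j = seq.find(probe)
    cut = -1
    while j != -1 and j <= n - min_overlap:
        if seq[j:] == adapter[: n - j]:
            cut = j
            break
        j = seq.find(probe, j + 1)

    if cut == -1:
        return replace(read, trimmed=False, original_length=n)
    insert = seq[:cut]
    return SmallRNARead(
        read_id=read.read_id,
        sequence=insert,
        trimmed=True,
        original_length=n,
        library_id=read.library_id,
        failed=len(insert) < min_length,
    )


def trim_library(
    library: Library,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> Library:
    """Trim every read in a library and set the RPM denominator.

    Consumes the input: read objects are updated in place (libraries run to
    millions of reads, so the per-read logic of ``trim_adapter`` is inlined
    here and re-allocation avoided). The returned Library carries the same
    read objects, trimmed.
    """
    if min_overlap < 1 or len(adapter) < min_overlap:
        raise ValueError("require adapter length >= min_overlap >= 1")
    probe = adapter[:min_overlap]
    # suffix length -> adapter prefix of that length (a suffix longer than
    # the adapter can never equal an adapter prefix)
    prefixes = {k: adapter[:k] for k in range(min_overlap, len(adapter) + 1)}
    denom = 0
    for read in library.reads:
        seq = read.sequence
        if not seq:
            raise ValueError(f"read {read.read_id!r}: empty sequence")
        if read.trimmed:
            if not read.failed:
                denom += 1
            continue
        n = len(seq)
        j = seq.find(probe)
        cut = -1
        while j != -1:
            k = n - j
            if k >= min_overlap and seq[j:] == prefixes.get(k):
                cut = j
                break
            j = seq.find(probe, j + 1)
        if cut != -1:
            read.sequence = seq[:cut]
            read.trimmed = True
            read.original_length = n
            read.failed = cut < min_length
        if not read.failed:
            denom += 1
    return Library(
        library_id=library.library_id,
        condition=library.condition,
        reads=library.reads,
        total_reads_post_trim=denom,
    )


def _open_maybe_gzip(source):
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_small_rna_library(
    fastq_source,
    adapter: str = DEFAULT_ADAPTER,
    condition: Condition = Condition.OTHER,
    library_id: str | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> Library:
    """Read a FASTQ file (gzip-transparent), trim adapters, apply length QC.

    ``total_reads_post_trim`` counts reads surviving trimming plus the
    minimum-length rule; it is the per-sample RPM denominator.
    """
    if library_id is None:
        name = Path(fastq_source).name
        for suffix in (".gz", ".fastq", ".fq"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
        library_id = name

    reads: list[SmallRNARead] = []
    with _open_maybe_gzip(fastq_source) as fh:
        try:
            for title, seq, _qual in FastqGeneralIterator(fh):
                read_id = title.split()[0] if title else f"read{len(reads)}"
                reads.append(
                    SmallRNARead(
                        read_id=read_id,
                        sequence=normalize_sequence(seq),
                        library_id=library_id,
                    )
                )
        except ValueError as exc:
            raise ValueError(
                f"truncated/malformed FASTQ {fastq_source} "
                f"near record {len(reads)}: {exc}"
            ) from exc

    lib = trim_library(
        Library(library_id=library_id, condition=condition, reads=reads),
        adapter,
        min_overlap,
        min_length,
    )
    n_failed = sum(1 for r in lib.reads if r.failed)
    n_untrimmed = sum(1 for r in lib.reads if not r.trimmed)
    logger.info(
        "library %s: %d reads, %d post-trim (denominator), %d length-failed, "
        "%d without adapter",
        library_id,
        len(lib.reads),
        lib.total_reads_post_trim,
        n_failed,
        n_untrimmed,
    )
    return lib


def write_library_fastq(library: Library, path) -> None:
    """Write raw (untrimmed) read sequences as FASTQ with dummy qualities."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for read in library.reads:
            fh.write(
                f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n"
            )


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV with columns library_id, path, condition."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"library_id", "path", "condition"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    sheet["condition"] = sheet["condition"].map(Condition)
    return sheet
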