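"""Fragment calling: coverage profiles, Haar step detection, RPM.

A specifically excised sdRNA shows up in per-precursor read coverage as a
sharp rectangular plateau: reads stack with near-identical 5' and 3' ends.
The caller scores every position with an unnormalized single-scale Haar
step response,

    score(i) = mean(depth[i : i + w]) - mean(depth[i - w : i]),

with zero padding at the precursor boundaries (w = ``haar_half_width``).
The response to an ideal step of height h is a triangular peak of apex h at
the step position, so local extrema of |score| above a threshold (a
multiple of the median nonzero |score|) recover plateau boundaries exactly.
Rise/fall extrema are paired into candidate fragments, constrained to the
sdRNA length range (16-36 nt by default), required to carry a minimum
number of supporting reads, and deduplicated by reciprocal overlap.

Discovery is two-pass across a cohort: fragments are called once on pooled
coverage, giving every library the same fragment universe, then quantified
per library in reads per million (RPM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from snofrag.aligner import Alignment, DEFAULT_BOUNDARY_SLOP
from snofrag.ingest import Library, NcRNARecord


@dataclass
class FragCallParams:
    """Tuning for the fragment caller.

    haar_half_width : window half-width w of the step detector, nt.
    edge_threshold_k : boundary candidates must exceed
        k * median(|nonzero edge scores|).
    min_support : minimum contained alignments for a retained fragment.
    len_min, len_max : allowed fragment length range, nt.
    boundary_slop : slack, nt, when attributing reads to a fragment.
    """

    haar_half_width: int = 4
    edge_threshold_k: float = 4.0
    min_support: int = 10
    len_min: int = 16
    len_max: int = 36
    boundary_slop: int = DEFAULT_BOUNDARY_SLOP

    def __post_init__(self) -> None:
        if self.len_min >= self.len_max:
            raise ValueError("require len_min < len_max")
        if min(
            self.haar_half_width,
            self.edge_threshold_k,
            self.min_support,
            self.len_min,
        ) <= 0:
            raise ValueError("parameters must be positive")


@dataclass
class CoverageProfile:
    """Per-position read coverage over one precursor.

    ``intervals`` keeps the contributing alignment intervals so fragment
    read support can be counted by containment after boundaries are known.
    """

    ncrna_id: str
    depth: np.ndarray
    n_alignments: int
    library_ids: tuple[str, ...] = ()
    intervals: list[tuple[int, int]] = field(default_factory=list)


@dataclass(frozen=True)
class FragmentCall:
    """A called sdRNA locus: ``fragment_id`` is ``ncrna_id:start-end`` with
    0-based half-open coordinates."""

    fragment_id: str
    ncrna_id: str
    start: int
    end: int
    sequence: str
    read_support: int
    rpm: float = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start


def build_coverage(
    alignments: Sequence[Alignment],
    record: NcRNARecord,
) -> CoverageProfile:
    """depth[i] = number of alignments whose interval contains position i."""
    n = len(record.sequence)
    delta = np.zeros(n + 1, dtype=np.int64)
    intervals: list[tuple[int, int]] = []
    libs: set[str] = set()
    for aln in alignments:
        if aln.ncrna_id != record.id:
            raise ValueError(
                f"alignment to {aln.ncrna_id!r} passed with record {record.id!r}"
            )
        if aln.start < 0 or aln.end > n:
            raise ValueError(
                f"alignment [{aln.start},{aln.end}) outside precursor "
                f"{record.id!r} of length {n}"
            )
        delta[aln.start] += 1
        delta[aln.end] -= 1
        intervals.append((aln.start, aln.end))
        libs.add(aln.library_id)
    return CoverageProfile(
        ncrna_id=record.id,
        depth=np.cumsum(delta[:-1]),
        n_alignments=len(intervals),
        library_ids=tuple(sorted(libs)),
        intervals=intervals,
    )


def haar_edge_scores(
    profile: CoverageProfile | np.ndarray,
    half_width: int = 4,
) -> np.ndarray:
    """Unnormalized Haar step response of the coverage track.

    score(i) = mean(depth[i:i+w]) - mean(depth[i-w:i]), zero-padded at the
    precursor ends: positive at coverage rises, negative at falls. Index i
    scores the *boundary* between positions i-1 and i, so the track has
    n+1 entries for an n-nt precursor — a fragment abutting the 3' end has
    its fall boundary at i = n.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    depth = profile.depth if isinstance(profile, CoverageProfile) else profile
    depth = np.asarray(depth, dtype=np.float64)
    w = half_width
    padded = np.concatenate([np.zeros(w), depth, np.zeros(w)])
    csum = np.concatenate([[0.0], np.cumsum(padded)])
    # right window [i, i+w) and left window [i-w, i) in padded coordinates
    i = np.arange(len(depth) + 1)
    right = csum[i + 2 * w] - csum[i + w]
    left = csum[i + w] - csum[i]
    return (right - left) / w


def _local_extrema(values: np.ndarray, threshold: float) -> list[int]:
    """Indices of local maxima of ``values`` strictly above ``threshold``;
    plateaus yield their leftmost index."""
    out: list[int] = []
    n = len(values)
    for i in np.flatnonzero(values > threshold):
        left = values[i - 1] if i > 0 else -np.inf
        right = values[i + 1] if i < n - 1 else -np.inf
        if values[i] > left and values[i] >= right:
            out.append(int(i))
    return out


def _support(intervals: Sequence[tuple[int, int]], start: int, end: int, slop: int) -> int:
    lo, hi = start - slop, end + slop
    return sum(1 for s, e in intervals if s >= lo and e <= hi)


def call_fragments(
    profile: CoverageProfile,
    params: FragCallParams | None = None,
    sequence: str | None = None,
) -> list[FragmentCall]:
    """Call sdRNA fragments from one precursor's coverage profile.

    Candidate boundaries are local extrema of |edge score| exceeding
    ``edge_threshold_k`` times the median nonzero |edge score|; rises pair
    with downstream falls within the length bounds; retained fragments need
    ``min_support`` contained alignments; calls overlapping reciprocally by
    >= 50% are merged keeping the higher-support (then leftmost) call.
    """
    if params is None:
        params = FragCallParams()
    scores = haar_edge_scores(profile, params.haar_half_width)
    magnitudes = np.abs(scores)
    if not np.any(magnitudes > 1e-12):
        return []
    # Robust noise floor: median |score| over the whole track (zeros
    # included). On a clean plateau the track is zero away from the two
    # edge ramps, so the floor is 0 and both edges survive; on a ragged
    # track the floor tracks typical jitter response.
    threshold = params.edge_threshold_k * float(np.median(magnitudes))

    rises = _local_extrema(scores, threshold)
    falls = _local_extrema(-scores, threshold)

    candidates: list[FragmentCall] = []
    seq = sequence
    depth = profile.depth
    slop = params.boundary_slop
    for r in rises:
        for f in falls:
            length = f - r
            if length < params.len_min:
                continue
            if length > params.len_max:
                break  # falls sorted ascending
            # plateau consistency: a genuine excised fragment is covered
            # across its interior, not just flanked by two strong edges
            # (rejects rise/fall pairs that bridge a low-coverage gap)
            inner = depth[min(r + slop, f) : max(f - slop, r)]
            if inner.size and inner.min() < params.min_support:
                continue
            support = _support(profile.intervals, r, f, slop)
            if support < params.min_support:
                continue
            candidates.append(
                FragmentCall(
                    fragment_id=f"{profile.ncrna_id}:{r}-{f}",
                    ncrna_id=profile.ncrna_id,
                    start=r,
                    end=f,
                    sequence=seq[r:f] if seq else "",
                    read_support=support,
                )
            )

    # Reciprocal-overlap >= 50% dedup, higher support wins, leftmost on ties.
    candidates.sort(key=lambda c: (-c.read_support, c.start, c.end))
    kept: list[FragmentCall] = []
    for cand in candidates:
        clash = False
        for other in kept:
            if cand.ncrna_id != other.ncrna_id:
                continue
            ov = min(cand.end, other.end) - max(cand.start, other.start)
            if ov <= 0:
                continue
            if ov >= 0.5 * cand.length and ov >= 0.5 * other.length:
                clash = True
                break
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda c: (c.ncrna_id, c.start, c.end))
    return kept


def quantify_rpm(read_support: int, library: Library | int) -> float:
    """reads-per-million: read_support * 1e6 / total post-trim reads."""
    total = (
        library.total_reads_post_trim
        if isinstance(library, Library)
        else int(library)
    )
    if total <= 0:
        raise ZeroDivisionError(
            "RPM undefined: library has zero post-trim reads"
        )
    return read_support * 1e6 / total


def discover_on_pooled(
    per_library_alignments: Mapping[str, Sequence[Alignment]],
    records: Sequence[NcRNARecord],
    params: FragCallParams | None = None,
) -> list[FragmentCall]:
    """Call a shared fragment catalogue from coverage pooled over libraries.

    Libraries are pooled in sorted library-ID order, so the catalogue is
    independent of input ordering.
    """
    if params is None:
        params = FragCallParams()
    by_ncrna: dict[str, list[Alignment]] = {}
    for lib_id in sorted(per_library_alignments):
        for aln in per_library_alignments[lib_id]:
            by_ncrna.setdefault(aln.ncrna_id, []).append(aln)
    catalogue: list[FragmentCall] = []
    for rec in sorted(records, key=lambda r: r.id):
        alns = by_ncrna.get(rec.id)
        if not alns:
            continue
        profile = build_coverage(alns, rec)
        catalogue.extend(call_fragments(profile, params, sequence=rec.sequence))
    return catalogue


def quantify_per_library(
    catalogue: Sequence[FragmentCall],
    per_library_alignments: Mapping[str, Sequence[Alignment]],
    libraries: Mapping[str, Library | int],
    boundary_slop: int = DEFAULT_BOUNDARY_SLOP,
) -> pd.DataFrame:
    """Per-library RPM for every catalogue fragment.

    Read support is counted by containment within the fragment interval
    extended by ``boundary_slop``. Returns a fragments x libraries frame.
    """
    frag_ids = [f.fragment_id for f in catalogue]
    data: dict[str, list[float]] = {}
    for lib_id in sorted(per_library_alignments):
        intervals_by_ncrna: dict[str, list[tuple[int, int]]] = {}
        for aln in per_library_alignments[lib_id]:
            intervals_by_ncrna.setdefault(aln.ncrna_id, []).append(
                (aln.start, aln.end)
            )
        lib = libraries[lib_id]
        col: list[float] = []
        for frag in catalogue:
            support = _support(
                intervals_by_ncrna.get(frag.ncrna_id, ()),
                frag.start,
                frag.end,
                boundary_slop,
            )
            col.append(quantify_rpm(support, lib))
        data[lib_id] = col
    return pd.DataFrame(data, index=pd.Index(frag_ids, name="fragment_id"))


def write_catalogue_bed(catalogue: Iterable[FragmentCall], path) -> None:
    with open(path, "w") as fh:
        for f in catalogue:
            fh.write(
                f"{f.ncrna_id}\t{f.start}\t{f.end}\t{f.fragment_id}\t"
                f"{f.read_support}\t+\n"
            )


def write_catalogue_tsv(catalogue: Iterable[FragmentCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("fragment_id\tncrna_id\tstart_1based\tend\tlength\t"
                 "sequence\tread_support\n")
        for f in catalogue:
            fh.write(
                f"{f.fragment_id}\t{f.ncrna_id}\t{f.start + 1}\t{f.end}\t"
                f"{f.length}\t{f.sequence}\t{f.read_support}\n"
            )


def write_coverage_bedgraph(profile: CoverageProfile, path) -> None:
    """Coverage as bedGraph-style TSV (runs of equal depth collapsed)."""
    depth = profile.depth
    with open(path, "w") as fh:
        if len(depth) == 0:
            return
        run_start = 0
        for i in range(1, len(depth) + 1):
            if i == len(depth) or depth[i] != depth[run_start]:
                fh.write(
                    f"{profile.ncrna_id}\t{run_start}\t{i}\t{int(depth[run_start])}\n"
                )
                run_start = i
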