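"""miRNA-like target-site scanning of 3'UTRs against an sdRNA guide.

The duplex model is ungapped and antiparallel: each UTR window of sdRNA
length is paired base-by-base against the guide, classifying every position
as Watson-Crick (A:U, G:C), G:U wobble, or unpaired. No thermodynamics —
the contract is the per-position pair-class track plus contiguous-match
statistics. Guide positions are numbered 1-based from the 5' end, so a
site fully complementary to guide positions 2 through 18 reports a longest
Watson-Crick run of (2, 18, 17). The seed is guide positions 2-8, the
standard miRNA convention.

Sequences are handled in the DNA alphabet (T standing in for U), so the
wobble pairs G:U and U:G appear as G:T and T:G.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO

from snofrag.ingest import normalize_sequence

logger = logging.getLogger(__name__)


class PairClass:
    """Pair classes for one (guide base, UTR base) antiparallel pairing."""

    WC = "WC"
    GU = "GU"
    NONE = "NONE"


_WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "T"), ("T", "G")}


def pair_class(sdrna_base: str, utr_base: str) -> str:
    """Classify one antiparallel base pairing; any N is unpaired."""
    a = normalize_sequence(sdrna_base)
    b = normalize_sequence(utr_base)
    if (a, b) in _WC_PAIRS:
        return PairClass.WC
    if (a, b) in _GU_PAIRS:
        return PairClass.GU
    return PairClass.NONE


@dataclass
class ScanParams:
    """min_seed retained for interface compatibility (seed length is fixed
    at guide positions 2-8); min_report_contiguous is the shortest paired
    (WC or wobble) run worth reporting."""

    min_seed: int = 7
    min_report_contiguous: int = 7


@dataclass(frozen=True)
class TargetSite:
    """One UTR window paired against the guide.

    pair_track[i] is the class of guide position i+1 (1-based from 5').
    longest_contiguous_wc / longest_contiguous_paired are
    (first_pos, last_pos, length) in 1-based guide positions, (0, 0, 0)
    when no position pairs. score is the paired (WC or GU) fraction.
    """

    utr_id: str
    utr_start: int
    utr_end: int
    pair_track: tuple[str, ...]
    longest_contiguous_wc: tuple[int, int, int]
    longest_contiguous_paired: tuple[int, int, int]
    seed_perfect: bool
    score: float


def _longest_run(flags: Sequence[bool]) -> tuple[int, int, int]:
    """Longest True run as 1-based (first, last, length); leftmost on ties."""
    best = (0, 0, 0)
    run_start = None
    for i, ok in enumerate(list(flags) + [False]):
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            length = i - run_start
            if length > best[2]:
                best = (run_start + 1, i, length)
            run_start = None
    return best


def evaluate_window(
    sdrna_seq: str,
    utr_window: str,
    utr_id: str = "",
    utr_start: int = 0,
) -> TargetSite:
    """Pair one UTR window (5'->3') against the guide, antiparallel:
    guide position p (1-based from its 5' end) faces UTR window position
    L - p (0-based from the window's 5' end)."""
    n = len(sdrna_seq)
    if len(utr_window) != n:
        raise ValueError("window length must equal guide length")
    track = tuple(
        pair_class(sdrna_seq[i], utr_window[n - 1 - i]) for i in range(n)
    )
    wc = [c == PairClass.WC for c in track]
    paired = [c != PairClass.NONE for c in track]
    return TargetSite(
        utr_id=utr_id,
        utr_start=utr_start,
        utr_end=utr_start + n,
        pair_track=track,
        longest_contiguous_wc=_longest_run(wc),
        longest_contiguous_paired=_longest_run(paired),
        seed_perfect=all(wc[1:8]),
        score=sum(paired) / n,
    )


def scan_utr(
    sdrna_seq: str,
    utr,
    params: ScanParams | None = None,
) -> list[TargetSite]:
    """Scan every window of a 3'UTR for miRNA-like sites of the guide.

    ``utr`` may be a Bio.SeqRecord, an (id, sequence) pair, or a plain
    string. Windows with a perfect seed (guide positions 2-8 all
    Watson-Crick) or with a paired run of at least
    ``min_report_contiguous`` are reported, sorted by
    (longest WC run desc, score desc, position asc).
    """
    if params is None:
        params = ScanParams()
    if hasattr(utr, "seq"):
        utr_id, utr_seq = utr.id, str(utr.seq)
    elif isinstance(utr, tuple):
        utr_id, utr_seq = utr
    else:
        utr_id, utr_seq = "", str(utr)
    guide = normalize_sequence(sdrna_seq)
    utr_seq = normalize_sequence(utr_seq)
    if len(guide) < 16:
        raise ValueError("guide must be at least 16 nt")
    n = len(guide)
    if len(utr_seq) < n:
        logger.warning(
            "UTR %s shorter than guide (%d < %d); no windows to scan",
            utr_id, len(utr_seq), n,
        )
        return []

    sites = [
        site
        for w in range(len(utr_seq) - n + 1)
        if (
            site := evaluate_window(guide, utr_seq[w : w + n], utr_id, w)
        ).seed_perfect
        or site.longest_contiguous_paired[2] >= params.min_report_contiguous
    ]
    sites.sort(
        key=lambda s: (-s.longest_contiguous_wc[2], -s.score, s.utr_start)
    )
    return sites


def scan_utr_fasta(
    sdrna_seq: str,
    fasta_source,
    params: ScanParams | None = None,
    allowed_ids: set[str] | None = None,
) -> dict[str, list[TargetSite]]:
    """Scan every UTR in a FASTA file; ``allowed_ids`` optionally restricts
    to an expressed-gene allow-list."""
    out: dict[str, list[TargetSite]] = {}
    for rec in SeqIO.parse(fasta_source, "fasta"):
        if allowed_ids is not None and rec.id not in allowed_ids:
            continue
        out[rec.id] = scan_utr(sdrna_seq, rec, params)
    return out


_SYMBOL = {PairClass.WC: "|", PairClass.GU: ":", PairClass.NONE: " "}
_CLASS_OF_SYMBOL = {v: k for k, v in _SYMBOL.items()}


def render_duplex(site: TargetSite, sdrna_seq: str, utr_seq: str) -> str:
    """Three-line duplex text: UTR window 5'->3' on top, pair symbols
    ('|' Watson-Crick, ':' wobble) in the middle, guide 3'->5' below."""
    guide = normalize_sequence(sdrna_seq)
    window = normalize_sequence(utr_seq)[site.utr_start : site.utr_end]
    n = len(guide)
    if len(window) != n or len(site.pair_track) != n:
        raise ValueError("site does not fit the given sequences")
    symbols = "".join(_SYMBOL[site.pair_track[n - 1 - c]] for c in range(n))
    return (
        f"5'-{window}-3'  {site.utr_id}:{site.utr_start + 1}-{site.utr_end}\n"
        f"   {symbols}\n"
        f"3'-{guide[::-1]}-5'"
    )


def parse_duplex(text: str) -> tuple[str, ...]:
    """Recover the pair track (1-based guide order) from rendered duplex
    text; inverse of the symbol line of ``render_duplex``."""
    lines = text.split("\n")
    top = lines[0]
    window_len = len(top.split("-")[1])
    symbols = lines[1][3 : 3 + window_len].ljust(window_len)
    return tuple(_CLASS_OF_SYMBOL[s] for s in reversed(symbols))


def write_sites_tsv(
    sites_by_utr: dict[str, list[TargetSite]], path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "utr_id\tutr_start_1based\tutr_end\tlongest_wc_first\t"
            "longest_wc_last\tlongest_wc_len\tlongest_paired_len\t"
            "seed_perfect\tscore\n"
        )
        for utr_id, sites in sites_by_utr.items():
            for s in sites:
                fh.write(
                    f"{utr_id}\t{s.utr_start + 1}\t{s.utr_end}\t"
                    f"{s.longest_contiguous_wc[0]}\t{s.longest_contiguous_wc[1]}\t"
                    f"{s.longest_contiguous_wc[2]}\t{s.longest_contiguous_paired[2]}\t"
                    f"{s.seed_perfect}\t{s.score:.4f}\n"
                )
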