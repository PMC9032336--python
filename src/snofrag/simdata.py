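"""Synthetic data emulating every input of the sdRNA analysis.

The generator family mirrors the structure of the real study inputs while
staying download-free and fully seed-deterministic:

* snoRNA-like precursors: uniform-random sequences harbouring zero to two
  planted, non-overlapping 16-36 nt fragment intervals (the "specifically
  excised" sdRNAs);
* small RNA libraries: fragment reads are near-exact copies of planted
  intervals (a little end jitter, never below the 20-nt alignment floor),
  each with the 3' adapter appended; background reads are random 20-30 nt
  inserts rejection-sampled so they can never align perfectly to any
  precursor, making false-positive tests exact rather than probabilistic;
* tumor/normal cohorts: per sample a fragment is expressed with a
  class-specific Bernoulli probability; expressing samples draw their RPM
  from a mean-parameterized Gamma truncated at the expression threshold;
* Ago-IP libraries: reads drawn only from an enriched fragment subset plus
  background;
* 3'UTRs with planted antiparallel complementary sites, optionally
  carrying G:U wobbles at chosen guide positions.

Every generator records its ground truth in plain data structures that
serialize to a JSON manifest, so downstream recovery can be asserted
exactly.

Default cohort parameters emulate the cohort scale and the two headline
fragments of the motivating prostate-cancer screen: 489 tumor / 52 normal
samples; one fragment expressed in 91.6% of tumors (mean 384 RPM among
expressing samples) versus 42.3% of normals (162 RPM), the other in 97.5%
versus 30.8% (711 versus 150 RPM).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from snofrag.aligner import reverse_complement
from snofrag.ingest import (
    Condition,
    Library,
    NcRNARecord,
    RnaClass,
    SmallRNARead,
    DEFAULT_ADAPTER,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: read-mode cohorts are capped to keep memory and runtime sane; raise the
#: cap explicitly for bigger experiments.
MAX_READ_MODE_LIBRARIES = 64

MIN_ALIGNABLE_READ = 20


@dataclass(frozen=True)
class PlantedFragment:
    """Truth for one planted sdRNA: where it lives and how it expresses."""

    fragment_id: str
    ncrna_id: str
    start: int
    end: int
    p_tumor: float = 1.0
    p_normal: float = 0.0
    mu_tumor: float = 400.0
    mu_normal: float = 100.0
    dispersion_shape: float = 2.0

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class SimTruth:
    """Machine-readable manifest of a simulation."""

    seed: int
    fragments: list[PlantedFragment] = field(default_factory=list)
    libraries: dict[str, dict] = field(default_factory=dict)
    utr_sites: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "fragments": [asdict(f) for f in self.fragments],
            "libraries": self.libraries,
            "utr_sites": self.utr_sites,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def simulate_reference(
    n_snornas: int,
    length_range: tuple[int, int] = (90, 160),
    rng: np.random.Generator | int | None = None,
    fragments_per_precursor: tuple[int, int] = (0, 2),
    fragment_length_range: tuple[int, int] = (16, 36),
) -> tuple[list[NcRNARecord], list[PlantedFragment]]:
    """Uniform-random precursors with 0-2 planted fragment intervals each.

    Planted intervals never overlap one another on a precursor. Lengths
    below 60 nt are rejected (too short to host distinct fragments).
    """
    rng = np.random.default_rng(rng)
    if length_range[0] < 60:
        raise ValueError("precursor lengths must be >= 60 nt")
    lo, hi = fragment_length_range
    records: list[NcRNARecord] = []
    planted: list[PlantedFragment] = []
    for i in range(n_snornas):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        rid = f"SNOSIM{i + 1:03d}"
        records.append(
            NcRNARecord(
                id=rid,
                name=f"sim-snoRNA-{i + 1}",
                rna_class=RnaClass.CD_BOX if i % 2 == 0 else RnaClass.HACA_BOX,
                sequence=_random_seq(rng, length),
            )
        )
        n_frag = int(
            rng.integers(fragments_per_precursor[0], fragments_per_precursor[1] + 1)
        )
        taken: list[tuple[int, int]] = []
        for _ in range(n_frag):
            for _attempt in range(50):
                flen = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(0, length - flen + 1))
                end = start + flen
                # keep >= 5 nt clearance so coverage edges stay separable
                if all(end + 5 <= s or e + 5 <= start for s, e in taken):
                    taken.append((start, end))
                    planted.append(
                        PlantedFragment(
                            fragment_id=f"{rid}:{start}-{end}",
                            ncrna_id=rid,
                            start=start,
                            end=end,
                        )
                    )
                    break
    return records, planted


def _substring_pool(records: Sequence[NcRNARecord], min_len: int, max_len: int) -> set[str]:
    """Every precursor substring in the background length range; membership
    here is exactly 'would align perfectly'."""
    pool: set[str] = set()
    for rec in records:
        seq = rec.sequence
        for k in range(min_len, max_len + 1):
            for i in range(len(seq) - k + 1):
                pool.add(seq[i : i + k])
    return pool


def _background_reads(
    rng: np.random.Generator,
    n: int,
    forbidden: set[str],
    length_range: tuple[int, int] = (20, 30),
) -> list[str]:
    """Random inserts rejection-sampled to never match any precursor."""
    out: list[str] = []
    lo, hi = length_range
    while len(out) < n:
        batch = n - len(out)
        lens = rng.integers(lo, hi + 1, size=batch)
        flat = _BASES[rng.integers(0, 4, size=int(lens.sum()))].tobytes().decode()
        offset = 0
        for L in lens:
            seq = flat[offset : offset + L]
            offset += L
            if seq not in forbidden:
                out.append(seq)
    return out


def _jittered_copy(
    rng: np.random.Generator, sequence: str, start: int, end: int, max_jitter: int = 2
) -> str:
    """A read copied from [start, end) with up to ``max_jitter`` nt shaved
    off each end, constrained to stay alignable (>= 20 nt)."""
    length = end - start
    budget = max(0, length - MIN_ALIGNABLE_READ)
    ds = int(rng.integers(0, min(max_jitter, budget) + 1))
    de = int(rng.integers(0, min(max_jitter, budget - ds) + 1))
    return sequence[start + ds : end - de]


def simulate_library(
    records: Sequence[NcRNARecord],
    fragment_counts: Mapping[str, int],
    fragments: Sequence[PlantedFragment],
    depth: int,
    condition: Condition = Condition.TUMOR,
    library_id: str = "lib1",
    adapter: str = DEFAULT_ADAPTER,
    rng: np.random.Generator | int | None = None,
    substring_pool: set[str] | None = None,
) -> tuple[Library, dict[str, int]]:
    """One small RNA library: fragment copies plus guaranteed-nonaligning
    background, every read carrying the 3' adapter.

    ``fragment_counts`` maps fragment_id -> exact read count; background
    fills up to ``depth`` total reads. Returns the untrimmed library and
    the true per-fragment counts.
    """
    rng = np.random.default_rng(rng)
    if depth < 0:
        raise ValueError("depth must be >= 0")
    frag_by_id = {f.fragment_id: f for f in fragments}
    seq_by_ncrna = {r.id: r.sequence for r in records}
    n_fragment_reads = sum(fragment_counts.values())
    if n_fragment_reads > depth:
        raise ValueError(
            f"fragment reads ({n_fragment_reads}) exceed depth ({depth})"
        )
    reads: list[SmallRNARead] = []
    idx = 0
    for frag_id in sorted(fragment_counts):
        frag = frag_by_id[frag_id]
        precursor = seq_by_ncrna[frag.ncrna_id]
        for _ in range(fragment_counts[frag_id]):
            insert = _jittered_copy(rng, precursor, frag.start, frag.end)
            reads.append(
                SmallRNARead(
                    read_id=f"r{idx}",
                    sequence=insert + adapter,
                    library_id=library_id,
                )
            )
            idx += 1
    if substring_pool is None:
        substring_pool = _substring_pool(records, MIN_ALIGNABLE_READ, 30)
    for insert in _background_reads(rng, depth - n_fragment_reads, substring_pool):
        reads.append(
            SmallRNARead(
                read_id=f"r{idx}",
                sequence=insert + adapter,
                library_id=library_id,
            )
        )
        idx += 1
    lib = Library(library_id=library_id, condition=condition, reads=reads)
    return lib, dict(fragment_counts)


def default_cohort_fragments(
    records: Sequence[NcRNARecord],
    planted: Sequence[PlantedFragment],
) -> list[PlantedFragment]:
    """Attach the two emulated headline expression profiles to the first two
    planted intervals of a simulated reference."""
    if len(planted) < 2:
        raise ValueError("need at least two planted intervals")
    profiles = [
        # prevalence 91.6% vs 42.3%; expressing means 384 vs 162 RPM
        dict(p_tumor=0.916, p_normal=0.423, mu_tumor=384.0, mu_normal=162.0),
        # prevalence 97.5% vs 30.8%; expressing means 711 vs 150 RPM
        dict(p_tumor=0.975, p_normal=0.308, mu_tumor=711.0, mu_normal=150.0),
    ]
    out = []
    for frag, prof in zip(planted[:2], profiles):
        out.append(
            PlantedFragment(
                fragment_id=frag.fragment_id,
                ncrna_id=frag.ncrna_id,
                start=frag.start,
                end=frag.end,
                **prof,
            )
        )
    return out


def _truncated_gamma_rpm(
    rng: np.random.Generator, mu: float, shape: float, floor: float
) -> float:
    """Gamma(shape, mean mu) conditioned on >= floor, by resampling."""
    scale = mu / shape
    for _ in range(10_000):
        x = float(rng.gamma(shape, scale))
        if x >= floor:
            return x
    raise RuntimeError(
        f"truncated Gamma stuck: mean {mu} far below floor {floor}"
    )


def simulate_cohort(
    records: Sequence[NcRNARecord],
    fragments: Sequence[PlantedFragment],
    n_tumor: int = 489,
    n_normal: int = 52,
    mode: str = "matrix",
    depth: int = 100_000,
    expressed_threshold: float = 30.0,
    adapter: str = DEFAULT_ADAPTER,
    rng: np.random.Generator | int | None = None,
):
    """Tumor/normal cohort realizing per-fragment Bernoulli prevalence and
    truncated-Gamma expression.

    mode="matrix" returns ``(rpm_frame, conditions, truth)`` where
    rpm_frame is fragments x samples and truth maps sample -> fragment ->
    true RPM. mode="reads" returns ``(libraries, truth)`` with untrimmed
    Library objects whose fragment read counts realize the drawn RPMs at
    ``depth`` total reads per library.
    """
    import pandas as pd

    rng = np.random.default_rng(rng)
    if mode not in ("matrix", "reads"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "reads" and n_tumor + n_normal > MAX_READ_MODE_LIBRARIES:
        raise ValueError(
            f"reads mode capped at {MAX_READ_MODE_LIBRARIES} libraries; "
            f"requested {n_tumor + n_normal}"
        )

    samples = [(f"tumor{i + 1:03d}", Condition.TUMOR) for i in range(n_tumor)]
    samples += [(f"normal{i + 1:03d}", Condition.NORMAL) for i in range(n_normal)]

    true_rpm: dict[str, dict[str, float]] = {}
    for sample_id, cond in samples:
        row: dict[str, float] = {}
        for frag in fragments:
            p = frag.p_tumor if cond == Condition.TUMOR else frag.p_normal
            mu = frag.mu_tumor if cond == Condition.TUMOR else frag.mu_normal
            if rng.random() < p:
                row[frag.fragment_id] = _truncated_gamma_rpm(
                    rng, mu, frag.dispersion_shape, expressed_threshold
                )
            else:
                row[frag.fragment_id] = 0.0
        true_rpm[sample_id] = row

    conditions = {sid: cond for sid, cond in samples}
    if mode == "matrix":
        frame = pd.DataFrame(true_rpm).loc[
            sorted(f.fragment_id for f in fragments), [s for s, _ in samples]
        ]
        return frame, conditions, true_rpm

    pool = _substring_pool(records, MIN_ALIGNABLE_READ, 30)
    libraries: list[Library] = []
    truth_counts: dict[str, dict[str, int]] = {}
    for sample_id, cond in samples:
        counts = {
            fid: int(round(rpm_val * depth / 1e6))
            for fid, rpm_val in true_rpm[sample_id].items()
        }
        lib, _ = simulate_library(
            records,
            counts,
            fragments,
            depth=depth,
            condition=cond,
            library_id=sample_id,
            adapter=adapter,
            rng=rng,
            substring_pool=pool,
        )
        libraries.append(lib)
        truth_counts[sample_id] = counts
    return libraries, {"rpm": true_rpm, "counts": truth_counts,
                       "conditions": {s: c.value for s, c in conditions.items()}}


def simulate_ago_library(
    records: Sequence[NcRNARecord],
    fragments: Sequence[PlantedFragment],
    enriched_fragment_ids: Iterable[str],
    depth: int = 2000,
    reads_per_enriched: int = 50,
    adapter: str = DEFAULT_ADAPTER,
    library_id: str = "ago_ip",
    rng: np.random.Generator | int | None = None,
) -> tuple[Library, dict[str, int]]:
    """Ago-IP library: reads only from the enriched fragments plus
    background; non-enriched planted fragments get exactly zero reads."""
    enriched = sorted(set(enriched_fragment_ids))
    known = {f.fragment_id for f in fragments}
    missing = set(enriched) - known
    if missing:
        raise KeyError(f"unknown enriched fragment ids: {sorted(missing)}")
    counts = {fid: reads_per_enriched for fid in enriched}
    return simulate_library(
        records,
        counts,
        fragments,
        depth=depth,
        condition=Condition.AGO_IP,
        library_id=library_id,
        adapter=adapter,
        rng=rng,
    )


_WOBBLE_SWAP = {"C": "T", "A": "G"}  # WC partner -> G:U-compatible partner


def plant_target_site(
    utr_seq: str,
    sdrna_seq: str,
    span: tuple[int, int],
    wobble_positions: Iterable[int] = (),
    insert_at: int = 0,
    clamp_flanks: bool = True,
) -> tuple[str, dict]:
    """Overwrite a UTR stretch with the antiparallel complement of guide
    positions ``span=(first, last)`` (1-based, inclusive).

    At each guide position in ``wobble_positions`` the complementary base
    is swapped to its G:U-compatible alternative (C->T opposite guide G,
    A->G opposite guide U), turning that pair from Watson-Crick into a
    wobble. Only guide G/U positions admit a wobble.

    With ``clamp_flanks`` (default), the UTR bases facing guide positions
    first-1 and last+1 are set to the guide's own base there — a base never
    pairs with itself, Watson-Crick or wobble — so the planted span is
    exactly the longest paired run, not merely a lower bound.
    """
    first, last = span
    guide = sdrna_seq.upper().replace("U", "T")
    if not 1 <= first <= last <= len(guide):
        raise ValueError(f"span {span} outside guide of length {len(guide)}")
    segment = guide[first - 1 : last]
    target = list(reverse_complement(segment))
    # target[j] pairs guide position (last - j)
    for pos in wobble_positions:
        if not first <= pos <= last:
            raise ValueError(f"wobble position {pos} outside span {span}")
        j = last - pos
        if target[j] not in _WOBBLE_SWAP:
            raise ValueError(
                f"guide position {pos} ({guide[pos - 1]}) admits no G:U wobble"
            )
        target[j] = _WOBBLE_SWAP[target[j]]
    target_str = "".join(target)
    if insert_at < 0 or insert_at + len(target_str) > len(utr_seq):
        raise ValueError("planted site does not fit in the UTR")
    utr = list(utr_seq)
    utr[insert_at : insert_at + len(target_str)] = target_str
    if clamp_flanks:
        # UTR index facing guide position p within the aligned window is
        # insert_at + (last - p)
        if last < len(guide) and insert_at - 1 >= 0:
            utr[insert_at - 1] = guide[last]  # faces guide position last+1
        if first > 1 and insert_at + len(target_str) < len(utr):
            utr[insert_at + len(target_str)] = guide[first - 2]
    modified = "".join(utr)
    truth = {
        "span": [first, last],
        "wobble_positions": sorted(wobble_positions),
        "insert_at": insert_at,
        "site_length": len(target_str),
    }
    return modified, truth


def simulate_utr(
    length: int,
    rng: np.random.Generator | int | None = None,
) -> str:
    """Uniform-random UTR sequence."""
    rng = np.random.default_rng(rng)
    return _random_seq(rng, length)
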