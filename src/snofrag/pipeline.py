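"""End-to-end orchestration: ingest -> align -> call -> cohort -> select
(-> scan), shared by the command-line interface, the test-suite and the
reproduction script.

``run_cohort_from_libraries`` is the in-memory fast path used when
libraries are generated programmatically; ``run_discovery`` is the
file-driven entry point behind the CLI, reading a declarative YAML config
and writing every artifact plus a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from snofrag import aligner, cohort, fragcall, ingest, targetscan

logger = logging.getLogger(__name__)


@dataclass
class CohortRunResult:
    catalogue: list[fragcall.FragmentCall]
    rpm_matrix: pd.DataFrame
    matrix: cohort.ExpressionMatrix
    stats: pd.DataFrame
    ranked: pd.DataFrame
    ago_counts: dict[str, int]
    final: pd.DataFrame


def run_cohort_from_libraries(
    records: Sequence[ingest.NcRNARecord],
    libraries: Iterable[ingest.Library],
    ago_library: ingest.Library | None = None,
    params: fragcall.FragCallParams | None = None,
    config: cohort.SelectionConfig | None = None,
    adapter: str = ingest.DEFAULT_ADAPTER,
    pre_trimmed: bool = False,
) -> CohortRunResult:
    """Full discovery/selection run over in-memory libraries.

    Libraries may be raw (adapters still on) or already trimmed
    (``pre_trimmed=True``). The Ago library contributes only to fragment
    Ago support, never to discovery coverage or to the cohort matrix.
    """
    if params is None:
        params = fragcall.FragCallParams()
    if config is None:
        config = cohort.SelectionConfig()
    index = aligner.build_reference_index(records)

    per_lib_alignments: dict[str, list[aligner.Alignment]] = {}
    denominators: dict[str, int] = {}
    conditions: dict[str, ingest.Condition] = {}
    for lib in libraries:
        if not pre_trimmed:
            lib = ingest.trim_library(lib, adapter)
        per_lib_alignments[lib.library_id] = aligner.align_library(lib, index)
        denominators[lib.library_id] = lib.total_reads_post_trim
        conditions[lib.library_id] = lib.condition

    catalogue = fragcall.discover_on_pooled(per_lib_alignments, records, params)
    rpm_matrix = fragcall.quantify_per_library(
        catalogue, per_lib_alignments, denominators, params.boundary_slop
    )
    matrix = cohort.build_expression_matrix(rpm_matrix, conditions)
    stats = cohort.compute_cohort_stats(matrix, config)
    ranked = cohort.filter_differential(stats, config)

    ago_counts: dict[str, int] = {}
    if ago_library is not None:
        if not pre_trimmed:
            ago_library = ingest.trim_library(ago_library, adapter)
        ago_alignments = aligner.align_library(ago_library, index)
        for frag in catalogue:
            ago_counts[frag.fragment_id] = cohort.ago_support(
                frag, ago_alignments, params.boundary_slop
            )
    final = cohort.select_final_candidates(ranked, ago_counts, config)
    return CohortRunResult(
        catalogue=catalogue,
        rpm_matrix=rpm_matrix,
        matrix=matrix,
        stats=stats,
        ranked=ranked,
        ago_counts=ago_counts,
        final=final,
    )


# --- file-driven run ---------------------------------------------------------

_KNOWN_KEYS = {
    "reference_fasta",
    "reference_metadata",
    "sample_sheet",
    "ago_fastq",
    "utr_fasta",
    "allowed_genes",
    "adapter",
    "seed",
    "out_dir",
    "fragcall",
    "selection",
    "scan_guides",
}


@dataclass
class RunConfig:
    """Declarative run configuration (one YAML file)."""

    reference_fasta: str
    sample_sheet: str
    out_dir: str
    reference_metadata: str | None = None
    ago_fastq: str | None = None
    utr_fasta: str | None = None
    allowed_genes: str | None = None
    adapter: str = ingest.DEFAULT_ADAPTER
    seed: int = 0
    fragcall_params: fragcall.FragCallParams = field(
        default_factory=fragcall.FragCallParams
    )
    selection: cohort.SelectionConfig = field(
        default_factory=cohort.SelectionConfig
    )
    scan_guides: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("reference_fasta", "sample_sheet", "out_dir"):
            if key not in raw:
                raise ValueError(f"config missing required key {key!r}")
        return cls(
            reference_fasta=raw["reference_fasta"],
            sample_sheet=raw["sample_sheet"],
            out_dir=raw["out_dir"],
            reference_metadata=raw.get("reference_metadata"),
            ago_fastq=raw.get("ago_fastq"),
            utr_fasta=raw.get("utr_fasta"),
            allowed_genes=raw.get("allowed_genes"),
            adapter=raw.get("adapter", ingest.DEFAULT_ADAPTER),
            seed=int(raw.get("seed", 0)),
            fragcall_params=fragcall.FragCallParams(**raw.get("fragcall", {})),
            selection=cohort.SelectionConfig(**raw.get("selection", {})),
            scan_guides=list(raw.get("scan_guides", [])),
        )

    def to_manifest_dict(self) -> dict:
        return {
            "reference_fasta": self.reference_fasta,
            "reference_metadata": self.reference_metadata,
            "sample_sheet": self.sample_sheet,
            "ago_fastq": self.ago_fastq,
            "utr_fasta": self.utr_fasta,
            "allowed_genes": self.allowed_genes,
            "adapter": self.adapter,
            "seed": self.seed,
            "fragcall": vars(self.fragcall_params),
            "selection": vars(self.selection),
            "scan_guides": self.scan_guides,
        }


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_discovery(config: RunConfig) -> CohortRunResult:
    """File-driven end-to-end run; every stage failure is re-raised with the
    stage name so the CLI can abort with a clear cause."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    input_hashes: dict[str, str] = {}

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    current = stage("ingest")
    try:
        records = ingest.load_ncrna_reference(
            config.reference_fasta, config.reference_metadata
        )
        input_hashes["reference_fasta"] = _sha256(config.reference_fasta)
        sheet = ingest.read_sample_sheet(config.sample_sheet)
        input_hashes["sample_sheet"] = _sha256(config.sample_sheet)
        libraries = []
        for _, row in sheet.iterrows():
            lib = ingest.read_small_rna_library(
                row["path"],
                adapter=config.adapter,
                condition=row["condition"],
                library_id=row["library_id"],
            )
            input_hashes[f"library:{row['library_id']}"] = _sha256(row["path"])
            libraries.append(lib)
        ago_lib = None
        if config.ago_fastq:
            ago_lib = ingest.read_small_rna_library(
                config.ago_fastq,
                adapter=config.adapter,
                condition=ingest.Condition.AGO_IP,
                library_id="ago_ip",
            )
            input_hashes["ago_fastq"] = _sha256(config.ago_fastq)

        current = stage("align+call+cohort+select")
        result = run_cohort_from_libraries(
            records,
            libraries,
            ago_library=ago_lib,
            params=config.fragcall_params,
            config=config.selection,
            adapter=config.adapter,
            pre_trimmed=True,  # read_small_rna_library already trimmed
        )

        current = stage("report")
        fragcall.write_catalogue_tsv(result.catalogue, out / "catalogue.tsv")
        fragcall.write_catalogue_bed(result.catalogue, out / "catalogue.bed")
        result.rpm_matrix.to_csv(out / "rpm_matrix.tsv", sep="\t")
        cohort.write_candidate_report(
            result.stats, result.ago_counts, config.selection,
            out / "candidate_report.tsv",
        )
        result.final.to_csv(out / "final_candidates.tsv", sep="\t",
                            index_label="fragment_id")

        if config.utr_fasta:
            current = stage("scan")
            input_hashes["utr_fasta"] = _sha256(config.utr_fasta)
            allowed = None
            if config.allowed_genes:
                allowed = set(
                    pd.read_csv(config.allowed_genes, sep="\t", header=None)[0]
                )
            guides = config.scan_guides
            if not guides:
                frag_by_id = {f.fragment_id: f for f in result.catalogue}
                guides = [
                    frag_by_id[fid].sequence
                    for fid in result.final.index
                    if fid in frag_by_id
                ]
            all_sites: dict[str, dict] = {}
            report_lines: list[str] = []
            from Bio import SeqIO

            utr_records = {
                r.id: ingest.normalize_sequence(str(r.seq))
                for r in SeqIO.parse(config.utr_fasta, "fasta")
            }
            for guide in guides:
                sites = targetscan.scan_utr_fasta(
                    guide, config.utr_fasta, allowed_ids=allowed
                )
                targetscan.write_sites_tsv(
                    sites, out / f"sites_{hashlib.sha1(guide.encode()).hexdigest()[:8]}.tsv"
                )
                for utr_id, site_list in sites.items():
                    for site in site_list[:3]:
                        report_lines.append(
                            targetscan.render_duplex(
                                site, guide, utr_records[utr_id]
                            )
                        )
                        report_lines.append("")
            (out / "duplexes.txt").write_text("\n".join(report_lines))
    except Exception as exc:
        raise RuntimeError(f"stage {current!r} failed: {exc}") from exc

    manifest = {
        "config": config.to_manifest_dict(),
        "input_sha256": input_hashes,
        "n_libraries": len(libraries),
        "n_fragments_called": len(result.catalogue),
        "n_final_candidates": int(result.final.shape[0]),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return result
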