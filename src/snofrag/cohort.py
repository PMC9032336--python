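"""Cohort-level expression statistics and candidate selection.

A fragment is "expressed" in a sample when its RPM meets the expression
threshold (30 RPM by default). Prevalence is the fraction of a class's
samples expressing the fragment; fold change is the pseudocounted ratio of
class mean RPMs (means over all samples of the class, zeros included, by
default). Candidates are first filtered on fold change and tumor
prevalence, ranked by (prevalence, fold change), then the final selection
additionally requires high tumor prevalence, low normal prevalence, and
Argonaute-IP read support — the screen that isolates tumor-enriched,
Ago-loaded sdRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from snofrag.aligner import Alignment, DEFAULT_BOUNDARY_SLOP
from snofrag.fragcall import FragmentCall
from snofrag.ingest import Condition


@dataclass
class SelectionConfig:
    """Thresholds of the candidate screen.

    expressed_threshold : RPM at or above which a sample "expresses" a
        fragment (default 30 RPM).
    min_fold : minimum tumor/normal fold change (default 2).
    min_expressed_frac_tumor : minimum tumor prevalence at the first filter
        (default 0.5).
    final_prev_tumor_gt / final_prev_normal_lt : strict prevalence bounds of
        the final selection (defaults 0.9 / 0.5).
    min_ago_reads : minimum Ago-IP alignments contained in the fragment
        (default 1).
    epsilon : RPM pseudocount in the fold-change ratio (default 1).
    """

    expressed_threshold: float = 30.0
    min_fold: float = 2.0
    min_expressed_frac_tumor: float = 0.5
    final_prev_tumor_gt: float = 0.9
    final_prev_normal_lt: float = 0.5
    min_ago_reads: int = 1
    epsilon: float = 1.0
    mean_over_expressing_only: bool = False

    def __post_init__(self) -> None:
        if self.expressed_threshold <= 0 or self.min_fold <= 0:
            raise ValueError("thresholds must be positive")
        for frac in (
            self.min_expressed_frac_tumor,
            self.final_prev_tumor_gt,
            self.final_prev_normal_lt,
        ):
            if not 0.0 < frac < 1.0:
                raise ValueError("prevalence fractions must lie in (0, 1)")


@dataclass
class ExpressionMatrix:
    """Fragments x samples RPM matrix with tumor/normal sample labels."""

    values: pd.DataFrame  # rows fragment_id, columns library_id
    conditions: pd.Series  # library_id -> Condition

    @property
    def tumor_ids(self) -> list[str]:
        return [s for s in self.values.columns if self.conditions[s] == Condition.TUMOR]

    @property
    def normal_ids(self) -> list[str]:
        return [s for s in self.values.columns if self.conditions[s] == Condition.NORMAL]


def build_expression_matrix(
    per_library_rpm: pd.DataFrame | Mapping[str, Mapping[str, float]],
    sample_conditions: Mapping[str, Condition] | pd.DataFrame,
) -> ExpressionMatrix:
    """Assemble the cohort RPM matrix.

    ``per_library_rpm`` is either the fragments x libraries frame from
    ``quantify_per_library`` or a mapping library_id -> {fragment_id: rpm}.
    Fragments absent from a library get 0 RPM. Every library must appear in
    the sample sheet with condition tumor or normal.
    """
    if isinstance(sample_conditions, pd.DataFrame):
        sample_conditions = dict(
            zip(sample_conditions["library_id"], sample_conditions["condition"])
        )
    if isinstance(per_library_rpm, pd.DataFrame):
        frame = per_library_rpm.copy()
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate fragment_id rows: {dupes}")
    else:
        frame = pd.DataFrame(
            {lib: pd.Series(table) for lib, table in per_library_rpm.items()}
        )
    frame = frame.fillna(0.0)
    frame = frame.loc[sorted(frame.index), sorted(frame.columns)]

    conditions: dict[str, Condition] = {}
    for lib in frame.columns:
        if lib not in sample_conditions:
            raise KeyError(f"library {lib!r} missing from sample sheet")
        cond = sample_conditions[lib]
        if cond not in (Condition.TUMOR, Condition.NORMAL):
            raise ValueError(
                f"library {lib!r}: cohort matrix accepts tumor/normal only, "
                f"got {cond}"
            )
        conditions[lib] = cond
    return ExpressionMatrix(
        values=frame, conditions=pd.Series(conditions, dtype=object)
    )


def compute_cohort_stats(
    matrix: ExpressionMatrix,
    config: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Per-fragment prevalence, class mean RPM, and fold change.

    Returns a frame indexed by fragment_id with columns prev_tumor,
    prev_normal, mean_rpm_tumor, mean_rpm_normal, fold_change.
    """
    if config is None:
        config = SelectionConfig()
    tumor = matrix.values[matrix.tumor_ids]
    normal = matrix.values[matrix.normal_ids]
    if tumor.shape[1] == 0 or normal.shape[1] == 0:
        raise ValueError("cohort needs at least one tumor and one normal sample")

    thr = config.expressed_threshold
    prev_tumor = (tumor >= thr).mean(axis=1)
    prev_normal = (normal >= thr).mean(axis=1)
    if config.mean_over_expressing_only:
        mean_tumor = tumor.where(tumor >= thr).mean(axis=1).fillna(0.0)
        mean_normal = normal.where(normal >= thr).mean(axis=1).fillna(0.0)
    else:
        mean_tumor = tumor.mean(axis=1)
        mean_normal = normal.mean(axis=1)
    eps = config.epsilon
    fold = (mean_tumor + eps) / (mean_normal + eps)
    return pd.DataFrame(
        {
            "prev_tumor": prev_tumor,
            "prev_normal": prev_normal,
            "mean_rpm_tumor": mean_tumor,
            "mean_rpm_normal": mean_normal,
            "fold_change": fold,
        }
    )


def filter_differential(
    stats: pd.DataFrame,
    config: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Retain fragments with fold_change >= min_fold and tumor prevalence
    >= min_expressed_frac_tumor; rank by (prev_tumor desc, fold_change desc,
    fragment_id asc)."""
    if config is None:
        config = SelectionConfig()
    keep = stats[
        (stats["fold_change"] >= config.min_fold)
        & (stats["prev_tumor"] >= config.min_expressed_frac_tumor)
    ].copy()
    keep["_id"] = keep.index
    keep = keep.sort_values(
        ["prev_tumor", "fold_change", "_id"], ascending=[False, False, True]
    ).drop(columns="_id")
    return keep


def ago_support(
    fragment: FragmentCall,
    ago_alignments: Sequence[Alignment],
    boundary_slop: int = DEFAULT_BOUNDARY_SLOP,
) -> int:
    """Ago-IP alignments to the fragment's precursor contained within
    [start - slop, end + slop)."""
    lo = fragment.start - boundary_slop
    hi = fragment.end + boundary_slop
    return sum(
        1
        for aln in ago_alignments
        if aln.ncrna_id == fragment.ncrna_id and aln.start >= lo and aln.end <= hi
    )


def select_final_candidates(
    ranked: pd.DataFrame,
    ago_counts: Mapping[str, int],
    config: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Final screen: tumor prevalence strictly above ``final_prev_tumor_gt``,
    normal prevalence strictly below ``final_prev_normal_lt``, and Ago
    support at least ``min_ago_reads``. Rank order is preserved."""
    if config is None:
        config = SelectionConfig()
    ago = pd.Series(
        [ago_counts.get(fid, 0) for fid in ranked.index],
        index=ranked.index,
        dtype=np.int64,
    )
    out = ranked.copy()
    out["ago_support"] = ago
    return out[
        (out["prev_tumor"] > config.final_prev_tumor_gt)
        & (out["prev_normal"] < config.final_prev_normal_lt)
        & (out["ago_support"] >= config.min_ago_reads)
    ]


def write_candidate_report(
    stats: pd.DataFrame,
    ago_counts: Mapping[str, int],
    config: SelectionConfig,
    path,
) -> None:
    """Full per-fragment report with pass/fail flags for every predicate."""
    report = stats.copy()
    report["ago_support"] = [ago_counts.get(fid, 0) for fid in report.index]
    report["pass_fold"] = report["fold_change"] >= config.min_fold
    report["pass_prev_tumor_filter"] = (
        report["prev_tumor"] >= config.min_expressed_frac_tumor
    )
    report["pass_final_prev_tumor"] = report["prev_tumor"] > config.final_prev_tumor_gt
    report["pass_final_prev_normal"] = (
        report["prev_normal"] < config.final_prev_normal_lt
    )
    report["pass_ago"] = report["ago_support"] >= config.min_ago_reads
    report.to_csv(path, sep="\t", index_label="fragment_id")
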