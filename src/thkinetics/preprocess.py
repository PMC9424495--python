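"""Normalisation, expression filtering and fold-change computation.

Quantile normalisation forces every sample column onto the common
distribution of rank-wise column means (ties averaged); the expressed-gene
filter retains a gene only if its mean expression in at least one condition
exceeds the global median of the whole matrix; fold changes are computed on
the log2 scale relative to the first measured timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import ExpressionMatrix, SampleDesign

__all__ = [
    "FilterReport",
    "quantile_normalize",
    "log2_transform",
    "filter_expressed",
    "log2_fold_change",
    "replicate_mean_profiles",
]


@dataclass
class FilterReport:
    """Summary of an expressed-gene filtering step."""

    n_input: int
    n_retained: int
    rule: str
    per_condition_pass: dict[str, int]

    def __post_init__(self) -> None:
        if self.n_retained > self.n_input:
            raise ValueError("n_retained cannot exceed n_input")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalise samples to a common distribution.

    After normalisation every column holds the same multiset of values:
    the rank-wise mean across the input columns, with ties replaced by the
    mean over the tied ranks. The operation is idempotent and preserves the
    within-column rank order.
    """
    m.require_complete("quantile normalisation")
    x = m.values.astype(float)
    order = np.sort(x, axis=0)
    reference = order.mean(axis=1)  # mean of the k-th smallest value per column
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")  # 1-based, ties averaged
        # fractional ranks interpolate between neighbouring reference values
        out[:, j] = np.interp(ranks, np.arange(1, x.shape[0] + 1), reference)
    data = pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids)
    data.index.name = "gene_id"
    return ExpressionMatrix(data, log_scale=m.log_scale)


def log2_transform(m: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Elementwise ``log2(value + offset)``; flags the matrix as log scale."""
    if offset < 0:
        raise ValueError("offset must be non-negative")
    m.require_complete("log2 transform")
    shifted = m.values + offset
    if (shifted <= 0).any():
        raise ValueError(
            "non-positive values encountered; supply a positive offset")
    data = pd.DataFrame(np.log2(shifted), index=m.gene_ids, columns=m.sample_ids)
    data.index.name = "gene_id"
    return ExpressionMatrix(data, log_scale=True)


def filter_expressed(m: ExpressionMatrix, design: SampleDesign
                     ) -> tuple[ExpressionMatrix, FilterReport]:
    """Retain genes expressed above the global median in >= 1 condition.

    A gene passes if, for at least one condition, its mean over that
    condition's samples exceeds the median of the entire matrix. On an
    all-identical matrix nothing exceeds the median and zero genes are
    retained (degenerate but intended behaviour).
    """
    design.validate_against(m)
    m.require_complete("expression filtering")
    global_median = float(np.median(m.values))
    passes = {}
    for cond in design.conditions:
        samples = list(design.samples_for(cond)["sample_id"])
        passes[cond] = m.data[samples].mean(axis=1) > global_median
    pass_frame = pd.DataFrame(passes)
    keep = pass_frame.any(axis=1)
    retained = ExpressionMatrix(m.data.loc[keep].copy(), log_scale=m.log_scale)
    report = FilterReport(
        n_input=m.shape[0],
        n_retained=int(keep.sum()),
        rule=f"mean(condition) > global median ({global_median:.4g}) in >=1 condition",
        per_condition_pass={c: int(v.sum()) for c, v in passes.items()},
    )
    return retained, report


def replicate_mean_profiles(m: ExpressionMatrix, design: SampleDesign,
                            condition: str) -> pd.DataFrame:
    """Genes x timepoints table of replicate-mean log2 expression."""
    sub = design.samples_for(condition)
    groups = sub.groupby("time_h")["sample_id"].apply(list).sort_index()
    cols = {time: m.data[samples].mean(axis=1) for time, samples in groups.items()}
    out = pd.DataFrame(cols)
    out.columns.name = "time_h"
    return out


def log2_fold_change(m: ExpressionMatrix, design: SampleDesign,
                     reference_time: float = 0.0) -> pd.DataFrame:
    """Per gene x condition x time log2 fold change vs the reference time.

    ``FC(g, c, t) = mean_log2(g, c, t) - mean_log2(g, c, reference_time)``,
    so the value at the reference timepoint is identically zero and adding
    a constant to a gene's whole profile leaves the table unchanged.

    Returns a long-format DataFrame with columns gene_id, condition,
    time_h, log2_fc.
    """
    if not m.log_scale:
        raise ValueError("fold changes require a log2-scale matrix")
    design.validate_against(m)
    frames = []
    for cond in design.conditions:
        prof = replicate_mean_profiles(m, design, cond)
        if reference_time not in prof.columns:
            raise ValueError(
                f"reference time {reference_time} not measured in condition {cond!r}")
        fc = prof.sub(prof[reference_time], axis=0)
        long = fc.reset_index(names="gene_id").melt(
            id_vars="gene_id", var_name="time_h", value_name="log2_fc")
        long.insert(1, "condition", cond)
        frames.append(long)
    out = pd.concat(frames, ignore_index=True)
    out["time_h"] = out["time_h"].astype(float)
    return out
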