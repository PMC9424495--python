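"""Exploratory analyses: PCA trajectories, bifurcation timing, quadrant stats.

The differentiation time course is summarised by a gene-centred PCA on
samples; lineage divergence is read off the difference of replicate-mean
principal-component scores against the neutral (Th0) reference over time;
and a simple threshold detector reports the first timepoint of divergence
("bifurcation") and the time at which the divergence plateaus. Genes whose
profiles are highly correlated across *all* condition pairs carry no
lineage information and can be removed beforehand to sharpen the
trajectories. Quadrant co-expression statistics translate a 2x2 cytometry
frequency table (e.g. IFN-g x IL-4) into conditional and marginal
positive-cell frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data_io import ExpressionMatrix, SampleDesign
from .preprocess import replicate_mean_profiles

logger = logging.getLogger(__name__)

__all__ = [
    "PcaResult",
    "QuadrantTable",
    "remove_correlated_genes",
    "pca_timecourse",
    "pc_difference_trajectory",
    "bifurcation_time",
    "quadrant_coexpression_stats",
]

NO_DIVERGENCE = float("nan")


@dataclass
class PcaResult:
    """Sample scores, explained variance and loadings of a time-course PCA."""

    scores: pd.DataFrame            # samples x components, annotated index
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame          # genes x components
    sample_annotations: pd.DataFrame  # condition / time_h / replicate per sample

    def __post_init__(self) -> None:
        evr = self.explained_variance_ratio
        if np.any(np.diff(evr) > 1e-12) or evr.sum() > 1 + 1e-9:
            raise ValueError("explained-variance ratios must be non-increasing "
                             "and sum to at most 1")


@dataclass
class QuadrantTable:
    """2x2 cytometry quadrant frequencies in percent."""

    both_positive: float
    a_only: float
    b_only: float
    double_negative: float
    marker_a: str = "A"
    marker_b: str = "B"

    def __post_init__(self) -> None:
        vals = (self.both_positive, self.a_only, self.b_only, self.double_negative)
        if any(v < 0 for v in vals):
            raise ValueError("quadrant frequencies must be non-negative")
        if sum(vals) > 100.5:  # 0.5 tolerance for rounded inputs
            raise ValueError("quadrant frequencies exceed 100%")


def remove_correlated_genes(m: ExpressionMatrix, design: SampleDesign,
                            r_threshold: float = 0.9
                            ) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes whose profiles agree across every pair of conditions.

    A gene is removed iff the *minimum* over all condition pairs of the
    Pearson correlation between its replicate-mean profiles exceeds
    ``r_threshold`` — i.e. it responds identically in all subsets and so
    cannot discriminate lineages. Constant profiles (undefined r) are
    treated as correlated and removed (logged).
    """
    conds = design.conditions
    if len(conds) < 2:
        raise ValueError("need at least two conditions")
    profiles = {c: replicate_mean_profiles(m, design, c).to_numpy(dtype=float)
                for c in conds}
    min_r = np.full(m.shape[0], np.inf)
    any_constant = np.zeros(m.shape[0], dtype=bool)
    for a, b in combinations(conds, 2):
        xa, xb = profiles[a], profiles[b]
        xa_c = xa - xa.mean(axis=1, keepdims=True)
        xb_c = xb - xb.mean(axis=1, keepdims=True)
        na = np.sqrt((xa_c ** 2).sum(axis=1))
        nb = np.sqrt((xb_c ** 2).sum(axis=1))
        const = (na <= 1e-12) | (nb <= 1e-12)
        any_constant |= const
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xa_c * xb_c).sum(axis=1) / (na * nb)
        r = np.where(const, 1.0, r)  # constant = indistinguishable = correlated
        min_r = np.minimum(min_r, r)
    remove = min_r > r_threshold
    if any_constant.any():
        logger.info("remove_correlated_genes: %d constant profiles treated "
                    "as correlated", int(any_constant.sum()))
    removed = [g for g, flag in zip(m.gene_ids, remove) if flag]
    kept = [g for g, flag in zip(m.gene_ids, remove) if not flag]
    return m.subset_genes(kept), removed


def pca_timecourse(m: ExpressionMatrix, design: SampleDesign,
                   n_components: int = 4) -> PcaResult:
    """Gene-centred PCA of samples, with PC1 oriented along time.

    Each gene is centred across samples, samples are projected onto the
    principal axes, and every component's sign is fixed so that its score
    correlates non-negatively with measurement time (PCA signs are
    otherwise arbitrary, which would break downstream determinism).
    """
    design.validate_against(m)
    m.require_complete("PCA")
    X = m.values.T  # samples x genes
    if n_components > min(X.shape):
        raise ValueError(
            f"{n_components} components exceed the matrix rank bound "
            f"{min(X.shape)}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    annot = design.table.set_index("sample_id").loc[m.sample_ids]
    times = annot["time_h"].to_numpy(dtype=float)
    loadings = pca.components_.T.copy()
    for c in range(n_components):
        if np.std(scores[:, c]) > 0:
            sign = np.sign(np.corrcoef(scores[:, c], times)[0, 1])
            if sign < 0:
                scores[:, c] *= -1
                loadings[:, c] *= -1
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=m.sample_ids, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(loadings, index=m.gene_ids, columns=cols),
        sample_annotations=annot[["condition", "time_h", "replicate"]],
    )


def pc_difference_trajectory(pca: PcaResult, design: SampleDesign,
                             reference: str = "Th0", component: int = 1
                             ) -> pd.DataFrame:
    """Per-condition time series of PC score differences vs the reference.

    ``dPC(c, t) = mean score(c, t) - mean score(reference, t)`` on
    replicate-mean scores; the reference's own trajectory is identically
    zero. Timepoints missing in either condition are omitted with a
    warning. Returns a long DataFrame (condition, time_h, delta_pc).
    """
    if reference not in design.conditions:
        raise ValueError(f"reference condition {reference!r} not in design")
    col = f"PC{component}"
    if col not in pca.scores.columns:
        raise ValueError(f"component {component} not computed")
    merged = pca.scores[[col]].join(pca.sample_annotations)
    means = merged.groupby(["condition", "time_h"])[col].mean().unstack("time_h")
    ref = means.loc[reference]
    rows = []
    for cond in design.conditions:
        for t in means.columns:
            val, rv = means.loc[cond, t], ref[t]
            if np.isnan(val) or np.isnan(rv):
                logger.warning("dPC: timepoint %s missing for %s or %s; omitted",
                               t, cond, reference)
                continue
            rows.append({"condition": cond, "time_h": float(t),
                         "delta_pc": float(val - rv), "component": component})
    return pd.DataFrame(rows)


def bifurcation_time(trajectories: pd.DataFrame, fraction: float = 0.2
                     ) -> pd.DataFrame:
    """First divergence and plateau times per condition.

    For each condition the bifurcation time is the first timepoint at
    which |dPC| exceeds ``fraction`` x its maximum over the trajectory;
    the plateau time is the first timepoint reaching 0.9 x the maximum.
    An all-zero trajectory yields NaN ("no divergence").
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rows = []
    for cond, sub in trajectories.groupby("condition", sort=False):
        sub = sub.sort_values("time_h")
        mag = sub["delta_pc"].abs().to_numpy()
        times = sub["time_h"].to_numpy()
        peak = mag.max()
        if peak <= 1e-12:
            rows.append({"condition": cond, "bifurcation_h": NO_DIVERGENCE,
                         "plateau_h": NO_DIVERGENCE, "max_abs_delta": 0.0})
            continue
        t_bif = times[mag > fraction * peak][0]
        t_plateau = times[mag >= 0.9 * peak][0]
        rows.append({"condition": cond, "bifurcation_h": float(t_bif),
                     "plateau_h": float(t_plateau),
                     "max_abs_delta": float(peak)})
    return pd.DataFrame(rows)


def quadrant_coexpression_stats(q: QuadrantTable) -> dict[str, float]:
    """Conditional and marginal positive frequencies from a 2x2 quadrant table.

    conditional = both_positive / (both_positive + A_only) x 100 is the
    frequency of B-producers *within* A-producing cells; marginal =
    both_positive + B_only is the overall frequency of B-producers. A
    conditional above the marginal indicates co-expression synergy.
    Returns percentages; the conditional is NaN when no cell is A-positive.
    """
    denom = q.both_positive + q.a_only
    conditional = 100.0 * q.both_positive / denom if denom > 0 else float("nan")
    marginal = q.both_positive + q.b_only
    return {
        "conditional_b_within_a_pct": conditional,
        "marginal_b_pct": marginal,
        "synergy": bool(denom > 0 and conditional > marginal),
    }
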