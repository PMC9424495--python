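"""Per-gene linear decomposition of a hybrid lineage's transcriptome.

For each gene the hybrid condition's time profile ``Y_hyb`` is regressed on
the same gene's Th1 and Th2 profiles,

    Y_hyb(t) = beta_Th1 * Y_Th1(t) + beta_Th2 * Y_Th2(t) + eps,

with no intercept term. The significance pattern of the two coefficients
classifies the gene into four categories: both significant and positive ->
*Superposition*; only beta_Th1 -> *Th1_like*; only beta_Th2 -> *Th2_like*;
neither -> *Independent* (an expression program attributable to neither
lineage nor their combination).

Profiles are mean-centred before fitting by default: on the log2 scale all
conditions share a gene's baseline level, and without centring that common
constant dominates both regressors, pushing every fit toward
beta = (0.5, 0.5) regardless of kinetics. Centring removes the shared
baseline so the coefficients measure the contribution of each lineage's
*kinetic response*, which is the quantity of interest; the uncentred fit
on raw values remains available via ``center=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .data_io import ExpressionMatrix, SampleDesign
from .preprocess import replicate_mean_profiles

__all__ = [
    "HybridFit",
    "CategoryFractions",
    "fit_hybrid_model",
    "classify_hybrid_gene",
    "decompose_all",
    "threshold_robustness_scan",
    "CATEGORIES",
]

CATEGORIES = ("Th1_like", "Th2_like", "Superposition", "Independent")

_RSS_EPS = 1e-10
_BETA_EPS = 1e-8


@dataclass
class HybridFit:
    """One gene's two-coefficient decomposition onto the Th1/Th2 programs."""

    gene: str
    target: str
    beta_th1: float
    beta_th2: float
    se_th1: float
    se_th2: float
    t_th1: float
    t_th2: float
    p_th1: float
    p_th2: float
    rss: float
    n_points: int
    category: str = ""
    negative_significant: bool = False
    collinear: bool = False


@dataclass
class CategoryFractions:
    """Counts and fractions of analyzed genes per hybrid category."""

    counts: dict[str, int]
    n_analyzed: int
    n_unfit: int
    gene_set_provenance: str

    @property
    def fractions(self) -> dict[str, float]:
        if self.n_analyzed == 0:
            return {c: float("nan") for c in CATEGORIES}
        return {c: self.counts.get(c, 0) / self.n_analyzed for c in CATEGORIES}

    def as_frame(self) -> pd.DataFrame:
        fr = self.fractions
        return pd.DataFrame({
            "category": list(CATEGORIES),
            "count": [self.counts.get(c, 0) for c in CATEGORIES],
            "fraction": [fr[c] for c in CATEGORIES],
        })


def _profile_matrices(m: ExpressionMatrix, design: SampleDesign,
                      genes: list[str], target: str,
                      use_all_samples: bool) -> dict[str, np.ndarray]:
    """Genes x fitted-points arrays for the target, Th1 and Th2 conditions.

    The Th1/Th2 regressors are always the replicate-mean lineage profiles
    (the best available estimate of each lineage's expression program —
    using raw replicate samples as regressors would inflate the
    errors-in-variables attenuation of the coefficients). With
    ``use_all_samples`` the target keeps every replicate sample as a
    separate fitted point and the lineage profiles are expanded to match;
    otherwise the target is its replicate-mean profile (10 points).
    """
    sub = m.subset_genes(genes)
    for cond in (target, "Th1", "Th2"):
        if cond not in design.conditions:
            raise ValueError(f"condition {cond!r} not in design")
    mean_prof = {cond: replicate_mean_profiles(sub, design, cond)
                 for cond in (target, "Th1", "Th2")}
    if not use_all_samples:
        return {cond: prof.to_numpy(dtype=float)
                for cond, prof in mean_prof.items()}
    srows = design.samples_for(target).sort_values(["time_h", "replicate"])
    out = {target: sub.data[list(srows["sample_id"])].to_numpy(dtype=float)}
    times = list(mean_prof["Th1"].columns)
    col_idx = [times.index(t) for t in srows["time_h"]]
    for cond in ("Th1", "Th2"):
        out[cond] = mean_prof[cond].to_numpy(dtype=float)[:, col_idx]
    return out


def fit_hybrid_model(m: ExpressionMatrix, design: SampleDesign, gene: str,
                     target: str = "Th12", center: bool = True,
                     use_all_samples: bool = False) -> HybridFit:
    """No-intercept least squares of the target profile on Th1 and Th2.

    Coefficient t-tests use n - 2 residual degrees of freedom, n being the
    number of fitted points (10 replicate-mean timepoints by default).
    Near-collinear regressors (|Pearson r(Th1, Th2)| > 0.999) make the
    decomposition unidentifiable; such genes are returned flagged
    ``collinear`` and excluded from classification.
    """
    profs = _profile_matrices(m, design, [gene], target, use_all_samples)
    return _fit_one(gene, target, profs[target][0], profs["Th1"][0],
                    profs["Th2"][0], center)


def _fit_one(gene: str, target: str, y: np.ndarray, x1: np.ndarray,
             x2: np.ndarray, center: bool) -> HybridFit:
    y, x1, x2 = y.copy(), x1.copy(), x2.copy()
    if center:
        y -= y.mean()
        x1 -= x1.mean()
        x2 -= x2.mean()
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 fitted points for a 2-coefficient model")

    s1, s2 = np.std(x1), np.std(x2)
    if s1 > 0 and s2 > 0:
        r12 = float(np.corrcoef(x1, x2)[0, 1])
    else:
        r12 = 1.0  # a constant regressor leaves the split unidentifiable
    if abs(r12) > 0.999:
        return HybridFit(gene, target, np.nan, np.nan, np.nan, np.nan,
                         np.nan, np.nan, np.nan, np.nan, np.nan, n,
                         category="unfit", collinear=True)

    X = np.column_stack([x1, x2])
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - 2
    if rss <= _RSS_EPS:
        # perfect (noiseless) fit: a coefficient is "significant" iff nonzero
        se = np.zeros(2)
        tstat = np.where(np.abs(beta) > _BETA_EPS, np.inf, 0.0)
        pvals = np.where(np.abs(beta) > _BETA_EPS, 0.0, 1.0)
    else:
        sigma2 = rss / df
        se = np.sqrt(sigma2 * np.diag(xtx_inv))
        tstat = beta / se
        pvals = 2.0 * t_dist.sf(np.abs(tstat), df)
    return HybridFit(gene, target, float(beta[0]), float(beta[1]),
                     float(se[0]), float(se[1]), float(tstat[0]),
                     float(tstat[1]), float(pvals[0]), float(pvals[1]),
                     rss, n)


def classify_hybrid_gene(fit: HybridFit, alpha: float = 0.05) -> str:
    """Four-way category from the significance pattern of the coefficients.

    A coefficient counts as significant only if its two-sided p-value is
    below alpha AND the estimate is positive. A significant *negative*
    coefficient sets ``negative_significant`` (the gene anti-correlates
    with that lineage) and classification proceeds on the remaining
    positive pattern.
    """
    if fit.collinear:
        fit.category = "unfit"
        return fit.category
    sig1 = fit.p_th1 < alpha and fit.beta_th1 > 0
    sig2 = fit.p_th2 < alpha and fit.beta_th2 > 0
    fit.negative_significant = bool(
        (fit.p_th1 < alpha and fit.beta_th1 < 0)
        or (fit.p_th2 < alpha and fit.beta_th2 < 0))
    if sig1 and sig2:
        fit.category = "Superposition"
    elif sig1:
        fit.category = "Th1_like"
    elif sig2:
        fit.category = "Th2_like"
    else:
        fit.category = "Independent"
    return fit.category


def decompose_all(m: ExpressionMatrix, design: SampleDesign,
                  gene_set: list[str], target: str = "Th12",
                  alpha: float = 0.05, center: bool = True,
                  use_all_samples: bool = False,
                  gene_set_provenance: str = "Th1-vs-Th2 qualitative DEG"
                  ) -> tuple[pd.DataFrame, CategoryFractions]:
    """Fit and classify every gene of the analysis set.

    Returns the per-gene fit table and the category counts/fractions over
    the genes that could be fit (collinear/unfit genes are reported in the
    table and counted separately).
    """
    if not gene_set:
        raise ValueError("empty gene set for hybrid decomposition")
    profs = _profile_matrices(m, design, gene_set, target, use_all_samples)
    rows = []
    counts: dict[str, int] = {c: 0 for c in CATEGORIES}
    n_unfit = 0
    for i, gene in enumerate(gene_set):
        fit = _fit_one(gene, target, profs[target][i], profs["Th1"][i],
                       profs["Th2"][i], center)
        if not fit.collinear:
            classify_hybrid_gene(fit, alpha=alpha)
            counts[fit.category] += 1
        else:
            n_unfit += 1
        rows.append({
            "gene_id": fit.gene, "target": fit.target,
            "beta_th1": fit.beta_th1, "beta_th2": fit.beta_th2,
            "se_th1": fit.se_th1, "se_th2": fit.se_th2,
            "p_th1": fit.p_th1, "p_th2": fit.p_th2,
            "rss": fit.rss, "n_points": fit.n_points,
            "category": fit.category,
            "negative_significant": fit.negative_significant,
            "collinear": fit.collinear,
        })
    table = pd.DataFrame(rows)
    fractions = CategoryFractions(counts, sum(counts.values()), n_unfit,
                                  gene_set_provenance)
    return table, fractions


def threshold_robustness_scan(m: ExpressionMatrix, design: SampleDesign,
                              gene_set: list[str], alphas: list[float],
                              index_thresholds: list[float] | None = None,
                              target: str = "Th12", center: bool = True,
                              contrasts: pd.DataFrame | None = None
                              ) -> pd.DataFrame:
    """Category fractions across a grid of significance thresholds.

    For each alpha (and, when a Th1-vs-Th2 contrast table is supplied,
    each correlation-index threshold regenerating the qualitative-DEG
    analysis set), genes are re-classified and the fractions recorded in
    long format. Documents the robustness of the four-way split to the
    exact statistical thresholds.
    """
    if not alphas or (index_thresholds is not None and not index_thresholds):
        raise ValueError("threshold grids must be non-empty")
    index_thresholds = index_thresholds if index_thresholds is not None else [None]
    rows = []
    for idx_thr in index_thresholds:
        if idx_thr is None or contrasts is None:
            genes = gene_set
        else:
            from .differential import qualitative_deg
            flagged = qualitative_deg(contrasts, index_threshold=idx_thr)
            genes = list(flagged.loc[flagged["qualitative_deg"], "gene_id"])
        if not genes:
            continue
        # fits do not depend on alpha; classify once per gene per index grid
        table, _ = decompose_all(m, design, genes, target=target, alpha=alphas[0],
                                 center=center)
        for alpha in alphas:
            counts = {c: 0 for c in CATEGORIES}
            for _, row in table.iterrows():
                if row["collinear"]:
                    continue
                fit = HybridFit(row["gene_id"], target, row["beta_th1"],
                                row["beta_th2"], row["se_th1"], row["se_th2"],
                                np.nan, np.nan, row["p_th1"], row["p_th2"],
                                row["rss"], int(row["n_points"]))
                counts[classify_hybrid_gene(fit, alpha=alpha)] += 1
            total = sum(counts.values())
            for cat in CATEGORIES:
                rows.append({
                    "alpha": alpha,
                    "index_threshold": np.nan if idx_thr is None else idx_thr,
                    "category": cat, "count": counts[cat],
                    "fraction": counts[cat] / total if total else np.nan,
                })
    return pd.DataFrame(rows)
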