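"""Differential kinetics between conditions: quantitative and qualitative DEG.

The multi-condition model regresses each gene's log2 expression on a shared
polynomial in time plus, for every non-reference condition, an offset and
polynomial-time interaction terms. A nested F-test of the full model
against the time-only model flags genes with *any* condition effect; a
joint F-test on the coefficients distinguishing a pair of conditions then
yields per-pair *quantitative DEG*. The *correlation index* 1 - r (r =
Pearson correlation of the two conditions' replicate-mean time profiles)
separates genes that merely differ in level from genes with dissimilar
temporal trends: quantitative DEG with index > 0.3 are *qualitative DEG*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .data_io import ExpressionMatrix, SampleDesign, benjamini_hochberg
from .kinetics import _f_test_from_rss, _RSS_EPS
from .preprocess import replicate_mean_profiles

__all__ = [
    "GroupModelFits",
    "fit_group_model",
    "contrast_test",
    "correlation_index",
    "correlation_index_table",
    "qualitative_deg",
    "build_volcano_table",
]


@dataclass
class GroupModelFits:
    """Fitted multi-condition polynomial model for a set of genes.

    Holds the per-gene coefficient estimates and shared design quantities
    needed for downstream contrast tests, plus the nested-F table
    (full model vs time-only) with Benjamini-Hochberg q-values across
    genes.
    """

    table: pd.DataFrame  # gene_id, f_stat, p_value, q_value, significant
    genes: list[str]
    conditions: list[str]
    reference: str
    degree: int
    alpha: float
    beta: np.ndarray        # p x G coefficient matrix
    xtx_inv: np.ndarray     # p x p
    rss: np.ndarray         # per gene
    df_resid: int
    col_index: dict[str, list[int]]  # condition -> its distinguishing columns

    def significant_genes(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "gene_id"])


def _group_design(design: SampleDesign, samples: pd.DataFrame, degree: int,
                  reference: str) -> tuple[np.ndarray, dict[str, list[int]]]:
    t = samples["time_h"].to_numpy(dtype=float)
    cond = samples["condition"].to_numpy()
    conditions = [c for c in design.conditions]
    others = [c for c in conditions if c != reference]
    n = len(samples)
    cols = [np.ones(n)]
    for d in range(1, degree + 1):
        cols.append(t ** d)
    col_index: dict[str, list[int]] = {}
    for c in others:
        dummy = (cond == c).astype(float)
        idx = []
        for d in range(0, degree + 1):
            idx.append(len(cols))
            cols.append(dummy * t ** d)
        col_index[c] = idx
    return np.column_stack(cols), col_index


def fit_group_model(m: ExpressionMatrix, design: SampleDesign,
                    gene_set: list[str], degree: int = 3,
                    reference: str = "Th0", alpha: float = 0.05
                    ) -> GroupModelFits:
    """Fit the full time x condition model and the nested overall F-test.

    ``gene_set`` is normally the union of kinetic genes. The test compares
    the full model (shared time polynomial + per-condition offset and
    time interactions, reference condition carrying no own terms) against
    the time-only model; p-values are BH-corrected across genes.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if reference not in design.conditions:
        raise ValueError(f"reference condition {reference!r} not in design")
    if not gene_set:
        raise ValueError("empty gene set")
    design.validate_against(m)
    sub = m.subset_genes(gene_set)
    samples = design.table
    X, col_index = _group_design(design, samples, degree, reference)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(
            "rank-deficient group design: condition/time terms are collinear "
            f"(n={n}, p={p}); reduce the polynomial degree")
    Y = sub.data[list(samples["sample_id"])].to_numpy(dtype=float).T
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)

    X0 = X[:, :degree + 1]  # time-only model
    beta0, _, _, _ = np.linalg.lstsq(X0, Y, rcond=None)
    resid0 = Y - X0 @ beta0
    rss0 = np.einsum("ij,ij->j", resid0, resid0)

    df_num = p - (degree + 1)
    df_den = n - p
    f, pval = _f_test_from_rss(rss, rss0, df_num, df_den)
    q = benjamini_hochberg(pval)
    table = pd.DataFrame({
        "gene_id": sub.gene_ids, "f_stat": f, "p_value": pval,
        "q_value": q, "significant": q < alpha,
    })
    return GroupModelFits(
        table=table, genes=sub.gene_ids, conditions=list(design.conditions),
        reference=reference, degree=degree, alpha=alpha, beta=beta,
        xtx_inv=np.linalg.inv(X.T @ X), rss=rss, df_resid=df_den,
        col_index=col_index)


def _restriction_matrix(fits: GroupModelFits, pair: tuple[str, str]) -> np.ndarray:
    a, b = pair
    for c in pair:
        if c not in fits.conditions:
            raise ValueError(f"condition {c!r} not in the fitted design")
    if a == b:
        raise ValueError("contrast requires two distinct conditions")
    p = fits.beta.shape[0]
    k = fits.degree + 1
    R = np.zeros((k, p))
    if a == fits.reference:
        R[np.arange(k), fits.col_index[b]] = 1.0
    elif b == fits.reference:
        R[np.arange(k), fits.col_index[a]] = 1.0
    else:
        R[np.arange(k), fits.col_index[a]] = 1.0
        R[np.arange(k), fits.col_index[b]] = -1.0
    return R


def contrast_test(fits: GroupModelFits, pair: tuple[str, str],
                  alpha: float | None = None) -> pd.DataFrame:
    """Joint F-test that all coefficients distinguishing a pair are zero.

    Only genes that passed the overall nested F (step one) are tested;
    the per-contrast p-values are BH-corrected among those genes and
    ``quantitative_deg`` requires both steps. The test is symmetric in the
    pair ordering.
    """
    alpha = fits.alpha if alpha is None else alpha
    R = _restriction_matrix(fits, pair)
    q_dim = R.shape[0]
    M = R @ fits.xtx_inv @ R.T
    Rb = R @ fits.beta                       # q x G
    quad = np.einsum("ig,ig->g", Rb, np.linalg.solve(M, Rb))
    quad = np.maximum(quad, 0.0)
    sigma2 = fits.rss / fits.df_resid
    f = np.full_like(quad, np.inf)
    pval = np.zeros_like(quad)
    ok = sigma2 > _RSS_EPS / fits.df_resid
    f[ok] = (quad[ok] / q_dim) / sigma2[ok]
    pval[ok] = f_dist.sf(f[ok], q_dim, fits.df_resid)
    perfect_null = (~ok) & (quad <= _RSS_EPS)
    f[perfect_null] = 0.0
    pval[perfect_null] = 1.0

    out = pd.DataFrame({
        "gene_id": fits.genes, "pair": f"{pair[0]}:{pair[1]}",
        "contrast_f": f, "contrast_p": pval,
    })
    eligible = fits.table["significant"].to_numpy()
    qvals = np.full(len(out), np.nan)
    if eligible.any():
        qvals[eligible] = benjamini_hochberg(pval[eligible])
    out["contrast_q"] = qvals
    out["quantitative_deg"] = eligible & (np.nan_to_num(qvals, nan=1.0) < alpha)
    return out


def stepwise_contrast_flags(m: ExpressionMatrix, design: SampleDesign,
                            fits: GroupModelFits, pair: tuple[str, str],
                            alpha_exit: float = 0.05) -> pd.DataFrame:
    """Backward-stepwise alternative to the joint contrast F-test.

    Per gene, condition coefficients are eliminated one at a time (largest
    coefficient p-value first, refitting after each drop) until every
    remaining condition coefficient is significant at ``alpha_exit``; the
    shared time polynomial and intercept are never dropped. A gene is
    flagged for the pair when any retained coefficient distinguishes the
    two conditions. Slower and greedier than the joint F default, but
    mirrors the stepwise coefficient-selection style of regression-based
    time-course DEG workflows.
    """
    a, b = pair
    if a == b or not {a, b} <= set(fits.conditions):
        raise ValueError(f"invalid pair {pair!r}")
    # reparameterize with the pair's second condition as reference so the
    # first condition's own columns directly encode the a-vs-b difference
    samples = design.table
    X_full, col_index = _group_design(design, samples, fits.degree, b)
    sub = m.subset_genes(fits.genes)
    Y = sub.data[list(samples["sample_id"])].to_numpy(dtype=float).T
    n = X_full.shape[0]
    protected = list(range(fits.degree + 1))
    candidates = [j for cols in col_index.values() for j in cols]
    distinguishing = set(col_index[a])

    flags = np.zeros(len(fits.genes), dtype=bool)
    for g in range(Y.shape[1]):
        keep = protected + candidates
        y = Y[:, g]
        while len(keep) > len(protected):
            X = X_full[:, keep]
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            rss = float(resid @ resid)
            df = n - len(keep)
            if rss <= _RSS_EPS:
                pvals = np.where(np.abs(beta) > 1e-8, 0.0, 1.0)
            else:
                sigma2 = rss / df
                se = np.sqrt(sigma2 * np.diag(
                    np.linalg.inv(X.T @ X)))
                from scipy.stats import t as t_dist
                pvals = 2.0 * t_dist.sf(np.abs(beta / se), df)
            cand_pos = [i for i, j in enumerate(keep) if j not in protected]
            worst = max(cand_pos, key=lambda i: pvals[i])
            if pvals[worst] <= alpha_exit:
                break
            keep.pop(worst)
        flags[g] = bool(distinguishing & set(keep))
    return pd.DataFrame({"gene_id": fits.genes,
                         "pair": f"{a}:{b}",
                         "stepwise_flag": flags})


# ---------------------------------------------------------------------------
# Correlation index
# ---------------------------------------------------------------------------

def correlation_index(m: ExpressionMatrix, design: SampleDesign, gene: str,
                      pair: tuple[str, str], mode: str = "mean"
                      ) -> tuple[float, float]:
    """Pearson r between a gene's time profiles in two conditions, and 1 - r.

    ``mode="mean"`` correlates the replicate-mean profiles over shared
    timepoints (default); ``mode="all"`` correlates time-matched individual
    replicate samples. A constant profile in either condition leaves r
    undefined and returns NaN for both values.
    """
    table = correlation_index_table(m, design, [gene], pair, mode=mode)
    row = table.iloc[0]
    return float(row["pearson_r"]), float(row["correlation_index"])


def correlation_index_table(m: ExpressionMatrix, design: SampleDesign,
                            genes: list[str], pair: tuple[str, str],
                            mode: str = "mean") -> pd.DataFrame:
    """Vectorised correlation index for many genes at once."""
    if mode not in ("mean", "all"):
        raise ValueError(f"unknown correlation mode {mode!r}")
    a, b = pair
    prof_a = replicate_mean_profiles(m.subset_genes(genes), design, a)
    prof_b = replicate_mean_profiles(m.subset_genes(genes), design, b)
    shared = [t for t in prof_a.columns if t in set(prof_b.columns)]
    if len(shared) < 3:
        raise ValueError(f"conditions {a!r}/{b!r} share only {len(shared)} timepoints")
    if mode == "mean":
        xa = prof_a[shared].to_numpy(dtype=float)
        xb = prof_b[shared].to_numpy(dtype=float)
    else:
        xa, xb = _matched_replicate_matrices(m, design, genes, pair, shared)
    xa_c = xa - xa.mean(axis=1, keepdims=True)
    xb_c = xb - xb.mean(axis=1, keepdims=True)
    denom = np.sqrt((xa_c ** 2).sum(axis=1) * (xb_c ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (xa_c * xb_c).sum(axis=1) / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame({
        "gene_id": genes, "pair": f"{a}:{b}",
        "pearson_r": r, "correlation_index": 1.0 - r,
    })


def _matched_replicate_matrices(m, design, genes, pair, shared):
    sub = m.subset_genes(genes)
    mats = []
    for cond in pair:
        srows = design.samples_for(cond)
        srows = srows[srows["time_h"].isin(shared)].sort_values(
            ["time_h", "replicate"])
        mats.append((sub.data[list(srows["sample_id"])].to_numpy(dtype=float),
                     srows[["time_h", "replicate"]].reset_index(drop=True)))
    (xa, meta_a), (xb, meta_b) = mats
    if not meta_a.equals(meta_b):
        raise ValueError(
            f"conditions {pair[0]!r}/{pair[1]!r} have unmatched replicate "
            "structure; use mode='mean'")
    return xa, xb


def qualitative_deg(contrasts: pd.DataFrame,
                    index_threshold: float = 0.3) -> pd.DataFrame:
    """Flag qualitative DEG: quantitative DEG with correlation index > threshold.

    Genes with an undefined (NaN) correlation index are excluded from
    qualitative calls; the nesting qualitative => quantitative always holds.
    """
    if not 0 <= index_threshold <= 2:
        raise ValueError("index threshold must lie in [0, 2]")
    if "correlation_index" not in contrasts.columns:
        raise ValueError("contrast table lacks correlation_index column")
    out = contrasts.copy()
    idx = out["correlation_index"]
    out["qualitative_deg"] = (
        out["quantitative_deg"] & idx.notna() & (idx > index_threshold))
    return out


def build_volcano_table(calls: pd.DataFrame, contrasts: pd.DataFrame,
                        pair: tuple[str, str],
                        switches: pd.DataFrame | None = None) -> pd.DataFrame:
    """Correlation-volcano table for one condition pair.

    One row per kinetic-union gene, with x = correlation index, y =
    -log10 contrast q, and the nested category label (kinetic <
    quantitative DEG < qualitative DEG). Cluster-switch status, when
    supplied, is carried as an independent column.
    """
    union = pd.unique(calls.loc[calls["kinetic"], "gene_id"])
    sub = contrasts.set_index("gene_id").reindex(union)
    q = sub["contrast_q"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        neg_log_q = -np.log10(np.where(np.isnan(q), 1.0, q))
    def _bool(col: str) -> np.ndarray:
        return sub[col].map(lambda v: bool(v) if pd.notna(v) else False).to_numpy()

    category = np.where(
        _bool("qualitative_deg"), "qualitative DEG",
        np.where(_bool("quantitative_deg"), "quantitative DEG", "kinetic"))
    out = pd.DataFrame({
        "gene_id": union, "pair": f"{pair[0]}:{pair[1]}",
        "correlation_index": sub["correlation_index"].to_numpy(),
        "neg_log10_q": neg_log_q, "category": category,
    })
    if switches is not None:
        sw = switches.set_index("gene_id")["switch"]
        out["cluster_switch"] = out["gene_id"].map(
            lambda g: bool(sw.get(g, False))).to_numpy()
    return out
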