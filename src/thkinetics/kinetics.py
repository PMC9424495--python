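"""Detection of kinetic genes and their temporal patterns.

A gene is *kinetic* in a condition if a polynomial regression of its log2
expression on time explains significant variance (F-test against the
intercept-only model, Benjamini-Hochberg FDR within the condition), or if
it shows a two-fold change versus the t=0 baseline at two consecutive
timepoints (the fold-change rescue rule). Kinetic genes are then grouped
into temporal archetypes by agglomerative clustering under the correlation
distance (1 - Pearson r between replicate-mean profiles), and cluster
centroids are labelled as fast-transient-up (C1), delayed-stable-up (C2)
or stable-down (C3) from their shape features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import cdist, pdist
from scipy.stats import f as f_dist

from .data_io import ExpressionMatrix, SampleDesign, benjamini_hochberg
from .preprocess import replicate_mean_profiles

__all__ = [
    "PolyFit",
    "ClusterAssignment",
    "fit_time_polynomial",
    "fit_condition_polynomials",
    "foldchange_rule",
    "call_kinetic_genes",
    "cluster_profiles",
    "assign_archetype_labels",
    "detect_cluster_switches",
]

_RSS_EPS = 1e-12


@dataclass
class PolyFit:
    """Per-gene, per-condition polynomial time-regression fit."""

    gene: str
    condition: str
    degree: int
    coefficients: np.ndarray  # ascending powers, length degree+1
    rss: float
    tss: float
    f_stat: float
    p_value: float


def _poly_design(t: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(t, degree + 1, increasing=True)


def _f_test_from_rss(rss_full: np.ndarray, rss_reduced: np.ndarray,
                     df_num: int, df_den: int) -> tuple[np.ndarray, np.ndarray]:
    """F statistic and p-value comparing nested least-squares fits.

    Degenerate cases: no variance to explain (reduced RSS ~ 0) gives F=0,
    p=1; a perfect full fit with explained variance gives p=0.
    """
    rss_full = np.atleast_1d(np.asarray(rss_full, dtype=float))
    rss_reduced = np.atleast_1d(np.asarray(rss_reduced, dtype=float))
    explained = np.maximum(rss_reduced - rss_full, 0.0)
    f = np.zeros_like(rss_full)
    p = np.ones_like(rss_full)
    trivial = rss_reduced <= _RSS_EPS
    perfect = (~trivial) & (rss_full <= _RSS_EPS)
    regular = (~trivial) & (~perfect)
    f[regular] = (explained[regular] / df_num) / (rss_full[regular] / df_den)
    p[regular] = f_dist.sf(f[regular], df_num, df_den)
    f[perfect] = np.inf
    p[perfect] = 0.0
    return f, p


def fit_time_polynomial(times: np.ndarray, values: np.ndarray, degree: int = 3,
                        gene: str = "", condition: str = "") -> PolyFit:
    """Least-squares polynomial fit of one expression profile on time.

    Tests the full degree-``degree`` model against the intercept-only model
    with an exact F-test on (degree, n - degree - 1) degrees of freedom.
    Replicate samples enter as independent observations.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and values must have equal length")
    n = t.size
    if n < degree + 2:
        raise ValueError(
            f"gene {gene!r} / condition {condition!r}: {n} samples cannot "
            f"support degree {degree} (need >= {degree + 2})")
    if np.unique(t).size < degree + 1:
        raise ValueError(
            f"gene {gene!r} / condition {condition!r}: need >= {degree + 1} "
            "distinct times")
    X = _poly_design(t, degree)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    f, p = _f_test_from_rss(rss, tss, degree, n - degree - 1)
    return PolyFit(gene, condition, degree, beta, rss, tss, float(f[0]), float(p[0]))


def fit_condition_polynomials(m: ExpressionMatrix, design: SampleDesign,
                              condition: str, degree: int = 3) -> pd.DataFrame:
    """Vectorised polynomial time regression for every gene in one condition.

    Returns a DataFrame with columns gene_id, condition, f_stat, p_value,
    rss, tss (one row per gene; same statistics as
    :func:`fit_time_polynomial`).
    """
    sub = design.samples_for(condition)
    samples = list(sub["sample_id"])
    t = sub["time_h"].to_numpy(dtype=float)
    n = t.size
    if n < degree + 2 or np.unique(t).size < degree + 1:
        raise ValueError(
            f"condition {condition!r}: insufficient samples/times for degree {degree}")
    Y = m.data[samples].to_numpy(dtype=float).T  # samples x genes
    X = _poly_design(t, degree)
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    centered = Y - Y.mean(axis=0)
    tss = np.einsum("ij,ij->j", centered, centered)
    f, p = _f_test_from_rss(rss, tss, degree, n - degree - 1)
    return pd.DataFrame({
        "gene_id": m.gene_ids, "condition": condition,
        "f_stat": f, "p_value": p, "rss": rss, "tss": tss,
    })


def foldchange_rule(fc_table: pd.DataFrame, threshold_log2: float = 1.0,
                    consecutive: int = 2, two_sided: bool = True,
                    reference_time: float = 0.0) -> pd.DataFrame:
    """Flag genes with a two-fold change sustained at consecutive timepoints.

    A gene x condition is flagged when ``consecutive`` adjacent
    non-reference timepoints all show |log2 FC| >= ``threshold_log2``
    (or signed FC >= threshold with ``two_sided=False``). The two-sided
    default keeps stably downregulated genes eligible.
    """
    if consecutive < 1:
        raise ValueError("consecutive must be >= 1")
    rows = []
    for cond, sub in fc_table.groupby("condition", sort=False):
        wide = sub.pivot(index="gene_id", columns="time_h", values="log2_fc")
        wide = wide[sorted(wide.columns)]
        nonref = wide.drop(columns=[reference_time], errors="ignore")
        if nonref.shape[1] < consecutive:
            raise ValueError(
                f"condition {cond!r}: {nonref.shape[1]} non-reference timepoints "
                f"cannot contain {consecutive} consecutive hits")
        arr = nonref.to_numpy(dtype=float)
        hits = (np.abs(arr) >= threshold_log2) if two_sided else (arr >= threshold_log2)
        run = np.zeros(arr.shape[0], dtype=bool)
        for k in range(arr.shape[1] - consecutive + 1):
            run |= hits[:, k:k + consecutive].all(axis=1)
        rows.append(pd.DataFrame({
            "gene_id": nonref.index, "condition": cond, "fc_flag": run,
        }))
    return pd.concat(rows, ignore_index=True)


def call_kinetic_genes(fits: pd.DataFrame, flags: pd.DataFrame,
                       alpha: float = 0.05) -> tuple[pd.DataFrame, list[str]]:
    """Combine regression significance and the fold-change rule per condition.

    FDR (Benjamini-Hochberg) is applied to the regression p-values within
    each condition; a gene is kinetic in a condition if q < alpha OR its
    fold-change flag is set. Returns the per-gene-x-condition call table
    and the union set (genes kinetic in at least one condition, in input
    gene order).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    merged = fits.merge(flags, on=["gene_id", "condition"], how="inner",
                        validate="one_to_one")
    if len(merged) != len(fits):
        raise ValueError("fits and fold-change flags cover different genes/conditions")
    merged = merged.copy()
    merged["q_value"] = np.nan
    for _, idx in merged.groupby("condition", sort=False).groups.items():
        merged.loc[idx, "q_value"] = benjamini_hochberg(
            merged.loc[idx, "p_value"].to_numpy())
    merged["regression_significant"] = merged["q_value"] < alpha
    merged["kinetic"] = merged["regression_significant"] | merged["fc_flag"]
    gene_order = {g: i for i, g in enumerate(pd.unique(fits["gene_id"]))}
    union = sorted(
        set(merged.loc[merged["kinetic"], "gene_id"]), key=gene_order.get)
    cols = ["gene_id", "condition", "f_stat", "p_value", "q_value",
            "regression_significant", "fc_flag", "kinetic"]
    return merged[cols], union


# ---------------------------------------------------------------------------
# Temporal pattern clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Clustering of one condition's kinetic genes into temporal patterns."""

    condition: str
    labels: pd.Series  # gene_id -> cluster index (1..k)
    linkage: str
    k: int
    centroids: pd.DataFrame  # cluster index x timepoints (mean profile)
    archetypes: dict[int, str] = field(default_factory=dict)

    def archetype_of(self, gene: str) -> str:
        return self.archetypes[int(self.labels.loc[gene])]


def cluster_profiles(m: ExpressionMatrix, design: SampleDesign,
                     kinetic_set: list[str], condition: str, k: int = 3,
                     linkage: str = "complete") -> ClusterAssignment:
    """Agglomerative clustering of kinetic genes under correlation distance.

    The distance between two genes is 1 - Pearson r of their replicate-mean
    time profiles (shift- and scale-invariant), the dendrogram is cut at
    exactly ``k`` clusters. Genes with constant profiles (undefined
    correlation) are held out and assigned to the nearest centroid by
    Euclidean distance afterwards.
    """
    if len(kinetic_set) < k:
        raise ValueError(f"{len(kinetic_set)} genes cannot form {k} clusters")
    profiles = replicate_mean_profiles(m.subset_genes(kinetic_set), design, condition)
    arr = profiles.to_numpy(dtype=float)
    constant = arr.std(axis=1) <= 1e-12
    active = np.flatnonzero(~constant)
    if active.size < k:
        raise ValueError("too few non-constant profiles to cluster")
    dist = pdist(arr[active], metric="correlation")
    Z = scipy_linkage(dist, method=linkage)
    idx = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(index=profiles.index, dtype=int, name="cluster")
    labels.iloc[active] = idx
    centroids = pd.DataFrame(
        {c: arr[active][idx == c].mean(axis=0) for c in np.unique(idx)},
        index=profiles.columns).T
    if constant.any():
        # deterministic fallback: nearest centroid in Euclidean distance
        d = cdist(arr[constant], centroids.to_numpy())
        labels.iloc[np.flatnonzero(constant)] = centroids.index.to_numpy()[
            d.argmin(axis=1)]
    labels = labels.astype(int)
    ca = ClusterAssignment(condition, labels, linkage, k, centroids)
    return assign_archetype_labels(ca)


def _centroid_features(profile: np.ndarray) -> tuple[float, float]:
    net = float(profile[-1] - profile[0])
    prominence = float(profile.max() - max(profile[0], profile[-1]))
    return net, prominence


def assign_archetype_labels(ca: ClusterAssignment) -> ClusterAssignment:
    """Label cluster centroids as C1/C2/C3 from their shape features.

    Net change (final - initial) below zero marks stable downregulation
    (C3); otherwise a dominant peak prominence (max above both endpoints)
    marks the fast transient pattern (C1) and the remainder the delayed
    stable rise (C2). With k=3 duplicate labels are resolved by keeping the
    stronger exemplar (larger |net change|, or larger prominence for C1)
    and relabelling the weaker cluster with the unused archetype.
    """
    feats = {c: _centroid_features(ca.centroids.loc[c].to_numpy())
             for c in ca.centroids.index}
    labels = {}
    for c, (net, prom) in feats.items():
        if net < 0:
            labels[c] = "C3"
        elif prom > net:
            labels[c] = "C1"
        else:
            labels[c] = "C2"
    if ca.k == 3 and len(set(labels.values())) < 3:
        strength = {"C1": lambda c: feats[c][1],
                    "C2": lambda c: feats[c][0],
                    "C3": lambda c: -feats[c][0]}
        missing = [a for a in ("C1", "C2", "C3") if a not in labels.values()]
        for arch in ("C1", "C2", "C3"):
            holders = [c for c, a in labels.items() if a == arch]
            while len(holders) > 1 and missing:
                holders.sort(key=strength[arch], reverse=True)
                weakest = holders.pop()
                labels[weakest] = missing.pop(0)
    ca.archetypes = labels
    return ca


def detect_cluster_switches(calls_a: pd.DataFrame, ca_a: ClusterAssignment,
                            calls_b: pd.DataFrame, ca_b: ClusterAssignment
                            ) -> pd.DataFrame:
    """Compare archetype labels of kinetic genes between two conditions.

    A *switch* is a gene kinetic in both conditions whose cluster archetype
    labels differ; genes kinetic in only one condition are reported with
    status ``only_<condition>`` and are never counted as switches.
    """
    kin_a = set(calls_a.loc[calls_a["kinetic"], "gene_id"])
    kin_b = set(calls_b.loc[calls_b["kinetic"], "gene_id"])
    rows = []
    for gene in sorted(kin_a | kin_b):
        in_a, in_b = gene in kin_a, gene in kin_b
        lab_a = ca_a.archetype_of(gene) if in_a and gene in ca_a.labels.index else ""
        lab_b = ca_b.archetype_of(gene) if in_b and gene in ca_b.labels.index else ""
        if in_a and in_b:
            status = "switch" if (lab_a and lab_b and lab_a != lab_b) else "stable"
        else:
            status = f"only_{ca_a.condition if in_a else ca_b.condition}"
        rows.append({
            "gene_id": gene,
            f"label_{ca_a.condition}": lab_a,
            f"label_{ca_b.condition}": lab_b,
            "status": status,
            "switch": status == "switch",
        })
    return pd.DataFrame(rows)
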