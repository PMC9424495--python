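"""Containers and text-format I/O for expression time-courses and gene sets.

The in-memory containers are thin, validated wrappers around pandas objects:

* :class:`ExpressionMatrix` — genes x samples log2-intensity matrix,
* :class:`SampleDesign` — sample -> (condition, time, replicate) annotation,
* :class:`GeneSetCollection` — named gene sets read from GMT files,
* :class:`ProbeMap` — many-to-one probe -> gene symbol map.

All readers consume plain tab-separated text; all writers emit the same
formats so that read/write round-trips are identity at the declared
precision. Shared statistical utilities (Benjamini-Hochberg FDR) live here
because every downstream analysis module uses them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SampleDesign",
    "GeneSetCollection",
    "ProbeMap",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_design",
    "read_gmt",
    "collapse_probes_to_genes",
    "benjamini_hochberg",
    "write_result_table",
    "read_result_table",
]


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    counts = pd.Index(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ValidationError(
            f"duplicate {what}: {', '.join(map(str, dups.index[:10]))}"
            + (" ..." if len(dups) > 10 else "")
        )


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of expression values.

    Parameters
    ----------
    data:
        DataFrame indexed by gene (or probe) identifier with one column per
        sample. Values are log2 intensities unless ``log_scale`` is False.
    log_scale:
        Whether values are on the log2 scale. Normalisation and all
        downstream statistics require ``log_scale=True``.
    """

    data: pd.DataFrame
    log_scale: bool = True

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "gene IDs")
        _check_unique(list(self.data.columns), "sample IDs")
        if not np.issubdtype(np.asarray(self.data.values).dtype, np.number):
            raise ValidationError("expression values must be numeric")

    # -- accessors ---------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def has_missing(self) -> bool:
        return bool(self.data.isna().any().any())

    def require_complete(self, context: str = "analysis") -> None:
        if self.has_missing():
            n = int(self.data.isna().sum().sum())
            raise ValidationError(f"{n} missing values not allowed for {context}")

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = set(genes) - set(self.data.index)
        if missing:
            raise KeyError(f"genes absent from matrix: {sorted(missing)[:10]}")
        return ExpressionMatrix(self.data.loc[genes].copy(), log_scale=self.log_scale)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        missing = set(samples) - set(self.data.columns)
        if missing:
            raise KeyError(f"samples absent from matrix: {sorted(missing)[:10]}")
        return ExpressionMatrix(self.data[samples].copy(), log_scale=self.log_scale)


@dataclass
class SampleDesign:
    """Annotation of samples with condition, time (hours) and replicate.

    The table must contain the columns ``sample_id``, ``condition``,
    ``time_h`` and ``replicate``; each (condition, time_h, replicate) triple
    must be unique, and every condition needs at least four distinct
    timepoints so that the polynomial time regressions downstream are
    identifiable.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "condition", "time_h", "replicate")
    MIN_TIMEPOINTS = 4

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"design table missing column(s): {missing}")
        t = self.table
        if not np.issubdtype(t["time_h"].dtype, np.number):
            raise ValidationError("time_h must be numeric")
        if (t["time_h"] < 0).any():
            raise ValidationError("time_h must be non-negative")
        _check_unique(list(t["sample_id"]), "sample IDs in design")
        trip = t[["condition", "time_h", "replicate"]].apply(tuple, axis=1)
        _check_unique(list(trip), "(condition, time_h, replicate) triples")
        for cond, sub in t.groupby("condition"):
            if sub["time_h"].nunique() < self.MIN_TIMEPOINTS:
                raise ValidationError(
                    f"condition {cond!r} has {sub['time_h'].nunique()} distinct "
                    f"timepoints; at least {self.MIN_TIMEPOINTS} required"
                )

    @property
    def conditions(self) -> list[str]:
        return list(pd.unique(self.table["condition"]))

    def times(self, condition: str) -> np.ndarray:
        sub = self.table[self.table["condition"] == condition]
        return np.sort(sub["time_h"].unique())

    def samples_for(self, condition: str) -> pd.DataFrame:
        sub = self.table[self.table["condition"] == condition]
        if sub.empty:
            raise KeyError(f"condition {condition!r} not in design")
        return sub

    def validate_against(self, m: ExpressionMatrix) -> None:
        design_samples = set(self.table["sample_id"])
        matrix_samples = set(m.sample_ids)
        if design_samples != matrix_samples:
            only_d = sorted(design_samples - matrix_samples)[:5]
            only_m = sorted(matrix_samples - design_samples)[:5]
            raise ValidationError(
                f"design/matrix sample mismatch (design-only: {only_d}, "
                f"matrix-only: {only_m})"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets, e.g. pathways or transcription-factor targets."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def merged(self, other: "GeneSetCollection") -> "GeneSetCollection":
        """Pool two collections (e.g. several databases) into one."""
        overlap = set(self.sets) & set(other.sets)
        if overlap:
            raise ValidationError(f"duplicate set names when pooling: {sorted(overlap)[:5]}")
        label = " + ".join(x for x in (self.source_label, other.source_label) if x)
        return GeneSetCollection({**self.sets, **other.sets}, source_label=label)


@dataclass
class ProbeMap:
    """Many-to-one probe -> gene symbol mapping."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        for probe, gene in self.mapping.items():
            if not isinstance(gene, str) or not gene:
                raise ValidationError(f"probe {probe!r} maps to invalid gene {gene!r}")

    def __contains__(self, probe: str) -> bool:
        return probe in self.mapping

    def __getitem__(self, probe: str) -> str:
        return self.mapping[probe]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path, orientation: str = "genes_in_rows",
                           log_scale: bool = True) -> ExpressionMatrix:
    """Read a tab-separated expression matrix (genes in rows).

    The first column holds gene/probe identifiers, the header row holds
    sample identifiers. Ragged rows and non-numeric cells raise a parse
    error naming the offending line; duplicate gene IDs raise a validation
    error listing them.
    """
    if orientation != "genes_in_rows":
        raise ValueError(f"unsupported orientation {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: header must contain at least one sample column")
        sample_ids = header[1:]
        n_cols = len(header)
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_cols:
                raise ValueError(
                    f"{path}: line {lineno} has {len(parts)} fields, expected {n_cols}"
                )
            gene_ids.append(parts[0])
            vals = []
            for j, cell in enumerate(parts[1:], start=2):
                if cell in ("", "NA", "nan", "NaN"):
                    vals.append(np.nan)
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} at line {lineno}, column {j}"
                    ) from None
            rows.append(vals)
    data = pd.DataFrame(rows, index=gene_ids, columns=sample_ids, dtype=float)
    data.index.name = "gene_id"
    return ExpressionMatrix(data, log_scale=log_scale)


def write_expression_matrix(m: ExpressionMatrix, path, float_format: str = "%.6g") -> None:
    out = m.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format=float_format)


def read_sample_design(path) -> SampleDesign:
    """Read and validate a sample design TSV (sample_id, condition, time_h, replicate)."""
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    missing = [c for c in SampleDesign.REQUIRED if c not in table.columns]
    if missing:
        raise ValidationError(f"{path}: design table missing column(s): {missing}")
    try:
        table["time_h"] = pd.to_numeric(table["time_h"])
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non-numeric time_h value ({exc})") from None
    design = SampleDesign(table)
    logger.info(
        "design: %d samples, conditions=%s",
        len(table), {c: len(design.times(c)) for c in design.conditions},
    )
    return design


def read_gmt(path, source_label: str = "") -> GeneSetCollection:
    """Read gene sets in GMT format (name TAB description TAB member...).

    Duplicate members within a set are dropped with a warning; a line with
    fewer than three fields is a parse error.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            n_lines += 1
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(parts)} fields; GMT requires "
                    "name, description and at least one member"
                )
            name, desc = parts[0], parts[1]
            members = [g for g in parts[2:] if g]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                warnings.warn(
                    f"{path}: set {name!r} contains duplicate members; deduplicated"
                )
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r} at line {lineno}")
            sets[name] = (desc, unique)
    if n_lines == 0:
        warnings.warn(f"{path}: empty GMT file, returning empty collection")
    return GeneSetCollection(sets, source_label=source_label or str(path))


# ---------------------------------------------------------------------------
# Probe collapsing
# ---------------------------------------------------------------------------

def collapse_probes_to_genes(m: ExpressionMatrix, probe_map: ProbeMap,
                             rule: str = "max_mean") -> ExpressionMatrix:
    """Collapse a probe-level matrix to one row per gene symbol.

    rule="max_mean": the probe with the highest mean across all samples
    represents the gene (deterministic; ties broken by input order).
    rule="mean": gene row is the arithmetic mean of its probes' rows.
    Probes absent from the map are dropped (count logged).
    """
    if rule not in ("max_mean", "mean"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    mapped = [p for p in m.gene_ids if p in probe_map]
    n_dropped = len(m.gene_ids) - len(mapped)
    if n_dropped:
        logger.info("collapse_probes_to_genes: dropped %d unmapped probes", n_dropped)
    if not mapped:
        raise ValidationError("no probes map to any gene")
    sub = m.data.loc[mapped]
    genes = pd.Series([probe_map[p] for p in mapped], index=sub.index, name="gene")
    if rule == "mean":
        out = sub.groupby(genes, sort=False).mean()
    else:
        probe_means = sub.mean(axis=1)
        # stable arg-max per gene: first probe with the maximal mean
        best = probe_means.groupby(genes, sort=False).idxmax()
        out = sub.loc[best]
        out.index = pd.Index(best.index, name="gene_id")
    out.index.name = "gene_id"
    return ExpressionMatrix(out, log_scale=m.log_scale)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR q-values.

    q_(i) = min_{j >= i} (m * p_(j) / j) over the sorted p-values, mapped
    back to input order. All inputs must lie in [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# Result tables with provenance
# ---------------------------------------------------------------------------

def write_result_table(table: pd.DataFrame, path, *, step: str,
                       parameters: Mapping[str, object] | None = None,
                       seed: int | None = None,
                       float_format: str = "%.6g") -> None:
    """Write a per-gene result table as TSV with a commented provenance header."""
    if not step:
        raise ValueError("provenance step must be non-empty")
    with open(path, "w") as fh:
        fh.write(f"# step: {step}\n")
        for key, val in sorted((parameters or {}).items()):
            fh.write(f"# param {key}: {val}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        table.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
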