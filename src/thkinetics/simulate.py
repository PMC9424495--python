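"""Synthetic multi-condition time-course expression data with ground truth.

The generator emulates the structure of a dense in-vitro Th-cell
differentiation experiment: four polarizing conditions (Th0, Th1, Th2 and
the Th1/2 hybrid "Th12"), ten timepoints over 120 h with 3-h spacing at the
start, and two independent replicate experiments, on the log2 intensity
scale.

Genes are drawn from three kinetic archetypes plus a flat class:

* ``C1_transient_up`` — fast transient upregulation, a gamma-pulse
  ``A * (t/tau) * exp(1 - t/tau)`` peaking at ``t = tau``;
* ``C2_delayed_up``  — delayed stable upregulation, a logistic ramp
  anchored to zero at ``t = 0``;
* ``C3_down``        — stable downregulation, the negated logistic ramp;
* ``flat``           — no kinetic response.

Hybrid-condition genes follow one of four generating programs: an exact
copy of the Th1 curve, an exact copy of the Th2 curve, a convex
superposition ``w*Th1 + (1-w)*Th2``, or an independent curve whose Pearson
correlation to both the Th1 and Th2 mean curves is bounded (rejection
sampled). Every gene carries a complete ground-truth record so that each
analysis step can be scored against the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.special import expit

from .data_io import ExpressionMatrix, SampleDesign

__all__ = [
    "ArchetypeSpec",
    "SimulationConfig",
    "GroundTruth",
    "archetype_curve",
    "simulate_dataset",
    "simulate_null_dataset",
    "DEFAULT_TIME_GRID",
]

#: Ten timepoints over 120 h with the first three in 3-h intervals.
DEFAULT_TIME_GRID: tuple[float, ...] = (0, 3, 6, 12, 24, 36, 48, 72, 96, 120)

ARCHETYPES = ("C1_transient_up", "C2_delayed_up", "C3_down", "flat")
HYBRID_CATEGORIES = ("Th1_like", "Th2_like", "Superposition", "Independent")


@dataclass(frozen=True)
class ArchetypeSpec:
    """Parametric description of one temporal archetype.

    amplitude is in log2 units (peak height for C1, asymptotic change for
    C2/C3, always stated positive — the sign of C3 is applied internally);
    tau is the C1 peak time in hours; t0 and s are the logistic midpoint
    and slope scale (hours) for C2/C3.
    """

    archetype: str
    amplitude: float = 2.0
    tau: float = 6.0
    t0: float = 24.0
    s: float = 8.0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.archetype != "flat" and self.amplitude <= 0:
            raise ValueError("amplitude must be positive (sign is applied internally)")
        if self.tau <= 0 or self.s <= 0:
            raise ValueError("timescale parameters tau and s must be positive")


def archetype_curve(spec: ArchetypeSpec, t: np.ndarray) -> np.ndarray:
    """Mean log2 offset (relative to baseline) of one archetype over time.

    All curves are exactly zero at ``t = 0`` so that the baseline is the
    t=0 expression level.
    """
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("time vector must be non-negative")
    if np.any(np.diff(t) < 0):
        raise ValueError("time vector must be ascending")
    a = spec.amplitude
    if spec.archetype == "flat":
        return np.zeros_like(t)
    if spec.archetype == "C1_transient_up":
        return a * (t / spec.tau) * np.exp(1.0 - t / spec.tau)
    # logistic ramp anchored at zero for t=0
    ramp = expit((t - spec.t0) / spec.s) - expit((0.0 - spec.t0) / spec.s)
    if spec.archetype == "C2_delayed_up":
        return a * ramp
    return -a * ramp  # C3_down


@dataclass
class SimulationConfig:
    """Configuration of one synthetic dataset.

    Defaults mirror the study design the analysis assumes: 4 conditions x
    10 timepoints x 2 replicates, homoscedastic Gaussian noise of 0.25 log2
    units, and a hybrid condition built from the Th1/Th2 programs.
    """

    times: tuple[float, ...] = DEFAULT_TIME_GRID
    conditions: tuple[str, ...] = ("Th0", "Th1", "Th2", "Th12")
    hybrid_condition: str = "Th12"
    replicates: int = 2
    n_flat: int = 1400
    #: genes with one shared archetype curve in every condition
    n_shared_per_archetype: Mapping[str, int] = field(
        default_factory=lambda: {"C1_transient_up": 100, "C2_delayed_up": 100,
                                 "C3_down": 100})
    #: genes with distinct Th1/Th2 programs, hybrid built per category
    n_hybrid_per_category: Mapping[str, int] = field(
        default_factory=lambda: {"Th1_like": 0, "Th2_like": 0,
                                 "Superposition": 0, "Independent": 0})
    noise_sigma: float = 0.25
    baseline: float = 7.0
    baseline_sd: float = 0.75
    superposition_weight: float = 0.5
    independence_r_max: float = 0.3
    #: Th1-vs-Th2 dissimilarity for hybrid genes (signed Pearson r below this)
    pair_r_max: float = 0.5
    max_retries: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n_flat < 0 or any(v < 0 for v in self.n_shared_per_archetype.values()) \
                or any(v < 0 for v in self.n_hybrid_per_category.values()):
            raise ValueError("gene counts must be >= 0")
        if not 0 < self.superposition_weight < 1:
            raise ValueError("superposition_weight must lie in (0, 1)")
        if self.hybrid_condition not in self.conditions:
            raise ValueError(
                f"hybrid condition {self.hybrid_condition!r} not among conditions")
        unknown = set(self.n_hybrid_per_category) - set(HYBRID_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown hybrid categories: {sorted(unknown)}")

    @property
    def n_genes(self) -> int:
        return (self.n_flat + sum(self.n_shared_per_archetype.values())
                + sum(self.n_hybrid_per_category.values()))


@dataclass
class GroundTruth:
    """Per-gene generating truth for a simulated dataset.

    ``table`` has one row per gene with the gene class, per-condition
    archetype and kinetic flag (columns ``archetype_<cond>`` /
    ``kinetic_<cond>``), the hybrid category (empty string for non-hybrid
    genes) and the generating parameters.
    """

    table: pd.DataFrame
    config: SimulationConfig

    def kinetic_genes(self, condition: str) -> list[str]:
        col = f"kinetic_{condition}"
        return list(self.table.loc[self.table[col], "gene_id"])

    def genes_in_class(self, gene_class: str) -> list[str]:
        return list(self.table.loc[self.table["gene_class"] == gene_class, "gene_id"])

    def hybrid_genes(self) -> pd.DataFrame:
        return self.table[self.table["hybrid_category"] != ""]

    def class_counts(self) -> pd.Series:
        return self.table["gene_class"].value_counts()


# ---------------------------------------------------------------------------
# internal draws
# ---------------------------------------------------------------------------

def _random_spec(rng: np.random.Generator, archetype: str) -> ArchetypeSpec:
    """Randomised but realistic parameters for one archetype curve."""
    amplitude = float(rng.uniform(1.5, 3.5))
    if archetype == "C1_transient_up":
        return ArchetypeSpec(archetype, amplitude, tau=float(rng.uniform(4.0, 12.0)))
    return ArchetypeSpec(archetype, amplitude,
                         t0=float(rng.uniform(12.0, 48.0)),
                         s=float(rng.uniform(4.0, 12.0)))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return 1.0  # constant curves count as maximally correlated
    return float(np.corrcoef(a, b)[0, 1])


def _draw_distinct_pair(rng: np.random.Generator, t: np.ndarray, r_max: float,
                        max_retries: int) -> tuple[ArchetypeSpec, ArchetypeSpec]:
    """Two archetype curves with dissimilar trends (Th1 vs Th2 program).

    Accepted when the signed Pearson r is below ``r_max`` — anticorrelated
    trends are maximally dissimilar and belong in this class — while
    near-perfect anticollinearity (r < -0.95, e.g. a ramp against its own
    negation) is excluded so the two programs stay separately identifiable.
    """
    shapes = [a for a in ARCHETYPES if a != "flat"]
    for _ in range(max_retries):
        a1, a2 = rng.choice(shapes, size=2, replace=False)
        s1, s2 = _random_spec(rng, a1), _random_spec(rng, a2)
        r = _pearson(archetype_curve(s1, t), archetype_curve(s2, t))
        if -0.95 < r < r_max:
            return s1, s2
    raise RuntimeError(
        f"could not draw Th1/Th2 curve pair with r < {r_max} in "
        f"{max_retries} tries; loosen pair_r_max")


def _draw_independent(rng: np.random.Generator, t: np.ndarray,
                      c1: np.ndarray, c2: np.ndarray, r_max: float,
                      max_retries: int, amplitude: float) -> np.ndarray:
    """An 'independent program' curve decorrelated from both lineage curves.

    Candidates are smooth random trajectories — a natural cubic spline
    through Gaussian control values at a coarse knot grid, anchored at
    zero for t=0 and scaled to the requested peak amplitude. A candidate
    is accepted only if its |Pearson r| to both the Th1 and Th2 mean
    curves is below the bound. (The single-archetype family is too
    low-dimensional on a 10-point grid to ever satisfy a tight bound
    against two archetype curves simultaneously.)
    """
    knots = np.linspace(0.0, t[-1], 5) if t[-1] > 0 else np.arange(5.0)
    for _ in range(max_retries):
        vals = np.concatenate([[0.0], rng.normal(0.0, 1.0, knots.size - 1)])
        curve = CubicSpline(knots, vals)(t)
        peak = np.abs(curve).max()
        if peak <= 0:
            continue
        curve = amplitude * curve / peak
        if abs(_pearson(curve, c1)) < r_max and abs(_pearson(curve, c2)) < r_max:
            return curve
    raise RuntimeError(
        f"could not draw an independent curve with |r| < {r_max} to both "
        f"lineage curves in {max_retries} tries; loosen independence_r_max")


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _build_design(cfg: SimulationConfig) -> SampleDesign:
    rows = [
        {"sample_id": f"{cond}_t{time:g}_r{rep}", "condition": cond,
         "time_h": float(time), "replicate": rep}
        for cond in cfg.conditions
        for time in cfg.times
        for rep in range(1, cfg.replicates + 1)
    ]
    return SampleDesign(pd.DataFrame(rows))


def simulate_dataset(cfg: SimulationConfig
                     ) -> tuple[ExpressionMatrix, SampleDesign, GroundTruth]:
    """Generate one complete synthetic dataset with ground truth.

    Every sample value is ``gene baseline + condition-specific archetype
    curve(t) + N(0, sigma)``; at ``sigma = 0`` the matrix is an exact,
    seed-reproducible function of the configuration.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.times, dtype=float)
    design = _build_design(cfg)
    non_hybrid = [c for c in cfg.conditions if c != cfg.hybrid_condition]

    gene_rows: list[dict] = []
    curves: list[dict[str, np.ndarray]] = []  # per gene: condition -> mean offset
    zero = np.zeros_like(t)

    def add_gene(gene_class: str, cond_curves: dict[str, np.ndarray],
                 cond_arch: dict[str, str], hybrid_category: str = "",
                 params: str = "") -> None:
        gid = f"g{len(gene_rows):05d}"
        row = {"gene_id": gid, "gene_class": gene_class,
               "hybrid_category": hybrid_category, "params": params}
        for cond in cfg.conditions:
            curve = cond_curves.get(cond, zero)
            row[f"archetype_{cond}"] = cond_arch.get(cond, "flat")
            row[f"kinetic_{cond}"] = bool(np.ptp(curve) > 0)
        gene_rows.append(row)
        curves.append(cond_curves)

    # flat genes
    for _ in range(cfg.n_flat):
        add_gene("flat", {}, {})

    # shared-response kinetic genes: one curve in every condition
    for arch, count in cfg.n_shared_per_archetype.items():
        for _ in range(count):
            spec = _random_spec(rng, arch)
            curve = archetype_curve(spec, t)
            add_gene(f"kinetic_{_short(arch)}",
                     {c: curve for c in cfg.conditions},
                     {c: _short(arch) for c in cfg.conditions},
                     params=_fmt(spec))

    # hybrid-program genes: distinct Th1/Th2 curves, hybrid per category
    for category in HYBRID_CATEGORIES:
        for _ in range(cfg.n_hybrid_per_category.get(category, 0)):
            s1, s2 = _draw_distinct_pair(rng, t, cfg.pair_r_max, cfg.max_retries)
            c1, c2 = archetype_curve(s1, t), archetype_curve(s2, t)
            cond_curves = {"Th1": c1, "Th2": c2}
            cond_arch = {"Th1": _short(s1.archetype), "Th2": _short(s2.archetype)}
            params = f"Th1={_fmt(s1)};Th2={_fmt(s2)}"
            if category == "Th1_like":
                cond_curves[cfg.hybrid_condition] = c1
                cond_arch[cfg.hybrid_condition] = cond_arch["Th1"]
            elif category == "Th2_like":
                cond_curves[cfg.hybrid_condition] = c2
                cond_arch[cfg.hybrid_condition] = cond_arch["Th2"]
            elif category == "Superposition":
                w = cfg.superposition_weight
                cond_curves[cfg.hybrid_condition] = w * c1 + (1.0 - w) * c2
                cond_arch[cfg.hybrid_condition] = "mix"
                params += f";w={w:g}"
            else:  # Independent
                amp = float(rng.uniform(1.5, 3.5))
                curve_i = _draw_independent(
                    rng, t, c1, c2, cfg.independence_r_max, cfg.max_retries,
                    amplitude=amp)
                cond_curves[cfg.hybrid_condition] = curve_i
                cond_arch[cfg.hybrid_condition] = "independent"
                params += f";ind=spline(A={amp:.2f})"
            add_gene(f"hybrid_{category}", cond_curves, cond_arch,
                     hybrid_category=category, params=params)

    truth = pd.DataFrame(gene_rows)
    n_genes = len(truth)
    baselines = cfg.baseline + cfg.baseline_sd * rng.standard_normal(n_genes)
    truth["baseline"] = baselines

    sample_ids = list(design.table["sample_id"])
    time_idx = {time: i for i, time in enumerate(t)}
    values = np.empty((n_genes, len(sample_ids)))
    mean_by_cond = {
        cond: np.stack([curves[g].get(cond, zero) for g in range(n_genes)])
        for cond in cfg.conditions
    }  # (genes x timepoints) per condition
    for j, (_, srow) in enumerate(design.table.iterrows()):
        cond, time = srow["condition"], srow["time_h"]
        values[:, j] = baselines + mean_by_cond[cond][:, time_idx[time]]
    if cfg.noise_sigma > 0:
        values = values + cfg.noise_sigma * rng.standard_normal(values.shape)

    data = pd.DataFrame(values, index=list(truth["gene_id"]), columns=sample_ids)
    data.index.name = "gene_id"
    matrix = ExpressionMatrix(data, log_scale=True)
    return matrix, design, GroundTruth(truth, cfg)


def simulate_null_dataset(cfg: SimulationConfig
                          ) -> tuple[ExpressionMatrix, SampleDesign, GroundTruth]:
    """All-flat dataset: pure noise around gene baselines, no kinetic genes.

    Total gene count equals ``cfg.n_genes``; every kinetic ground-truth
    flag is False. Used for type-I-error calibration of the kinetic and
    group-model F-tests.
    """
    null_cfg = replace(cfg,
                       n_flat=cfg.n_genes,
                       n_shared_per_archetype={},
                       n_hybrid_per_category={})
    return simulate_dataset(null_cfg)


def _short(archetype: str) -> str:
    return {"C1_transient_up": "C1", "C2_delayed_up": "C2",
            "C3_down": "C3", "flat": "flat"}[archetype]


def _fmt(spec: ArchetypeSpec) -> str:
    if spec.archetype == "C1_transient_up":
        return f"{_short(spec.archetype)}(A={spec.amplitude:.2f},tau={spec.tau:.1f})"
    return (f"{_short(spec.archetype)}(A={spec.amplitude:.2f},"
            f"t0={spec.t0:.1f},s={spec.s:.1f})")
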