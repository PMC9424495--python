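# thkinetics

Kinetic transcriptomics of T helper (Th) cell differentiation: a tested,
reusable implementation of a time-course expression workflow that detects
kinetic genes, classifies their temporal patterns, separates quantitative
from qualitative differential kinetics with a correlation-index filter,
and decomposes a hybrid lineage's transcriptome into the contributions of
the two canonical lineages.

## The problem

During the first days after antigen stimulation, CD4+ T cells differentiate
into effector lineages — Th1 (T-bet, IFN-γ), Th2 (GATA-3, IL-4) — and also
into stable hybrid phenotypes (Th1/2) that co-express both master
regulators. Dense time-course expression data (here: 4 conditions × 10
timepoints over 120 h × 2 replicates, log2 intensities) make it possible to
ask *when* the lineages bifurcate, *which* genes change and in what
temporal pattern, and whether each gene of the hybrid lineage follows the
Th1 program, the Th2 program, a mixture of both, or an independent program
of its own. The package is aimed at computational immunologists and anyone
analysing multi-condition expression time courses with replicated dense
sampling.

## The statistics at the core

**Kinetic genes.** Per condition, expression is regressed on a polynomial
in time; the F-test against the intercept-only model (BH-FDR < 0.05 within
the condition) is OR-ed with a fold-change rescue rule (|log2 FC vs t=0| ≥ 1
at ≥ 2 consecutive timepoints). Kinetic genes are clustered under the
correlation distance 1 − r and the cluster centroids are labelled by shape:
C1 fast transient up, C2 delayed stable up, C3 stable down.

**Differential kinetics.** With conditions g and shared time polynomial
x(t), the full model per gene is

    y = β₀ + Σ_d β_d t^d + Σ_{g≠ref} ( γ_g + Σ_d δ_{g,d} t^d ) 1[condition=g] + ε

A nested F-test against the time-only model finds genes with any condition
effect; a joint F-test on the coefficients distinguishing a pair yields
**quantitative DEG**, and those with correlation index 1 − r > 0.3 between
the pair's time profiles are **qualitative DEG** (dissimilar trends, not
level shifts). The categories nest: qualitative ⊆ quantitative ⊆ kinetic.

**Hybrid decomposition.** For each Th1-vs-Th2 qualitative DEG, the hybrid
profile is fit without intercept on mean-centred lineage profiles:

    Y_hyb(t) = β_Th1 · Y_Th1(t) + β_Th2 · Y_Th2(t) + ε

The significance pattern of (β_Th1, β_Th2) classifies the gene as
*Th1-like*, *Th2-like*, *Superposition* (both positive and significant) or
*Independent* (neither) — the four-way split that quantifies how much of a
hybrid phenotype is a mixture of the canonical programs.

A synthetic-data generator with exact per-gene ground truth (archetypes,
kinetic flags, hybrid categories) backs every recovery claim; see
`docs/methods.md` for models, defaults and limitations.

## Worked example

`examples/04_hybrid_decomposition.py` simulates 200 hybrid-program genes
(60/60/40/40 across the four categories, noise σ = 0.25 log2 units) and
decomposes the hybrid condition:

```
category fractions over the analysed genes:
     category  count  fraction
     Th1_like     57     0.285
     Th2_like     62     0.310
Superposition     41     0.205
  Independent     40     0.200

agreement with generating truth: 95.0%
```

The fractions recover the generated 30/30/20/20% split; "agreement" scores
each gene's assigned category against the program that generated it. The
other scripts in `examples/` walk through simulation, kinetic-gene calling
and clustering, differential kinetics, enrichment, and the PCA/bifurcation
analysis — e.g. `examples/06_explore_bifurcation.py` ends with the quadrant
co-expression computation:

```
IL-4+ within IFN-g+ cells: 41% vs marginal IL-4+ frequency 32.2% -> synergy: True
```

i.e. among IFN-γ-producing hybrid cells, IL-4 producers are *more* frequent
(41%) than in the population at large (32.2%), the signature of synergistic
co-expression.

A command-line layer mirrors the library:
`thkinetics simulate | preprocess | kinetics | deg | hybrid | enrich |
explore | run-all` (see `--help` for flags); `run-all` executes the whole
pipeline from one YAML config and writes a manifest with SHA-256 digests so
reruns are verifiably byte-identical.

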