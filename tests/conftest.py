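"""Shared fixtures: tiny hand-built matrices and seeded simulated datasets."""

import numpy as np
import pandas as pd
import pytest

import thkinetics as tk


def make_design(conditions, times, replicates=1):
    rows = [
        {"sample_id": f"{c}_t{t:g}_r{r}", "condition": c, "time_h": float(t),
         "replicate": r}
        for c in conditions for t in times for r in range(1, replicates + 1)
    ]
    return tk.SampleDesign(pd.DataFrame(rows))


def make_matrix(profiles, design):
    """ExpressionMatrix from {gene: {condition: curve over times}} + design."""
    data = {}
    for _, row in design.table.iterrows():
        col = []
        times = sorted(design.table["time_h"].unique())
        t_idx = times.index(row["time_h"])
        for gene, per_cond in profiles.items():
            col.append(per_cond[row["condition"]][t_idx])
        data[row["sample_id"]] = col
    df = pd.DataFrame(data, index=list(profiles))
    df.index.name = "gene_id"
    return tk.ExpressionMatrix(df)


@pytest.fixture(scope="session")
def small_dataset():
    """300 flat + 90 shared-archetype + 80 hybrid genes at sigma=0.25."""
    cfg = tk.SimulationConfig(
        n_flat=300,
        n_shared_per_archetype={"C1_transient_up": 30, "C2_delayed_up": 30,
                                "C3_down": 30},
        n_hybrid_per_category={"Th1_like": 20, "Th2_like": 20,
                               "Superposition": 20, "Independent": 20},
        seed=101)
    return tk.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_dataset():
    cfg = tk.SimulationConfig(
        n_flat=50,
        n_shared_per_archetype={"C1_transient_up": 20, "C2_delayed_up": 20,
                                "C3_down": 20},
        n_hybrid_per_category={"Th1_like": 10, "Th2_like": 10,
                               "Superposition": 10, "Independent": 10},
        noise_sigma=0.0, seed=7)
    return tk.simulate_dataset(cfg)


@pytest.fixture()
def toy_two_condition():
    """Two conditions, four timepoints, hand-readable profiles."""
    design = make_design(["A", "B"], [0, 1, 2, 3])
    profiles = {
        "rising": {"A": [0, 1, 2, 3], "B": [0, 1, 0, 1]},
        "flat": {"A": [5, 5, 5, 5], "B": [5, 5, 5, 5]},
    }
    return make_matrix(profiles, design), design
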