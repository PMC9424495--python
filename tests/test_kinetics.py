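"""Kinetic-gene calls: regression F-test, fold-change rule, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest
from sklearn.metrics import adjusted_rand_score

import thkinetics as tk
from thkinetics import kinetics as kin
from thkinetics import preprocess as pp
from tests.conftest import make_design, make_matrix


GRID = np.array(tk.DEFAULT_TIME_GRID, dtype=float)


class TestFitTimePolynomial:
    def test_constant_profile_explains_nothing(self):
        fit = kin.fit_time_polynomial(GRID, np.full(10, 7.0))
        assert fit.f_stat == 0.0
        assert fit.p_value == 1.0

    def test_exact_polynomial_has_zero_residual(self):
        y = 1.0 + 0.5 * GRID - 0.01 * GRID ** 2 + 1e-4 * GRID ** 3
        fit = kin.fit_time_polynomial(GRID, y, degree=3)
        assert fit.rss == pytest.approx(0.0, abs=1e-8)
        assert fit.p_value == 0.0

    def test_insufficient_dof_rejected(self):
        with pytest.raises(ValueError, match="gene 'g'"):
            kin.fit_time_polynomial(np.arange(4.0), np.arange(4.0), degree=3,
                                    gene="g")

    def test_null_pvalues_uniform(self):
        cfg = tk.SimulationConfig(n_flat=2000, seed=17,
                                  n_shared_per_archetype={},
                                  n_hybrid_per_category={})
        m, design, _ = tk.simulate_null_dataset(cfg)
        fits = kin.fit_condition_polynomials(m, design, "Th1")
        stat = kstest(fits["p_value"], "uniform")
        assert stat.pvalue > 0.01

    def test_batch_matches_single_gene_fit(self, small_dataset):
        m, design, _ = small_dataset
        batch = kin.fit_condition_polynomials(m, design, "Th2")
        sub = design.samples_for("Th2")
        for gene in m.gene_ids[:5]:
            single = kin.fit_time_polynomial(
                sub["time_h"].to_numpy(),
                m.data.loc[gene, list(sub["sample_id"])].to_numpy())
            row = batch[batch["gene_id"] == gene].iloc[0]
            assert row["f_stat"] == pytest.approx(single.f_stat, rel=1e-9)
            assert row["p_value"] == pytest.approx(single.p_value, rel=1e-9)


def _fc_frame(values, condition="A"):
    times = np.arange(len(values), dtype=float)
    return pd.DataFrame({"gene_id": "g", "condition": condition,
                         "time_h": times, "log2_fc": values})


class TestFoldchangeRule:
    @pytest.mark.parametrize("fc, expected", [
        ([0, 1.2, 1.1, 0.2, 0, 0], True),       # two consecutive >= 1
        ([0, 1.2, 0.4, 1.3, 0.1, 0], False),    # never consecutive
        ([0, -1.1, -1.4, 0, 0, 0], True),       # two-sided: downregulation
    ])
    def test_rule_cases(self, fc, expected):
        out = kin.foldchange_rule(_fc_frame(fc))
        assert bool(out["fc_flag"].iloc[0]) is expected

    def test_one_sided_ignores_downregulation(self):
        out = kin.foldchange_rule(_fc_frame([0, -1.1, -1.4, 0, 0, 0]),
                                  two_sided=False)
        assert not out["fc_flag"].iloc[0]

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError, match="consecutive"):
            kin.foldchange_rule(_fc_frame([0, 1.0]), consecutive=2)


class TestCallKineticGenes:
    @pytest.fixture()
    def toy_calls(self):
        fits = pd.DataFrame({
            "gene_id": ["reg_only", "fc_only", "neither"],
            "condition": "A",
            "f_stat": [50.0, 1.0, 1.0],
            "p_value": [1e-9, 0.5, 0.6]})
        flags = pd.DataFrame({
            "gene_id": ["reg_only", "fc_only", "neither"],
            "condition": "A",
            "fc_flag": [False, True, False]})
        return fits, flags

    def test_or_semantics(self, toy_calls):
        calls, union = kin.call_kinetic_genes(*toy_calls)
        by_gene = calls.set_index("gene_id")["kinetic"]
        assert by_gene["reg_only"] and by_gene["fc_only"]
        assert not by_gene["neither"]
        assert union == ["reg_only", "fc_only"]

    def test_alpha_monotonicity(self, small_dataset):
        m, design, _ = small_dataset
        fits = kin.fit_condition_polynomials(m, design, "Th1")
        flags = kin.foldchange_rule(
            pp.log2_fold_change(m, design)).query("condition == 'Th1'")
        _, union_strict = kin.call_kinetic_genes(fits, flags, alpha=0.01)
        _, union_loose = kin.call_kinetic_genes(fits, flags, alpha=0.05)
        assert set(union_strict) <= set(union_loose)

    def test_recovery_on_archetype_genes(self):
        cfg = tk.SimulationConfig(
            n_flat=1700, seed=3,
            n_shared_per_archetype={"C1_transient_up": 100,
                                    "C2_delayed_up": 100, "C3_down": 100},
            n_hybrid_per_category={})
        m, design, truth = tk.simulate_dataset(cfg)
        fits = pd.concat([kin.fit_condition_polynomials(m, design, c)
                          for c in design.conditions], ignore_index=True)
        flags = kin.foldchange_rule(pp.log2_fold_change(m, design))
        calls, union = kin.call_kinetic_genes(fits, flags)
        kinetic_truth = set(truth.kinetic_genes("Th1"))
        sens = len(set(union) & kinetic_truth) / len(kinetic_truth)
        assert sens >= 0.95
        # FDR on the per-condition call table, the family BH controls
        long_truth = truth.table.melt(
            id_vars="gene_id",
            value_vars=[f"kinetic_{c}" for c in design.conditions],
            var_name="cond", value_name="true_kinetic")
        long_truth["condition"] = long_truth["cond"].str.replace("kinetic_", "")
        merged = calls.merge(long_truth[["gene_id", "condition", "true_kinetic"]],
                             on=["gene_id", "condition"])
        called = merged[merged["kinetic"]]
        assert (~called["true_kinetic"]).mean() <= 0.10


class TestClustering:
    def test_noiseless_partition_matches_archetypes(self, noiseless_dataset):
        m, design, truth = noiseless_dataset
        genes = [g for arch in ("C1", "C2", "C3")
                 for g in truth.genes_in_class(f"kinetic_{arch}")]
        ca = kin.cluster_profiles(m, design, genes, "Th1", k=3)
        pred = [ca.archetype_of(g) for g in genes]
        true = list(truth.table.set_index("gene_id").loc[genes, "archetype_Th1"])
        assert adjusted_rand_score(true, pred) == 1.0

    def test_noisy_recovery_across_seeds(self):
        aris = []
        for seed in range(20):
            cfg = tk.SimulationConfig(
                n_flat=0, seed=seed,
                n_shared_per_archetype={"C1_transient_up": 20,
                                        "C2_delayed_up": 20, "C3_down": 20},
                n_hybrid_per_category={})
            m, design, truth = tk.simulate_dataset(cfg)
            ca = kin.cluster_profiles(m, design, m.gene_ids, "Th1", k=3)
            pred = [ca.archetype_of(g) for g in m.gene_ids]
            aris.append(adjusted_rand_score(
                list(truth.table["archetype_Th1"]), pred))
        assert np.mean(aris) >= 0.8

    def test_k_larger_than_gene_count_rejected(self, noiseless_dataset):
        m, design, _ = noiseless_dataset
        with pytest.raises(ValueError):
            kin.cluster_profiles(m, design, m.gene_ids[:2], "Th1", k=3)

    def test_invariant_to_gene_order_and_constant_shift(self):
        cfg = tk.SimulationConfig(
            n_flat=0, seed=9,
            n_shared_per_archetype={"C1_transient_up": 15,
                                    "C2_delayed_up": 15, "C3_down": 15},
            n_hybrid_per_category={})
        m, design, _ = tk.simulate_dataset(cfg)
        ca1 = kin.cluster_profiles(m, design, m.gene_ids, "Th1", k=3)
        reordered = list(reversed(m.gene_ids))
        ca2 = kin.cluster_profiles(m, design, reordered, "Th1", k=3)
        shifted = tk.ExpressionMatrix(m.data + 5.0)
        ca3 = kin.cluster_profiles(shifted, design, m.gene_ids, "Th1", k=3)
        for g in m.gene_ids:
            assert ca1.archetype_of(g) == ca2.archetype_of(g)
            assert ca1.archetype_of(g) == ca3.archetype_of(g)


class TestArchetypeLabels:
    @pytest.mark.parametrize("archetype, expected", [
        ("C1_transient_up", "C1"),
        ("C2_delayed_up", "C2"),
        ("C3_down", "C3"),
    ])
    def test_canonical_curves_labelled(self, archetype, expected):
        curve = tk.archetype_curve(tk.ArchetypeSpec(archetype, 2.0, tau=6.0),
                                   GRID)
        centroids = pd.DataFrame([curve], index=[1], columns=GRID)
        ca = kin.ClusterAssignment("Th1", pd.Series({"g": 1}), "complete", 1,
                                   centroids)
        assert kin.assign_archetype_labels(ca).archetypes[1] == expected


class TestClusterSwitches:
    def _assignment(self, cond, labels):
        centroids = pd.DataFrame(np.zeros((3, len(GRID))), index=[1, 2, 3],
                                 columns=GRID)
        ca = kin.ClusterAssignment(cond, pd.Series(labels), "complete", 3,
                                   centroids)
        ca.archetypes = {1: "C1", 2: "C2", 3: "C3"}
        return ca

    def _calls(self, cond, genes):
        return pd.DataFrame({"gene_id": genes, "condition": cond,
                             "kinetic": True})

    def test_switch_stable_and_condition_specific(self):
        ca_a = self._assignment("Th1", {"g_switch": 1, "g_stable": 2,
                                        "g_only_a": 3})
        ca_b = self._assignment("Th2", {"g_switch": 3, "g_stable": 2})
        out = kin.detect_cluster_switches(
            self._calls("Th1", ["g_switch", "g_stable", "g_only_a"]), ca_a,
            self._calls("Th2", ["g_switch", "g_stable"]), ca_b)
        by_gene = out.set_index("gene_id")
        assert by_gene.loc["g_switch", "status"] == "switch"
        assert by_gene.loc["g_stable", "status"] == "stable"
        assert by_gene.loc["g_only_a", "status"] == "only_Th1"
        assert not by_gene.loc["g_only_a", "switch"]
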