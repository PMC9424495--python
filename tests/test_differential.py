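"""Multi-condition group model, contrasts, and the correlation-index filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import thkinetics as tk
from thkinetics import differential as diff
from thkinetics import kinetics as kin
from thkinetics import preprocess as pp
from tests.conftest import make_design, make_matrix


class TestGroupModel:
    def test_identical_conditions_give_null_fit(self):
        design = make_design(["Th0", "Th1"], [0, 1, 2, 3, 4, 5])
        curve = [0, 1, 2, 2, 1, 0]
        profiles = {"g": {"Th0": curve, "Th1": curve}}
        gm = diff.fit_group_model(make_matrix(profiles, design), design,
                                  ["g"], degree=2, reference="Th0")
        row = gm.table.iloc[0]
        assert row["f_stat"] == 0.0
        assert row["p_value"] == 1.0

    def test_large_offset_perfectly_detected(self):
        design = make_design(["Th0", "Th1"], [0, 1, 2, 3, 4, 5])
        # t*(5-t) is an exact quadratic, so the full model fits perfectly
        profiles = {"g": {"Th0": [0, 4, 6, 6, 4, 0],
                          "Th1": [5, 9, 11, 11, 9, 5]}}
        gm = diff.fit_group_model(make_matrix(profiles, design), design,
                                  ["g"], degree=2, reference="Th0")
        assert gm.table.iloc[0]["p_value"] == 0.0
        assert gm.table.iloc[0]["significant"]

    def test_null_false_positive_rate_calibrated(self):
        cfg = tk.SimulationConfig(n_flat=1000, seed=9,
                                  n_shared_per_archetype={},
                                  n_hybrid_per_category={})
        m, design, _ = tk.simulate_null_dataset(cfg)
        gm = diff.fit_group_model(m, design, m.gene_ids)
        rate = (gm.table["p_value"] < 0.05).mean()
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / 1000)
        assert abs(rate - 0.05) < half_width

    def test_empty_gene_set_rejected(self, small_dataset):
        m, design, _ = small_dataset
        with pytest.raises(ValueError, match="empty"):
            diff.fit_group_model(m, design, [])


@pytest.fixture(scope="module")
def contrast_dataset():
    cfg = tk.SimulationConfig(
        n_flat=0, seed=21,
        n_shared_per_archetype={"C1_transient_up": 134,
                                "C2_delayed_up": 133, "C3_down": 133},
        n_hybrid_per_category={"Th1_like": 100})
    return tk.simulate_dataset(cfg)


class TestContrastTest:
    def test_recovery_of_differing_genes(self, contrast_dataset):
        m, design, truth = contrast_dataset
        gm = diff.fit_group_model(m, design, m.gene_ids)
        ct = diff.contrast_test(gm, ("Th1", "Th2"))
        truly_diff = set(truth.genes_in_class("hybrid_Th1_like"))
        called = set(ct.loc[ct["quantitative_deg"], "gene_id"])
        assert len(called & truly_diff) / len(truly_diff) >= 0.9
        assert len(called - truly_diff) / max(len(called), 1) <= 0.10

    def test_symmetric_in_pair_order(self, contrast_dataset):
        m, design, _ = contrast_dataset
        gm = diff.fit_group_model(m, design, m.gene_ids[:100])
        p_ab = diff.contrast_test(gm, ("Th1", "Th2"))["contrast_p"]
        p_ba = diff.contrast_test(gm, ("Th2", "Th1"))["contrast_p"]
        np.testing.assert_allclose(p_ab, p_ba, atol=1e-12)

    def test_identical_pair_profiles_not_significant(self):
        design = make_design(["Th0", "Th1", "Th2"], [0, 1, 2, 3, 4, 5])
        shared = [0, 2, 3, 3, 2, 0]
        profiles = {"g": {"Th0": [0] * 6, "Th1": shared, "Th2": shared}}
        gm = diff.fit_group_model(make_matrix(profiles, design), design,
                                  ["g"], degree=2, reference="Th0")
        ct = diff.contrast_test(gm, ("Th1", "Th2"))
        assert ct.iloc[0]["contrast_p"] == 1.0

    def test_unknown_condition_rejected(self, contrast_dataset):
        m, design, _ = contrast_dataset
        gm = diff.fit_group_model(m, design, m.gene_ids[:10])
        with pytest.raises(ValueError, match="Th17"):
            diff.contrast_test(gm, ("Th1", "Th17"))


class TestStepwiseMode:
    def test_stepwise_agrees_on_clear_cases(self, contrast_dataset):
        m, design, truth = contrast_dataset
        genes = (truth.genes_in_class("hybrid_Th1_like")[:40]
                 + truth.genes_in_class("kinetic_C1")[:40])
        gm = diff.fit_group_model(m, design, genes)
        sw = diff.stepwise_contrast_flags(m, design, gm, ("Th1", "Th2"))
        flagged = set(sw.loc[sw["stepwise_flag"], "gene_id"])
        truly_diff = set(truth.genes_in_class("hybrid_Th1_like")[:40])
        # stepwise retention must find every strongly differing gene
        assert truly_diff <= flagged

    def test_identical_conditions_retain_nothing(self):
        design = make_design(["Th0", "Th1", "Th2"], [0, 1, 2, 3, 4, 5])
        shared = [0.0, 2.0, 3.0, 3.0, 2.0, 0.0]
        profiles = {"g": {"Th0": shared, "Th1": shared, "Th2": shared}}
        m = make_matrix(profiles, design)
        gm = diff.fit_group_model(m, design, ["g"], degree=2,
                                  reference="Th0")
        sw = diff.stepwise_contrast_flags(m, design, gm, ("Th1", "Th2"))
        assert not sw["stepwise_flag"].any()


class TestCorrelationIndex:
    def test_hand_computed_pearson(self, toy_two_condition):
        m, design = toy_two_condition
        r, index = diff.correlation_index(m, design, "rising", ("A", "B"))
        assert r == pytest.approx(0.4472135955)
        assert index == pytest.approx(1 - 0.4472135955)

    def test_identical_profiles_index_zero(self, toy_two_condition):
        m, design = toy_two_condition
        design2 = make_design(["A", "B"], [0, 1, 2, 3])
        profiles = {"g": {"A": [0, 1, 2, 3], "B": [0, 1, 2, 3]}}
        r, index = diff.correlation_index(make_matrix(profiles, design2),
                                          design2, "g", ("A", "B"))
        assert index == pytest.approx(0.0, abs=1e-12)

    def test_negated_profile_index_two(self):
        design = make_design(["A", "B"], [0, 1, 2, 3])
        profiles = {"g": {"A": [0, 1, 2, 3], "B": [3, 2, 1, 0]}}
        r, index = diff.correlation_index(make_matrix(profiles, design),
                                          design, "g", ("A", "B"))
        assert index == pytest.approx(2.0, abs=1e-12)

    def test_constant_profile_gives_nan(self):
        design = make_design(["A", "B"], [0, 1, 2, 3])
        profiles = {"g": {"A": [5, 5, 5, 5], "B": [0, 1, 2, 3]}}
        r, index = diff.correlation_index(make_matrix(profiles, design),
                                          design, "g", ("A", "B"))
        assert np.isnan(r) and np.isnan(index)

    @settings(deadline=None, max_examples=40)
    @given(a=st.floats(min_value=0.1, max_value=50),
           b=st.floats(min_value=-20, max_value=20))
    def test_affine_invariance_and_negation(self, a, b):
        design = make_design(["A", "B"], [0, 1, 2, 3, 4])
        x = [0.0, 1.0, 3.0, 2.0, 5.0]
        y = [1.0, 0.0, 2.0, 4.0, 3.0]
        base = make_matrix({"g": {"A": x, "B": y}}, design)
        scaled = make_matrix({"g": {"A": x, "B": [a * v + b for v in y]}},
                             design)
        negated = make_matrix({"g": {"A": x, "B": [-v for v in y]}}, design)
        _, i0 = diff.correlation_index(base, design, "g", ("A", "B"))
        _, i1 = diff.correlation_index(scaled, design, "g", ("A", "B"))
        _, i2 = diff.correlation_index(negated, design, "g", ("A", "B"))
        assert i1 == pytest.approx(i0, abs=1e-9)
        assert i2 == pytest.approx(2 - i0, abs=1e-9)


@pytest.fixture(scope="module")
def analyzed(small_dataset):
    m, design, _ = small_dataset
    fits = pd.concat([kin.fit_condition_polynomials(m, design, c)
                      for c in design.conditions], ignore_index=True)
    flags = kin.foldchange_rule(pp.log2_fold_change(m, design))
    calls, union = kin.call_kinetic_genes(fits, flags)
    gm = diff.fit_group_model(m, design, union)
    ct = diff.contrast_test(gm, ("Th1", "Th2"))
    corr = diff.correlation_index_table(m, design, gm.genes, ("Th1", "Th2"))
    ct = ct.merge(corr[["gene_id", "pearson_r", "correlation_index"]],
                  on="gene_id")
    return calls, diff.qualitative_deg(ct)


class TestQualitativeAndVolcano:
    def test_nesting_qualitative_within_quantitative(self, analyzed):
        _, ct = analyzed
        assert (ct["qualitative_deg"] <= ct["quantitative_deg"]).all()
        assert ct["qualitative_deg"].sum() <= ct["quantitative_deg"].sum()

    def test_index_threshold_respected(self, analyzed):
        _, ct = analyzed
        qual = ct[ct["qualitative_deg"]]
        assert (qual["correlation_index"] > 0.3).all()

    def test_volcano_rows_and_categories(self, analyzed):
        calls, ct = analyzed
        volcano = diff.build_volcano_table(calls, ct, ("Th1", "Th2"))
        union = set(calls.loc[calls["kinetic"], "gene_id"])
        assert len(volcano) == len(union)
        counts = volcano["category"].value_counts()
        n_qual = counts.get("qualitative DEG", 0)
        n_quant = counts.get("quantitative DEG", 0)
        assert n_qual == ct["qualitative_deg"].sum()
        assert n_qual + n_quant == ct["quantitative_deg"].sum()

    def test_threshold_bounds_enforced(self, analyzed):
        _, ct = analyzed
        with pytest.raises(ValueError):
            diff.qualitative_deg(ct, index_threshold=2.5)
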