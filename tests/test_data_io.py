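"""I/O containers, GMT parsing, probe collapsing and BH correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import thkinetics as tk
from thkinetics.data_io import ValidationError


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestExpressionMatrixIO:
    def test_round_trip_identity(self, tmp_path):
        path = _write(tmp_path, "m.tsv",
                      "gene_id\ts1\ts2\ts3\ts4\n"
                      "g1\t1.5\t2\t3\t4\n"
                      "g2\t5\t6\t7\t8\n"
                      "g3\t-1\t0\t0.25\t9\n")
        m = tk.read_expression_matrix(path)
        assert m.shape == (3, 4)
        out = tmp_path / "roundtrip.tsv"
        tk.write_expression_matrix(m, out)
        m2 = tk.read_expression_matrix(out)
        assert m2.gene_ids == m.gene_ids
        assert m2.sample_ids == m.sample_ids
        np.testing.assert_array_equal(m2.values, m.values)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        path = _write(tmp_path, "dup.tsv",
                      "gene_id\ts1\ns1g\t1\ns1g\t2\n".replace("s1g", "gX"))
        with pytest.raises(ValidationError, match="gX"):
            tk.read_expression_matrix(path)

    def test_non_numeric_cell_names_position(self, tmp_path):
        path = _write(tmp_path, "bad.tsv",
                      "gene_id\ts1\ts2\ng1\t1\t2\ng2\t3\toops\n")
        with pytest.raises(ValueError, match="line 3.*column 3"):
            tk.read_expression_matrix(path)

    def test_ragged_row_names_line(self, tmp_path):
        path = _write(tmp_path, "ragged.tsv",
                      "gene_id\ts1\ts2\ng1\t1\t2\ng2\t3\n")
        with pytest.raises(ValueError, match="line 3"):
            tk.read_expression_matrix(path)


class TestSampleDesign:
    def test_full_factorial_design(self, tmp_path):
        rows = ["sample_id\tcondition\ttime_h\treplicate"]
        for c in ("Th0", "Th1", "Th2", "Th12"):
            for i, t in enumerate((0, 3, 6, 12, 24, 36, 48, 72, 96, 120)):
                for r in (1, 2):
                    rows.append(f"{c}_{t}_{r}\t{c}\t{t}\t{r}")
        design = tk.read_sample_design(
            _write(tmp_path, "d.tsv", "\n".join(rows) + "\n"))
        assert design.conditions == ["Th0", "Th1", "Th2", "Th12"]
        assert len(design.times("Th1")) == 10
        assert len(design.table) == 80

    def test_missing_column_named(self, tmp_path):
        path = _write(tmp_path, "d.tsv",
                      "sample_id\tcondition\ttime_h\na\tTh1\t0\n")
        with pytest.raises(ValidationError, match="replicate"):
            tk.read_sample_design(path)

    def test_too_few_timepoints_rejected(self, tmp_path):
        rows = ["sample_id\tcondition\ttime_h\treplicate"]
        for t in (0, 3, 6):
            rows.append(f"s{t}\tTh1\t{t}\t1")
        with pytest.raises(ValidationError, match="timepoints"):
            tk.read_sample_design(_write(tmp_path, "d.tsv", "\n".join(rows)))

    def test_duplicate_triple_rejected(self, tmp_path):
        rows = ["sample_id\tcondition\ttime_h\treplicate",
                "a\tTh1\t0\t1", "b\tTh1\t0\t1",
                "c\tTh1\t3\t1", "d\tTh1\t6\t1", "e\tTh1\t12\t1"]
        with pytest.raises(ValidationError, match="triple"):
            tk.read_sample_design(_write(tmp_path, "d.tsv", "\n".join(rows)))


class TestGmt:
    def test_two_sets_loaded(self, tmp_path):
        path = _write(tmp_path, "s.gmt",
                      "setA\tdesc\tg1\tg2\tg3\n"
                      "setB\tdesc\tg1\tg4\tg5\tg6\tg7\n")
        coll = tk.read_gmt(path)
        assert len(coll) == 2
        assert {len(coll.members(s)) for s in coll.sets} == {3, 5}

    def test_duplicate_member_deduplicated_with_warning(self, tmp_path):
        path = _write(tmp_path, "s.gmt", "setA\tdesc\tg1\tg2\tg1\n")
        with pytest.warns(UserWarning, match="duplicate"):
            coll = tk.read_gmt(path)
        assert coll.members("setA") == ["g1", "g2"]

    def test_short_line_is_parse_error(self, tmp_path):
        path = _write(tmp_path, "s.gmt", "setA\tdesc\n")
        with pytest.raises(ValueError, match="line 1"):
            tk.read_gmt(path)

    def test_empty_file_warns(self, tmp_path):
        path = _write(tmp_path, "s.gmt", "")
        with pytest.warns(UserWarning, match="empty"):
            coll = tk.read_gmt(path)
        assert len(coll) == 0


class TestCollapseProbes:
    def _matrix(self, rows):
        df = pd.DataFrame(rows, columns=["s1", "s2"])
        df.index.name = "gene_id"
        return tk.ExpressionMatrix(df)

    def test_max_mean_picks_highest_mean_probe(self):
        m = self._matrix(pd.DataFrame({"s1": [4, 6], "s2": [6, 8]},
                                      index=["p1", "p2"]))
        pm = tk.ProbeMap({"p1": "G", "p2": "G"})
        out = tk.collapse_probes_to_genes(m, pm, rule="max_mean")
        assert out.gene_ids == ["G"]
        np.testing.assert_array_equal(out.values[0], [6, 8])

    def test_mean_rule_averages(self):
        m = self._matrix(pd.DataFrame({"s1": [1, 3], "s2": [3, 5]},
                                      index=["p1", "p2"]))
        pm = tk.ProbeMap({"p1": "G", "p2": "G"})
        out = tk.collapse_probes_to_genes(m, pm, rule="mean")
        np.testing.assert_array_equal(out.values[0], [2, 4])

    def test_one_probe_per_gene_is_identity_up_to_rename(self):
        m = self._matrix(pd.DataFrame({"s1": [1, 2], "s2": [3, 4]},
                                      index=["p1", "p2"]))
        pm = tk.ProbeMap({"p1": "A", "p2": "B"})
        out = tk.collapse_probes_to_genes(m, pm)
        assert out.gene_ids == ["A", "B"]
        np.testing.assert_array_equal(out.values, m.values)

    def test_gene_count_equals_distinct_mapped_genes(self):
        rng = np.random.default_rng(0)
        probes = [f"p{i}" for i in range(40)]
        df = pd.DataFrame(rng.normal(size=(40, 3)), index=probes,
                          columns=["s1", "s2", "s3"])
        df.index.name = "gene_id"
        mapping = {p: f"G{i % 13}" for i, p in enumerate(probes[:35])}
        out = tk.collapse_probes_to_genes(tk.ExpressionMatrix(df),
                                          tk.ProbeMap(mapping))
        assert out.shape[0] == len(set(mapping.values()))


def bh_bruteforce(p):
    """Independent step-up oracle: q_(i) = min_{j>=i} m*p_(j)/j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            min(m * p[order[j]] / (j + 1) for j in range(i, m)), 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBenjaminiHochberg:
    @pytest.mark.parametrize("p, expected", [
        ([0.04] * 5, [0.04] * 5),
        ([0.01, 0.02, 0.03, 0.04], [0.04] * 4),
        ([0.2], [0.2]),
    ])
    def test_hand_examples(self, p, expected):
        np.testing.assert_allclose(tk.benjamini_hochberg(p), expected)

    def test_matches_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(1, 51)
            p = rng.uniform(size=n)
            np.testing.assert_allclose(tk.benjamini_hochberg(p),
                                       bh_bruteforce(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            tk.benjamini_hochberg([0.5, 1.2])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_q_in_unit_interval_and_at_least_p(self, p):
        q = tk.benjamini_hochberg(p)
        assert ((q >= -1e-12) & (q <= 1 + 1e-12)).all()
        # step-up never shrinks the largest p-value's q below itself
        assert q[np.argmax(p)] >= max(p) - 1e-12
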