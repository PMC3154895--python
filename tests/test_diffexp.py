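import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexnet import cre_filter, de_counts, overlay_on_network, ttest_de
from conftest import make_matrix
from oracles import pooled_t

# Published CREB-target annotation of the seven-gene panel (BV, BR).
PANEL = pd.DataFrame(
    {
        "gene": ["BEX1", "BICD1", "CHGB", "CPE", "GABRB3", "SCG2", "SCG3"],
        "bv": [5.0e-5, 1.3e-3, 7.5e-8, 1.1e-12, 1.2e-2, 1.7e-4, 2.5e-5],
        "br": [2.1, 1.7, 3.0, 7.4, 1.5, 1.9, 2.2],
    }
)


def two_group_matrix(tumor_rows, normal_rows, genes):
    n_t = len(tumor_rows[0])
    n_n = len(normal_rows[0])
    samples = [f"t{i}" for i in range(n_t)] + [f"n{i}" for i in range(n_n)]
    values = [list(t) + list(n) for t, n in zip(tumor_rows, normal_rows)]
    return make_matrix(values, genes, samples, ["tumor"] * n_t + ["normal"] * n_n)


class TestTtestDe:
    def test_hand_computed_t_and_p(self):
        matrix = two_group_matrix([[4, 5, 6]], [[1, 2, 3]], ["GA"])
        table = ttest_de(matrix, alpha=0.05)
        row = table.iloc[0]
        assert row["t"] == pytest.approx(3.0 / np.sqrt(2 / 3), abs=1e-3)  # 3.674
        assert row["p"] == pytest.approx(2 * stats.t.sf(3.674, df=4), abs=1e-3)  # 0.0213
        assert row["significant"] and row["direction"] == "up"

    def test_identical_groups_give_zero_t(self):
        matrix = two_group_matrix([[1, 2, 3]], [[1, 2, 3]], ["GA"])
        row = ttest_de(matrix).iloc[0]
        assert row["t"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)
        assert not row["significant"]

    def test_sign_flips_with_group_order(self):
        matrix = two_group_matrix([[1, 2, 3]], [[4, 5, 6]], ["GA"])
        row = ttest_de(matrix).iloc[0]
        assert row["t"] == pytest.approx(-3.674, abs=1e-3)
        assert row["direction"] == "down"

    def test_small_group_rejected(self):
        matrix = make_matrix(
            [[1, 2, 3]], ["GA"], ["s1", "s2", "s3"], ["tumor", "tumor", "normal"]
        )
        with pytest.raises(ValueError, match="2 samples per group"):
            ttest_de(matrix)

    def test_zero_variance_gene_flagged_undefined(self):
        matrix = two_group_matrix([[5, 5, 5], [4, 5, 6]], [[5, 5, 5], [1, 2, 3]], ["flat", "GA"])
        table = ttest_de(matrix)
        flat = table[table["gene"] == "flat"].iloc[0]
        assert np.isnan(flat["p"]) and not flat["significant"]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_two_pass_pooled_formula(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(15, 9))
        matrix = make_matrix(
            values, [f"g{i}" for i in range(15)], [f"s{j}" for j in range(9)],
            ["tumor"] * 5 + ["normal"] * 4,
        )
        table = ttest_de(matrix)
        for i in range(15):
            expected = pooled_t(values[i, :5], values[i, 5:])
            assert table.iloc[i]["t"] == pytest.approx(expected, abs=1e-10)

    def test_welch_variant_available(self):
        matrix = two_group_matrix([[4, 5, 6, 20]], [[1, 2, 3]], ["GA"])
        pooled = ttest_de(matrix).iloc[0]["t"]
        welch = ttest_de(matrix, equal_var=False).iloc[0]["t"]
        assert pooled != pytest.approx(welch)


class TestDeCounts:
    def make_table(self, n_up, n_down, n_null):
        genes = [f"g{i}" for i in range(n_up + n_down + n_null)]
        direction = ["up"] * n_up + ["down"] * n_down + [pd.NA] * n_null
        sig = [True] * (n_up + n_down) + [False] * n_null
        return pd.DataFrame(
            {"gene": genes, "t": 0.0, "p": 0.01, "p_adj": 0.1,
             "significant": sig, "direction": direction}
        )

    def test_study_scale_bookkeeping(self):
        counts = de_counts(self.make_table(539, 401, 0), background_size=3470)
        assert counts.n_total == 940
        assert round(100 * counts.fraction) == 27

    def test_empty_table(self):
        counts = de_counts(self.make_table(0, 0, 0))
        assert counts == (0, 0, 0, 0.0)

    def test_all_up(self):
        counts = de_counts(self.make_table(5, 0, 2))
        assert counts.n_down == 0 and counts.n_total == 5


class TestOverlay:
    def overlay_pct(self, n_nodes, n_flagged):
        g = nx.path_graph(n_nodes)
        g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
        table = pd.DataFrame(
            {"gene": [], "t": [], "p": [], "p_adj": [], "significant": [], "direction": []}
        )
        flagged = {f"g{i}" for i in range(n_flagged)}
        _, summary = overlay_on_network(g, table, flagged)
        return summary

    def test_study_scale_mutated_share(self):
        # 788 flagged of 3470 network genes -> 23% to the nearest percent
        summary = self.overlay_pct(3470, 788)
        assert summary["pct_mutated"] == 23

    def test_empty_list(self):
        assert self.overlay_pct(10, 0)["n_mutated"] == 0

    def test_superset_list(self):
        assert self.overlay_pct(10, 10)["pct_mutated"] == 100

    def test_node_annotations(self):
        g = nx.Graph([("GA", "GB")])
        table = pd.DataFrame(
            {"gene": ["GA"], "t": [3.0], "p": [0.01], "p_adj": [0.02],
             "significant": [True], "direction": ["up"]}
        )
        nodes, summary = overlay_on_network(g, table, {"GB"}, partition={"GA": 0, "GB": 0})
        nodes = nodes.set_index("gene")
        assert bool(nodes.at["GA", "de"]) and nodes.at["GA", "direction"] == "up"
        assert bool(nodes.at["GB", "mutated"]) and not bool(nodes.at["GB", "de"])
        assert summary["n_de"] == 1 and summary["pct_de"] == 50


class TestCreFilter:
    def test_strong_target_passes(self):
        result = cre_filter(["CPE"], PANEL)
        assert result.passing == ["CPE"]

    def test_panel_filtered_by_stated_thresholds(self):
        # Of the seven panel genes, five clear BV <= 0.001 and BR >= 1.5;
        # BICD1 (BV 1.3e-3) and GABRB3 (BV 1.2e-2) fail the binding value.
        result = cre_filter(PANEL["gene"], PANEL)
        assert result.passing == ["BEX1", "CHGB", "CPE", "SCG2", "SCG3"]
        assert result.n_unannotated == 0

    def test_strict_mode_uses_open_inequalities(self):
        # GABRB3 sits exactly at BR = 1.5 but already fails on BV; a gene at
        # the BR boundary passes inclusively and fails strictly.
        table = pd.DataFrame({"gene": ["X"], "bv": [1e-4], "br": [1.5]})
        assert cre_filter(["X"], table).passing == ["X"]
        assert cre_filter(["X"], table, strict=True).passing == []

    def test_empty_input(self):
        result = cre_filter([], PANEL)
        assert result.passing == [] and result.input_genes == []

    def test_unannotated_genes_counted_not_passed(self):
        result = cre_filter(["CPE", "NOVEL1"], PANEL)
        assert result.passing == ["CPE"]
        assert result.n_unannotated == 1

    @pytest.mark.parametrize("bv_max, br_min", [(1e-4, 1.5), (0.001, 2.0), (1e-5, 3.0)])
    def test_tightening_thresholds_never_adds_genes(self, bv_max, br_min):
        base = set(cre_filter(PANEL["gene"], PANEL).passing)
        tightened = set(cre_filter(PANEL["gene"], PANEL, bv_max=bv_max, br_min=br_min).passing)
        assert tightened <= base
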