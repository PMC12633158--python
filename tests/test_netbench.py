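"""Preprocessing, correlation networks, and truth comparison."""

import numpy as np
import pandas as pd
import pytest

from qsimcells import (
    PreprocConfig,
    Topology,
    compare_to_truth,
    correlation_network,
    preprocess,
    simulate_counts,
)
from qsimcells.matrixgen import CountMatrix
from qsimcells.netbench import PreprocessedMatrix
from qsimcells.presets import make_fixtures


def make_matrix(values, gene_labels=None, cell_types=None):
    values = np.asarray(values)
    g, c = values.shape
    return CountMatrix(
        values=values,
        gene_labels=gene_labels or [f"g{i}" for i in range(g)],
        cell_labels=[f"cell{j}" for j in range(c)],
        cell_types=np.array(cell_types or ["CT1"] * c, dtype=object),
    )


class TestPreprocess:
    def test_library_size_scaling(self):
        matrix = make_matrix([[2, 3], [3, 1], [5, 1]])
        cfg = PreprocConfig(log1p=False, scale=False)
        pre = preprocess(matrix, cfg)
        np.testing.assert_allclose(pre.values[:, 0], [2000, 3000, 5000])
        np.testing.assert_allclose(pre.values[:, 1], [6000, 2000, 2000])

    def test_constant_gene_flagged_and_excluded(self):
        matrix = make_matrix([[0, 0, 0, 0], [1, 2, 3, 4], [2, 1, 4, 3]])
        pre = preprocess(matrix)
        assert pre.excluded_genes == ["g0"]
        assert pre.gene_labels == ["g1", "g2"]

    def test_zero_count_cell_flagged(self):
        matrix = make_matrix([[1, 0, 2], [3, 0, 1]])
        pre = preprocess(matrix, PreprocConfig(log1p=False, scale=False))
        assert pre.zero_count_cells == ["cell1"]
        np.testing.assert_allclose(pre.values[:, 1], [0, 0])

    def test_z_scored_rows_standardized(self, rng):
        matrix = make_matrix(rng.poisson(10, size=(6, 200)))
        pre = preprocess(matrix)
        assert np.allclose(pre.values.mean(axis=1), 0, atol=1e-10)
        assert np.allclose(pre.values.var(axis=1), 1, atol=1e-10)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            preprocess(make_matrix([[1], [2]]))


class TestCorrelationNetwork:
    def pre_from(self, values, labels=None):
        values = np.asarray(values, dtype=float)
        return PreprocessedMatrix(
            values=values,
            gene_labels=labels or [f"g{i}" for i in range(values.shape[0])],
            cell_labels=[f"c{j}" for j in range(values.shape[1])],
            cell_types=np.array(["CT1"] * values.shape[1], dtype=object),
        )

    def test_duplicated_gene_perfect_edge(self, rng):
        x = rng.normal(size=50)
        pre = self.pre_from([x, x, rng.normal(size=50)])
        for method in ("pearson", "spearman"):
            net = correlation_network(pre, method)
            assert net.corr.loc["g0", "g1"] == pytest.approx(1.0)
            assert net.adjacency.loc["g0", "g1"]

    def test_negated_gene_absolute_threshold(self, rng):
        x = rng.normal(size=50)
        net = correlation_network(self.pre_from([x, -x]), "pearson")
        assert net.corr.loc["g0", "g1"] == pytest.approx(-1.0)
        assert net.adjacency.loc["g0", "g1"]  # |corr| > 0.5 despite the sign

    def test_symmetry_and_unit_diagonal(self, rng):
        pre = self.pre_from(rng.normal(size=(5, 80)))
        for method in ("pearson", "spearman"):
            net = correlation_network(pre, method)
            np.testing.assert_allclose(net.corr.values, net.corr.values.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(net.corr.values), 1.0, atol=1e-12)
            assert (net.adjacency.values == net.adjacency.values.T).all()

    def test_every_edge_beats_threshold(self, rng):
        pre = self.pre_from(rng.normal(size=(6, 40)))
        cfg = PreprocConfig(corr_threshold=0.2)
        net = correlation_network(pre, "pearson", cfg)
        assert (net.edge_list["corr"].abs() > 0.2).all()

    def test_independent_genes_stay_below_02(self):
        """Joint-mode sampling of a gate-free circuit gives independent
        Bernoulli genes; null correlations scale like 1/sqrt(n_cells)."""
        config = make_fixtures("null-independent", seed=3)["config"]
        config = config.model_copy(update={"split_mode": "joint"})
        _, counts = simulate_counts(config)
        pre = preprocess(counts, config.preproc_config())
        model = [g for g in pre.gene_labels if not g.startswith("HKG")]
        corr = correlation_network(pre, "pearson").corr.loc[model, model].values
        off_diag = corr[~np.eye(len(model), dtype=bool)]
        assert np.abs(off_diag).max() < 0.2

    def test_unknown_method(self, rng):
        with pytest.raises(ValueError):
            correlation_network(self.pre_from(rng.normal(size=(3, 10))), "kendall")


class TestTransformInvariances:
    def test_spearman_invariant_to_log1p(self, rng):
        # equal per-cell totals so normalization is an exact global rescale:
        # log1p is then strictly monotone on the shared value grid and the
        # ranks (hence Spearman) are bit-for-bit unchanged
        counts = rng.negative_binomial(2, 0.3, size=(5, 300))
        filler = 100 - counts.sum(axis=0)
        assert (filler >= 0).all()
        matrix = make_matrix(np.vstack([counts, filler]))
        with_log = preprocess(matrix, PreprocConfig(log1p=True, scale=False))
        without = preprocess(matrix, PreprocConfig(log1p=False, scale=False))
        a = correlation_network(with_log, "spearman").corr.values
        b = correlation_network(without, "spearman").corr.values
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_pearson_invariant_to_z_score(self, rng):
        matrix = make_matrix(rng.negative_binomial(2, 0.3, size=(5, 300)))
        scaled = preprocess(matrix, PreprocConfig(scale=True))
        unscaled = preprocess(matrix, PreprocConfig(scale=False))
        a = correlation_network(scaled, "pearson").corr.values
        b = correlation_network(unscaled, "pearson").corr.values
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestCompareToTruth:
    def net_with_edges(self, edges, labels):
        """Build a NetworkResult whose adjacency holds exactly `edges`."""
        rng = np.random.default_rng(0)
        base = {lab: rng.normal(size=400) for lab in labels}
        for a, b in edges:
            base[b] = base[a] + rng.normal(scale=1e-3, size=400)
        pre = PreprocessedMatrix(
            values=np.array([base[lab] for lab in labels]),
            gene_labels=list(labels),
            cell_labels=[f"c{j}" for j in range(400)],
            cell_types=np.array(["CT1"] * 400, dtype=object),
        )
        return correlation_network(pre, "pearson")

    def test_recovered_undirected(self):
        labels = [f"g{i}" for i in range(5)]
        net = self.net_with_edges([("g1", "g2")], labels)
        report = compare_to_truth(net, Topology(((2, 1),)), labels)
        assert report.recovered == [("g1", "g2")]
        assert report.missed == []

    def test_empty_adjacency_all_missed(self):
        labels = [f"g{i}" for i in range(5)]
        net = self.net_with_edges([], labels)
        report = compare_to_truth(net, Topology(((2, 1), (3, 4))), labels)
        assert report.recovered == []
        assert set(report.missed) == {("g1", "g2"), ("g3", "g4")}

    def test_spurious_edges(self):
        labels = [f"g{i}" for i in range(5)]
        net = self.net_with_edges([("g3", "g4")], labels)
        report = compare_to_truth(net, Topology(((2, 1),)), labels)
        assert report.recovered == []
        assert report.spurious == [("g3", "g4")]

    def test_label_mismatch_rejected(self):
        labels = [f"g{i}" for i in range(3)]
        net = self.net_with_edges([], labels)
        with pytest.raises(ValueError):
            compare_to_truth(net, Topology(((0, 4),)), labels)

    def test_serialization(self, tmp_path):
        labels = [f"g{i}" for i in range(5)]
        net = self.net_with_edges([("g1", "g2"), ("g3", "g4")], labels)
        report = compare_to_truth(net, Topology(((2, 1),)), labels)
        report.to_json(tmp_path / "r.json")
        report.to_tsv(tmp_path / "r.tsv")
        df = pd.read_csv(tmp_path / "r.tsv", sep="\t")
        assert set(df["status"]) == {"truth_recovered", "spurious"}
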