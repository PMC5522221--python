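"""Correlation heatmaps, cross-model redundancy and partial-correlation networks."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from chromexpr import (
    correlation_heatmap,
    cross_model_pcc,
    fit_svr,
    log_expression,
    network_robustness,
    partial_correlation_network,
)
from chromexpr.errors import AlignmentError, SizingError, UndefinedCorrelationError
from chromexpr.network import attach_expression, partial_correlations


def chain_data(n=5000, seed=0):
    """A -> B -> C Gaussian chain: A and C conditionally independent given B."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = 0.8 * a + 0.6 * rng.standard_normal(n)
    c = 0.8 * b + 0.6 * rng.standard_normal(n)
    return pd.DataFrame({"A": a, "B": b, "C": c})


class TestHeatmap:
    def test_symmetric_unit_diagonal(self, assoc):
        cm = correlation_heatmap(assoc)
        np.testing.assert_allclose(cm.values, cm.values.T)
        np.testing.assert_allclose(np.diag(cm.values), 1.0)
        assert np.abs(cm.values).max() <= 1.0 + 1e-12

    def test_engineered_redundant_pair_shows_up(self, assoc):
        cm = correlation_heatmap(assoc).to_frame()
        assert 0.85 <= cm.loc["TF02", "TF03"] <= 0.95

    def test_constant_column_rejected(self, assoc):
        broken = assoc.logged.copy()
        broken["flat"] = 1.0
        import dataclasses

        bad = dataclasses.replace(assoc, logged=broken)
        with pytest.raises(UndefinedCorrelationError, match="flat"):
            correlation_heatmap(bad)


class TestCrossModel:
    def test_identical_predictions_give_unity(self, assoc, y):
        rep = fit_svr(assoc.subset(["TF01"]), y, seed=0)
        assert cross_model_pcc(rep, rep) == pytest.approx(1.0)

    def test_length_mismatch_raises(self, assoc, y):
        rep = fit_svr(assoc.subset(["TF01"]), y, seed=0)
        short = fit_svr(assoc.subset(["TF01"]).iloc[:100], y[:100], seed=0)
        with pytest.raises(AlignmentError):
            cross_model_pcc(rep, short)

    def test_shared_expression_signal_couples_class_models(self, assoc, y):
        tf = fit_svr(assoc.subset(assoc.names_of_class("TF")), y, seed=0)
        hm = fit_svr(assoc.subset(assoc.names_of_class("HM", "DNase")), y, seed=0)
        assert cross_model_pcc(tf, hm) > 0.8


class TestPartialCorrelation:
    def test_chain_conditional_independence(self):
        data = chain_data()
        net = partial_correlation_network(data, n_edges=3)
        pcor = net.pcor
        assert abs(pcor.loc["A", "C"]) < 0.05
        assert pcor.loc["A", "B"] > 0.3 and pcor.loc["B", "C"] > 0.3
        # the two true edges rank in the top 2
        top2 = {frozenset(e[:2]) for e in net.edges[:2]}
        assert top2 == {frozenset({"A", "B"}), frozenset({"B", "C"})}

    def test_matches_regression_residual_oracle(self):
        """Partial correlation via matrix inversion equals the correlation of
        OLS residuals after removing the conditioning variable."""
        data = chain_data(seed=1)
        pcor, lam = partial_correlations(data)
        assert 0 < lam < 0.05
        b = sm.add_constant(data["B"])
        ra = sm.OLS(data["A"], b).fit().resid
        rc = sm.OLS(data["C"], b).fit().resid
        assert pcor.loc["A", "C"] == pytest.approx(np.corrcoef(ra, rc)[0, 1], abs=0.02)

    def test_converges_to_precision_implied_values(self):
        """At large n, estimates approach the generating precision matrix's
        partial correlations."""
        data = chain_data(n=10_000, seed=2)
        # population covariance of the chain, inverted analytically
        cov = np.empty((3, 3))
        var_a, var_b = 1.0, 0.8 ** 2 + 0.6 ** 2
        var_c = 0.8 ** 2 * var_b + 0.6 ** 2
        cov[:] = [
            [var_a, 0.8 * var_a, 0.64 * var_a],
            [0.8 * var_a, var_b, 0.8 * var_b],
            [0.64 * var_a, 0.8 * var_b, var_c],
        ]
        omega = np.linalg.inv(cov)
        d = np.sqrt(np.diag(omega))
        truth = -omega / np.outer(d, d)
        pcor, _ = partial_correlations(data)
        for i, a in enumerate("ABC"):
            for j, b in enumerate("ABC"):
                if i < j:
                    assert pcor.loc[a, b] == pytest.approx(truth[i, j], abs=0.05)

    def test_edge_ranking_invariant_to_variable_order(self):
        data = chain_data(seed=3)
        net1 = partial_correlation_network(data, n_edges=3)
        net2 = partial_correlation_network(data[["C", "A", "B"]], n_edges=3)
        assert [e[:2] for e in net1.edges] == [e[:2] for e in net2.edges]

    def test_requesting_more_edges_than_pairs_warns(self):
        with pytest.warns(UserWarning, match="pairs"):
            net = partial_correlation_network(chain_data(n=200), n_edges=10)
        assert net.n_edges_selected == 3

    def test_sixty_edges_on_twelve_variables(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame(rng.standard_normal((400, 12)),
                            columns=[f"v{i}" for i in range(12)])
        net = partial_correlation_network(data, n_edges=60)
        assert net.n_edges_selected == 60
        assert all(e[0] != e[1] for e in net.edges)
        assert len({frozenset(e[:2]) for e in net.edges}) == 60

    def test_expression_node_attached(self, assoc, genes):
        data = attach_expression(assoc, genes)
        assert "expression" in data.columns
        net = partial_correlation_network(data, n_edges=10)
        assert "expression" in net.nodes


class TestRobustness:
    def test_no_removal_gives_perfect_jaccard(self):
        data = chain_data(n=1000, seed=5)
        rb = network_robustness(data, n_edges=2, n_reps=50, n_remove=0, seed=9)
        assert rb.jaccard.shape == (50,)
        np.testing.assert_allclose(rb.jaccard, 1.0)

    def test_strong_signal_network_is_stable(self):
        data = chain_data(n=5000, seed=6)
        rb = network_robustness(data, n_edges=2, n_reps=10, n_remove=200, seed=9)
        assert rb.mean_jaccard > 0.9

    def test_reproducible_removals(self):
        data = chain_data(n=800, seed=7)
        a = network_robustness(data, n_edges=2, n_reps=5, n_remove=100, seed=3)
        b = network_robustness(data, n_edges=2, n_reps=5, n_remove=100, seed=3)
        np.testing.assert_array_equal(a.jaccard, b.jaccard)

    def test_oversized_removal_rejected(self):
        with pytest.raises(SizingError):
            network_robustness(chain_data(n=100), n_reps=2, n_remove=99)
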