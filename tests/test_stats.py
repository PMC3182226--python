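"""Group comparison, nodal post-hoc, and symptom correlation statistics."""

import numpy as np
import pandas as pd
import pytest

from fncnet import (
    CostGrid,
    false_positive_budget,
    nodal_posthoc,
    percost_group_test,
    symptom_correlation,
)
from fncnet.stats import ClinicalScores


def make_curves(values_by_group, metric="c_net", node="network", edge_counts=(10, 20)):
    """Long-format curves table from {group: subjects x grid array}."""
    n_nodes = 10
    rows = []
    for group, mat in values_by_group.items():
        mat = np.asarray(mat, dtype=float)
        for s in range(mat.shape[0]):
            for gi, E in enumerate(edge_counts):
                rows.append(
                    {
                        "subject_id": f"{group}{s}",
                        "group": group,
                        "edge_count": E,
                        "k_cost": 2 * E / (n_nodes * 9),
                        "metric": metric,
                        "node": node,
                        "value": mat[s, gi],
                    }
                )
    return pd.DataFrame(rows), CostGrid(n_nodes=n_nodes, edge_counts=edge_counts)


class TestPerCostGroupTest:
    def test_identical_groups(self):
        vals = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        curves, grid = make_curves({"a": vals, "b": vals})
        out = percost_group_test(curves, grid, "c_net")
        np.testing.assert_allclose(out["t"], 0.0)
        np.testing.assert_allclose(out["p"], 1.0)
        assert not out["significant"].any()

    def test_matches_hand_pooled_t(self):
        a = np.array([[1.0], [2.0], [3.0]])
        b = np.array([[4.0], [5.0], [6.0]])
        curves, grid = make_curves({"a": a, "b": b}, edge_counts=(10,))
        out = percost_group_test(curves, grid, "c_net")
        sp2 = (2 * 1.0 + 2 * 1.0) / 4  # both sample variances are 1
        t_hand = (2.0 - 5.0) / np.sqrt(sp2 * (2 / 3))
        assert out["t"].iloc[0] == pytest.approx(t_hand, abs=1e-12)

    def test_label_swap_negates_t(self):
        a = np.array([[1.0], [2.0], [4.0]])
        b = np.array([[5.0], [6.0], [9.0]])
        c1, grid = make_curves({"a": a, "b": b}, edge_counts=(10,))
        c2, _ = make_curves({"a": b, "b": a}, edge_counts=(10,))
        t1 = percost_group_test(c1, grid, "c_net")["t"].iloc[0]
        t2 = percost_group_test(c2, grid, "c_net")["t"].iloc[0]
        assert t1 == pytest.approx(-t2)

    def test_requires_two_subjects_per_group(self):
        curves, grid = make_curves(
            {"a": [[1.0, 2.0]], "b": [[3.0, 4.0], [5.0, 6.0]]}
        )
        with pytest.raises(ValueError, match="at least 2"):
            percost_group_test(curves, grid, "c_net")


class TestNodalPosthoc:
    def test_identical_groups_no_discoveries(self):
        vals = np.random.default_rng(0).random((3, 2))
        frames = []
        for node in ("IC1", "IC2"):
            c, grid = make_curves(
                {"a": vals, "b": vals}, metric="k_node", node=node
            )
            frames.append(c)
        curves = pd.concat(frames, ignore_index=True)
        out = nodal_posthoc(curves, grid, metrics=("k_node",))
        assert not out["significant"].any()
        assert not out["significant_fdr"].any()

    def test_fdr_no_discoveries_at_flat_p(self):
        # t chosen so p ~ 0.5 everywhere -> BH yields no q < 0.05
        rng = np.random.default_rng(1)
        frames = []
        for node in ("IC1", "IC2", "IC3"):
            a = rng.normal(0, 1, size=(5, 2))
            b = rng.normal(0, 1, size=(5, 2))
            c, grid = make_curves({"a": a, "b": b}, metric="c_node", node=node)
            frames.append(c)
        curves = pd.concat(frames, ignore_index=True)
        out = nodal_posthoc(curves, grid, metrics=("c_node",))
        assert (out["q_fdr"] >= out["p"] - 1e-12).all()

    def test_designed_degree_difference_dominates(self):
        """A node whose ground-truth degree differs between groups should
        dominate the significant set of the nodal degree tests."""
        from fncnet import (
            CohortConfig,
            ConnectivityMatrices,
            GroupEffect,
            TopologySpec,
            build_grid,
            metric_curves,
        )
        from fncnet.synthetic import simulate_cohort

        n = 14
        base = TopologySpec(
            n_nodes=n, neighbors_k=4, rewire_prob=0.0,
            base_topology="ring_lattice", partial_corr_strength=0.15,
        )
        hub = TopologySpec(
            n_nodes=n, neighbors_k=4, rewire_prob=0.0,
            base_topology="ring_lattice", partial_corr_strength=0.15,
            group_effect=GroupEffect(
                extra_edges=tuple((0, j) for j in range(3, 10))
            ),
        )
        cfg = CohortConfig(
            group_sizes=(10, 10), group_labels=("A", "B"), n_timepoints=1000,
            topology_per_group={"A": base, "B": hub}, seed=21,
            symptom_model=None, temporal_ar1=0.0,
        )
        subjects, _, _ = simulate_cohort(cfg)
        grid = build_grid(n, 30, 30, 1)
        curves = pd.concat(
            [
                metric_curves(
                    ConnectivityMatrices.from_timecourses(tc).Z_fnc, grid,
                    subject_id=tc.subject_id, group=tc.group,
                )
                for tc in subjects
            ],
            ignore_index=True,
        )
        out = nodal_posthoc(curves, grid, metrics=("k_node",))
        sig = out[out["significant"]]
        assert "IC1" in set(sig["node"])  # node 0 is labelled IC1
        best = out.loc[out["p"].idxmin(), "node"]
        assert best == "IC1"


class TestSymptomCorrelation:
    def _tables(self, metric_vals, scores):
        curves, grid = make_curves({"SZ": metric_vals}, edge_counts=(10,))
        scores_df = pd.DataFrame(
            {
                "subject_id": [f"SZ{i}" for i in range(len(scores))],
                "group": "SZ",
                "score_negative": scores,
                "score_positive": np.nan,
            }
        )
        return curves, scores_df

    def test_perfect_positive_and_negative(self):
        vals = np.array([[10.0], [20.0], [30.0], [40.0]])
        curves, scores = self._tables(vals, [10, 20, 30, 40])
        out = symptom_correlation(curves, scores, "c_net")
        assert out["r"].iloc[0] == pytest.approx(1.0)
        curves, scores = self._tables(vals, [40, 30, 20, 10])
        out = symptom_correlation(curves, scores, "c_net")
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_zero_variance_scores_rejected(self):
        vals = np.array([[1.0], [2.0], [3.0]])
        curves, scores = self._tables(vals, [15, 15, 15])
        with pytest.raises(ValueError, match="zero variance"):
            symptom_correlation(curves, scores, "c_net")

    def test_needs_three_patients(self):
        vals = np.array([[1.0], [2.0]])
        curves, scores = self._tables(vals, [10, 20])
        with pytest.raises(ValueError, match="at least 3"):
            symptom_correlation(curves, scores, "c_net")


class TestFalsePositiveBudget:
    @pytest.mark.parametrize(
        "n,alpha,expected", [(16, 0.05, 0.80), (1, 0.05, 0.05), (20, 0.05, 1.0)]
    )
    def test_values(self, n, alpha, expected):
        assert false_positive_budget(n, alpha) == pytest.approx(expected)


class TestClinicalScores:
    def test_range_enforced(self):
        ClinicalScores("s1", 16, 15)
        with pytest.raises(ValueError, match="7-49"):
            ClinicalScores("s1", 50, 15)


class TestCalibration:
    def test_type_one_error_rate(self):
        """With no group effect the per-cost t-test rejects at ~alpha.

        2000 small null cohorts (10 nodes, 50 timepoints, 5v5 subjects, one
        cost); the rejection fraction must sit in 0.05 +/- 0.02.
        """
        from fncnet import (
            ConnectivityMatrices,
            TopologySpec,
            make_precision_matrix,
            network_metrics,
            simulate_subject,
            threshold_to_edges,
        )
        from scipy import stats as sps

        spec = TopologySpec(
            n_nodes=10, neighbors_k=2, base_topology="ring_lattice",
            partial_corr_strength=0.2,
        )
        P = make_precision_matrix(spec, seed=0)
        rejections = 0
        n_cohorts = 2000
        rng = np.random.default_rng(2024)
        seeds = rng.integers(0, 2**31, size=(n_cohorts, 10))
        for c in range(n_cohorts):
            cvals = []
            for s in range(10):
                tc = simulate_subject(P, 50, seed=int(seeds[c, s]))
                conn = ConnectivityMatrices.from_timecourses(tc)
                g = threshold_to_edges(conn.Z_fnc, 13)
                cvals.append(network_metrics(g).c_net)
            _, p = sps.ttest_ind(cvals[:5], cvals[5:], equal_var=True)
            rejections += p < 0.05
        rate = rejections / n_cohorts
        assert 0.03 <= rate <= 0.07

    def test_label_permutation_null(self):
        """Permuting group labels of null data gives a t distribution with
        the null's location and scale."""
        from scipy import stats as sps

        rng = np.random.default_rng(7)
        vals = rng.normal(0, 1, size=16)
        ts = []
        for _ in range(400):
            perm = rng.permutation(16)
            a, b = vals[perm[:8]], vals[perm[8:]]
            t, _ = sps.ttest_ind(a, b, equal_var=True)
            ts.append(t)
        ts = np.array(ts)
        assert abs(ts.mean()) < 0.2
        assert 0.75 < ts.std() < 1.35
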