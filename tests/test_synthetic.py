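"""Ground-truth construction and cohort simulation."""

import numpy as np
import pytest

from fncnet import (
    CohortConfig,
    ConnectivityMatrices,
    GroupEffect,
    TopologySpec,
    make_precision_matrix,
    partial_correlation_pair,
    sample_covariance,
    simulate_cohort,
    simulate_subject,
    threshold_to_edges,
    write_cohort,
)
from fncnet.synthetic import build_topology, implied_partial_correlations


def ring_spec(n=6, k=2, strength=0.3):
    return TopologySpec(
        n_nodes=n, base_topology="ring_lattice", neighbors_k=k,
        partial_corr_strength=strength,
    )


class TestPrecisionConstruction:
    def test_ring_support(self):
        P, A = make_precision_matrix(ring_spec(), seed=0, return_adjacency=True)
        assert int(np.triu(A, 1).sum()) == 6  # the 6-cycle
        off_support = np.triu(P, 1) != 0
        np.testing.assert_array_equal(off_support, np.triu(A, 1))

    def test_zero_strength_gives_identity_partials(self):
        P = make_precision_matrix(ring_spec(strength=0.0), seed=0)
        np.testing.assert_array_equal(P, np.eye(6))
        assert np.all(implied_partial_correlations(P) == 0)

    def test_spd_and_strength_magnitude(self):
        P = make_precision_matrix(ring_spec(), seed=1)
        assert np.linalg.eigvalsh(P)[0] > 0
        R = implied_partial_correlations(P)
        edges = np.abs(np.triu(R, 1)) > 1e-12
        np.testing.assert_allclose(np.abs(np.triu(R, 1))[edges], 0.3, atol=1e-12)

    def test_implied_partials_match_blockwise_oracle(self):
        # the normalized precision must agree with the per-pair Schur
        # complement route applied to Sigma = P^-1
        P = make_precision_matrix(ring_spec(n=8, k=2), seed=3)
        Sigma = np.linalg.inv(P)
        R = implied_partial_correlations(P)
        for j in range(8):
            for k in range(j + 1, 8):
                assert R[j, k] == pytest.approx(
                    partial_correlation_pair(Sigma, j, k), abs=1e-10
                )

    def test_unreachable_strength_raises(self):
        # dense topology + strong partial correlations cannot stay SPD
        spec = TopologySpec(
            n_nodes=12, base_topology="ring_lattice", neighbors_k=10,
            partial_corr_strength=0.6,
        )
        with pytest.raises(ValueError, match="strength"):
            make_precision_matrix(spec, seed=0)

    def test_triangle_effect_raises_truth_clustering(self):
        import networkx as nx

        base = TopologySpec(n_nodes=20, neighbors_k=4, rewire_prob=0.2,
                            partial_corr_strength=0.1)
        high = TopologySpec(
            n_nodes=20, neighbors_k=4, rewire_prob=0.2,
            partial_corr_strength=0.1,
            group_effect=GroupEffect(extra_triangle_edges=10),
        )
        A0 = build_topology(base, seed=7)
        A1 = build_topology(high, seed=7)
        c0 = nx.average_clustering(nx.from_numpy_array(A0))
        c1 = nx.average_clustering(nx.from_numpy_array(A1))
        assert c1 > c0
        assert A1.sum() == A0.sum() + 2 * 10


class TestSimulateSubject:
    def test_deterministic(self):
        P = make_precision_matrix(ring_spec(), seed=0)
        a = simulate_subject(P, 100, ar1=0.3, seed=42)
        b = simulate_subject(P, 100, ar1=0.3, seed=42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_identity_precision_gives_null_partials(self):
        tc = simulate_subject(np.eye(6), 2000, seed=1)
        from fncnet import partial_correlation_matrix

        R = partial_correlation_matrix(sample_covariance(tc))
        assert np.max(np.abs(R)) < 0.1

    def test_ring_support_recovered(self):
        P, A = make_precision_matrix(ring_spec(), seed=2, return_adjacency=True)
        tc = simulate_subject(P, 2000, seed=3)
        conn = ConnectivityMatrices.from_timecourses(tc)
        g = threshold_to_edges(conn.Z_fnc, 6)
        assert set(g.edge_list()) == {
            (i, j) for i, j in zip(*np.nonzero(np.triu(A, 1)))
        }

    def test_rejects_non_spd(self):
        P = np.eye(4)
        P[0, 1] = P[1, 0] = 2.0
        with pytest.raises(ValueError, match="positive definite"):
            simulate_subject(P, 50, seed=0)

    def test_support_recovery_jaccard(self):
        """Edge-set Jaccard >= 0.9 at T=5000 for a 20-node, 0.3-strength net."""
        spec = ring_spec(n=20, k=2, strength=0.3)
        P, A = make_precision_matrix(spec, seed=5, return_adjacency=True)
        tc = simulate_subject(P, 5000, seed=6)
        conn = ConnectivityMatrices.from_timecourses(tc)
        truth = {(i, j) for i, j in zip(*np.nonzero(np.triu(A, 1)))}
        est = set(threshold_to_edges(conn.Z_fnc, len(truth)).edge_list())
        jaccard = len(truth & est) / len(truth | est)
        assert jaccard >= 0.9


class TestSimulateCohort:
    def test_study_shape(self):
        cfg = CohortConfig(seed=1, symptom_model=None)
        subjects, manifest, truth = simulate_cohort(cfg)
        assert len(subjects) == 38
        assert all(tc.data.shape == (194, 57) for tc in subjects)
        assert manifest["group"].value_counts().to_dict() == {"HC": 19, "SZ": 19}
        assert set(truth["groups"]) == {"HC", "SZ"}

    def test_single_subject_cohort_passes_pipeline(self, tmp_path):
        from fncnet.synthetic import default_topology

        topo = {g: default_topology(g == "B", n_nodes=12) for g in ("A", "B")}
        cfg = CohortConfig(
            group_sizes=(1, 0), group_labels=("A", "B"), n_timepoints=60,
            topology_per_group=topo, seed=2, symptom_model=None,
        )
        subjects, manifest, truth = simulate_cohort(cfg)
        assert len(subjects) == 1
        conn = ConnectivityMatrices.from_timecourses(subjects[0])
        g = threshold_to_edges(conn.Z_fnc, 20)
        from fncnet import network_metrics

        m = network_metrics(g)
        assert 0 <= m.c_net <= 1

    def test_bit_reproducible(self):
        from fncnet.synthetic import default_topology

        topo = {g: default_topology(g == "SZ", n_nodes=10) for g in ("HC", "SZ")}
        cfg = CohortConfig(group_sizes=(2, 2), n_timepoints=50,
                           topology_per_group=topo, seed=9, symptom_model=None)
        s1, m1, t1 = simulate_cohort(cfg)
        s2, m2, t2 = simulate_cohort(cfg)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.data, b.data)
        assert t1 == t2
        assert m1.equals(m2)

    def test_symptom_scores_in_range_and_patient_only(self):
        from fncnet.synthetic import SymptomModel, default_topology

        topo = {g: default_topology(g == "SZ", n_nodes=12) for g in ("HC", "SZ")}
        cfg = CohortConfig(
            group_sizes=(3, 5), n_timepoints=80, topology_per_group=topo,
            seed=4, symptom_model=SymptomModel(metric="c_net", ref_cost=0.4),
        )
        _, manifest, _ = simulate_cohort(cfg)
        sz = manifest[manifest["group"] == "SZ"]
        hc = manifest[manifest["group"] == "HC"]
        assert sz["score_negative"].notna().all()
        assert hc["score_negative"].isna().all()
        assert sz["score_negative"].between(7, 49).all()

    def test_write_cohort_files(self, tmp_path):
        from fncnet.synthetic import default_topology

        topo = {g: default_topology(g == "SZ", n_nodes=10) for g in ("HC", "SZ")}
        cfg = CohortConfig(group_sizes=(2, 1), n_timepoints=50,
                           topology_per_group=topo, seed=0, symptom_model=None)
        subjects, manifest, truth = simulate_cohort(cfg)
        out = write_cohort(subjects, manifest, truth, tmp_path / "cohort")
        assert (out / "manifest.tsv").exists()
        assert (out / "ground_truth.json").exists()
        assert len(list((out / "subjects").glob("*.tsv"))) == 3


def test_symptom_correlation_recoverable():
    """Scores built with positive slope on l_net give positive sample R."""
    from fncnet.synthetic import SymptomModel, default_topology
    from scipy import stats

    topo = {g: default_topology(g == "SZ", n_nodes=15) for g in ("HC", "SZ")}
    rs = []
    for rep in range(25):
        cfg = CohortConfig(
            group_sizes=(0, 19), n_timepoints=100, topology_per_group=topo,
            seed=1000 + rep,
            symptom_model=SymptomModel(metric="l_net", slope=3.0, noise_sd=2.0,
                                       ref_cost=0.4),
        )
        subjects, manifest, _ = simulate_cohort(cfg)
        from fncnet import edges_for_cost, network_metrics

        E = edges_for_cost(0.4, 15)
        vals = []
        with np.errstate(all="ignore"):
            for tc in subjects:
                conn = ConnectivityMatrices.from_timecourses(tc)
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore", RuntimeWarning)
                    vals.append(
                        network_metrics(threshold_to_edges(conn.Z_fnc, E)).l_net
                    )
        vals = np.asarray(vals)
        # same convention as the generator: a disconnected graph counts as
        # the most severe finite path length
        finite = np.isfinite(vals)
        vals[~finite] = vals[finite].max()
        scores = manifest["score_negative"].to_numpy(dtype=float)
        r, _ = stats.pearsonr(vals, scores)
        rs.append(r)
    # designed population R = 3/sqrt(9+4) ~ 0.83; sample mean over 25
    # cohorts of n=19 should be clearly positive and near the design
    assert np.mean(rs) > 0.5
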