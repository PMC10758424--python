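"""Time-aware PC: sequential samples, CI test, skeleton, orientation,
weights and rolling."""

import numpy as np
import pytest
from scipy import stats

from causalfc.errors import DegenerateDataError, OrientationError
from causalfc.synthetic import (
    GroundTruthModel,
    make_ground_truth,
    simulate_subject,
    structure_recovery_metrics,
    true_cfc,
)
from causalfc.timeseries import ROITimeSeries
from causalfc.tpc import (
    FisherZ,
    TPCParams,
    UnrolledDAG,
    build_sequential_samples,
    ci_test_fisher_z,
    estimate_edge_weights,
    orient_unrolled,
    pc_skeleton,
    roll_cfc,
    run_tpc,
)
from causalfc.validation import dag_skeleton, dsep_ci_oracle, enumerate_dags


class TestSequentialSamples:
    def test_counts_for_tau_one(self, rng):
        ts = ROITimeSeries(rng.normal(size=(5, 2)), ("A", "B"))
        s = build_sequential_samples(ts, 1)
        assert s.n_samples == 4
        assert len(s.variables) == 4
        assert s.variables == (("A", 0), ("B", 0), ("A", 1), ("B", 1))

    def test_tau_zero_is_identity(self, rng):
        ts = ROITimeSeries(rng.normal(size=(7, 3)), ("A", "B", "C"))
        s = build_sequential_samples(ts, 0)
        np.testing.assert_array_equal(s.data, ts.values)
        assert s.variables == (("A", 0), ("B", 0), ("C", 0))

    def test_window_alignment(self, rng):
        ts = ROITimeSeries(rng.normal(size=(10, 2)), ("A", "B"))
        s = build_sequential_samples(ts, 2)
        # sample i, variable (v, off) = ts[i + off, v]
        for i in (0, 3, 7):
            for off in (0, 1, 2):
                assert s.data[i, s.index(("B", off))] == ts.values[i + off, 1]

    def test_too_short_series_rejected(self, rng):
        ts = ROITimeSeries(rng.normal(size=(3, 2)), ("A", "B"))
        with pytest.raises(ValueError, match="too short"):
            build_sequential_samples(ts, 2)

    def test_constant_region_stays_constant(self, rng):
        vals = rng.normal(size=(20, 2))
        vals[:, 0] = 1.0
        ts = ROITimeSeries(vals, ("A", "B"))
        s = build_sequential_samples(ts, 1)
        assert np.ptp(s.data[:, s.index(("A", 0))]) == 0


class TestFisherZ:
    def test_exact_zero_correlation_gives_p_one(self):
        # orthogonal columns: sample correlation exactly 0
        x = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]] * 10, dtype=float)
        f = FisherZ(x, alpha=0.05)
        indep, p, r = f.test(0, 1)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert indep

    def test_known_r_reference_value(self, rng):
        """r = 0.5, n = 50, empty conditioning: statistic ~ 3.77, p ~ 1.6e-4."""
        # construct a sample with correlation exactly 0.5
        n = 50
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        a = (a - a.mean()) / a.std()
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)  # exactly orthogonal to a
        b /= b.std()
        x = np.column_stack([a, 0.5 * a + np.sqrt(1 - 0.25) * b])
        f = FisherZ(x, alpha=0.05)
        indep, p, r = f.test(0, 1)
        assert r == pytest.approx(0.5, abs=1e-10)
        expected_stat = np.sqrt(n - 3) * 0.5 * np.log(1.5 / 0.5)
        assert expected_stat == pytest.approx(3.765, abs=0.01)
        assert p == pytest.approx(2 * stats.norm.sf(expected_stat), rel=1e-6)
        assert not indep

    def test_partial_correlation_blocks_mediated_path(self, rng):
        # chain A -> B -> C: A and C dependent marginally, independent given B
        n = 4000
        a = rng.normal(size=n)
        b = 0.8 * a + rng.normal(size=n)
        c = 0.8 * b + rng.normal(size=n)
        f = FisherZ(np.column_stack([a, b, c]), alpha=0.01)
        assert not f(0, 2)[0]
        assert f(0, 2, (1,))[0]

    def test_zero_variance_variable_signalled(self):
        x = np.column_stack([np.ones(50), np.arange(50.0)])
        f = FisherZ(x, alpha=0.05)
        with pytest.raises(DegenerateDataError, match="zero variance"):
            f(0, 1)

    def test_too_small_sample_signalled(self, rng):
        f = FisherZ(rng.normal(size=(5, 4)), alpha=0.05)
        with pytest.raises(DegenerateDataError, match="samples"):
            f(0, 1, (2, 3))

    def test_calibration_under_independence(self, rng):
        """Rejection rate under true independence ~ alpha (quick check;
        the full 2000-replicate calibration runs in the acceptance suite)."""
        rej = 0
        reps = 500
        for _ in range(reps):
            x = rng.normal(size=(200, 2))
            rej += not FisherZ(x, alpha=0.05)(0, 1)[0]
        assert rej / reps == pytest.approx(0.05, abs=0.025)

    def test_public_wrapper_accepts_variable_tuples(self, rng):
        ts = ROITimeSeries(rng.normal(size=(100, 2)), ("A", "B"))
        s = build_sequential_samples(ts, 1)
        indep, p = ci_test_fisher_z(s, ("A", 0), ("B", 1), [("A", 1)], alpha=0.05)
        assert 0 <= p <= 1


class TestSkeleton:
    def test_chain_oracle(self):
        """X - Y - Z with X indep Z | Y: skeleton {XY, YZ}, sepset {Y}."""
        ci = dsep_ci_oracle([(0, 1), (1, 2)], 3)
        variables = [("X", 0), ("Y", 0), ("Z", 0)]
        sk, sep = pc_skeleton(ci_test=ci, variables=variables)
        assert sk == {
            frozenset({("X", 0), ("Y", 0)}),
            frozenset({("Y", 0), ("Z", 0)}),
        }
        assert sep[frozenset({("X", 0), ("Z", 0)})] == frozenset({("Y", 0)})

    def test_collider_from_simulated_data(self):
        """X -> Z <- Y with X indep Y: skeleton keeps XZ, YZ; sepset(X,Y) empty."""
        rng = np.random.default_rng(42)
        n = 5000
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        z = 0.7 * x + 0.7 * y + rng.normal(size=n)
        data = np.column_stack([x, y, z])
        variables = [("X", 0), ("Y", 0), ("Z", 0)]
        sk, sep = pc_skeleton(
            params=TPCParams(alpha_ci=0.01),
            ci_test=FisherZ(data, 0.01),
            variables=variables,
        )
        assert sk == {
            frozenset({("X", 0), ("Z", 0)}),
            frozenset({("Y", 0), ("Z", 0)}),
        }
        assert sep[frozenset({("X", 0), ("Y", 0)})] == frozenset()

    def test_oracle_equivalence_on_sample_of_four_node_dags(self):
        """Perfect-CI PC returns the exact true skeleton (spot sample here;
        the exhaustive sweep runs in the acceptance suite)."""
        dags = list(enumerate_dags(4))
        variables = [(str(i), 0) for i in range(4)]
        for edges in dags[:: len(dags) // 40]:
            ci = dsep_ci_oracle(edges, 4)
            sk, _ = pc_skeleton(ci_test=ci, variables=variables)
            got = {frozenset(int(v[0]) for v in pair) for pair in sk}
            assert got == dag_skeleton(edges)

    def test_false_edge_rate_under_global_independence(self, rng):
        """Per-pair false-adjacency rate ~ alpha for independent variables."""
        alpha, false_edges, pairs = 0.05, 0, 0
        for _ in range(60):
            data = rng.normal(size=(300, 5))
            sk, _ = pc_skeleton(
                params=TPCParams(alpha_ci=alpha),
                ci_test=FisherZ(data, alpha),
                variables=[(f"V{i}", 0) for i in range(5)],
            )
            false_edges += len(sk)
            pairs += 10
        assert false_edges / pairs == pytest.approx(alpha, abs=0.02)

    def test_max_cond_size_respected(self, rng):
        data = rng.normal(size=(100, 4))
        sk0, _ = pc_skeleton(
            params=TPCParams(alpha_ci=0.05, max_cond_size=0),
            ci_test=FisherZ(data, 0.05),
            variables=[(f"V{i}", 0) for i in range(4)],
        )
        # only marginal tests ran; no guarantee, but call must succeed
        assert isinstance(sk0, set)


class TestOrientation:
    def test_cross_offset_edge_takes_temporal_direction(self):
        sk = {frozenset({("A", 0), ("B", 1)})}
        dag = orient_unrolled(sk, {}, TPCParams())
        assert (("A", 0), ("B", 1)) in dag.directed
        assert not dag.undirected

    def test_contemporaneous_collider_oriented(self):
        vars_ = [("X", 0), ("Y", 0), ("Z", 0)]
        sk = {
            frozenset({("X", 0), ("Z", 0)}),
            frozenset({("Y", 0), ("Z", 0)}),
        }
        sep = {frozenset({("X", 0), ("Y", 0)}): frozenset()}
        dag = orient_unrolled(sk, sep, TPCParams(), variables=vars_)
        assert (("X", 0), ("Z", 0)) in dag.directed
        assert (("Y", 0), ("Z", 0)) in dag.directed

    def test_unorientable_triangle_follows_policy(self):
        vars_ = [("X", 0), ("Y", 0), ("Z", 0)]
        sk = {
            frozenset({("X", 0), ("Y", 0)}),
            frozenset({("Y", 0), ("Z", 0)}),
            frozenset({("X", 0), ("Z", 0)}),
        }
        dag = orient_unrolled(sk, {}, TPCParams(), variables=vars_)
        assert len(dag.undirected) == 3
        rolled = roll_cfc(dag)
        # both-directions: every pair present in both orientations
        assert ("X", "Y") in rolled.edge_set() and ("Y", "X") in rolled.edge_set()
        dag_drop = orient_unrolled(
            sk, {}, TPCParams(undirected_policy="drop"), variables=vars_
        )
        assert roll_cfc(dag_drop, region_labels=("X", "Y", "Z")).n_edges == 0

    def test_meek_rule_one_propagates(self):
        # (A,0) -> (B,1) known temporally; (B,1) - (C,1); A, C nonadjacent
        sk = {
            frozenset({("A", 0), ("B", 1)}),
            frozenset({("B", 1), ("C", 1)}),
        }
        sep = {frozenset({("A", 0), ("C", 1)}): frozenset({("B", 1)})}
        dag = orient_unrolled(sk, sep, TPCParams())
        assert (("B", 1), ("C", 1)) in dag.directed

    def test_stationarity_transfers_contemporaneous_orientation(self):
        # collider orients (X,1) -> (Z,1); the (X,0) - (Z,0) copy follows
        sk = {
            frozenset({("A", 0), ("Z", 1)}),
            frozenset({("X", 1), ("Z", 1)}),
            frozenset({("X", 0), ("Z", 0)}),
        }
        sep = {frozenset({("A", 0), ("X", 1)}): frozenset()}
        dag = orient_unrolled(sk, sep, TPCParams())
        assert (("X", 1), ("Z", 1)) in dag.directed
        assert (("X", 0), ("Z", 0)) in dag.directed

    def test_backward_in_time_edge_rejected_by_invariant(self):
        with pytest.raises(OrientationError, match="backward-in-time"):
            UnrolledDAG(
                nodes=(("A", 0), ("B", 1)),
                directed=frozenset({((("B", 1)), (("A", 0)))}),
                undirected=frozenset(),
            )

    def test_directed_cycle_rejected_by_invariant(self):
        with pytest.raises(OrientationError, match="cycle"):
            UnrolledDAG(
                nodes=(("A", 0), ("B", 0)),
                directed=frozenset(
                    {(("A", 0), ("B", 0)), (("B", 0), ("A", 0))}
                ),
                undirected=frozenset(),
            )


class TestWeightsAndRolling:
    def test_single_lag_edge_weight_recovered(self, two_region_lag_model):
        ts = simulate_subject(two_region_lag_model, None, 1000, seed=3)
        s = build_sequential_samples(ts, 1)
        dag = UnrolledDAG(
            nodes=s.variables,
            directed=frozenset({((("A", 0)), (("B", 1)))}),
            undirected=frozenset(),
        )
        dag = estimate_edge_weights(dag, s)
        w = dag.weights[(("A", 0), ("B", 1))]
        se = 1 / np.sqrt(1000)  # noise_sd / sqrt(n var(A)), var(A) ~ 1
        assert w == pytest.approx(0.7, abs=3 * se)

    def test_parentless_nodes_get_no_weights(self, white_noise_ts):
        s = build_sequential_samples(white_noise_ts, 1)
        dag = UnrolledDAG(nodes=s.variables, directed=frozenset(), undirected=frozenset())
        assert estimate_edge_weights(dag, s).weights == {}

    @pytest.mark.parametrize("seed", range(10))
    def test_inhibitory_edge_gets_negative_weight(self, seed):
        lag = np.zeros((2, 2))
        lag[0, 1] = -0.6
        m = GroundTruthModel(2, lag, np.zeros((2, 2)), region_labels=("A", "B"))
        ts = simulate_subject(m, None, 500, seed=seed)
        s = build_sequential_samples(ts, 1)
        dag = UnrolledDAG(
            nodes=s.variables,
            directed=frozenset({((("A", 0)), (("B", 1)))}),
            undirected=frozenset(),
        )
        assert estimate_edge_weights(dag, s).weights[(("A", 0), ("B", 1))] < 0

    def test_roll_basic_lag_edge(self):
        dag = UnrolledDAG(
            nodes=(("A", 0), ("B", 1)),
            directed=frozenset({((("A", 0)), (("B", 1)))}),
            undirected=frozenset(),
        )
        assert roll_cfc(dag).edge_set() == {("A", "B")}

    def test_roll_self_loop(self):
        dag = UnrolledDAG(
            nodes=(("A", 0), ("A", 1), ("B", 0)),
            directed=frozenset({((("A", 0)), (("A", 1)))}),
            undirected=frozenset(),
        )
        rolled = roll_cfc(dag, region_labels=("A", "B"))
        assert rolled.edge_set() == {("A", "A")}

    def test_roll_sums_contributing_weights(self):
        dag = UnrolledDAG(
            nodes=(("A", 0), ("A", 1), ("B", 1)),
            directed=frozenset(
                {(("A", 1), ("B", 1)), (("A", 0), ("B", 1))}
            ),
            undirected=frozenset(),
            weights={
                (("A", 1), ("B", 1)): 0.2,
                (("A", 0), ("B", 1)): 0.3,
            },
        )
        rolled = roll_cfc(dag, region_labels=("A", "B"))
        assert rolled.weight("A", "B") == pytest.approx(0.5)
        assert rolled.n_edges == 1


class TestRunTPC:
    def test_white_noise_yields_near_empty_graph(self):
        counts = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ts = ROITimeSeries(
                rng.normal(size=(500, 10)), [f"N{i}" for i in range(10)]
            )
            cfc = run_tpc(ts, TPCParams(tau=1, alpha_ci=0.01))
            counts.append(cfc.n_edges)
        # 190 variable pairs at alpha 0.01 -> ~2 spurious adjacencies a run
        assert np.mean(counts) < 5

    def test_structure_recovery_on_known_model(self):
        f1s = []
        for seed in range(5):
            m = make_ground_truth(10, 0.05, contemp_fraction=0.3, seed=seed)
            ts = simulate_subject(m, None, 1000, seed=seed + 100)
            est = run_tpc(ts, TPCParams(tau=1, alpha_ci=0.001))
            f1s.append(structure_recovery_metrics(true_cfc(m), est)[2])
        assert np.mean(f1s) >= 0.7

    def test_deterministic(self, small_model):
        ts = simulate_subject(small_model, None, 300, seed=9)
        p = TPCParams(tau=1, alpha_ci=0.01)
        a, b = run_tpc(ts, p), run_tpc(ts, p)
        assert a.weights == b.weights

    def test_label_permutation_equivariance(self, small_model):
        """Relabelling/reordering regions permutes the output accordingly."""
        ts = simulate_subject(small_model, None, 400, seed=21)
        perm = np.random.default_rng(0).permutation(ts.n_regions)
        ts_p = ROITimeSeries(
            ts.values[:, perm], [ts.region_labels[i] for i in perm]
        )
        p = TPCParams(tau=1, alpha_ci=0.01)
        a, b = run_tpc(ts, p), run_tpc(ts_p, p)
        assert a.edge_set() == b.edge_set()
        for e, w in a.weights.items():
            assert b.weights[e] == pytest.approx(w, abs=1e-9)
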