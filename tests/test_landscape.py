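"""Saddle searches, connectivity and disconnectivity graphs on toy landscapes."""

import itertools

import networkx as nx
import numpy as np
import pytest

from mlscape import (
    MinimaDatabase,
    QuadraticCost,
    build_disconnectivity,
    connect_database,
    descend_paths,
    dneb_candidates,
    hybrid_ef_refine,
    lbfgs_minimize,
    minimax_barrier,
    toy_landscape,
)
from mlscape.errors import DisconnectedError, NotASaddleError
from mlscape.optimize import minimize

SADDLE_3W = 1.0 / np.sqrt(3.0)  # saddles of w^2(w^2-1)^2
E_SADDLE_3W = 4.0 / 27.0


def tight_min(oracle, start, max_step=0.1):
    return lbfgs_minimize(oracle, np.atleast_1d(np.asarray(start, float)),
                          tol=1e-10, max_step=max_step)


@pytest.fixture
def double_well_minima():
    dw = toy_landscape("double_well")
    return dw, tight_min(dw, [-1.1]), tight_min(dw, [0.9])


@pytest.fixture
def three_well_db():
    tw = toy_landscape("three_well")
    db = MinimaDatabase()
    for s in (-0.95, 0.05, 0.95):
        db.add(tight_min(tw, [s]))
    return tw, db


class TestDNEB:
    def test_double_well_candidate_near_saddle(self, double_well_minima):
        dw, ma, mb = double_well_minima
        cands = dneb_candidates(dw, ma, mb, n_images=7)
        assert len(cands) >= 1
        assert min(abs(c[0]) for c in cands) < 0.2

    def test_coincident_endpoints_rejected(self, double_well_minima):
        dw, ma, _ = double_well_minima
        with pytest.raises(Exception):
            dneb_candidates(dw, ma, ma, n_images=5)

    def test_two_dim_candidate_near_origin(self):
        td = toy_landscape("two_dim_double_well")
        ma = tight_min(td, [-1.0, 0.0])
        mb = tight_min(td, [1.0, 0.0])
        cands = dneb_candidates(td, ma, mb, n_images=11)
        # dense-grid oracle: the only saddle of this surface is (0, 0)
        assert min(np.linalg.norm(c) for c in cands) < 0.2


class TestHybridEF:
    def test_double_well_saddle_exact(self):
        dw = toy_landscape("double_well")
        ts = hybrid_ef_refine(dw, np.array([0.2]), tol=1e-10)
        assert ts.W[0] == pytest.approx(0.0, abs=1e-8)
        assert ts.E == pytest.approx(1.0, abs=1e-10)
        assert ts.neg_eigenvalue == pytest.approx(-4.0, abs=1e-6)

    def test_exact_saddle_returns_immediately(self):
        dw = toy_landscape("double_well")
        ts = hybrid_ef_refine(dw, np.array([0.0]), tol=1e-10)
        assert ts.W[0] == 0.0

    def test_two_dim_saddle_and_eigenvector(self):
        td = toy_landscape("two_dim_double_well")
        ts = hybrid_ef_refine(td, np.array([0.1, 0.3]), tol=1e-10)
        assert np.allclose(ts.W, [0.0, 0.0], atol=1e-7)
        # analytic Hessian at the saddle is diag(-4, 2)
        assert ts.neg_eigenvalue == pytest.approx(-4.0, abs=1e-6)
        assert abs(ts.neg_eigenvector[0]) == pytest.approx(1.0, abs=1e-8)

    def test_minimum_input_raises_not_a_saddle(self, small_data):
        X, c = small_data
        q = QuadraticCost(3, X, c, 1e-4).as_oracle()
        m = minimize(q, np.zeros(q.dim), tol=1e-10)
        with pytest.raises(NotASaddleError) as e:
            hybrid_ef_refine(q, m.W, tol=1e-8)
        assert e.value.index == 0


class TestDescend:
    def test_double_well_endpoints(self):
        dw = toy_landscape("double_well")
        ts = hybrid_ef_refine(dw, np.array([0.1]), tol=1e-10)
        ma, mb = descend_paths(dw, ts)
        ends = sorted([ma.W[0], mb.W[0]])
        assert ends[0] == pytest.approx(-1.0, abs=1e-8)
        assert ends[1] == pytest.approx(1.0, abs=1e-8)

    def test_endpoint_energies_below_saddle(self):
        tw = toy_landscape("three_well")
        ts = hybrid_ef_refine(tw, np.array([0.5]), tol=1e-10)
        ma, mb = descend_paths(tw, ts)
        assert ma.E < ts.E and mb.E < ts.E


class TestConnect:
    def test_double_well_database(self, double_well_minima):
        dw, ma, mb = double_well_minima
        db = MinimaDatabase()
        db.add(ma)
        db.add(mb)
        spdb = connect_database(dw, db, budget=10)
        assert spdb.connected
        assert len(spdb.transition_states) == 1
        assert spdb.transition_states[0].E == pytest.approx(1.0, abs=1e-8)

    def test_single_minimum_trivially_connected(self):
        dw = toy_landscape("double_well")
        db = MinimaDatabase()
        db.add(tight_min(dw, [0.9]))
        spdb = connect_database(dw, db, budget=10)
        assert spdb.connected
        assert spdb.transition_states == []

    def test_three_well_finds_both_analytic_saddles(self, three_well_db):
        tw, db = three_well_db
        spdb = connect_database(tw, db, budget=20)
        assert spdb.connected
        assert len(spdb.minima) == 3
        positions = sorted(float(t.W[0]) for t in spdb.transition_states)
        assert positions[0] == pytest.approx(-SADDLE_3W, abs=1e-6)
        assert positions[-1] == pytest.approx(SADDLE_3W, abs=1e-6)
        for t in spdb.transition_states:
            assert t.E == pytest.approx(E_SADDLE_3W, abs=1e-10)

    def test_every_stored_ts_has_index_one(self, three_well_db):
        tw, db = three_well_db
        spdb = connect_database(tw, db, budget=20)
        for t in spdb.transition_states:
            vals = np.linalg.eigvalsh(tw.hess(t.W))
            assert int(np.sum(vals < 0)) == 1


class TestDisconnectivity:
    def test_double_well_merges_at_barrier(self, double_well_minima):
        dw, ma, mb = double_well_minima
        db = MinimaDatabase()
        db.add(ma)
        db.add(mb)
        spdb = connect_database(dw, db, budget=10)
        dg = build_disconnectivity(spdb, delta_E=0.25)
        assert dg.n_leaves == 2
        # barrier is exactly 1: first threshold >= 1 is 1.0 on the 0.25 grid
        assert dg.leaf_merge_level(0, 1) == pytest.approx(1.0, abs=1e-8)

    def test_single_minimum_tree(self):
        dw = toy_landscape("double_well")
        db = MinimaDatabase()
        db.add(tight_min(dw, [1.05]))
        spdb = connect_database(dw, db, budget=5)
        dg = build_disconnectivity(spdb, delta_E=0.1)
        assert dg.n_leaves == 1
        assert dg.root.is_leaf

    def test_three_well_merge_levels_match_brute_force(self, three_well_db):
        tw, db = three_well_db
        spdb = connect_database(tw, db, budget=20)
        dg = build_disconnectivity(spdb, delta_E=0.02)
        assert dg.n_leaves == 3
        # brute-force superbasin oracle at every level: connected components
        # of the TS graph with edges below the threshold
        g = spdb.graph()
        prev_parts = None
        for L in dg.levels:
            sub = nx.Graph()
            sub.add_nodes_from(g.nodes)
            sub.add_edges_from(
                (u, v) for u, v, d in g.edges(data=True) if d["energy"] <= L
            )
            parts = {frozenset(cc) for cc in nx.connected_components(sub)}
            for i, j in itertools.combinations(range(3), 2):
                together = any(i in p and j in p for p in parts)
                assert together == (dg.leaf_merge_level(i, j) <= L + 1e-12)
            if prev_parts is not None:  # merging is monotone in the level
                for p_old in prev_parts:
                    assert any(p_old <= p_new for p_new in parts)
            prev_parts = parts

    def test_disconnected_database_raises(self, double_well_minima):
        from mlscape import StationaryPointDatabase
        dw, ma, mb = double_well_minima
        db = MinimaDatabase()
        db.add(ma)
        db.add(mb)
        spdb = StationaryPointDatabase(minima=db)  # no transition states
        with pytest.raises(DisconnectedError):
            build_disconnectivity(spdb, 0.1)
        with pytest.raises(DisconnectedError):
            minimax_barrier(spdb, 1)


class TestMinimaxBarrier:
    def test_global_minimum_barrier_is_zero(self, three_well_db):
        tw, db = three_well_db
        spdb = connect_database(tw, db, budget=20)
        assert minimax_barrier(spdb, 0) == 0.0

    def test_double_well_barrier_is_one(self, double_well_minima):
        dw, ma, mb = double_well_minima
        db = MinimaDatabase()
        db.add(ma)
        db.add(mb)
        spdb = connect_database(dw, db, budget=10)
        assert minimax_barrier(spdb, 1) == pytest.approx(1.0, abs=1e-8)

    def test_matches_exhaustive_path_enumeration(self, three_well_db):
        tw, db = three_well_db
        spdb = connect_database(tw, db, budget=20)
        g = spdb.graph()
        for m in range(len(spdb.minima)):
            if m == 0:
                continue
            # oracle: min over all simple paths of the max edge energy
            best = min(
                max(g[u][v]["energy"] for u, v in zip(path[:-1], path[1:]))
                for path in nx.all_simple_paths(g, m, 0)
            )
            assert minimax_barrier(spdb, m) == pytest.approx(
                best - spdb.minima[m].E, abs=1e-12
            )
            assert minimax_barrier(spdb, m) >= 0.0
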