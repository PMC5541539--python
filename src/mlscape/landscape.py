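"""Transition states and disconnectivity graphs for smooth cost landscapes.

A transition state is an index-1 saddle: a stationary point whose Hessian has
exactly one negative eigenvalue.  Steepest-descent paths leaving it along the
unique downhill direction connect two local minima, and the set of minima plus
transition states forms the analogue of a kinetic transition network.  The
machinery here mirrors the standard molecular-landscape toolchain at desk
scale: a doubly-nudged elastic band proposes saddle candidates between minima
pairs, hybrid eigenvector-following refines them to tight tolerance, and the
resulting database is rendered as a disconnectivity graph — the tree showing
at which cost thresholds groups of minima (superbasins) become mutually
accessible.  Single-funnel organization — every minimum joined to the global
minimum over low downhill barriers — is the signature of landscapes on which
global optimization is easy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import (
    DisconnectedError,
    DivergenceError,
    InvalidSpecError,
    NonConvergenceError,
    NotASaddleError,
)
from .optimize import MinimaDatabase, Minimum, lbfgs_minimize, lbfgs_relax_force, minimize
from .oracle import CostOracle


@dataclass
class TransitionState:
    """An index-1 saddle with its downhill eigendirection and endpoints."""

    W: np.ndarray
    E: float
    neg_eigenvalue: float
    neg_eigenvector: np.ndarray
    min_pair: tuple[int, int] = (-1, -1)
    degenerate: bool = False  # both descent paths reached the same minimum


@dataclass
class StationaryPointDatabase:
    """Minima plus the transition states connecting them."""

    minima: MinimaDatabase
    transition_states: list[TransitionState] = field(default_factory=list)
    connected: bool = False

    def graph(self) -> nx.Graph:
        """Connectivity graph: nodes = minima indices, edge weight = TS cost.

        Parallel transition states between the same pair keep the lowest one.
        """
        g = nx.Graph()
        g.add_nodes_from(range(len(self.minima)))
        for ts in self.transition_states:
            i, j = ts.min_pair
            if i == j:
                continue
            if g.has_edge(i, j):
                if ts.E < g[i][j]["energy"]:
                    g[i][j]["energy"] = ts.E
            else:
                g.add_edge(i, j, energy=ts.E)
        return g

    def components(self) -> list[set[int]]:
        return [set(c) for c in nx.connected_components(self.graph())]


# ---------------------------------------------------------------------------
# Doubly-nudged elastic band


def dneb_candidates(
    oracle: CostOracle,
    min_a: Minimum,
    min_b: Minimum,
    n_images: int = 11,
    spring_k: float = 1.0,
    dneb_fraction: float = 0.1,
    tol: float = 1e-3,
    max_iter: int = 3000,
) -> list[np.ndarray]:
    """Saddle candidates from a relaxed elastic band between two minima.

    ``n_images`` interior images are interpolated linearly between the fixed
    endpoints and relaxed under the doubly-nudged force: the component of the
    true gradient perpendicular to the path, the spring gradient component
    parallel to the path, plus a retained fraction of the perpendicular
    spring component (which stabilizes the band against corner cutting).
    Returns the interior images that are chain-local maxima in cost.
    """
    if n_images < 1:
        raise InvalidSpecError("need at least one interior image")
    wa, wb = np.asarray(min_a.W, float), np.asarray(min_b.W, float)
    if np.allclose(wa, wb):
        raise InvalidSpecError("band endpoints coincide")
    dim = wa.size
    ts = np.linspace(0.0, 1.0, n_images + 2)[1:-1]
    band0 = np.array([wa + t * (wb - wa) for t in ts])  # (n_images, dim)

    def force(flat: np.ndarray) -> np.ndarray:
        imgs = flat.reshape(n_images, dim)
        chain = np.vstack([wa[None, :], imgs, wb[None, :]])
        out = np.empty_like(imgs)
        for i in range(1, n_images + 1):
            tau = chain[i + 1] - chain[i - 1]
            nt = np.linalg.norm(tau)
            tau = tau / nt if nt > 0 else tau
            g = oracle.grad(chain[i])
            g_perp = g - np.dot(g, tau) * tau
            g_spr = spring_k * (2.0 * chain[i] - chain[i + 1] - chain[i - 1])
            spr_par = np.dot(g_spr, tau) * tau
            spr_perp = g_spr - spr_par
            out[i - 1] = g_perp + spr_par + dneb_fraction * spr_perp
        return out.ravel()

    flat = lbfgs_relax_force(force, band0.ravel(), tol=tol, max_iter=max_iter)
    imgs = flat.reshape(n_images, dim)
    energies = np.array(
        [oracle.f(wa)] + [oracle.f(x) for x in imgs] + [oracle.f(wb)]
    )
    if not np.all(np.isfinite(energies)):
        raise DivergenceError("band relaxation produced non-finite cost")
    cands = [
        imgs[i - 1].copy()
        for i in range(1, n_images + 1)
        if energies[i] >= energies[i - 1] and energies[i] >= energies[i + 1]
    ]
    return cands


# ---------------------------------------------------------------------------
# Hybrid eigenvector-following


def _lowest_eigpair(H: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = np.linalg.eigh(H)
    return float(vals[0]), vecs[:, 0].copy()


def hybrid_ef_refine(
    oracle: CostOracle,
    candidate: np.ndarray,
    tol: float = 1e-10,
    max_outer: int = 300,
    max_uphill_step: float = 0.3,
    subspace_iters: int = 30,
) -> TransitionState:
    """Refine a candidate to an index-1 saddle.

    Each outer iteration takes a bounded uphill Newton step along the
    smallest-eigenvalue Hessian direction and then minimizes in the
    orthogonal subspace (L-BFGS with the gradient and steps projected off
    that direction).  Converges when the RMS of the *full* gradient drops
    below ``tol``; the Hessian index is then verified to be exactly 1.
    The smallest eigenpair comes from a dense eigendecomposition — all
    landscapes treated here are desk-scale.
    """
    if oracle.hess is None:
        raise InvalidSpecError("saddle refinement requires a Hessian oracle")
    w = np.asarray(candidate, dtype=float).copy()
    if not np.all(np.isfinite(w)):
        raise InvalidSpecError("non-finite candidate")
    sqrtd = math.sqrt(oracle.dim)

    for _ in range(max_outer):
        g = oracle.grad(w)
        if np.linalg.norm(g) / sqrtd <= tol:
            return _certify_saddle(oracle, w)
        H = oracle.hess(w)
        lam1, v = _lowest_eigpair(H)
        gv = float(np.dot(g, v))
        if lam1 < -1e-12:
            step = -gv / lam1  # Newton step along the soft mode: uphill to the saddle
        else:
            # no negative curvature yet: push along the softest mode, uphill
            step = math.copysign(max_uphill_step * 0.5, gv if gv != 0 else 1.0)
        step = max(-max_uphill_step, min(max_uphill_step, step))
        w = w + step * v

        # minimize in the subspace orthogonal to v
        def proj_fg(x, v=v):
            f, gg = oracle.value_and_grad(x)
            return f, gg - np.dot(gg, v) * v

        sub = CostOracle(
            f=lambda x: proj_fg(x)[0],
            grad=lambda x: proj_fg(x)[1],
            dim=oracle.dim,
        )
        try:
            res = lbfgs_minimize(sub, w, tol=max(tol, 1e-3 * abs(step)),
                                 max_iter=subspace_iters, max_step=max_uphill_step)
            w = res.W
        except NonConvergenceError as err:  # partial subspace relaxation is fine
            if err.best is not None:
                w = err.best.W
    raise NonConvergenceError(
        f"saddle refinement did not converge in {max_outer} outer iterations",
        best=w,
    )


def _certify_saddle(oracle: CostOracle, w: np.ndarray) -> TransitionState:
    H = oracle.hess(w)
    vals, vecs = np.linalg.eigh(H)
    n_neg = int(np.sum(vals < 0.0))
    if n_neg != 1:
        raise NotASaddleError(
            f"converged stationary point has Hessian index {n_neg}, not 1",
            index=n_neg, point=w,
        )
    return TransitionState(
        W=w.copy(),
        E=float(oracle.f(w)),
        neg_eigenvalue=float(vals[0]),
        neg_eigenvector=vecs[:, 0].copy(),
    )


def descend_paths(
    oracle: CostOracle,
    ts: TransitionState,
    displacement: float | None = None,
    tol: float = 1e-10,
    max_iter: int = 20000,
) -> tuple[Minimum, Minimum]:
    """The two minima reached by minimizing off either side of a saddle.

    Displaces ``+-displacement`` along the downhill eigenvector (default
    1e-3 |W| with floor 1e-4) and minimizes at the tight tolerance.  The two
    endpoints may be the same minimum — a degenerate rearrangement — which
    the caller flags.
    """
    if displacement is None:
        displacement = max(1e-3 * float(np.linalg.norm(ts.W)), 1e-4)
    v = ts.neg_eigenvector
    m_plus = minimize(oracle, ts.W + displacement * v, tol=tol, max_iter=max_iter)
    m_minus = minimize(oracle, ts.W - displacement * v, tol=tol, max_iter=max_iter)
    return m_minus, m_plus


# ---------------------------------------------------------------------------
# Database connection


def connect_database(
    oracle: CostOracle,
    db: MinimaDatabase,
    budget: int = 50,
    n_images: int = 11,
    tight_tol: float = 1e-10,
    band_tol: float = 1e-3,
) -> StationaryPointDatabase:
    """Grow a connected stationary-point database from a set of minima.

    Repeatedly picks the closest-in-parameter-space pair of minima lying in
    different connected components, runs band + eigenvector-following +
    descent on it, and adds the transition states (and any newly discovered
    minima) found.  Stops at a single component or when ``budget`` pair
    attempts are exhausted.  Endpoint identification is by parameter-space
    proximity, so exactly degenerate minima keep separate identities.
    """
    if len(db) == 0:
        raise InvalidSpecError("empty minima database")
    spdb = StationaryPointDatabase(minima=db)
    if len(db) == 1:
        spdb.connected = True
        return spdb

    attempted: set[tuple[int, int]] = set()
    for _ in range(budget):
        comps = spdb.components()
        if len(comps) == 1:
            break
        pair = _nearest_unconnected_pair(spdb, comps, attempted)
        if pair is None:
            break
        attempted.add(pair)
        i, j = pair
        try:
            cands = dneb_candidates(
                oracle, spdb.minima[i], spdb.minima[j],
                n_images=n_images, tol=band_tol,
            )
        except (DivergenceError, NonConvergenceError):
            continue
        for cand in cands:
            try:
                ts = hybrid_ef_refine(oracle, cand, tol=tight_tol)
                ma, mb = descend_paths(oracle, ts, tol=tight_tol)
            except (NotASaddleError, NonConvergenceError, DivergenceError):
                continue
            ia = _resolve_minimum(spdb, ma, attempted)
            ib = _resolve_minimum(spdb, mb, attempted)
            ts.min_pair = (ia, ib)
            ts.degenerate = ia == ib
            spdb.transition_states.append(ts)
    spdb.connected = len(spdb.components()) == 1
    return spdb


def _nearest_unconnected_pair(spdb, comps, attempted) -> tuple[int, int] | None:
    best, best_d = None, np.inf
    for a in range(len(comps)):
        for b in range(a + 1, len(comps)):
            for i in comps[a]:
                for j in comps[b]:
                    key = (min(i, j), max(i, j))
                    if key in attempted:
                        continue
                    d = float(np.linalg.norm(spdb.minima[i].W - spdb.minima[j].W))
                    if d < best_d:
                        best, best_d = key, d
    return best


def _resolve_minimum(spdb, m: Minimum, attempted: set) -> int:
    """Map a descent endpoint onto a database index, inserting if new.

    Insertion into the sorted minima list can shift indices, so stored
    transition-state pairs and the attempted-pair set are remapped.
    """
    idx = spdb.minima.nearest_by_params(m.W)
    if idx is not None:
        return idx
    pos, inserted = spdb.minima.add(m)
    if inserted:
        def shift(k: int) -> int:
            return k + 1 if k >= pos else k
        for ts in spdb.transition_states:
            ts.min_pair = (shift(ts.min_pair[0]), shift(ts.min_pair[1]))
        remapped = {(shift(a), shift(b)) for a, b in attempted}
        attempted.clear()
        attempted.update(remapped)
    return pos


# ---------------------------------------------------------------------------
# Disconnectivity graphs and barriers


@dataclass
class DGNode:
    """A node of the disconnectivity tree.

    Leaves carry a single minimum index at its cost; internal nodes record
    the threshold level at which their children's superbasins merge.
    """

    level: float
    minima: tuple[int, ...]
    children: tuple["DGNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class DisconnectivityGraph:
    levels: np.ndarray
    root: DGNode

    @property
    def n_leaves(self) -> int:
        def count(node: DGNode) -> int:
            return 1 if node.is_leaf else sum(count(c) for c in node.children)
        return count(self.root)

    def leaf_merge_level(self, i: int, j: int) -> float:
        """Lowest threshold at which minima ``i`` and ``j`` share a superbasin."""
        def walk(node: DGNode) -> float | None:
            if i in node.minima and j in node.minima:
                for c in node.children:
                    r = walk(c)
                    if r is not None:
                        return r
                return node.level
            return None
        r = walk(self.root)
        if r is None:
            raise InvalidSpecError(f"minima {i} and {j} never merge")
        return r


def build_disconnectivity(spdb: StationaryPointDatabase, delta_E: float) -> DisconnectivityGraph:
    """Superbasin tree of a connected database at thresholds E_min + i dE.

    At each level minima are partitioned into superbasins — groups mutually
    reachable through transition states at or below the threshold.  Children
    of an internal node are ordered by basin size (descending) then energy.
    """
    if not delta_E > 0:
        raise InvalidSpecError("delta_E must be positive")
    comps = spdb.components()
    if len(comps) != 1:
        raise DisconnectedError(comps)
    g = spdb.graph()
    n = len(spdb.minima)
    e_min = spdb.minima[0].E
    e_top = max((ts.E for ts in spdb.transition_states), default=e_min)
    n_levels = max(1, int(math.ceil((e_top - e_min) / delta_E - 1e-12)))
    levels = e_min + delta_E * np.arange(1, n_levels + 1)

    nodes: dict[frozenset, DGNode] = {
        frozenset([i]): DGNode(level=spdb.minima[i].E, minima=(i,)) for i in range(n)
    }
    current = set(nodes.keys())
    for L in levels:
        sub = nx.Graph()
        sub.add_nodes_from(range(n))
        sub.add_edges_from(
            (u, v) for u, v, d in g.edges(data=True) if d["energy"] <= L
        )
        for comp in nx.connected_components(sub):
            members = [grp for grp in current if grp <= comp]
            if len(members) > 1:
                merged = frozenset().union(*members)
                children = sorted(
                    (nodes[grp] for grp in members),
                    key=lambda nd: (-len(nd.minima), nd.level),
                )
                nodes[merged] = DGNode(
                    level=float(L), minima=tuple(sorted(merged)),
                    children=tuple(children),
                )
                current -= set(members)
                current.add(merged)
    assert len(current) == 1, "connected database must merge to a single root"
    root = nodes[next(iter(current))]
    return DisconnectivityGraph(levels=levels, root=root)


def minimax_barrier(spdb: StationaryPointDatabase, m: int) -> float:
    """Downhill barrier from minimum ``m`` toward the global minimum.

    Over all paths through the transition-state graph from ``m`` to the
    global minimum, the smallest value of the highest transition-state cost
    along the path, minus the cost of ``m``.  Low values for every minimum
    are the quantitative signature of a single-funnel landscape.  Computed
    via the minimum spanning tree, whose unique path realizes the minimax
    edge value.
    """
    comps = spdb.components()
    if len(comps) != 1:
        raise DisconnectedError(comps)
    if m == 0:
        return 0.0
    g = spdb.graph()
    mst = nx.minimum_spanning_tree(g, weight="energy")
    path = nx.shortest_path(mst, source=m, target=0)
    peak = max(g[u][v]["energy"] for u, v in zip(path[:-1], path[1:]))
    return float(peak - spdb.minima[m].E)
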