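"""Local minimization and basin-hopping global optimization.

Basin-hopping explores a cost landscape by taking steps *between local
minima*: perturb the coordinates of the current minimum, re-minimize, and
accept or reject the move with a Metropolis criterion at a fictitious
temperature (downhill moves are always accepted).  Every distinct minimum
encountered is tightened to a stringent gradient tolerance and stored, so a
run yields a database of local minima rather than a single point — the raw
material for transition-state searches and disconnectivity graphs.

The local minimizer is a hand-rolled limited-memory BFGS: the convergence
contract here is on the root-mean-square gradient (|g| / sqrt(dim), matching
the dimension-independent thresholds 1e-6 loose / 1e-10 tight used for the
landscape databases), and the same core is reused for elastic-band relaxation
and the subspace minimization inside saddle refinement, where the "gradient"
fed in is a projected force rather than the derivative of a scalar.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass

import numpy as np

from .errors import DivergenceError, InvalidSpecError, NonConvergenceError
from .oracle import CostOracle


@dataclass
class Minimum:
    """A converged local minimum: parameters, cost, and convergence info."""

    W: np.ndarray
    E: float
    rms_grad: float
    n_iter: int

    def copy(self) -> "Minimum":
        return Minimum(self.W.copy(), self.E, self.rms_grad, self.n_iter)


@dataclass
class BasinHopConfig:
    """Knobs of a basin-hopping run.

    ``loose_tol`` is the RMS-gradient threshold for the in-loop minimizations;
    every distinct minimum is re-converged at ``tight_tol`` before storage,
    which is tight enough that distinct minima can be told apart by comparing
    cost values alone.
    """

    n_steps: int = 1000
    step_size: float = 1.0
    temperature: float = 1.0
    loose_tol: float = 1e-6
    tight_tol: float = 1e-10
    dedupe_tol: float = 1e-8
    seed: int = 0
    max_iter: int = 20000

    def __post_init__(self):
        if self.loose_tol <= 0 or self.tight_tol <= 0:
            raise InvalidSpecError("tolerances must be positive")
        if self.tight_tol >= self.loose_tol:
            raise InvalidSpecError("tight_tol must be below loose_tol")
        if self.step_size < 0 or self.temperature <= 0:
            raise InvalidSpecError("step_size >= 0 and temperature > 0 required")


# ---------------------------------------------------------------------------
# L-BFGS


def lbfgs_minimize(
    oracle: CostOracle,
    w0: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 20000,
    memory: int = 10,
    max_step: float = 1.0,
) -> Minimum:
    """Limited-memory BFGS to an RMS-gradient tolerance.

    Two-loop recursion with memory ``memory``, an Armijo backtracking line
    search with quadratic/cubic interpolation, and a cap ``max_step`` on the
    Euclidean step length per iteration.  Raises :class:`DivergenceError` on a
    non-finite cost and :class:`NonConvergenceError` (carrying the best point)
    at the iteration cap.
    """
    w = np.asarray(w0, dtype=float).copy()
    if not np.all(np.isfinite(w)):
        raise DivergenceError("non-finite starting point")
    f, g = oracle.value_and_grad(w)
    if not np.isfinite(f):
        raise DivergenceError("non-finite cost at starting point")
    sqrtd = math.sqrt(oracle.dim)

    s_hist: list[np.ndarray] = []
    y_hist: list[np.ndarray] = []
    rho_hist: list[float] = []

    best = (f, w.copy(), float(np.linalg.norm(g) / sqrtd))
    for it in range(max_iter):
        rms = np.linalg.norm(g) / sqrtd
        if f < best[0]:
            best = (f, w.copy(), rms)
        if rms <= tol:
            return Minimum(W=w, E=float(f), rms_grad=float(rms), n_iter=it)

        d = _two_loop(g, s_hist, y_hist, rho_hist)
        if np.dot(d, g) >= 0:  # not a descent direction: reset memory
            s_hist.clear(); y_hist.clear(); rho_hist.clear()
            d = -g
        dn = np.linalg.norm(d)
        if dn > max_step:
            d = d * (max_step / dn)

        f_new, w_new, g_new, ok = _armijo(oracle, w, f, g, d)
        if not ok:
            # line search stalled: drop the memory and retry steepest descent
            s_hist.clear(); y_hist.clear(); rho_hist.clear()
            d = -g / max(1.0, np.linalg.norm(g) / max_step)
            f_new, w_new, g_new, ok = _armijo(oracle, w, f, g, d)
            if not ok:
                rms = float(np.linalg.norm(g) / sqrtd)
                if rms <= tol * 10:
                    # numerically at the floor of what the cost resolves
                    return Minimum(W=w, E=float(f), rms_grad=rms, n_iter=it)
                raise NonConvergenceError(
                    f"line search failed at iteration {it} (rms grad {rms:.3e})",
                    best=Minimum(W=best[1], E=best[0], rms_grad=best[2], n_iter=it),
                )
        s = w_new - w
        y = g_new - g
        sy = float(np.dot(s, y))
        if sy > 1e-12 * float(np.linalg.norm(s) * np.linalg.norm(y) + 1e-300):
            s_hist.append(s); y_hist.append(y); rho_hist.append(1.0 / sy)
            if len(s_hist) > memory:
                s_hist.pop(0); y_hist.pop(0); rho_hist.pop(0)
        w, f, g = w_new, f_new, g_new
        if not np.isfinite(f):
            raise DivergenceError("cost became non-finite during minimization")

    rms = float(np.linalg.norm(g) / sqrtd)
    raise NonConvergenceError(
        f"no convergence in {max_iter} iterations (rms grad {rms:.3e})",
        best=Minimum(W=best[1], E=best[0], rms_grad=best[2], n_iter=max_iter),
    )


def _two_loop(g, s_hist, y_hist, rho_hist) -> np.ndarray:
    q = -g.copy()
    alphas = []
    for s, y, rho in zip(reversed(s_hist), reversed(y_hist), reversed(rho_hist)):
        a = rho * np.dot(s, q)
        alphas.append(a)
        q -= a * y
    if s_hist:
        s, y = s_hist[-1], y_hist[-1]
        q *= np.dot(s, y) / np.dot(y, y)
    for (s, y, rho), a in zip(zip(s_hist, y_hist, rho_hist), reversed(alphas)):
        b = rho * np.dot(y, q)
        q += (a - b) * s
    return q


def _armijo(oracle, w, f, g, d, c1: float = 1e-4, max_backtracks: int = 40):
    """Backtracking line search with quadratic interpolation."""
    gd = float(np.dot(g, d))
    alpha = 1.0
    for _ in range(max_backtracks):
        w_new = w + alpha * d
        f_new, g_new = oracle.value_and_grad(w_new)
        if np.isfinite(f_new) and f_new <= f + c1 * alpha * gd:
            return f_new, w_new, g_new, True
        # quadratic interpolation on f(0), f'(0), f(alpha); clamp to [0.1, 0.5]a
        if np.isfinite(f_new):
            denom = 2.0 * (f_new - f - gd * alpha)
            a_q = -gd * alpha**2 / denom if denom > 0 else 0.5 * alpha
            alpha = min(max(a_q, 0.1 * alpha), 0.5 * alpha)
        else:
            alpha *= 0.1
    return f, w, g, False


def newton_polish(
    oracle: CostOracle,
    w0: np.ndarray,
    tol: float,
    max_iter: int = 60,
    max_step: float = 1.0,
    n_iter_offset: int = 0,
) -> Minimum:
    """Modified-Newton refinement to a stringent gradient tolerance.

    Solves the Newton system through an eigendecomposition with the spectrum
    clamped positive, which both guarantees a descent direction away from the
    minimum and handles the near-singular directions a small ridge
    coefficient leaves in the cost (eigenvalues of order 2 lambda) that make
    first-order methods crawl over the last few orders of magnitude.
    """
    if oracle.hess is None:
        raise InvalidSpecError("newton_polish requires a Hessian oracle")
    w = np.asarray(w0, dtype=float).copy()
    sqrtd = math.sqrt(oracle.dim)
    f, g = oracle.value_and_grad(w)
    for it in range(max_iter):
        rms = float(np.linalg.norm(g) / sqrtd)
        if rms <= tol:
            return Minimum(W=w, E=float(f), rms_grad=rms, n_iter=n_iter_offset + it)
        H = oracle.hess(w)
        vals, vecs = np.linalg.eigh(H)
        floor = max(1e-12, 1e-9 * float(np.max(np.abs(vals))))
        vals_mod = np.maximum(np.abs(vals), floor)
        s = -vecs @ ((vecs.T @ g) / vals_mod)
        sn = float(np.linalg.norm(s))
        if sn > max_step:
            s *= max_step / sn
        accepted = False
        for _ in range(30):
            f_new, g_new = oracle.value_and_grad(w + s)
            if np.isfinite(f_new) and f_new <= f + 1e-12 * abs(f):
                w, f, g = w + s, f_new, g_new
                accepted = True
                break
            s *= 0.5
        if not accepted:
            break
    rms = float(np.linalg.norm(g) / sqrtd)
    if rms <= tol:
        return Minimum(W=w, E=float(f), rms_grad=rms, n_iter=n_iter_offset + max_iter)
    raise NonConvergenceError(
        f"newton polish stalled at rms gradient {rms:.3e} (target {tol:.3e})",
        best=Minimum(W=w, E=float(f), rms_grad=rms, n_iter=n_iter_offset + max_iter),
    )


def minimize(
    oracle: CostOracle,
    w0: np.ndarray,
    tol: float,
    max_iter: int = 20000,
    switch_tol: float = 1e-4,
    max_step: float = 1.0,
) -> Minimum:
    """Local minimization to an RMS-gradient tolerance.

    L-BFGS carries the point into the quadratic basin; when a Hessian oracle
    is available and the target is tighter than ``switch_tol``, a modified
    Newton stage finishes the convergence.  If the Newton stage stalls (it
    can zigzag in regions of negative curvature between basins), the stages
    alternate with a progressively tighter handoff point before giving up.
    Pure L-BFGS when no Hessian is available.
    """
    if oracle.hess is None or tol >= switch_tol:
        return lbfgs_minimize(oracle, w0, tol, max_iter=max_iter, max_step=max_step)
    w = np.asarray(w0, dtype=float)
    handoff = switch_tol
    n_done = 0
    last_err: NonConvergenceError | None = None
    for _ in range(4):
        pre = lbfgs_minimize(oracle, w, max(handoff, tol),
                             max_iter=max_iter, max_step=max_step)
        n_done += pre.n_iter
        if pre.rms_grad <= tol:
            return Minimum(W=pre.W, E=pre.E, rms_grad=pre.rms_grad, n_iter=n_done)
        try:
            return newton_polish(oracle, pre.W, tol, n_iter_offset=n_done)
        except NonConvergenceError as err:
            last_err = err
            w = err.best.W if err.best is not None else pre.W
            handoff /= 10.0
    raise NonConvergenceError(
        f"minimization did not reach rms gradient {tol:.1e}",
        best=last_err.best if last_err is not None else None,
    ) from last_err


def lbfgs_relax_force(
    force_fn,
    w0: np.ndarray,
    tol: float,
    max_iter: int = 2000,
    memory: int = 10,
    max_step: float = 0.5,
) -> np.ndarray:
    """L-BFGS-style relaxation driven by a force that is not a true gradient.

    Used for elastic-band relaxation, where the doubly-nudged force has no
    underlying scalar potential so a line search on a cost value is
    meaningless.  Steps follow the two-loop direction with a trust cap;
    memory pairs are only kept when the curvature condition holds.  Converges
    when the RMS force drops below ``tol``.
    """
    w = np.asarray(w0, dtype=float).copy()
    g = np.asarray(force_fn(w), dtype=float)
    sqrtd = math.sqrt(w.size)
    s_hist: list[np.ndarray] = []
    y_hist: list[np.ndarray] = []
    rho_hist: list[float] = []
    for _ in range(max_iter):
        if np.linalg.norm(g) / sqrtd <= tol:
            return w
        d = _two_loop(g, s_hist, y_hist, rho_hist)
        if np.dot(d, g) >= 0:
            s_hist.clear(); y_hist.clear(); rho_hist.clear()
            d = -g
        dn = np.linalg.norm(d)
        if dn > max_step:
            d *= max_step / dn
        w_new = w + d
        g_new = np.asarray(force_fn(w_new), dtype=float)
        if not np.all(np.isfinite(g_new)):
            raise DivergenceError("non-finite force during band relaxation")
        s, y = w_new - w, g_new - g
        sy = float(np.dot(s, y))
        if sy > 1e-12:
            s_hist.append(s); y_hist.append(y); rho_hist.append(1.0 / sy)
            if len(s_hist) > memory:
                s_hist.pop(0); y_hist.pop(0); rho_hist.pop(0)
        w, g = w_new, g_new
    return w  # caller checks residual force


# ---------------------------------------------------------------------------
# Minima database


class MinimaDatabase:
    """Distinct local minima kept sorted in ascending cost order.

    Two minima are considered the same when their cost values differ by less
    than ``dedupe_tol`` *and* their parameter vectors coincide (within
    ``match_rtol`` relative Euclidean distance).  With minima converged to
    RMS gradient 1e-10 the cost alone distinguishes genuinely different
    minima on generic landscapes; the parameter check additionally keeps
    *exactly* degenerate minima apart — symmetry-related network fits, or
    the two wells of the toy fixtures, which share one cost value but sit at
    different points.
    """

    def __init__(self, dedupe_tol: float = 1e-8, match_rtol: float = 1e-2):
        if not dedupe_tol > 0:
            raise InvalidSpecError("dedupe_tol must be positive")
        self.dedupe_tol = float(dedupe_tol)
        self.match_rtol = float(match_rtol)
        self.minima: list[Minimum] = []
        self._energies: list[float] = []

    def __len__(self) -> int:
        return len(self.minima)

    def __iter__(self):
        return iter(self.minima)

    def __getitem__(self, i: int) -> Minimum:
        return self.minima[i]

    @property
    def global_minimum(self) -> Minimum:
        return self.minima[0]

    def _energy_window(self, E: float):
        lo = bisect.bisect_left(self._energies, E - self.dedupe_tol)
        hi = bisect.bisect_right(self._energies, E + self.dedupe_tol)
        return range(lo, hi)

    def find_duplicate(self, E: float, W: np.ndarray | None = None) -> int | None:
        """Index of an entry matching in cost (and, if given, parameters)."""
        scale = 1.0 if W is None else self.match_rtol * (1.0 + float(np.linalg.norm(W)))
        for j in self._energy_window(E):
            if abs(self._energies[j] - E) >= self.dedupe_tol:
                continue
            if W is None or np.linalg.norm(self.minima[j].W - W) <= scale:
                return j
        return None

    def add(self, m: Minimum, tol_required: float | None = None) -> tuple[int, bool]:
        """Insert ``m`` maintaining sorted order.

        Returns ``(index, inserted)``; a duplicate leaves the database
        unchanged and returns the duplicate's index.  ``tol_required``
        enforces the contract that candidates were converged at the tight
        tolerance before storage.
        """
        if tol_required is not None and m.rms_grad > tol_required:
            raise InvalidSpecError(
                f"candidate rms gradient {m.rms_grad:.3e} exceeds required {tol_required:.3e}"
            )
        j = self.find_duplicate(m.E, m.W)
        if j is not None:
            return j, False
        # bisect_right keeps exact energy ties in insertion order, which makes
        # database serialization round-trips order-stable
        i = bisect.bisect_right(self._energies, m.E)
        self.minima.insert(i, m)
        self._energies.insert(i, m.E)
        return i, True

    def nearest_by_params(self, W: np.ndarray, rtol: float = 1e-5) -> int | None:
        """Index of the minimum closest to ``W`` in parameter space, if close.

        "Close" means within ``rtol * (1 + |W|)`` Euclidean distance — used to
        identify path endpoints with database entries even when cost values
        are exactly degenerate.
        """
        if not self.minima:
            return None
        d = [float(np.linalg.norm(m.W - W)) for m in self.minima]
        i = int(np.argmin(d))
        if d[i] <= rtol * (1.0 + float(np.linalg.norm(W))):
            return i
        return None


def dedupe_minima(db: MinimaDatabase, candidate: Minimum,
                  tight_tol: float = 1e-10) -> MinimaDatabase:
    """Insert ``candidate`` unless an energy-duplicate exists (in place)."""
    db.add(candidate, tol_required=tight_tol * 1.0001)
    return db


# ---------------------------------------------------------------------------
# Basin-hopping


def bh_step(W: np.ndarray, step_size: float, rng: np.random.Generator) -> np.ndarray:
    """Perturb each coordinate by an independent uniform draw in [-s, +s]."""
    W = np.asarray(W, dtype=float)
    return W + rng.uniform(-step_size, step_size, size=W.shape)


def metropolis_accept(delta_E: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: downhill always accepted, uphill with exp(-dE/T)."""
    if not temperature > 0:
        raise InvalidSpecError("temperature must be positive")
    if delta_E <= 0:
        return True
    x = delta_E / temperature
    if x > 700:  # exp underflows; probability is numerically zero
        return False
    return bool(rng.random() < math.exp(-x))


def random_params(dim: int, rng: np.random.Generator) -> np.ndarray:
    """Starting weights: independent uniform draws in [-1, 1] per coordinate."""
    return rng.uniform(-1.0, 1.0, size=dim)


def basin_hop(oracle: CostOracle, w0: np.ndarray | None,
              config: BasinHopConfig) -> MinimaDatabase:
    """Basin-hopping global optimization accumulating a minima database.

    Starting from ``w0`` (or random uniform [-1,1] weights drawn from the run
    seed when ``None``), performs ``config.n_steps`` iterations of: perturb
    the coordinates of the last accepted minimum, minimize at the loose
    tolerance, Metropolis-accept on the minimized cost.  Every new minimum —
    accepted or not — is re-converged at the tight tolerance and stored.
    Fully reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    if w0 is None:
        w0 = random_params(oracle.dim, rng)

    db = MinimaDatabase(dedupe_tol=config.dedupe_tol)
    current = minimize(oracle, w0, tol=config.loose_tol, max_iter=config.max_iter)
    _store_tight(oracle, db, current, config)

    for _ in range(config.n_steps):
        proposal_ok = False
        last_err = None
        for attempt in range(3):  # retry persistent minimization failures
            w_try = bh_step(current.W, config.step_size, rng)
            try:
                trial = minimize(
                    oracle, w_try, tol=config.loose_tol, max_iter=config.max_iter
                )
                proposal_ok = True
                break
            except (DivergenceError, NonConvergenceError) as err:
                last_err = err
        if not proposal_ok:
            raise NonConvergenceError(
                "local minimization failed on 3 consecutive proposals",
                best=db.global_minimum if len(db) else None,
            ) from last_err
        _store_tight(oracle, db, trial, config)
        if metropolis_accept(trial.E - current.E, config.temperature, rng):
            current = trial
    return db


def _store_tight(oracle: CostOracle, db: MinimaDatabase, m: Minimum,
                 config: BasinHopConfig) -> None:
    """Tighten a loose minimum and store it, skipping known duplicates.

    The pre-check against the loose cost and position is only a shortcut:
    anything that survives it is re-converged at the tight tolerance and
    deduplicated again on insertion.
    """
    if db.find_duplicate(m.E, m.W) is not None:
        return
    tight = minimize(oracle, m.W, tol=config.tight_tol, max_iter=config.max_iter)
    db.add(tight, tol_required=config.tight_tol * 1.0001)
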