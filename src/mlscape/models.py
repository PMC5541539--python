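r"""Classifier cost surfaces with analytic first and second derivatives.

Two fitting functions map a patient feature vector ``x`` (length ``N_in``) to
a pair of outputs ``y = (y_0, y_1)`` for the two outcome classes
(0 = death in hospital, 1 = survival):

* a three-layer neural network with one tanh hidden layer,

  .. math:: y_i = w_i^{bo} + \sum_j w^{(1)}_{ij}
            \tanh\bigl(w_j^{bh} + \sum_k w^{(2)}_{jk} x_k\bigr),

* a quadratic (convex) alternative,

  .. math:: y_i = w^{(0)}(i) + \sum_k w^{(1)}_k(i) x_k
            + \sum_{k,\ j \ge k} w^{(2)}_{kj}(i)\, x_k x_j,

  with :math:`N_{out}(1 + N_{in}(N_{in}+3)/2)` parameters.

Outputs become class probabilities through a softmax, and the training cost is
the mean negative log-probability of the true class plus an :math:`L^2`
penalty :math:`\lambda \lVert W\rVert^2` over *all* parameters, biases
included.  Penalizing the biases lifts the uniform output-bias-shift zero mode
of the softmax (which depends only on :math:`y_0 - y_1`) to an exact Hessian
eigenvalue :math:`2\lambda`.

All derivatives here are exact analytic expressions — the landscape machinery
(saddle searches, Hessian index checks) requires second derivatives far more
accurate than finite differences provide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import InvalidSpecError, ShapeError
from .oracle import CostOracle

N_OUT = 2  # two outcome classes, fixed throughout


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass(frozen=True)
class NNShape:
    """Architecture of the single-hidden-layer network."""

    n_in: int
    n_hidden: int

    def __post_init__(self):
        if self.n_in < 1 or self.n_hidden < 1:
            raise InvalidSpecError("n_in and n_hidden must be >= 1")

    @property
    def n_out(self) -> int:
        return N_OUT


@dataclass
class NNParams:
    """Network weights with a fixed bijective flattening.

    Flat order: output biases ``wbo`` (2), hidden biases ``wbh`` (n_hidden),
    hidden-to-output ``w1`` row-major (2 x n_hidden), then input-to-hidden
    ``w2`` row-major (n_hidden x n_in).
    """

    w1: np.ndarray  # (2, n_hidden)
    w2: np.ndarray  # (n_hidden, n_in)
    wbh: np.ndarray  # (n_hidden,)
    wbo: np.ndarray  # (2,)

    @property
    def shape(self) -> NNShape:
        return NNShape(n_in=self.w2.shape[1], n_hidden=self.w2.shape[0])

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [self.wbo.ravel(), self.wbh.ravel(), self.w1.ravel(), self.w2.ravel()]
        )

    @classmethod
    def unflatten(cls, w: np.ndarray, shape: NNShape) -> "NNParams":
        w = np.asarray(w, dtype=float)
        h, ni = shape.n_hidden, shape.n_in
        expected = N_OUT + h + N_OUT * h + h * ni
        if w.size != expected:
            raise ShapeError(f"expected {expected} parameters, got {w.size}")
        o = 0
        wbo = w[o : o + N_OUT].copy(); o += N_OUT
        wbh = w[o : o + h].copy(); o += h
        w1 = w[o : o + N_OUT * h].reshape(N_OUT, h).copy(); o += N_OUT * h
        w2 = w[o:].reshape(h, ni).copy()
        return cls(w1=w1, w2=w2, wbh=wbh, wbo=wbo)


@dataclass
class QuadParams:
    """Quadratic-model weights: constant, linear, and upper-triangle quadratic.

    ``wquad[i]`` stores coefficients for the pairs ``(k, j)`` with ``j >= k``
    in row-major order (k outer, j inner); each unordered pair appears once.
    Flat order: ``w0`` (2), ``wlin`` row-major (2 x n_in), ``wquad`` row-major
    (2 x n_in(n_in+1)/2).
    """

    w0: np.ndarray  # (2,)
    wlin: np.ndarray  # (2, n_in)
    wquad: np.ndarray  # (2, n_in*(n_in+1)//2)

    @property
    def n_in(self) -> int:
        return self.wlin.shape[1]

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.w0.ravel(), self.wlin.ravel(), self.wquad.ravel()])

    @classmethod
    def unflatten(cls, w: np.ndarray, n_in: int) -> "QuadParams":
        w = np.asarray(w, dtype=float)
        ntri = n_in * (n_in + 1) // 2
        expected = N_OUT * (1 + n_in + ntri)
        if w.size != expected:
            raise ShapeError(f"expected {expected} parameters, got {w.size}")
        o = 0
        w0 = w[o : o + N_OUT].copy(); o += N_OUT
        wlin = w[o : o + N_OUT * n_in].reshape(N_OUT, n_in).copy(); o += N_OUT * n_in
        wquad = w[o:].reshape(N_OUT, ntri).copy()
        return cls(w0=w0, wlin=wlin, wquad=wquad)


@dataclass(frozen=True)
class CostSpec:
    """Which fitting function, and the regularization weight lambda > 0."""

    kind: str  # "nn" | "quadratic"
    lam: float
    shape: NNShape | None = None  # required for kind == "nn"

    def __post_init__(self):
        if self.kind not in ("nn", "quadratic"):
            raise InvalidSpecError(f"unknown model kind {self.kind!r}")
        if not self.lam > 0:
            raise InvalidSpecError("lambda must be > 0")
        if self.kind == "nn" and self.shape is None:
            raise InvalidSpecError("NN cost requires an NNShape")


def param_count(kind: str, shape: NNShape | int) -> int:
    """Number of free parameters of a fitting function.

    For the quadratic model pass ``shape = n_in``; the count is
    ``N_out (1 + N_in (N_in + 3) / 2)``.
    """
    if kind == "nn":
        if not isinstance(shape, NNShape):
            raise InvalidSpecError("NN param_count requires an NNShape")
        h, ni = shape.n_hidden, shape.n_in
        return N_OUT + h + N_OUT * h + h * ni
    if kind == "quadratic":
        n_in = int(shape.n_in if isinstance(shape, NNShape) else shape)
        return N_OUT * (1 + n_in * (n_in + 3) // 2)
    raise InvalidSpecError(f"unknown model kind {kind!r}")


# ---------------------------------------------------------------------------
# Forward maps


def softmax(y: np.ndarray) -> np.ndarray:
    """Overflow-safe softmax along the last axis (max-subtracted)."""
    y = np.asarray(y, dtype=float)
    z = y - np.max(y, axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / np.sum(ez, axis=-1, keepdims=True)


def nn_forward(params: NNParams, x: np.ndarray) -> np.ndarray:
    """Network outputs ``y`` for one input vector or a batch (rows)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] != params.w2.shape[1]:
        raise ShapeError(f"input has {x2.shape[1]} features, model expects {params.w2.shape[1]}")
    t = np.tanh(params.wbh + x2 @ params.w2.T)  # (N, h)
    y = params.wbo + t @ params.w1.T  # (N, 2)
    return y[0] if single else y


def _tri_indices(n_in: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-major upper-triangle index pairs (k, j) with j >= k."""
    k, j = np.triu_indices(n_in)
    return k, j


def quad_design(X: np.ndarray) -> np.ndarray:
    """Feature expansion ``phi(x) = (1, x, {x_k x_j}_{j>=k})`` per row."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, n_in = X.shape
    k, j = _tri_indices(n_in)
    return np.concatenate([np.ones((n, 1)), X, X[:, k] * X[:, j]], axis=1)


def quad_forward(params: QuadParams, x: np.ndarray) -> np.ndarray:
    """Quadratic-model outputs for one input vector or a batch."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    phi = quad_design(x)
    theta = np.concatenate(
        [params.w0[:, None], params.wlin, params.wquad], axis=1
    )  # (2, F)
    y = phi @ theta.T
    return y[0] if single else y


# ---------------------------------------------------------------------------
# Cost, gradient, Hessian


def _check_data(X: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    c = np.asarray(c, dtype=int).ravel()
    if X.shape[0] == 0:
        raise InvalidSpecError("empty dataset")
    if c.shape[0] != X.shape[0]:
        raise ShapeError("outcomes length does not match number of rows")
    if not np.all((c == 0) | (c == 1)):
        raise InvalidSpecError("outcomes must be 0 or 1")
    return X, c


def _loss_terms(Y: np.ndarray, c: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and per-sample output-space gradient (p - onehot)/N."""
    n = Y.shape[0]
    lse = logsumexp(Y, axis=1)
    data_loss = float(np.mean(lse - Y[np.arange(n), c]))
    G = softmax(Y)
    G[np.arange(n), c] -= 1.0
    return data_loss, G / n


class NeuralNetCost:
    """Regularized NN training cost over a fixed dataset, as a CostOracle.

    Exposes exact value, gradient and Hessian of
    ``E(W) = -(1/N) sum_a ln p_{c(a)}(W; x_a) + lambda |W|^2``.
    """

    def __init__(self, shape: NNShape, X: np.ndarray, c: np.ndarray, lam: float):
        if lam < 0:
            raise InvalidSpecError("lambda must be >= 0")
        self.shape = shape
        self.X, self.c = _check_data(X, c)
        if self.X.shape[1] != shape.n_in:
            raise ShapeError(
                f"data has {self.X.shape[1]} features, shape expects {shape.n_in}"
            )
        self.lam = float(lam)
        self.dim = param_count("nn", shape)
        h = shape.n_hidden
        # flat-vector offsets of each weight block
        self._o_bo = 0
        self._o_bh = N_OUT
        self._o_w1 = N_OUT + h
        self._o_w2 = N_OUT + h + N_OUT * h

    def value(self, w: np.ndarray) -> float:
        return self.value_and_grad(w)[0]

    def value_and_grad(self, w: np.ndarray) -> tuple[float, np.ndarray]:
        w = np.asarray(w, dtype=float)
        p = NNParams.unflatten(w, self.shape)
        X, c = self.X, self.c
        T = np.tanh(p.wbh + X @ p.w2.T)  # (N, h)
        Y = p.wbo + T @ p.w1.T  # (N, 2)
        data_loss, G = _loss_terms(Y, c)
        E = data_loss + self.lam * float(w @ w)

        d_wbo = G.sum(axis=0)  # (2,)
        d_w1 = G.T @ T  # (2, h)
        Hmid = (G @ p.w1) * (1.0 - T**2)  # (N, h)
        d_wbh = Hmid.sum(axis=0)
        d_w2 = Hmid.T @ X  # (h, n_in)
        grad = np.concatenate([d_wbo, d_wbh, d_w1.ravel(), d_w2.ravel()])
        grad += 2.0 * self.lam * w
        return E, grad

    def gradient(self, w: np.ndarray) -> np.ndarray:
        return self.value_and_grad(w)[1]

    def hessian(self, w: np.ndarray) -> np.ndarray:
        """Exact Hessian: Gauss-Newton term J^T A J plus curvature of tanh.

        Per sample, with softmax Jacobian ``A = diag(p) - p p^T`` and network
        Jacobian ``J = dy/dW``, the data Hessian is ``J^T A J`` plus
        ``sum_i g_i d2y_i/dW2``; the second term involves the tanh second
        derivative through the hidden activations only.
        """
        w = np.asarray(w, dtype=float)
        p = NNParams.unflatten(w, self.shape)
        X, c = self.X, self.c
        n, n_in = X.shape
        h = self.shape.n_hidden
        T = np.tanh(p.wbh + X @ p.w2.T)  # (N, h)
        Y = p.wbo + T @ p.w1.T
        P = softmax(Y)  # (N, 2)
        G = P.copy()
        G[np.arange(n), c] -= 1.0  # per-sample dL/dy, unnormalized

        S = 1.0 - T**2  # tanh'
        D = -2.0 * T * S  # tanh''

        # Jacobian J: (N, 2, dim), built block-wise
        J = np.zeros((n, N_OUT, self.dim))
        for i in range(N_OUT):
            J[:, i, self._o_bo + i] = 1.0
        # d y_i / d wbh_j = w1_ij * S_j
        J[:, :, self._o_bh : self._o_bh + h] = S[:, None, :] * p.w1[None, :, :]
        # d y_i / d w1_ij = T_j  (row-major over (i, j))
        for i in range(N_OUT):
            J[:, i, self._o_w1 + i * h : self._o_w1 + (i + 1) * h] = T
        # d y_i / d w2_jk = w1_ij * S_j * x_k  (row-major over (j, k))
        JW2 = np.einsum("ij,nj,nk->nijk", p.w1, S, X).reshape(n, N_OUT, h * n_in)
        J[:, :, self._o_w2 :] = JW2

        # softmax curvature A_n = diag(p) - p p^T
        A = np.einsum("ni,ij->nij", P, np.eye(N_OUT)) - np.einsum("ni,nj->nij", P, P)
        H = np.einsum("nip,nij,njq->pq", J, A, J)

        # second-derivative-of-y term: sum_i g_i d2y_i/dW2
        U = G @ p.w1  # (N, h): sum_i g_i w1_ij
        UD = U * D  # (N, h)
        GS = np.einsum("ni,nj->nij", G, S)  # (N, 2, h): g_i S_j

        # (w1_ij, bh_j) and (w1_ij, w2_jk) cross blocks
        for i in range(N_OUT):
            r0 = self._o_w1 + i * h
            # w1 x bh: diagonal in j
            blk = GS[:, i, :].sum(axis=0)  # (h,)
            H[r0 : r0 + h, self._o_bh : self._o_bh + h] += np.diag(blk)
            H[self._o_bh : self._o_bh + h, r0 : r0 + h] += np.diag(blk)
            # w1 x w2: g_i S_j x_k, diagonal in j
            cross = np.einsum("nj,nk->jk", GS[:, i, :], X)  # (h, n_in)
            for j in range(h):
                c0 = self._o_w2 + j * n_in
                H[r0 + j, c0 : c0 + n_in] += cross[j]
                H[c0 : c0 + n_in, r0 + j] += cross[j]

        # a_j-quadratic blocks: coefficient UD_j on (bh_j, w2_jk) quadratic form
        ud_sum = UD.sum(axis=0)  # (h,)
        H[self._o_bh : self._o_bh + h, self._o_bh : self._o_bh + h] += np.diag(ud_sum)
        bh_w2 = np.einsum("nj,nk->jk", UD, X)  # (h, n_in)
        w2_w2 = np.einsum("nj,nk,nl->jkl", UD, X, X)  # (h, n_in, n_in)
        for j in range(h):
            c0 = self._o_w2 + j * n_in
            H[self._o_bh + j, c0 : c0 + n_in] += bh_w2[j]
            H[c0 : c0 + n_in, self._o_bh + j] += bh_w2[j]
            H[c0 : c0 + n_in, c0 : c0 + n_in] += w2_w2[j]

        H /= n
        H += 2.0 * self.lam * np.eye(self.dim)
        return 0.5 * (H + H.T)

    def predict_p0(self, w: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Predicted probability of class 0 (death) per row of ``X``."""
        p = NNParams.unflatten(w, self.shape)
        T = np.tanh(p.wbh + np.atleast_2d(X) @ p.w2.T)
        Y = p.wbo + T @ p.w1.T
        return softmax(Y)[:, 0]

    def as_oracle(self) -> CostOracle:
        return CostOracle(
            f=self.value, grad=self.gradient, hess=self.hessian, dim=self.dim,
            name=f"nn(h={self.shape.n_hidden},lam={self.lam:g})",
        )


class QuadraticCost:
    """Regularized quadratic-model cost over a fixed dataset.

    The outputs are linear in the parameters (constant + linear + one copy of
    each unordered input pair), so the data term is a softmax cross-entropy
    composed with a linear map — convex — and the ridge term makes the total
    cost strictly convex with smallest Hessian eigenvalue >= 2 lambda.
    """

    def __init__(self, n_in: int, X: np.ndarray, c: np.ndarray, lam: float):
        if lam < 0:
            raise InvalidSpecError("lambda must be >= 0")
        self.n_in = int(n_in)
        self.X, self.c = _check_data(X, c)
        if self.X.shape[1] != self.n_in:
            raise ShapeError(f"data has {self.X.shape[1]} features, expected {n_in}")
        self.lam = float(lam)
        self.Phi = quad_design(self.X)  # (N, F)
        self.F = self.Phi.shape[1]
        self.dim = N_OUT * self.F

    def _theta(self, w: np.ndarray) -> np.ndarray:
        """Reshape the flat vector into per-output rows over the design basis."""
        p = QuadParams.unflatten(w, self.n_in)
        return np.concatenate([p.w0[:, None], p.wlin, p.wquad], axis=1)  # (2, F)

    def _flatten_theta(self, theta: np.ndarray) -> np.ndarray:
        w0 = theta[:, 0]
        wlin = theta[:, 1 : 1 + self.n_in]
        wquad = theta[:, 1 + self.n_in :]
        return QuadParams(w0=w0, wlin=wlin, wquad=wquad).flatten()

    def value(self, w: np.ndarray) -> float:
        return self.value_and_grad(w)[0]

    def value_and_grad(self, w: np.ndarray) -> tuple[float, np.ndarray]:
        w = np.asarray(w, dtype=float)
        theta = self._theta(w)
        Y = self.Phi @ theta.T  # (N, 2)
        data_loss, G = _loss_terms(Y, self.c)
        E = data_loss + self.lam * float(w @ w)
        d_theta = G.T @ self.Phi  # (2, F)
        grad = self._flatten_theta(d_theta) + 2.0 * self.lam * w
        return E, grad

    def gradient(self, w: np.ndarray) -> np.ndarray:
        return self.value_and_grad(w)[1]

    def hessian(self, w: np.ndarray) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        theta = self._theta(w)
        Y = self.Phi @ theta.T
        P = softmax(Y)
        A = np.einsum("ni,ij->nij", P, np.eye(N_OUT)) - np.einsum("ni,nj->nij", P, P)
        # H[(i,f),(j,g)] over the theta layout, then permuted into flat layout
        Hth = np.einsum("nij,nf,ng->ifjg", A, self.Phi, self.Phi) / self.Phi.shape[0]
        Hth = Hth.reshape(self.dim, self.dim)
        perm = self._theta_to_flat_perm()
        H = Hth[np.ix_(perm, perm)]
        H += 2.0 * self.lam * np.eye(self.dim)
        return 0.5 * (H + H.T)

    def _theta_to_flat_perm(self) -> np.ndarray:
        """Index map: flat-layout position -> theta-layout position."""
        idx_theta = np.arange(self.dim).reshape(N_OUT, self.F)
        flat_order = np.concatenate(
            [idx_theta[:, 0], idx_theta[:, 1 : 1 + self.n_in].ravel(),
             idx_theta[:, 1 + self.n_in :].ravel()]
        )
        return flat_order

    def predict_p0(self, w: np.ndarray, X: np.ndarray) -> np.ndarray:
        theta = self._theta(np.asarray(w, dtype=float))
        Y = quad_design(X) @ theta.T
        return softmax(Y)[:, 0]

    def as_oracle(self) -> CostOracle:
        return CostOracle(
            f=self.value, grad=self.gradient, hess=self.hessian, dim=self.dim,
            name=f"quadratic(n_in={self.n_in},lam={self.lam:g})",
        )


def make_cost(spec: CostSpec, X: np.ndarray, c: np.ndarray):
    """Instantiate the cost surface named by ``spec`` over the dataset."""
    if spec.kind == "nn":
        return NeuralNetCost(spec.shape, X, c, spec.lam)
    return QuadraticCost(np.atleast_2d(X).shape[1], X, c, spec.lam)


def cost(spec: CostSpec, w: np.ndarray, X: np.ndarray, c: np.ndarray) -> tuple[float, np.ndarray]:
    """Convenience wrapper: (E, gradient) of the regularized cost at ``w``."""
    if not np.all(np.isfinite(np.asarray(w, dtype=float))):
        raise InvalidSpecError("non-finite parameters")
    return make_cost(spec, X, c).value_and_grad(w)


def cost_hessian(spec: CostSpec, w: np.ndarray, X: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Exact symmetric Hessian of the regularized cost at ``w``."""
    if not np.all(np.isfinite(np.asarray(w, dtype=float))):
        raise InvalidSpecError("non-finite parameters")
    return make_cost(spec, X, c).hessian(w)


def bias_shift_direction(dim: int) -> np.ndarray:
    """Unit vector shifting both output biases uniformly (zeros elsewhere).

    The unregularized cost is invariant along this direction (softmax depends
    only on y_0 - y_1); with the ridge term it becomes an exact Hessian
    eigenvector with eigenvalue 2 lambda.
    """
    u = np.zeros(dim)
    u[0] = u[1] = 1.0 / np.sqrt(2.0)
    return u
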