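"""Batched small-matrix exponentials and directional derivatives.

The panel likelihood evaluates tens of thousands of matrix exponentials of
tiny (3x3 or 5x5) generator slices per objective call, so these kernels
are vectorised over a leading batch axis rather than delegating to
``scipy.linalg.expm`` one matrix at a time.  Scaling-and-squaring with a
truncated Taylor series is accurate to machine precision for the scaled
norm bound used here.  When numba is available the per-matrix loops are
JIT-compiled; a pure-numpy path provides the same results otherwise.
"""

from __future__ import annotations

import math

import numpy as np

_MAX_NORM = 0.25
_DEG = 10

try:  # pragma: no cover - exercised indirectly
    import numba as _numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

_FACT = np.array([math.factorial(k) for k in range(2 * _DEG + 2)], dtype=float)
_COEF = 1.0 / _FACT[np.add.outer(np.arange(_DEG + 1), np.arange(_DEG + 1)) + 1]


def _scaling(a: np.ndarray) -> int:
    norm = float(np.abs(a).sum(axis=-1).max()) if a.size else 0.0
    if not np.isfinite(norm):
        raise FloatingPointError("non-finite entries in generator batch")
    if norm <= _MAX_NORM:
        return 0
    return min(100, int(math.ceil(math.log2(norm / _MAX_NORM))))


def _taylor_expm(a: np.ndarray) -> np.ndarray:
    """exp(a) by truncated Taylor (machine precision for ||a|| <= _MAX_NORM)."""
    n = a.shape[-1]
    eye = np.zeros_like(a)
    eye[..., range(n), range(n)] = 1.0
    p = eye + a / _DEG
    for k in range(_DEG - 1, 0, -1):
        p = eye + (a @ p) / k
    return p


def _expm_batch_np(a: np.ndarray) -> np.ndarray:
    s = _scaling(a)
    p = _taylor_expm(a / (2.0**s))
    for _ in range(s):
        p = p @ p
    return p


def _frechet_np(a: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    s = _scaling(a)
    a2 = a / (2.0**s)
    cols_u = [np.asarray(u, dtype=a2.dtype)]
    cols_v = [np.asarray(v, dtype=a2.dtype)]
    a2t = a2.swapaxes(-1, -2)
    for _ in range(_DEG):
        cols_u.append((a2 @ cols_u[-1][..., None])[..., 0])
        cols_v.append((a2t @ cols_v[-1][..., None])[..., 0])
    umat = np.stack(cols_u, axis=-1)  # (..., n, deg+1)
    vmat = np.stack(cols_v, axis=-1)
    t = vmat @ _COEF.T  # t[..., j, k] = sum_l V[..., j, l] C[k, l]
    g = (umat @ t.swapaxes(-1, -2)) / (2.0**s)
    if s:
        f = _taylor_expm(a2)
        for _ in range(s):
            g = f @ g + g @ f
            f = f @ f
    return g


if _HAVE_NUMBA:

    @_numba.njit(cache=True, fastmath=False)
    def _expm_kernel(a, max_norm, deg):  # pragma: no cover - jitted
        nb, n, _ = a.shape
        out = np.empty_like(a)
        A = np.empty((n, n))
        P = np.empty((n, n))
        T1 = np.empty((n, n))
        for b in range(nb):
            norm = 0.0
            for i in range(n):
                rs = 0.0
                for j in range(n):
                    rs += abs(a[b, i, j])
                if rs > norm:
                    norm = rs
            s = 0
            while norm > max_norm and s < 100:
                norm *= 0.5
                s += 1
            sc = 2.0**s
            for i in range(n):
                for j in range(n):
                    A[i, j] = a[b, i, j] / sc
            for i in range(n):
                for j in range(n):
                    P[i, j] = A[i, j] / deg
                P[i, i] += 1.0
            for k in range(deg - 1, 0, -1):
                for i in range(n):
                    for j in range(n):
                        acc = 0.0
                        for l in range(n):
                            acc += A[i, l] * P[l, j]
                        T1[i, j] = acc
                for i in range(n):
                    for j in range(n):
                        P[i, j] = T1[i, j] / k
                    P[i, i] += 1.0
            for _ in range(s):
                for i in range(n):
                    for j in range(n):
                        acc = 0.0
                        for l in range(n):
                            acc += P[i, l] * P[l, j]
                        T1[i, j] = acc
                P, T1 = T1, P
            out[b] = P
        return out

    @_numba.njit(cache=True, fastmath=False)
    def _frechet_kernel(a, u, v, coef, max_norm, deg):  # pragma: no cover
        nb, n, _ = a.shape
        out = np.empty_like(a)
        A = np.empty((n, n))
        U = np.empty((deg + 1, n))
        V = np.empty((deg + 1, n))
        W = np.empty((deg + 1, n))
        G = np.empty((n, n))
        T1 = np.empty((n, n))
        F = np.empty((n, n))
        for b in range(nb):
            norm = 0.0
            for i in range(n):
                rs = 0.0
                for j in range(n):
                    rs += abs(a[b, i, j])
                if rs > norm:
                    norm = rs
            s = 0
            while norm > max_norm and s < 100:
                norm *= 0.5
                s += 1
            sc = 2.0**s
            for i in range(n):
                for j in range(n):
                    A[i, j] = a[b, i, j] / sc
            for i in range(n):
                U[0, i] = u[b, i]
                V[0, i] = v[b, i]
            for k in range(deg):
                for i in range(n):
                    au = 0.0
                    av = 0.0
                    for l in range(n):
                        au += A[i, l] * U[k, l]
                        av += A[l, i] * V[k, l]
                    U[k + 1, i] = au
                    V[k + 1, i] = av
            for k in range(deg + 1):
                for j in range(n):
                    acc = 0.0
                    for l in range(deg + 1):
                        acc += coef[k, l] * V[l, j]
                    W[k, j] = acc
            for i in range(n):
                for j in range(n):
                    acc = 0.0
                    for k in range(deg + 1):
                        acc += U[k, i] * W[k, j]
                    G[i, j] = acc / sc
            if s > 0:
                # F = exp(A) by the same Horner scheme
                for i in range(n):
                    for j in range(n):
                        F[i, j] = A[i, j] / deg
                    F[i, i] += 1.0
                for k in range(deg - 1, 0, -1):
                    for i in range(n):
                        for j in range(n):
                            acc = 0.0
                            for l in range(n):
                                acc += A[i, l] * F[l, j]
                            T1[i, j] = acc
                    for i in range(n):
                        for j in range(n):
                            F[i, j] = T1[i, j] / k
                        F[i, i] += 1.0
                for _ in range(s):
                    for i in range(n):
                        for j in range(n):
                            acc = 0.0
                            for l in range(n):
                                acc += F[i, l] * G[l, j] + G[i, l] * F[l, j]
                            T1[i, j] = acc
                    G, T1 = T1, G
                    for i in range(n):
                        for j in range(n):
                            acc = 0.0
                            for l in range(n):
                                acc += F[i, l] * F[l, j]
                            T1[i, j] = acc
                    F, T1 = T1, F
            out[b] = G
        return out


def expm_batch(a: np.ndarray) -> np.ndarray:
    """Matrix exponential of a batch ``a`` with shape (..., n, n)."""
    a = np.asarray(a)
    if (
        _HAVE_NUMBA
        and a.ndim == 3
        and a.dtype == np.float64
        and a.shape[0] > 64
    ):
        if not np.isfinite(a).all():
            raise FloatingPointError("non-finite entries in generator batch")
        return _expm_kernel(np.ascontiguousarray(a), _MAX_NORM, _DEG)
    return _expm_batch_np(a)


def expm_frechet_rank1(a: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Fréchet derivative L(a, u v^T) of the matrix exponential, batched.

    ``a`` has shape (..., n, n); ``u`` and ``v`` have shape (..., n).  The
    rank-one direction lets the scaled Taylor series be assembled from two
    Krylov ladders instead of an augmented-matrix exponential:
    L(X, u v^T) = sum_{i,j} X^i u v^T X^j / (i+j+1)!.
    Scaling is undone with the doubling rule
    L(2X, E) = F L(X, E) + L(X, E) F with F = exp(X).
    """
    a = np.asarray(a)
    if (
        _HAVE_NUMBA
        and a.ndim == 3
        and a.dtype == np.float64
        and a.shape[0] > 64
    ):
        if not np.isfinite(a).all():
            raise FloatingPointError("non-finite entries in generator batch")
        return _frechet_kernel(
            np.ascontiguousarray(a),
            np.ascontiguousarray(u, dtype=np.float64),
            np.ascontiguousarray(v, dtype=np.float64),
            _COEF,
            _MAX_NORM,
            _DEG,
        )
    return _frechet_np(a, u, v)


def nearest_psd(m: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping."""
    sym = 0.5 * (m + m.T)
    w, q = np.linalg.eigh(sym)
    return (q * np.clip(w, eps, None)) @ q.T
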