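"""Linear-algebra core shared by the VAR simulator and the GC reduction.

All routines operate on batches of VAR(p) models: coefficient stacks have
shape ``(B, p, n, n)`` where ``A[b, k]`` maps ``x(t-k-1)`` to ``x(t)``
(row = target channel, column = source channel).  A batch axis of size 1
is used for single models.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "companion",
    "spectral_radius",
    "stationary_autocov",
    "extend_autocov",
    "reduced_innovation_cov",
]


def companion(coeffs: np.ndarray) -> np.ndarray:
    """Companion matrices ``(B, n*p, n*p)`` of coefficient stacks ``(B, p, n, n)``."""
    coeffs = np.asarray(coeffs, dtype=float)
    b, p, n, _ = coeffs.shape
    m = n * p
    comp = np.zeros((b, m, m))
    # top block row [A1 ... Ap]
    comp[:, :n, :] = coeffs.transpose(0, 2, 1, 3).reshape(b, n, m)
    if p > 1:
        idx = np.arange(m - n)
        comp[:, n + idx, idx] = 1.0
    return comp


def spectral_radius(coeffs: np.ndarray) -> np.ndarray:
    """Largest |eigenvalue| of the companion matrix, per batch element."""
    comp = companion(coeffs)
    return np.abs(np.linalg.eigvals(comp)).max(axis=-1)


def stationary_autocov(
    coeffs: np.ndarray,
    noise_cov: np.ndarray,
    n_lags: int,
    max_doubling: int = 64,
    tol: float = 1e-13,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact autocovariance sequence of stationary VAR(p) models.

    Solves the companion-form discrete Lyapunov equation
    ``G = F G F' + Q`` by doubling (``G_{s+1} = G_s + F^{2^s} G_s F^{2^s}'``),
    which vectorizes cleanly over the batch, then extends the lagged blocks
    with the Yule-Walker recursion.

    Parameters
    ----------
    coeffs : (B, p, n, n)
    noise_cov : (B, n, n) innovation covariance per model.
    n_lags : number of lags to return beyond lag zero.

    Returns
    -------
    gammas : (B, n_lags + 1, n, n) with ``gammas[:, k] = E[x(t) x(t-k)']``.
    converged : (B,) boolean; False where the doubling did not contract
        (an effectively unstable model).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    noise_cov = np.asarray(noise_cov, dtype=float)
    b, p, n, _ = coeffs.shape
    m = n * p
    f = companion(coeffs)
    q = np.zeros((b, m, m))
    q[:, :n, :n] = noise_cov

    # stability pre-check: divergent models would overflow the doubling
    stable = np.abs(np.linalg.eigvals(f)).max(axis=-1) < 1.0 - 1e-10

    g = q.copy()
    fk = np.where(stable[:, None, None], f, 0.0)
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(max_doubling):
            norms = np.abs(fk).max(axis=(1, 2))
            if np.all(norms <= tol):
                break
            g = g + fk @ g @ fk.transpose(0, 2, 1)
            fk = fk @ fk
            if not np.all(np.isfinite(fk)):
                break
    norms = np.abs(fk).max(axis=(1, 2))
    g_ok = np.isfinite(g).all(axis=(1, 2))
    converged = stable & np.isfinite(norms) & (norms <= np.sqrt(tol)) & g_ok
    g = np.where(converged[:, None, None], g, 0.0)
    g = 0.5 * (g + g.transpose(0, 2, 1))

    gammas = np.empty((b, n_lags + 1, n, n))
    for k in range(min(p, n_lags + 1)):
        gammas[:, k] = g[:, :n, k * n : (k + 1) * n]
    if n_lags + 1 > p:
        gammas = extend_autocov(coeffs, gammas, p, n_lags)
    return gammas, converged


def extend_autocov(
    coeffs: np.ndarray, gammas: np.ndarray, start: int, n_lags: int
) -> np.ndarray:
    """Extend ``gammas`` in place from lag ``start`` to ``n_lags`` via
    ``Gamma_k = sum_m A_m Gamma_{k-m}`` (with ``Gamma_{-j} = Gamma_j'``)."""
    b, p = coeffs.shape[:2]
    for k in range(start, n_lags + 1):
        acc = np.zeros_like(gammas[:, 0])
        for m in range(1, p + 1):
            lag = k - m
            gm = gammas[:, lag] if lag >= 0 else gammas[:, -lag].transpose(0, 2, 1)
            acc += coeffs[:, m - 1] @ gm
        gammas[:, k] = acc
    return gammas


def reduced_innovation_cov(
    gammas: np.ndarray, keep: np.ndarray, order: int, ridge: float = 1e-10
) -> np.ndarray:
    """One-step prediction-error covariance of the sub-process ``x[keep]``.

    Fits an AR(``order``) model to the kept channels from the exact
    autocovariances (multivariate Yule-Walker) and returns the implied
    residual covariance ``Gamma_0 - sum_m B_m Gamma_m'``.  The sub-process
    of a VAR is VARMA, so this is an approximation from above that
    converges geometrically in ``order``.

    Parameters
    ----------
    gammas : (B, L + 1, n, n) autocovariances with ``L >= order``.
    keep : indices of the retained channels.
    order : AR order of the reduced fit.

    Returns
    -------
    (B, k, k) residual covariance for the retained channels.
    """
    keep = np.asarray(keep)
    sub = gammas[:, :, keep[:, None], keep[None, :]]
    b = sub.shape[0]
    k = keep.size
    q = order
    if sub.shape[1] < q + 1:
        raise ValueError("need autocovariances up to the reduced order")

    big = np.empty((b, q * k, q * k))
    for a in range(q):
        for c in range(q):
            d = c - a
            blk = sub[:, d] if d >= 0 else sub[:, -d].transpose(0, 2, 1)
            big[:, a * k : (a + 1) * k, c * k : (c + 1) * k] = blk
    rhs = np.empty((b, q * k, k))
    for a in range(q):
        rhs[:, a * k : (a + 1) * k] = sub[:, a + 1].transpose(0, 2, 1)

    diag_scale = np.einsum("bii->b", big) / (q * k)
    big[:, np.arange(q * k), np.arange(q * k)] += ridge * np.maximum(diag_scale, 1e-300)[:, None]
    sol = np.linalg.solve(big, rhs)  # stacked B_m' blocks

    resid = sub[:, 0].copy()
    for m in range(1, q + 1):
        xm = sol[:, (m - 1) * k : m * k]  # B_m'
        resid -= (sub[:, m] @ xm).transpose(0, 2, 1)
    return 0.5 * (resid + resid.transpose(0, 2, 1))
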