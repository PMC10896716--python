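"""Core EASI share-equation algebra.

The demand system models budget shares of J food groups plus a non-food
numeraire.  Food-group share equations are

    w_j = sum_r b_jr y^r + sum_k a_jk ln p_k + y sum_k d_jk ln p_k
          + g_j' z + m_j' zbar + e_j

where y is implicit utility (real total expenditures).  The numeraire
share follows by adding-up, its log price is normalised to zero, and the
numeraire rows/columns of the price matrices are implied by homogeneity
and symmetry.

Two flavours of implicit utility are supported:

* ``"exact"`` (default): y = (ln x - w.ln p + 0.5 ln p'A ln p)
  / (1 - 0.5 ln p'D ln p).  With symmetric A and D this makes the
  Slutsky matrix of the fixed-point demand exactly symmetric at any
  price vector, so Engel/Cournot aggregation, homogeneity and Hicksian
  symmetry all hold to machine precision.
* ``"stone"``: y = ln x - w.ln p (Stone-deflated expenditures).  The
  identities then hold exactly only at base prices (ln p = 0).

Everything here is vectorised over observations: ``lnp`` is (N, J),
``lnx`` is (N,), shares are (N, J+1) with the numeraire last.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

__all__ = [
    "full_price_matrix",
    "latent_food_shares",
    "solve_shares",
    "implicit_utility",
    "share_derivatives",
    "elasticities_from_derivatives",
    "censored_mean_shares",
]


def full_price_matrix(A: np.ndarray) -> np.ndarray:
    """Extend a J x J food-price block to the full (J+1) x (J+1) matrix.

    The numeraire row/column are implied by homogeneity (rows sum to
    zero) and symmetry, so the full matrix is symmetric with zero row
    and column sums.
    """
    A = np.asarray(A, dtype=float)
    J = A.shape[0]
    F = np.zeros((J + 1, J + 1))
    F[:J, :J] = A
    F[:J, J] = -A.sum(axis=1)
    F[J, :J] = -A.sum(axis=0)
    F[J, J] = A.sum()
    return F


def _poly(y: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Evaluate sum_r b_jr y^r for each equation j.  Returns (N, J)."""
    R = b.shape[1] - 1
    Y = np.vander(np.asarray(y, float), R + 1, increasing=True)  # (N, R+1)
    return Y @ b.T


def _dpoly(y: np.ndarray, b: np.ndarray) -> np.ndarray:
    """d/dy of the share polynomial, (N, J)."""
    R = b.shape[1] - 1
    if R == 0:
        return np.zeros((np.size(y), b.shape[0]))
    coefs = b[:, 1:] * np.arange(1, R + 1)  # (J, R)
    Y = np.vander(np.asarray(y, float), R, increasing=True)
    return Y @ coefs.T


def latent_food_shares(b, A, D, G, M, y, lnp, z=None, cmeans=None, errors=None):
    """Mean latent food-group shares at given implicit utility y.  (N, J)."""
    w = _poly(y, b) + lnp @ A.T + y[:, None] * (lnp @ D.T)
    if z is not None and G is not None and G.size:
        w = w + z @ G.T
    if cmeans is not None and M is not None and M.size:
        w = w + cmeans @ M.T
    if errors is not None:
        w = w + errors
    return w


def implicit_utility(lnx, w_full, lnp, A=None, D=None, utility="exact"):
    """Implicit utility y from observed/latent shares.

    ``w_full`` is (N, J+1) including the numeraire; only the food block
    of ``lnp`` enters because the numeraire log price is zero.  The
    ``"stone"`` flavour is ln x minus the Stone index; the ``"exact"``
    flavour adds the quadratic price corrections from A and D.
    """
    lnx = np.asarray(lnx, float)
    stone = np.einsum("nj,nj->n", w_full[:, :-1], lnp)
    if utility == "stone" or A is None:
        return lnx - stone
    quad_a = 0.5 * np.einsum("nj,jk,nk->n", lnp, A, lnp)
    quad_d = 0.5 * np.einsum("nj,jk,nk->n", lnp, D, lnp)
    return (lnx - stone + quad_a) / (1.0 - quad_d)


def solve_shares(b, A, D, G, M, lnp, lnx, z=None, cmeans=None, errors=None,
                 utility="exact", tol=1e-10, maxiter=200, damping=0.5,
                 y0=None):
    """Solve the joint fixed point in (w, y).

    Returns ``(w_full, y)`` where ``w_full`` is (N, J+1) latent shares
    (numeraire last, by adding-up) and ``y`` the converged implicit
    utility.  Raises ``RuntimeError`` with the iteration trace if the
    damped iteration does not converge.
    """
    lnp = np.atleast_2d(np.asarray(lnp, float))
    lnx = np.atleast_1d(np.asarray(lnx, float))
    N = lnp.shape[0]
    if y0 is None:
        y = lnx.copy()
    else:
        y = np.array(y0, float, copy=True)
    trace = []
    for it in range(maxiter):
        wf = latent_food_shares(b, A, D, G, M, y, lnp, z, cmeans, errors)
        w_full = np.column_stack([wf, 1.0 - wf.sum(axis=1)])
        y_new = implicit_utility(lnx, w_full, lnp, A, D, utility)
        delta = float(np.max(np.abs(y_new - y))) if N else 0.0
        trace.append(delta)
        y = (1.0 - damping) * y + damping * y_new
        if delta < tol:
            wf = latent_food_shares(b, A, D, G, M, y, lnp, z, cmeans, errors)
            w_full = np.column_stack([wf, 1.0 - wf.sum(axis=1)])
            return w_full, y
    raise RuntimeError(
        f"share fixed point did not converge in {maxiter} iterations; "
        f"last deltas {trace[-5:]}")


def y_interactions(Df, p, food_only=True):
    """phi_j = d(latent share)/dy price-interaction part, with numeraire.

    For the full system the polynomial part of the numeraire equation is
    implied by adding-up; this helper returns (Dp)_j for all J+1
    equations given the full interaction matrix and (N, J+1) log prices.
    """
    out = np.einsum("jk,nk->nj", Df, p)
    return out[:, :-1] if food_only else out


def _dpoly_full(y, b):
    """d/dy polynomial for all J+1 equations (numeraire by adding-up)."""
    d = _dpoly(y, b)
    return np.column_stack([d, -d.sum(axis=1)])


def _full_dphi(b, Df, y, p):
    return _dpoly_full(y, b) + y_interactions(Df, p, food_only=False)


def share_derivatives(b, A, D, y, w_full, lnp, utility="exact"):
    """Total derivatives of the fixed-point demand.

    Returns ``(dw_dlnx, dw_dlnp, dy_dlnx, dy_dlnp)`` with shapes
    (N, J+1), (N, J+1, J+1), (N,), (N, J+1).  Derivatives are with
    respect to log total expenditures and each of the J+1 log prices
    (numeraire included), taken through the (w, y) fixed point with the
    latent error held fixed.
    """
    lnp = np.atleast_2d(lnp)
    N, J = lnp.shape
    Af = full_price_matrix(A)
    Df = full_price_matrix(D)
    p = np.column_stack([lnp, np.zeros(N)])

    dphi = _full_dphi(b, Df, y, p)  # (N, J+1)
    S = np.einsum("nk,nk->n", p, dphi)
    if utility == "exact":
        Delta = 1.0 - 0.5 * np.einsum("nj,jk,nk->n", p, Df, p)
        denom = Delta + S
        dy_dlnx = 1.0 / denom
        dy_dlnp = -w_full / denom[:, None]
    else:
        T = np.einsum("nj,jk->nk", p, Af) + y[:, None] * np.einsum("nj,jk->nk", p, Df)
        denom = 1.0 + S
        dy_dlnx = 1.0 / denom
        dy_dlnp = -(w_full + T) / denom[:, None]

    dw_dlnx = dphi * dy_dlnx[:, None]
    direct = Af[None, :, :] + y[:, None, None] * Df[None, :, :]
    dw_dlnp = direct + dphi[:, :, None] * dy_dlnp[:, None, :]
    return dw_dlnx, dw_dlnp, dy_dlnx, dy_dlnp


def elasticities_from_derivatives(w_full, dw_dlnx, dw_dlnp):
    """Expenditure and Marshallian/Hicksian price elasticities.

    eta_j = 1 + (dw_j/dlnx)/w_j
    eps_jk = (dw_j/dlnp_k)/w_j - delta_jk          (Marshallian)
    eps^H_jk = eps_jk + eta_j w_k                   (Hicksian)
    """
    w = w_full
    eta = 1.0 + dw_dlnx / w
    K = w.shape[1]
    eye = np.eye(K)
    E_marsh = dw_dlnp / w[:, :, None] - eye[None, :, :]
    E_hicks = E_marsh + eta[:, :, None] * w[:, None, :]
    return eta, E_marsh, E_hicks


def censored_mean_shares(w_latent_food, sigma):
    """Expected observed share under truncation at zero.

    For latent share mu with N(0, sigma^2) noise already included in the
    mean argument semantics: E[max(0, w)] where w ~ N(mu, sigma^2) is
    Phi(mu/sigma) mu + sigma phi(mu/sigma).  sigma may be a scalar or a
    length-J vector; sigma = 0 degenerates to max(mu, 0).
    """
    mu = np.asarray(w_latent_food, float)
    sig = np.broadcast_to(np.asarray(sigma, float), mu.shape)
    out = np.where(mu > 0, mu, 0.0)
    pos = sig > 0
    if np.any(pos):
        ratio = np.zeros_like(mu)
        ratio[pos] = mu[pos] / sig[pos]
        adj = norm.cdf(ratio) * mu + sig * norm.pdf(ratio)
        out = np.where(pos, adj, out)
    return out
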