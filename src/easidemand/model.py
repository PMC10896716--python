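"""Censored EASI demand system: model and results objects.

``EASIDemandModel`` is built from a :class:`~easidemand.prep.PreparedData`
table and estimates the J food-group share equations (the numeraire
equation is dropped and recovered by adding-up) by iterated linear
instrumental variables with cross-equation restrictions:

* symmetry and homogeneity of the price and price-utility matrices
  (homogeneity via the implied numeraire column);
* two endogeneity corrections: the average-share Stone index instruments
  the own-share Stone index inside implicit utility, and leave-one-out
  neighbour log prices instrument the household's Fisher group indices
  (quality choice and price search make unit values endogenous);
* community-level correlated random effects (Mundlak-Chamberlain
  cluster-mean regressors);
* a two-step censoring correction: a probit participation model per
  censored food group supplies Phi and phi, and the share equation
  becomes w = Phi * (latent index) + theta * phi.

``fit`` iterates between the linear IV solve and the implicit-utility
fixed point until predicted shares stabilise, and returns an
``EASIDemandResults`` with parameters, a household-clustered robust
covariance, diagnostics and ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import demand
from .prep import PreparedData

__all__ = ["EASIParameters", "FitReport", "EASIDemandModel",
           "EASIDemandResults", "select_degree"]


# ---------------------------------------------------------------------------
# parameters

@dataclass
class EASIParameters:
    """Structural parameters of the censored EASI system.

    ``A`` and ``D`` are the symmetric J x J food blocks; the numeraire
    rows/columns implied by adding-up are available via
    :meth:`A_full` / :meth:`D_full`.  ``theta`` are the censoring
    loadings on phi (zero for uncensored groups).
    """

    b: np.ndarray
    A: np.ndarray
    D: np.ndarray
    G: np.ndarray
    M: np.ndarray
    theta: np.ndarray
    Sigma: np.ndarray | None = None
    degree: int = 1
    group_names: list = field(default_factory=list)
    z_names: list = field(default_factory=list)
    cmeans_names: list = field(default_factory=list)
    utility: str = "exact"

    def __post_init__(self):
        self.b = np.atleast_2d(np.asarray(self.b, float))
        self.A = np.asarray(self.A, float)
        self.D = np.asarray(self.D, float)
        self.G = np.atleast_2d(np.asarray(self.G, float))
        self.M = np.atleast_2d(np.asarray(self.M, float))
        self.theta = np.asarray(self.theta, float)
        self.degree = self.b.shape[1] - 1

    @property
    def n_groups(self):
        return self.A.shape[0]

    def A_full(self):
        return demand.full_price_matrix(self.A)

    def D_full(self):
        return demand.full_price_matrix(self.D)

    @classmethod
    def cobb_douglas(cls, shares, n_z=0, n_c=0, **kw):
        """Constant-share (unit-elastic) benchmark preferences.

        ``shares`` are the J food budget shares; only b_j0 is nonzero,
        so demand is independent of prices and expenditures.
        """
        shares = np.asarray(shares, float)
        J = shares.size
        return cls(b=shares[:, None], A=np.zeros((J, J)), D=np.zeros((J, J)),
                   G=np.zeros((J, max(n_z, 0))), M=np.zeros((J, max(n_c, 0))),
                   theta=np.zeros(J), **kw)

    def solve(self, lnp, lnx, z=None, cmeans=None, **kw):
        G = self.G if self.G.size else None
        M = self.M if self.M.size else None
        return demand.solve_shares(self.b, self.A, self.D, G, M,
                                   lnp, lnx, z=z, cmeans=cmeans,
                                   utility=self.utility, **kw)

    def to_dict(self):
        return {
            "b": self.b.tolist(), "A": self.A.tolist(), "D": self.D.tolist(),
            "G": self.G.tolist(), "M": self.M.tolist(),
            "theta": self.theta.tolist(),
            "Sigma": None if self.Sigma is None else self.Sigma.tolist(),
            "degree": int(self.degree), "group_names": list(self.group_names),
            "z_names": list(self.z_names),
            "cmeans_names": list(self.cmeans_names), "utility": self.utility,
        }

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        sig = d.pop("Sigma", None)
        obj = cls(b=np.array(d.pop("b")), A=np.array(d.pop("A")),
                  D=np.array(d.pop("D")), G=np.array(d.pop("G")),
                  M=np.array(d.pop("M")), theta=np.array(d.pop("theta")),
                  degree=d.pop("degree", 1), **d)
        obj.Sigma = None if sig is None else np.array(sig)
        return obj


@dataclass
class FitReport:
    """Diagnostics of one fit: first stages, censoring, iteration path."""

    first_stage_F: dict = field(default_factory=dict)
    censoring_rates: np.ndarray | None = None
    iterations: list = field(default_factory=list)
    degree: int = 1
    criterion: str = "bic"
    criterion_values: dict = field(default_factory=dict)
    renormalization: float = 0.0
    notes: list = field(default_factory=list)


class _ParamIndex:
    """Free-parameter layout for the restricted stacked system."""

    def __init__(self, J, R, n_z, n_c, censored):
        self.J, self.R = J, R
        self.pairs = [(j, k) for j in range(J) for k in range(j, J)]
        self.censored = np.asarray(censored, bool)
        n = 0
        self.b_ix = np.arange(J * (R + 1)).reshape(J, R + 1); n += J * (R + 1)
        self.a_ix = {p: n + i for i, p in enumerate(self.pairs)}; n += len(self.pairs)
        self.d_ix = {p: n + i for i, p in enumerate(self.pairs)}; n += len(self.pairs)
        self.g_ix = np.arange(n, n + J * n_z).reshape(J, n_z); n += J * n_z
        self.m_ix = np.arange(n, n + J * n_c).reshape(J, n_c); n += J * n_c
        self.t_ix = {}
        for j in np.flatnonzero(self.censored):
            self.t_ix[int(j)] = n; n += 1
        self.n_free = n
        self.n_z, self.n_c = n_z, n_c

    def unpack(self, beta, **meta):
        J, R = self.J, self.R
        b = beta[self.b_ix]
        A = np.zeros((J, J)); D = np.zeros((J, J))
        for (j, k) in self.pairs:
            A[j, k] = A[k, j] = beta[self.a_ix[(j, k)]]
            D[j, k] = D[k, j] = beta[self.d_ix[(j, k)]]
        G = beta[self.g_ix] if self.n_z else np.zeros((J, 0))
        M = beta[self.m_ix] if self.n_c else np.zeros((J, 0))
        theta = np.zeros(J)
        for j, ix in self.t_ix.items():
            theta[j] = beta[ix]
        return EASIParameters(b=b, A=A, D=D, G=G, M=M, theta=theta, **meta)

    def pack(self, params: EASIParameters):
        beta = np.zeros(self.n_free)
        beta[self.b_ix] = params.b
        for (j, k) in self.pairs:
            beta[self.a_ix[(j, k)]] = params.A[j, k]
            beta[self.d_ix[(j, k)]] = params.D[j, k]
        if self.n_z:
            beta[self.g_ix] = params.G
        if self.n_c:
            beta[self.m_ix] = params.M
        for j, ix in self.t_ix.items():
            beta[ix] = params.theta[j]
        return beta


# ---------------------------------------------------------------------------
# model

class EASIDemandModel:
    """Censored EASI demand system on a prepared observation table.

    Parameters
    ----------
    data : PreparedData
    degree : polynomial degree R in implicit utility.
    utility : "exact" (exact affine Stone index, default) or "stone".
    censor : apply the two-step probit censoring correction.
    instrument : use the neighbour-price and average-share instruments;
        ``False`` gives the restricted least-squares benchmark.
    cre : include cluster-mean correlated-random-effects regressors.
    """

    def __init__(self, data: PreparedData, degree: int = 2,
                 utility: str = "exact", censor: bool = True,
                 instrument: bool = True, cre: bool = True,
                 weighting: str = "3sls"):
        if utility not in ("exact", "stone"):
            raise ValueError("utility must be 'exact' or 'stone'")
        if weighting not in ("3sls", "2sls"):
            raise ValueError("weighting must be '3sls' or '2sls'")
        self.data = data
        self.degree = int(degree)
        self.utility = utility
        self.censor = censor
        self.instrument = instrument
        self.cre = cre
        self.weighting = weighting
        self.J = data.n_groups
        if np.unique(data.wave).size < 2:
            raise ValueError("need at least 2 waves")

    # -- censoring first stage ------------------------------------------

    @staticmethod
    def censor_design(data: PreparedData):
        """Participation-probit regressors (exogenous and instruments only)."""
        y_inst = data.lnx - data.stone_avg
        return np.column_stack([np.ones(data.n_obs), y_inst, y_inst ** 2,
                                data.lnp_nbr, y_inst[:, None] * data.lnp_nbr,
                                data.z, data.cmeans])

    def fit_censoring_stage(self):
        """Probit participation model per food group.

        Returns ``(Phi, phi, coefs, censored, rates, notes)``; groups
        with no zero observations get Phi = 1, phi = 0 and a log note.
        """
        import statsmodels.api as sm

        data = self.data
        X = self.censor_design(data)
        N, J = data.n_obs, self.J
        Phi = np.ones((N, J)); phi = np.zeros((N, J))
        coefs = np.zeros((X.shape[1], J)); censored = np.zeros(J, bool)
        rates = np.zeros(J); notes = []
        for j in range(J):
            pos = data.w[:, j] > 0
            rates[j] = 1.0 - pos.mean()
            if pos.all():
                notes.append(f"group {data.group_names[j]}: no zeros, "
                             "censoring correction degenerate (Phi=1)")
                continue
            if not pos.any():
                raise ValueError(
                    f"group {data.group_names[j]} never consumed")
            import warnings
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.Probit(pos.astype(float), X).fit(disp=0,
                                                              maxiter=100)
                beta = res.params
            except Exception:  # failure to converge
                beta = None
            if beta is None or not np.all(np.isfinite(beta)):
                notes.append(f"group {data.group_names[j]}: probit failed "
                             "(perfect separation?), falling back to Phi=1")
                continue
            idx = np.clip(X @ beta, -8.0, 8.0)
            Phi[:, j] = norm.cdf(idx)
            phi[:, j] = norm.pdf(idx)
            coefs[:, j] = beta
            censored[j] = True
        return Phi, phi, coefs, censored, rates, notes

    # -- design construction --------------------------------------------

    def _build_design(self, pix: _ParamIndex, y, Phi, phi):
        data = self.data
        N, J, R = data.n_obs, self.J, self.degree
        lnp, z, cm = data.lnp, data.z, data.cmeans
        X = np.zeros((J, N, pix.n_free))
        ypow = np.vander(y, R + 1, increasing=True)
        for j in range(J):
            Pj = Phi[:, j]
            X[j, :, pix.b_ix[j]] = (Pj[:, None] * ypow).T
            for (k, l) in pix.pairs:
                col = pix.a_ix[(k, l)]
                dcol = pix.d_ix[(k, l)]
                if j == k:
                    X[j, :, col] += Pj * lnp[:, l]
                    X[j, :, dcol] += Pj * y * lnp[:, l]
                if j == l and l != k:
                    X[j, :, col] += Pj * lnp[:, k]
                    X[j, :, dcol] += Pj * y * lnp[:, k]
            if pix.n_z:
                X[j, :, pix.g_ix[j]] = (Pj[:, None] * z).T
            if pix.n_c:
                X[j, :, pix.m_ix[j]] = (Pj[:, None] * cm).T
            if j in pix.t_ix:
                X[j, :, pix.t_ix[j]] = phi[:, j]
        return X

    def _instrument_basis(self, phi):
        """Orthonormal basis of the common instrument set.

        Instruments: constant, powers of the average-share-deflated log
        expenditure, neighbour log prices and their interactions with
        it, shifters, cluster means, and the (exogenous) probit phi
        columns of the censored equations.
        """
        data = self.data
        y_inst = data.lnx - data.stone_avg
        R = self.degree
        ypow = np.vander(y_inst, R + 1, increasing=True)[:, 1:]
        inter = y_inst[:, None] * data.lnp_nbr
        cols = [np.ones(data.n_obs), ypow, data.lnp_nbr, inter, data.z,
                data.cmeans]
        act = [phi[:, j] for j in range(self.J) if np.any(phi[:, j])]
        if act:
            cols.append(np.column_stack(act))
        Z = np.column_stack(cols)
        Q, Rm = np.linalg.qr(Z)
        keep = np.abs(np.diag(Rm)) > 1e-10 * np.abs(np.diag(Rm)).max()
        return Q[:, keep]

    # -- estimation ------------------------------------------------------

    def _iv_loop(self, pix, wvec, Phi, phi, y0, maxiter, tol, damping,
                 meta, report, stage, phi_inst=None, weight=None):
        """Inner iterated linear IV solve with the y fixed point.

        ``phi_inst`` is the exogenous participation density used as the
        instrument for the phi regressor (the first-stage probit phi;
        the refined structural phi is endogenous and must not
        instrument itself).  ``weight`` is the inverse residual
        covariance across equations for the 3SLS step (identity when
        None).
        """
        data = self.data
        N, J = data.n_obs, self.J
        Q = self._instrument_basis(phi if phi_inst is None else phi_inst) \
            if self.instrument else None
        y = y0.copy()
        wpred_prev = None
        W = weight
        wmat = wvec.reshape(J, N)
        for it in range(maxiter):
            X = self._build_design(pix, y, Phi, phi)
            if self.instrument:
                Xhat3 = np.stack([Q @ (Q.T @ X[j]) for j in range(J)])
            else:
                Xhat3 = X
            Xflat = X.reshape(J * N, pix.n_free)
            Xhat = Xhat3.reshape(J * N, pix.n_free)
            if W is None:
                XtX = Xhat.T @ Xflat
                Xtw = Xhat.T @ wvec
            else:
                # 3SLS: X'(W kron P_Z)X and X'(W kron P_Z)w; P_Z = QQ'
                # is common across equations so Xhat_j' Xhat_k is exact
                XtX = np.zeros((pix.n_free, pix.n_free))
                Xtw = np.zeros(pix.n_free)
                for j in range(J):
                    for k in range(J):
                        if W[j, k] == 0.0:
                            continue
                        XtX += W[j, k] * (Xhat3[j].T @ Xhat3[k])
                        Xtw += W[j, k] * (Xhat3[j].T @ wmat[k])
            try:
                beta = np.linalg.solve(XtX, Xtw)
            except np.linalg.LinAlgError as e:
                raise RuntimeError(
                    "rank-deficient restricted system (collinear regressors "
                    "or instruments)") from e
            if not np.all(np.isfinite(beta)):
                raise RuntimeError("non-finite estimates: instrument "
                                   "column collinearity suspected")
            params = pix.unpack(beta, **meta)
            wpred = Xflat @ beta
            delta = np.inf if wpred_prev is None else \
                float(np.max(np.abs(wpred - wpred_prev)))
            report.iterations.append({"stage": stage, "iter": it,
                                      "max_dshare": delta})
            wpred_prev = wpred
            # update implicit utility from current A, D and observed shares
            y_new = demand.implicit_utility(data.lnx, data.w, data.lnp,
                                            params.A, params.D, self.utility)
            y = (1.0 - damping) * y + damping * y_new
            if delta < tol:
                return beta, params, y, X, Xhat3, XtX
        raise RuntimeError(
            f"estimation did not converge in {maxiter} iterations; "
            f"trace tail {[r['max_dshare'] for r in report.iterations[-5:]]}")

    @staticmethod
    def _calibrate_sigma(m, zero_rate, sig_ref=None):
        """Latent-error scale matching a group's observed zero rate.

        Solves mean Phi(-m_i / sigma) = zero_rate for sigma given latent
        mean predictions m; used to turn the fitted latent index into
        participation probabilities without the first-stage probit
        approximation.  When ``sig_ref`` (the equation's residual scale)
        is given, the solution is clipped to [sig_ref/4, 4 sig_ref]: a
        root far outside the residual scale signals a biased latent
        mean, and an unbounded sigma would flatten Phi and destabilise
        the next pass.
        """
        from scipy.optimize import brentq

        def f(sig):
            return float(norm.cdf(-m / sig).mean()) - zero_rate

        lo, hi = 1e-4, 2.0
        if f(lo) >= 0:
            sig = lo
        elif f(hi) <= 0:
            sig = hi
        else:
            sig = float(brentq(f, lo, hi, xtol=1e-10))
        out_of_band = False
        if sig_ref is not None and sig_ref > 0:
            clipped = float(np.clip(sig, sig_ref / 4.0, sig_ref * 4.0))
            out_of_band = clipped != sig
            sig = clipped
        return sig, out_of_band

    def fit(self, maxiter: int = 100, tol: float = 1e-8, damping: float = 0.5,
            compute_cov: bool = True, structural_iters: int = 3) \
            -> "EASIDemandResults":
        data = self.data
        N, J, R = data.n_obs, self.J, self.degree

        if self.censor:
            Phi, phi, cens_coefs, censored, rates, notes = \
                self.fit_censoring_stage()
        else:
            Phi = np.ones((N, J)); phi = np.zeros((N, J))
            cens_coefs = None; censored = np.zeros(J, bool)
            rates = (data.w[:, :J] == 0).mean(axis=0); notes = []

        n_z, n_c = data.z.shape[1], (data.cmeans.shape[1] if self.cre else 0)
        pix = _ParamIndex(J, R, n_z, n_c, censored)
        wvec = data.w[:, :J].T.reshape(-1)

        y_inst = data.lnx - data.stone_avg
        report = FitReport(censoring_rates=rates, degree=R, notes=list(notes))
        meta = dict(group_names=data.group_names, z_names=data.z_names,
                    cmeans_names=(data.cmeans_names if self.cre else []),
                    utility=self.utility)

        # stage 1: Shonkwiler-Yen two-step with probit participation
        # fields and a free theta loading per censored equation
        phi0 = phi.copy()
        beta, params, y, X3, Xhat3, XtX = self._iv_loop(
            pix, wvec, Phi, phi, y_inst, maxiter, tol, damping, meta,
            report, stage="probit")
        wfit = wvec

        # stage 2: structural participation fields.  The probit index is
        # only a projection of the true latent index m/sigma, which
        # attenuates Phi and biases the correction; here Phi and phi are
        # rebuilt from the model's own latent prediction with sigma
        # calibrated to each group's zero rate (exact at the truth), and
        # the phi term moves to the left-hand side with coefficient
        # sigma (a free theta would be collinear with the Phi-scaled
        # regressors)
        sigma_cens = np.zeros(J)
        cm = data.cmeans if n_c else None
        if self.censor and censored.any() and structural_iters > 0:
            pix_s = _ParamIndex(J, R, n_z, n_c, np.zeros(J, bool))
            zero_phi = np.zeros((N, J))
            prev_target = wfit
            Phi0 = Phi.copy()
            theta0 = params.theta.copy()   # SY free loadings, stage 1
            structural_ok = censored.copy()
            for ref in range(structural_iters):
                resid = prev_target.reshape(J, N) \
                    - np.einsum("jnk,k->jn", X3, beta)
                resid_sd = resid.std(axis=1)
                m = demand.latent_food_shares(
                    params.b, params.A, params.D,
                    params.G if n_z else None, params.M if n_c else None,
                    y, data.lnp, data.z if n_z else None, cm)
                Phi = np.ones((N, J)); phi = np.zeros((N, J))
                offsets = np.zeros((J, N))
                for j in np.flatnonzero(censored):
                    if structural_ok[j]:
                        sigma_cens[j], bad = self._calibrate_sigma(
                            m[:, j], rates[j], sig_ref=resid_sd[j])
                        if bad:
                            # calibrated scale inconsistent with the
                            # residual scale: the latent mean is not
                            # trustworthy for this group, keep the
                            # probit (Shonkwiler-Yen) fields instead
                            structural_ok[j] = False
                            report.notes.append(
                                f"group {data.group_names[j]}: structural "
                                "censoring scale out of band, keeping the "
                                "probit correction")
                    if structural_ok[j]:
                        idx = np.clip(m[:, j] / sigma_cens[j], -8, 8)
                        Phi[:, j] = norm.cdf(idx)
                        phi[:, j] = norm.pdf(idx)
                        offsets[j] = sigma_cens[j] * phi[:, j]
                    else:
                        sigma_cens[j] = 0.0
                        Phi[:, j] = Phi0[:, j]
                        offsets[j] = theta0[j] * phi0[:, j]
                wfit = wvec - offsets.reshape(-1)
                beta, params, y, X3, Xhat3, XtX = self._iv_loop(
                    pix_s, wfit, Phi, zero_phi, y, maxiter, tol, damping,
                    meta, report, stage=f"structural{ref + 1}",
                    phi_inst=phi0)
                prev_target = wfit
            pix = pix_s
            # loadings for prediction: calibrated sigma where structural,
            # the stage-1 probit loading otherwise
            params.theta = np.where(structural_ok, sigma_cens, theta0)
            params.theta[~censored] = 0.0

        u = wfit - X3.reshape(J * N, -1) @ beta
        U = u.reshape(J, N)
        Sigma = (U @ U.T) / N

        Wmat = None
        if self.weighting == "3sls":
            ev = np.linalg.eigvalsh(Sigma)
            if ev.min() > 1e-10 * max(ev.max(), 1e-30):
                Wmat = np.linalg.inv(Sigma)
                phi_reg = phi if not sigma_cens.any() else np.zeros((N, J))
                beta, params, y, X3, Xhat3, XtX = self._iv_loop(
                    pix, wfit, Phi, phi_reg, y, maxiter, tol, damping, meta,
                    report, stage="3sls", phi_inst=phi0, weight=Wmat)
                u = wfit - X3.reshape(J * N, -1) @ beta
                U = u.reshape(J, N)
                Sigma = (U @ U.T) / N
            else:
                report.notes.append("residual covariance near-singular; "
                                    "kept unweighted (2SLS) estimates")

        if sigma_cens.any():
            # re-calibrate the structural groups at the final parameters
            resid_sd = U.std(axis=1)
            m = demand.latent_food_shares(
                params.b, params.A, params.D,
                params.G if n_z else None, params.M if n_c else None,
                y, data.lnp, data.z if n_z else None, cm)
            for j in np.flatnonzero(sigma_cens > 0):
                sigma_cens[j], _ = self._calibrate_sigma(
                    m[:, j], rates[j], sig_ref=resid_sd[j])
                params.theta[j] = sigma_cens[j]

        params.Sigma = Sigma
        rss = float(u @ u)
        k = pix.n_free
        nobs = J * N
        report.criterion_values = {
            "rss": rss,
            "bic": nobs * np.log(rss / nobs) + k * np.log(nobs),
            "aic": nobs * np.log(rss / nobs) + 2 * k,
        }

        cov = None
        if compute_cov:
            bread = np.linalg.inv(XtX)
            WU = U if Wmat is None else Wmat @ U
            scores = Xhat3.reshape(J * N, -1) * WU.reshape(-1)[:, None]
            hh_codes = pd.factorize(np.tile(data.hh, J))[0]
            S = np.zeros((hh_codes.max() + 1, pix.n_free))
            np.add.at(S, hh_codes, scores)
            cov = bread @ (S.T @ S) @ bread.T

        if self.instrument:
            report.first_stage_F = self._first_stage_stats(phi)

        return EASIDemandResults(self, params, pix, beta, cov, report,
                                 Phi=Phi, phi=phi, cens_coefs=cens_coefs,
                                 censored=censored, y=y,
                                 sigma_cens=sigma_cens if self.censor else None)

    def _first_stage_stats(self, phi):
        """Partial F of the excluded instruments per endogenous regressor."""
        data = self.data
        y_inst = data.lnx - data.stone_avg
        R = self.degree
        ypow_i = np.vander(y_inst, R + 1, increasing=True)[:, 1:]
        inter = y_inst[:, None] * data.lnp_nbr
        excl = np.column_stack([ypow_i, data.lnp_nbr, inter])
        exog = np.column_stack([np.ones(data.n_obs), data.z, data.cmeans])
        Zfull = np.column_stack([exog, excl])
        y_own = data.lnx - (data.w[:, :-1] * data.lnp).sum(axis=1)
        endos = {"y": y_own}
        for r in range(2, R + 1):
            endos[f"y^{r}"] = y_own ** r
        for j, g in enumerate(data.group_names):
            endos[f"lnp_{g}"] = data.lnp[:, j]
        out = {}
        N = data.n_obs
        q = excl.shape[1]
        for name, v in endos.items():
            rss_r = _ols_rss(exog, v)
            rss_u = _ols_rss(Zfull, v)
            dof = N - Zfull.shape[1]
            out[name] = float(((rss_r - rss_u) / q) / (rss_u / dof))
        return out


def _ols_rss(X, v):
    beta, res, *_ = np.linalg.lstsq(X, v, rcond=None)
    r = v - X @ beta
    return float(r @ r)


# ---------------------------------------------------------------------------
# results

class EASIDemandResults:
    """Fitted censored EASI system.

    Carries the structural parameters, the free-parameter vector and its
    household-clustered covariance, the censoring first stage, and the
    converged implicit utility.  Elasticities, diet-quality scoring and
    policy simulation consume this object.
    """

    def __init__(self, model, params, pix, beta, cov, report,
                 Phi=None, phi=None, cens_coefs=None, censored=None, y=None,
                 sigma_cens=None):
        self.model = model
        self.params: EASIParameters = params
        self._pix = pix
        self.beta = beta
        self.cov = cov
        self.report: FitReport = report
        self.Phi, self.phi = Phi, phi
        self.cens_coefs = cens_coefs
        self.censored = censored
        self.y = y
        self.sigma_cens = sigma_cens

    @property
    def data(self):
        return self.model.data

    # -- prediction ------------------------------------------------------

    def censor_fields(self, data: PreparedData, w_latent_food=None):
        """(Phi, phi) evaluated on (possibly counterfactual) data.

        Uses the same participation fields the share equations were
        estimated with, so adjusted predictions are mean-consistent with
        the fitted data: the structural latent index m/sigma when the
        structural stage ran (re-evaluable on counterfactual data
        because m shifts with prices and expenditures), otherwise the
        first-stage probit.
        """
        J = self.params.n_groups
        N = data.n_obs
        Phi = np.ones((N, J)); phi = np.zeros((N, J))
        if self.censored is None or not np.any(self.censored):
            return Phi, phi
        probit_idx = None
        for j in np.flatnonzero(self.censored):
            if self.sigma_cens is not None and self.sigma_cens[j] > 0:
                if w_latent_food is None:
                    cmeans = data.cmeans if self.params.M.size else None
                    w_lat, _ = self.params.solve(data.lnp, data.lnx,
                                                 z=data.z, cmeans=cmeans)
                    w_latent_food = w_lat[:, :J]
                idx = np.clip(w_latent_food[:, j] / self.sigma_cens[j],
                              -8, 8)
            elif self.cens_coefs is not None:
                if probit_idx is None:
                    X = EASIDemandModel.censor_design(data)
                    probit_idx = np.clip(X @ self.cens_coefs, -8.0, 8.0)
                idx = probit_idx[:, j]
            else:
                continue
            Phi[:, j] = norm.cdf(idx)
            phi[:, j] = norm.pdf(idx)
        return Phi, phi

    def predict_shares(self, data: PreparedData | None = None,
                       adjusted: bool = True, renormalize: bool = True):
        """Predicted budget shares (latent or censoring-adjusted mean).

        Solves the (w, y) fixed point at each observation's prices,
        expenditures and shifters.  With ``adjusted`` the unconditional
        mean w_j = Phi_j * latent + theta_j * phi_j is returned; the
        numeraire closes the budget and the vector is renormalised to
        the simplex (the renormalisation magnitude is logged).
        """
        data = data if data is not None else self.data
        cmeans = data.cmeans if self.params.M.size else None
        w_lat, y = self.params.solve(data.lnp, data.lnx, z=data.z,
                                     cmeans=cmeans)
        if not adjusted:
            return w_lat
        J = self.params.n_groups
        Phi, phi = self.censor_fields(data, w_latent_food=w_lat[:, :J])
        w_food = Phi * w_lat[:, :J] + phi * self.params.theta[None, :]
        w = np.column_stack([w_food, 1.0 - w_food.sum(axis=1)])
        if renormalize:
            wc = np.clip(w, 0.0, None)
            s = wc.sum(axis=1, keepdims=True)
            self.report.renormalization = float(np.abs(wc / s - w).max())
            w = wc / s
        return w

    # -- downstream conveniences ----------------------------------------

    def elasticities(self, data=None, **kw):
        from . import elasticity
        return elasticity.compute_elasticities(
            self.params, data if data is not None else self.data, **kw)

    def simulate_params(self, n_draws: int, seed: int = 0):
        """Parameter draws from N(beta, cov); restrictions hold by
        construction since the free vector encodes symmetric blocks."""
        if self.cov is None:
            raise ValueError("covariance not computed")
        rng = np.random.default_rng(seed)
        cov = 0.5 * (self.cov + self.cov.T)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            vals, vecs = np.linalg.eigh(cov)
            vals = np.clip(vals, 0.0, None)
            L = vecs * np.sqrt(vals)
            self.report.notes.append(
                "covariance repaired to nearest PSD for simulation")
        meta = dict(group_names=self.params.group_names,
                    z_names=self.params.z_names,
                    cmeans_names=self.params.cmeans_names,
                    utility=self.params.utility)
        for _ in range(n_draws):
            draw = self.beta + L @ rng.standard_normal(len(self.beta))
            yield self._pix.unpack(draw, **meta)

    def summary(self):
        p = self.params
        lines = ["Censored EASI demand system", "=" * 60]
        lines.append(f"observations: {self.data.n_obs}   food groups: "
                     f"{p.n_groups}   degree R: {p.degree}   "
                     f"utility: {p.utility}")
        if self.report.iterations:
            lines.append(f"iterations: {len(self.report.iterations)}   "
                         f"converged dshare: "
                         f"{self.report.iterations[-1]['max_dshare']:.2e}")
        se = None
        if self.cov is not None:
            se_vec = np.sqrt(np.clip(np.diag(self.cov), 0, None))
            se = self._pix.unpack(se_vec, group_names=p.group_names)
        lines.append("")
        lines.append("own-price coefficients a_jj (se) and censoring rates:")
        for j, g in enumerate(p.group_names):
            s = f"  {g:<18} a_jj = {p.A[j, j]:+.4f}"
            if se is not None:
                s += f" ({se.A[j, j]:.4f})"
            if self.report.censoring_rates is not None and \
                    len(self.report.censoring_rates) > j:
                s += f"   zero share: {self.report.censoring_rates[j]:.1%}"
            lines.append(s)
        if self.report.first_stage_F:
            fmin = min(self.report.first_stage_F.values())
            lines.append(f"first-stage partial F (min over endogenous "
                         f"regressors): {fmin:.1f}")
        for n in self.report.notes:
            lines.append(f"note: {n}")
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------

    def save(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        blob = self.params.to_dict()
        blob["censored"] = None if self.censored is None \
            else self.censored.astype(int).tolist()
        blob["cens_coefs"] = None if self.cens_coefs is None \
            else self.cens_coefs.tolist()
        blob["sigma_cens"] = None if self.sigma_cens is None \
            else np.asarray(self.sigma_cens).tolist()
        blob["beta"] = self.beta.tolist()
        with open(outdir / "params.json", "w") as f:
            json.dump(blob, f, indent=1)
        if self.cov is not None:
            np.savetxt(outdir / "cov.csv", self.cov, delimiter=",")
        with open(outdir / "fit_report.json", "w") as f:
            json.dump({
                "first_stage_F": self.report.first_stage_F,
                "censoring_rates": self.report.censoring_rates.tolist(),
                "iterations": self.report.iterations,
                "criterion_values": self.report.criterion_values,
                "notes": self.report.notes,
            }, f, indent=1, default=float)
        return outdir

    @classmethod
    def load(cls, indir, model=None):
        indir = Path(indir)
        with open(indir / "params.json") as f:
            blob = json.load(f)
        censored = blob.pop("censored", None)
        cens_coefs = blob.pop("cens_coefs", None)
        sigma_cens = blob.pop("sigma_cens", None)
        beta = np.array(blob.pop("beta"))
        params = EASIParameters.from_dict(blob)
        cov = None
        if (indir / "cov.csv").exists():
            cov = np.loadtxt(indir / "cov.csv", delimiter=",")
        J = params.n_groups
        censored = None if censored is None else np.array(censored, bool)
        # the structural censoring stage has no free theta, so the saved
        # beta may or may not carry theta slots; match by length
        pix = _ParamIndex(J, params.degree, params.G.shape[1],
                          params.M.shape[1], np.zeros(J, bool))
        if pix.n_free != len(beta) and censored is not None:
            pix = _ParamIndex(J, params.degree, params.G.shape[1],
                              params.M.shape[1], censored)
        res = cls(model, params, pix, beta, cov, FitReport(
            censoring_rates=np.zeros(J), degree=params.degree))
        res.censored = censored
        res.cens_coefs = None if cens_coefs is None else np.array(cens_coefs)
        res.sigma_cens = None if sigma_cens is None else np.array(sigma_cens)
        return res


def select_degree(data: PreparedData, degrees=(1, 2, 3, 4, 5),
                  criterion: str = "bic", **model_kw):
    """Fit each candidate polynomial degree and keep the criterion minimiser.

    Returns the winning ``EASIDemandResults``; the criterion value of
    every candidate is recorded in its fit report.
    """
    results = {}
    values = {}
    for R in degrees:
        res = EASIDemandModel(data, degree=R, **model_kw).fit()
        results[R] = res
        values[R] = res.report.criterion_values[criterion]
    best = min(values, key=values.get)
    win = results[best]
    win.report.criterion = criterion
    win.report.criterion_values = {f"{criterion}_R{R}": v
                                   for R, v in values.items()}
    win.report.criterion_values["selected_degree"] = best
    return win
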