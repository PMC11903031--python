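"""Bayesian linear regression in warped space.

Per phenotype, the model is

    phi(y_n) = w' phi(x_n) + eps_n,    eps_n ~ N(0, sigma^2),
    w ~ N(0, omega^2 I),

where phi(y) is the monotone warp (``warp`` module) and phi(x) the feature
expansion (``basis`` module).  The posterior over weights is Gaussian with
precision A = sigma^-2 Phi'Phi + omega^-2 I and mean
w_bar = sigma^-2 A^-1 Phi' phi(y).  Hyper-parameters (sigma^2, omega^2 and
the warp shape gamma) are estimated by maximising the warped marginal
log-likelihood: the Gaussian evidence of phi(y) under
N(0, sigma^2 I + omega^2 Phi Phi') plus the Jacobian term
sum_n log phi'(y_n).

The cross-sectional deviation score of a subject (x, y) is

    z = (phi(y) - w_bar' phi(x)) / sqrt(phi(x)' A^-1 phi(x) + sigma^2),

standard normal for the healthy population the model was trained on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .basis import BasisSpec, design_matrix, expand_basis
from .warp import WarpSpec, warp, warp_logderiv

logger = logging.getLogger(__name__)

SIGMA2_FLOOR = 1e-8


class UnknownSiteError(ValueError):
    """Raised when scoring at a site the model has not seen nor been adapted to."""


@dataclass
class PosteriorModel:
    """Fitted normative model for one phenotype.

    ``chol_A`` is the lower Cholesky factor of the posterior precision A;
    A itself is never inverted elementwise.  ``adaptations`` maps site
    labels unseen at training time to their residual recentering/rescaling
    (see ``site_adapt``).
    """

    w_bar: np.ndarray
    chol_A: np.ndarray
    sigma2: float
    omega2: float
    warp: WarpSpec
    basis: BasisSpec
    n_train: int
    adaptations: dict = field(default_factory=dict)

    @property
    def A(self) -> np.ndarray:
        return self.chol_A @ self.chol_A.T

    def quad_Ainv(self, V: np.ndarray) -> np.ndarray:
        """Row-wise quadratic form diag(V A^-1 V') for V of shape (n, K)."""
        V = np.atleast_2d(V)
        X = linalg.solve_triangular(self.chol_A, V.T, lower=True)
        return np.einsum("ij,ij->j", X, X)


def fit_posterior(
    design: np.ndarray,
    warped_targets: np.ndarray,
    sigma2: float,
    omega2: float,
    *,
    warp_spec: WarpSpec | None = None,
    basis: BasisSpec | None = None,
) -> PosteriorModel:
    """Closed-form Gaussian posterior over weights.

    An empty design (N = 0) returns the prior: w_bar = 0, A = omega^-2 I.
    K > N is allowed (the prior regularises) but logged.
    """
    Phi = np.asarray(design, dtype=float)
    if Phi.ndim != 2:
        raise ValueError("design must be a 2-d array")
    y = np.asarray(warped_targets, dtype=float).ravel()
    if Phi.shape[0] != y.size:
        raise ValueError("design and targets disagree on N")
    if not (np.all(np.isfinite(Phi)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite entries in design or targets")
    if not (sigma2 > 0 and omega2 > 0):
        raise ValueError("sigma2 and omega2 must be > 0")
    n, K = Phi.shape
    if 0 < n < K:
        logger.info("fit_posterior: K=%d > N=%d; posterior is prior-dominated", K, n)

    A = Phi.T @ Phi / sigma2 + np.eye(K) / omega2
    L = linalg.cholesky(A, lower=True)
    rhs = Phi.T @ y / sigma2
    w_bar = linalg.cho_solve((L, True), rhs)
    return PosteriorModel(
        w_bar=w_bar, chol_A=L, sigma2=float(sigma2), omega2=float(omega2),
        warp=warp_spec or WarpSpec(), basis=basis, n_train=n,
    )


def warped_marginal_loglik(
    raw_targets: np.ndarray,
    design: np.ndarray,
    sigma2: float,
    omega2: float,
    warp_spec: WarpSpec,
) -> float:
    """Log marginal likelihood of the raw targets under the warped model.

    Evidence of phi(y) under N(0, sigma^2 I + omega^2 Phi Phi'), computed
    through the K x K posterior precision (Woodbury), plus the warp
    Jacobian sum_n log phi'(y_n).
    """
    if not (sigma2 > 0 and omega2 > 0):
        raise ValueError("variances must be > 0")
    Phi = np.asarray(design, dtype=float)
    y_raw = np.asarray(raw_targets, dtype=float).ravel()
    n, K = Phi.shape
    yw = warp(y_raw, warp_spec)

    A = Phi.T @ Phi / sigma2 + np.eye(K) / omega2
    L = linalg.cholesky(A, lower=True)
    b = Phi.T @ yw
    u = linalg.solve_triangular(L, b, lower=True)
    # y' C^-1 y with C = sigma^2 I + omega^2 Phi Phi'
    quad = (yw @ yw) / sigma2 - (u @ u) / sigma2**2
    # log|C| = n log sigma^2 + K log omega^2 + log|A|
    logdet = n * np.log(sigma2) + K * np.log(omega2) + 2 * np.sum(np.log(np.diag(L)))
    evidence = -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
    return float(evidence + np.sum(warp_logderiv(y_raw, warp_spec)))


def _pack_warp(family: str, theta: np.ndarray, loc: float, scale: float) -> WarpSpec:
    if family == "identity":
        return WarpSpec()
    a, log_b = theta
    return WarpSpec(family="sinh-arcsinh", gamma=(float(a), float(np.exp(log_b))),
                    loc=loc, scale=scale)


def optimize_hyperparams(
    raw_targets: np.ndarray,
    design: np.ndarray,
    warp_family: str = "identity",
    *,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-6,
) -> tuple[float, float, WarpSpec]:
    """Maximise the warped marginal log-likelihood.

    Search is quasi-Newton (L-BFGS-B) in (log sigma^2, log omega^2) and,
    for the sinh-arcsinh family, unconstrained (a, log b); multi-start
    with ``n_restarts`` seeded perturbations around a moment-based
    initialisation.  The warp's standardization (loc, scale) is frozen at
    the target mean and standard deviation.

    Returns ``(sigma2, omega2, warp_spec)`` at the best optimum found.
    """
    y_raw = np.asarray(raw_targets, dtype=float).ravel()
    Phi = np.asarray(design, dtype=float)
    n, K = Phi.shape
    if n < K:
        logger.info("optimize_hyperparams: N=%d < K=%d", n, K)

    loc = float(np.mean(y_raw))
    sd = float(np.std(y_raw))
    scale = sd if sd > 0 else 1.0
    n_warp = 0 if warp_family == "identity" else 2

    def unpack(params):
        sigma2 = max(float(np.exp(params[0])), SIGMA2_FLOOR)
        omega2 = max(float(np.exp(params[1])), SIGMA2_FLOOR)
        wspec = _pack_warp(warp_family, params[2:], loc, scale)
        return sigma2, omega2, wspec

    def neg_loglik(params):
        sigma2, omega2, wspec = unpack(params)
        try:
            return -warped_marginal_loglik(y_raw, Phi, sigma2, omega2, wspec)
        except (linalg.LinAlgError, FloatingPointError, OverflowError):
            return 1e12

    var0 = sd**2 if sd > 0 else SIGMA2_FLOOR
    base = np.r_[np.log(var0), np.log(max(var0, 1.0)), np.zeros(n_warp)]
    rng = np.random.default_rng(seed)
    starts = [base] + [base + rng.normal(0, 0.5, size=base.size) for _ in range(n_restarts - 1)]

    best = None
    any_converged = False
    start_values = [-neg_loglik(s) for s in starts]
    for s in starts:
        res = optimize.minimize(neg_loglik, s, method="L-BFGS-B",
                                options={"ftol": tol, "maxiter": 500})
        any_converged = any_converged or res.success
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("hyper-parameter optimisation failed to produce a finite optimum")
    if not any_converged:
        sigma2, omega2, wspec = unpack(best.x)
        raise RuntimeError(
            "hyper-parameter optimisation did not converge from any restart; "
            f"best found sigma2={sigma2:.4g}, omega2={omega2:.4g}, warp={wspec}"
        )
    # a successful restart never ends below its own initialisation
    if -best.fun < max(start_values) - 1e-6:
        logger.warning("optimizer returned a point below an initialisation; keeping best start")
    sigma2, omega2, wspec = unpack(best.x)
    if sigma2 <= SIGMA2_FLOOR * 1.01:
        logger.warning("sigma2 hit its lower bound %.1e", SIGMA2_FLOOR)
    return sigma2, omega2, wspec


# ---------------------------------------------------------------------------
# prediction and scoring

def _phi_for_scoring(x_row: Mapping, model: PosteriorModel):
    """Feature vector and (optional) adaptation for a covariate record."""
    site = x_row.get("site")
    if site is not None and model.basis.site_labels and site not in model.basis.site_labels:
        adapt = model.adaptations.get(site)
        if adapt is None:
            raise UnknownSiteError(
                f"site {site!r} is neither in the training sites nor adapted; "
                "run site adaptation first"
            )
        return expand_basis(x_row, model.basis, zero_site_block=True), adapt
    return expand_basis(x_row, model.basis), None


def predictive(x_row: Mapping, model: PosteriorModel) -> tuple[float, float]:
    """Warped-space predictive mean and variance for covariates x.

    mean = w_bar' phi(x); variance = phi(x)' A^-1 phi(x) + sigma^2.
    Raises ``UnknownSiteError`` for unadapted new sites.
    """
    phi, adapt = _phi_for_scoring(x_row, model)
    if adapt is not None:
        raise UnknownSiteError(
            f"predictive distribution at adapted site {x_row.get('site')!r} is only "
            "defined up to the adaptation's offset/scale; use zscore instead"
        )
    mean = float(model.w_bar @ phi)
    var = float(model.quad_Ainv(phi)[0] + model.sigma2)
    return mean, var


def zscore(y: float, x_row: Mapping, model: PosteriorModel) -> float:
    """Cross-sectional deviation score of one observation.

    At adapted sites the site-agnostic residual is recentred and rescaled
    with the site's adaptation constants.
    """
    phi, adapt = _phi_for_scoring(x_row, model)
    yw = float(warp(y, model.warp))
    r = (yw - float(model.w_bar @ phi)) / np.sqrt(model.quad_Ainv(phi)[0] + model.sigma2)
    if adapt is not None:
        r = (r - adapt.offset) / adapt.scale
    return float(r)


# ---------------------------------------------------------------------------
# model collections (one PosteriorModel per phenotype)

@dataclass
class NormativeModel:
    """A collection of per-phenotype posterior models sharing one basis."""

    basis: BasisSpec
    idps: dict[str, PosteriorModel]

    @property
    def idp_names(self) -> list[str]:
        return list(self.idps)


def build_basis_from_data(
    df: pd.DataFrame,
    *,
    spline_degree: int = 3,
    n_interior_knots: int = 5,
    linear_covariates: tuple[str, ...] = ("sex",),
) -> BasisSpec:
    """Cubic age spline with interior knots at equally spaced age quantiles,
    boundary knots at the training age range, sites one-hot, intercept on."""
    ages = np.asarray(df["age"], dtype=float)
    lo, hi = float(ages.min()), float(ages.max())
    if n_interior_knots > 0:
        qs = np.linspace(0, 1, n_interior_knots + 2)[1:-1]
        interior = tuple(float(q) for q in np.quantile(ages, qs))
    else:
        interior = ()
    sites = tuple(sorted(map(str, pd.unique(df["site"])))) if "site" in df else ()
    return BasisSpec(
        spline_degree=spline_degree,
        interior_knots=interior,
        boundary_knots=(lo, hi),
        linear_covariates=linear_covariates,
        site_labels=sites,
    )


def fit_normative_model(
    train: pd.DataFrame,
    idp_cols: list[str],
    *,
    basis: BasisSpec | None = None,
    warp_family: str = "identity",
    sigma2: float | None = None,
    omega2: float | None = None,
    seed: int = 0,
    n_restarts: int = 5,
) -> NormativeModel:
    """Fit one posterior model per phenotype column.

    Hyper-parameters are estimated per phenotype by marginal-likelihood
    maximisation unless ``sigma2`` and ``omega2`` are both given (then the
    warp is the identity and the values are used as known).
    """
    if basis is None:
        basis = build_basis_from_data(train)
    Phi = design_matrix(train, basis)
    models: dict[str, PosteriorModel] = {}
    for j, idp in enumerate(idp_cols):
        y_raw = np.asarray(train[idp], dtype=float)
        if sigma2 is not None and omega2 is not None:
            s2, o2, wspec = float(sigma2), float(omega2), WarpSpec()
        else:
            s2, o2, wspec = optimize_hyperparams(
                y_raw, Phi, warp_family, seed=seed + j, n_restarts=n_restarts
            )
        models[idp] = fit_posterior(
            Phi, warp(y_raw, wspec), s2, o2, warp_spec=wspec, basis=basis
        )
    return NormativeModel(basis=basis, idps=models)


def zscore_frame(df: pd.DataFrame, model: NormativeModel, idp_cols: list[str] | None = None) -> pd.DataFrame:
    """Cross-sectional z-scores for every row and phenotype, long format."""
    idp_cols = idp_cols or model.idp_names
    keep = [c for c in ("subject_id", "visit", "group", "site") if c in df.columns]
    records = []
    for idp in idp_cols:
        m = model.idps[idp]
        sites = df["site"] if "site" in df else pd.Series([None] * len(df))
        new_site = model.basis.site_labels and not sites.isin(model.basis.site_labels).all()
        Phi = design_matrix(df, m.basis, zero_site_block=bool(new_site))
        yw = warp(np.asarray(df[idp], dtype=float), m.warp)
        z = (yw - Phi @ m.w_bar) / np.sqrt(m.quad_Ainv(Phi) + m.sigma2)
        if new_site:
            labels = set(sites)
            if len(labels) != 1:
                raise UnknownSiteError("mixed known/unknown sites in one scoring call")
            adapt = m.adaptations.get(labels.pop())
            if adapt is None:
                raise UnknownSiteError("site not adapted; run site adaptation first")
            z = (z - adapt.offset) / adapt.scale
        block = df[keep].copy()
        block["idp"] = idp
        block["z"] = z
        records.append(block)
    return pd.concat(records, ignore_index=True)
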