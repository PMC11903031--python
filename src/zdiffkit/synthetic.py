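"""Synthetic cohorts for testing and simulation.

The generator draws phenotypes from the same observation model the
package fits: a smooth age/sex mean surface per phenotype (in warped
units), an additive per-site offset, and Gaussian residuals.  For
longitudinal cohorts the residual of subject n at visit i is

    eps_i = eta + xi_i            (subject-stable factor + visit noise)

with variances sigma_eta^2 and sigma_xi^2, or — when ``general_rho`` is
set — a stationary bivariate Gaussian pair with total variance
sigma^2 = sigma_eta^2 + sigma_xi^2 and lag correlation rho (which can be
negative, unlike the eta+xi special case).  Patients receive an additive
disruption Delta on the warped visit-2 value.

A truth table (per-subject residual components and Delta) is always
emitted beside the data so tests never re-derive ground truth from data.

Everything here is synthetic: no spatial covariance between phenotypes,
no scanner drift, no missing visits, and mean surfaces in standardized
warped units rather than millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import BasisSpec, design_matrix
from .blr import NormativeModel, fit_normative_model
from .warp import WarpSpec, unwarp

# Truth surface for the default (hand-checkable) cohort: a degree-1
# spline over age (two hat functions => linear in age) plus sex, no
# intercept, no site block; site offsets are added separately so cohorts
# can contain sites the fitted model has never seen.
_DEFAULT_IDPS = ("idp_a", "idp_b")


def _truth_basis(age_range: tuple[float, float], *, curvature: bool = False) -> BasisSpec:
    if curvature:
        lo, hi = age_range
        knots = tuple(np.linspace(lo, hi, 5)[1:-1])
        return BasisSpec(spline_degree=3, interior_knots=knots, boundary_knots=age_range,
                         linear_covariates=("sex",), site_labels=(), include_intercept=False)
    return BasisSpec(spline_degree=1, interior_knots=(), boundary_knots=age_range,
                     linear_covariates=("sex",), site_labels=(), include_intercept=False)


@dataclass
class CohortSpec:
    """Ground-truth description of a synthetic cohort.

    Variances are in warped units squared; the defaults give total
    residual variance 1 with lag correlation 0.9, the level implied by
    typical test-retest reliability of regional thickness measures.
    """

    n_subjects: int = 2000
    age_range: tuple[float, float] = (18.0, 65.0)
    sites: tuple[str, ...] = ("siteA", "siteB")
    site_offsets: dict = field(default_factory=lambda: {"siteA": 0.0, "siteB": 0.15})
    sex_balance: float = 0.5
    truth_basis: BasisSpec | None = None
    weights: dict = field(default_factory=lambda: {
        "idp_a": np.array([0.6, -0.4, 0.2]),   # declining with age, small sex effect
        "idp_b": np.array([-0.2, 0.5, -0.1]),
    })
    sigma_eta2: float = 0.9
    sigma_xi2: float = 0.1
    general_rho: float | None = None
    warp: WarpSpec = field(default_factory=WarpSpec)
    disruption: float = 0.0
    interval_years: float = 1.1
    seed: int = 0

    def __post_init__(self):
        if self.truth_basis is None:
            self.truth_basis = _truth_basis(self.age_range)
        if self.sigma_eta2 < 0 or self.sigma_xi2 < 0 or self.sigma2 <= 0:
            raise ValueError("residual variances must be >= 0 and not both 0")
        if self.general_rho is not None and not -1 < self.general_rho < 1:
            raise ValueError("general_rho must lie strictly inside (-1, 1)")
        for idp, w in self.weights.items():
            if len(np.atleast_1d(w)) != self.truth_basis.n_features:
                raise ValueError(f"weights for {idp!r} do not match the truth basis")

    @property
    def sigma2(self) -> float:
        return self.sigma_eta2 + self.sigma_xi2

    @property
    def rho(self) -> float:
        """Lag correlation of residuals between visits."""
        if self.general_rho is not None:
            return self.general_rho
        return self.sigma_eta2 / self.sigma2

    @property
    def idp_names(self) -> list[str]:
        return list(self.weights)


def lifespan_cohort_spec(**overrides) -> CohortSpec:
    """A preset with spline curvature in the truth surface (lifespan-like)."""
    age_range = overrides.pop("age_range", (18.0, 80.0))
    basis = _truth_basis(age_range, curvature=True)
    K = basis.n_features
    rng = np.random.default_rng(7)
    weights = {idp: rng.normal(0, 0.5, K) for idp in _DEFAULT_IDPS}
    return CohortSpec(age_range=age_range, truth_basis=basis, weights=weights, **overrides)


def _covariates(spec: CohortSpec, n: int, rng, prefix: str) -> pd.DataFrame:
    lo, hi = spec.age_range
    sexes = (rng.random(n) < spec.sex_balance).astype(int)
    return pd.DataFrame({
        "subject_id": [f"{prefix}{i:05d}" for i in range(n)],
        "age": rng.uniform(lo, hi, n),
        "sex": sexes,
        "site": rng.choice(list(spec.sites), n),
    })


def _mean_surface(spec: CohortSpec, cov: pd.DataFrame, idp: str) -> np.ndarray:
    Phi = design_matrix(cov, spec.truth_basis)
    mu = Phi @ np.asarray(spec.weights[idp], dtype=float)
    return mu + cov["site"].map(spec.site_offsets).to_numpy(dtype=float)


def gen_cross_sectional(spec: CohortSpec, *, seed: int | None = None) -> pd.DataFrame:
    """One row per subject; phenotype columns in raw (unwarped) units."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    df = _covariates(spec, spec.n_subjects, rng, "cs")
    for idp in spec.idp_names:
        mu = _mean_surface(spec, df, idp)
        eps = rng.normal(0, np.sqrt(spec.sigma2), spec.n_subjects)
        df[idp] = unwarp(mu + eps, spec.warp)
    return df


def _residual_pairs(spec: CohortSpec, n: int, rng):
    """Per-subject (eps1, eps2) plus the eta/xi decomposition when defined."""
    if spec.general_rho is None:
        eta = rng.normal(0, np.sqrt(spec.sigma_eta2), n)
        xi1 = rng.normal(0, np.sqrt(spec.sigma_xi2), n)
        xi2 = rng.normal(0, np.sqrt(spec.sigma_xi2), n)
        return eta + xi1, eta + xi2, eta, xi1, xi2
    cov = spec.sigma2 * np.array([[1.0, spec.rho], [spec.rho, 1.0]])
    eps = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    nan = np.full(n, np.nan)
    return eps[:, 0], eps[:, 1], nan, nan, nan


def gen_longitudinal(
    spec: CohortSpec,
    n_controls: int,
    n_patients: int,
    *,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-visit cohort in long format plus its ground-truth table.

    Controls follow the healthy residual process; patients additionally
    receive the disruption Delta on the warped visit-2 observation.
    Returns ``(long_table, truth_table)``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = n_controls + n_patients
    cov1 = _covariates(spec, n, rng, "long")
    cov1["group"] = ["control"] * n_controls + ["patient"] * n_patients
    cov2 = cov1.copy()
    cov2["age"] = cov1["age"] + spec.interval_years

    rows1, rows2, truth_rows = cov1.copy(), cov2.copy(), []
    rows1["visit"] = 1
    rows2["visit"] = 2
    is_patient = (cov1["group"] == "patient").to_numpy()
    for idp in spec.idp_names:
        mu1 = _mean_surface(spec, cov1, idp)
        mu2 = _mean_surface(spec, cov2, idp)
        eps1, eps2, eta, xi1, xi2 = _residual_pairs(spec, n, rng)
        delta = np.where(is_patient, spec.disruption, 0.0)
        rows1[idp] = unwarp(mu1 + eps1, spec.warp)
        rows2[idp] = unwarp(mu2 + eps2 + delta, spec.warp)
        truth_rows.append(pd.DataFrame({
            "subject_id": cov1["subject_id"], "idp": idp, "group": cov1["group"],
            "eta": eta, "xi1": xi1, "xi2": xi2,
            "eps1": eps1, "eps2": eps2, "delta": delta,
        }))

    long_df = (
        pd.concat([rows1, rows2], ignore_index=True)
        .sort_values(["subject_id", "visit"], kind="stable")
        .reset_index(drop=True)
    )
    cols = ["subject_id", "visit", "age", "sex", "site", "group", *spec.idp_names]
    return long_df[cols], pd.concat(truth_rows, ignore_index=True)


def make_reference_model(
    *,
    n_train: int = 2000,
    sigma2: float = 1.0,
    omega2: float = 1.0,
    seed: int = 0,
    spec: CohortSpec | None = None,
    estimate_hyperparams: bool = False,
) -> NormativeModel:
    """Fit a normative model on a synthetic cross-sectional cohort.

    With ``estimate_hyperparams=False`` the generating sigma^2/omega^2 are
    used as known, which makes the model's cross-sectional estimates exact
    — the configuration the detection-power simulation assumes.
    """
    spec = spec or CohortSpec(n_subjects=n_train, seed=seed,
                              sigma_eta2=0.9 * sigma2, sigma_xi2=0.1 * sigma2)
    train = gen_cross_sectional(spec, seed=seed)
    kwargs = {} if estimate_hyperparams else {"sigma2": sigma2, "omega2": omega2}
    return fit_normative_model(train, spec.idp_names, seed=seed, **kwargs)
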