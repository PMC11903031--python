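"""Adaptation of a pre-trained model to a new scanner/site.

A normative model trained elsewhere has no dummy column for a new site.
Given a local sample of healthy controls, we compute their standardized
residuals under the site-agnostic basis (site block zeroed),

    r_n = (phi(y_n) - w_bar' phi_0(x_n)) / sqrt(phi_0' A^-1 phi_0 + sigma^2),

and store their mean and standard deviation.  Scoring at the new site
then returns (r - offset) / scale, which is zero-mean unit-variance for
local controls by construction.  The pre-trained weights stay frozen;
models for other sites are untouched.

For longitudinal differencing the offset and scale cancel between visits,
so adaptation mainly matters for interpreting the cross-sectional scores.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import design_matrix
from .blr import NormativeModel, PosteriorModel
from .warp import warp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SiteAdaptation:
    """Residual recentering/rescaling constants for one site and phenotype."""

    site_label: str
    offset: float
    scale: float
    n_controls: int

    def to_dict(self) -> dict:
        return {
            "site_label": self.site_label,
            "offset": float(self.offset),
            "scale": float(self.scale),
            "n_controls": int(self.n_controls),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SiteAdaptation":
        return cls(d["site_label"], float(d["offset"]), float(d["scale"]), int(d["n_controls"]))


def _adapt_one(model: PosteriorModel, controls: pd.DataFrame, idp: str, site_label: str) -> SiteAdaptation:
    Phi0 = design_matrix(controls, model.basis, zero_site_block=True)
    yw = warp(np.asarray(controls[idp], dtype=float), model.warp)
    r = (yw - Phi0 @ model.w_bar) / np.sqrt(model.quad_Ainv(Phi0) + model.sigma2)
    sd = float(np.std(r, ddof=1))
    if sd == 0:
        raise ValueError(f"zero residual variance among controls for {idp!r}; cannot adapt")
    return SiteAdaptation(site_label=site_label, offset=float(np.mean(r)), scale=sd,
                          n_controls=len(controls))


def adapt_to_site(
    model: NormativeModel,
    controls: pd.DataFrame,
    site_label: str,
    idp_cols: list[str] | None = None,
) -> NormativeModel:
    """Return a copy of the model with adaptation constants for ``site_label``.

    ``controls`` holds healthy-control rows from the new site (one row per
    scan) with the model's covariates plus the phenotype columns.
    """
    if "site" in controls.columns and not (controls["site"] == site_label).all():
        raise ValueError("all control rows must carry the site label being adapted")
    if len(controls) < 2:
        raise ValueError(f"need at least 2 controls to adapt, got {len(controls)}")
    if len(controls["subject_id"].unique() if "subject_id" in controls else controls) < 10:
        logger.warning("site adaptation with < 10 controls; constants will be noisy")

    idp_cols = idp_cols or model.idp_names
    adapted = NormativeModel(basis=model.basis, idps=dict(model.idps))
    for idp in idp_cols:
        m = model.idps[idp]
        new = copy.copy(m)
        new.adaptations = dict(m.adaptations)
        new.adaptations[site_label] = _adapt_one(m, controls, idp, site_label)
        adapted.idps[idp] = new
    return adapted


def split_controls(
    subjects: pd.DataFrame,
    *,
    frac_adapt: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split control subjects into an adaptation set and a noise-calibration set C.

    Stratified by age tertile and sex so both sets span the covariate
    range; subjects in C are reserved for noise estimation and must not be
    evaluated.  ``subjects`` needs columns subject_id, age, sex (one row
    per subject; for longitudinal data pass visit-1 rows).

    Returns ``(adapt_ids, calibration_ids)``.
    """
    if not 0 < frac_adapt < 1:
        raise ValueError("frac_adapt must be in (0, 1)")
    df = subjects.drop_duplicates("subject_id")
    tertile = pd.qcut(df["age"].rank(method="first"), 3, labels=False)
    strata = tertile.astype(str) + "|" + df["sex"].astype(str)
    rng = np.random.default_rng(seed)
    adapt_ids: list = []
    calib_ids: list = []
    for _, grp in df.groupby(strata.values, sort=True):
        ids = np.sort(grp["subject_id"].to_numpy())
        perm = rng.permutation(len(ids))
        n_adapt = int(round(frac_adapt * len(ids)))
        adapt_ids.extend(ids[perm[:n_adapt]])
        calib_ids.extend(ids[perm[n_adapt:]])
    return np.array(sorted(adapt_ids)), np.array(sorted(calib_ids))
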