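"""Longitudinal change scoring: the z-diff statistic.

A healthy subject's warped residual across two visits is modelled as a
subject-stable factor plus independent visit noise,

    eps_i = eta + xi_i,   eta ~ N(0, sigma_eta^2),  xi_i ~ N(0, sigma_xi^2),

with sigma^2 = sigma_eta^2 + sigma_xi^2 equal to the cross-sectional
noise variance.  The between-visit difference of warped observations then
has variance 2 sigma_xi^2 plus the model-uncertainty term, giving the
change score

    z-diff = (dphi_y - w_bar' dphi_x)
             / sqrt(dphi_x' A^-1 dphi_x + 2 sigma_xi^2),

with dphi_y = phi(y2) - phi(y1) and dphi_x = phi(x2) - phi(x1).  More
generally, for any stationary Gaussian residual process with lag
correlation rho between the visits, the noise scale is
2 sigma^2 (1 - rho); the subject-stable model is the special case
rho = sigma_eta^2 / sigma^2 >= 0.

The noise scale is estimated from a calibration subsample C of healthy
control pairs that is excluded from evaluation: the sample mean of the
squared model-adjusted differences minus the model-uncertainty term.  An
estimate exceeding 2 sigma^2 implies a negative lag correlation — healthy
subjects do not track their centile — and is surfaced as a
``tracking_violation`` diagnostic.

The naive alternative, subtracting the two cross-sectional z-scores, has
variance 2(1 - rho) under the null: it over-flags when rho < 0.5 and
under-flags when rho > 0.5.  It is provided only as a comparison
baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .basis import design_matrix
from .blr import NormativeModel, PosteriorModel, zscore
from .warp import warp

logger = logging.getLogger(__name__)

NOISE_FLOOR_REL = 1e-8  # floor on the noise scale, relative to 2 sigma^2


@dataclass
class VisitPair:
    """One subject's two visits: covariate records and phenotype values.

    ``y1``/``y2`` map phenotype name -> observed value.  Visits must be at
    the same site and in temporal order (positive age interval).
    """

    subject_id: object
    x1: dict
    x2: dict
    y1: dict
    y2: dict

    def __post_init__(self):
        if self.interval <= 0:
            raise ValueError(f"visit interval must be > 0 for subject {self.subject_id!r}")
        if self.x1.get("site") != self.x2.get("site"):
            raise ValueError(
                f"cross-site visit pair for subject {self.subject_id!r}; "
                "z-diff requires both visits on the same scanner"
            )

    @property
    def interval(self) -> float:
        return float(self.x2["age"]) - float(self.x1["age"])


@dataclass
class NoiseEstimate:
    """Estimated longitudinal noise scale for one phenotype.

    ``two_sigma_xi2`` is the (floored) estimate of 2 sigma_xi^2 — in the
    general stationary model, of 2 sigma^2 (1 - rho) — in warped units
    squared.  ``raw_value`` is the unclamped sample quantity;
    ``implied_rho`` = 1 - two_sigma_xi2 / (2 sigma^2) with the model's
    frozen cross-sectional sigma^2; ``tracking_violation`` is set when the
    raw estimate exceeds 2 sigma^2 (implied negative lag correlation).
    """

    idp: str
    two_sigma_xi2: float
    raw_value: float
    n_calibration: int
    implied_rho: float
    tracking_violation: bool

    def to_dict(self) -> dict:
        return {
            "idp": self.idp,
            "two_sigma_xi2": float(self.two_sigma_xi2),
            "raw_value": float(self.raw_value),
            "n_calibration": int(self.n_calibration),
            "implied_rho": float(self.implied_rho),
            "tracking_violation": bool(self.tracking_violation),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseEstimate":
        return cls(d["idp"], float(d["two_sigma_xi2"]), float(d["raw_value"]),
                   int(d["n_calibration"]), float(d["implied_rho"]),
                   bool(d["tracking_violation"]))


# ---------------------------------------------------------------------------
# pair construction

def pairs_from_long(df: pd.DataFrame, idp_cols: list[str]) -> list[VisitPair]:
    """Build visit pairs from a long table (columns subject_id, visit, age,
    sex, site, one column per phenotype).  Subjects need exactly two
    visits; subjects with more are rejected — score consecutive pairs
    explicitly instead."""
    pairs = []
    for sid, grp in df.groupby("subject_id", sort=True):
        if len(grp) != 2:
            raise ValueError(
                f"subject {sid!r} has {len(grp)} visits; z-diff evaluates change "
                "between exactly two visits (score consecutive pairs separately)"
            )
        grp = grp.sort_values("visit")
        rows = grp.to_dict("records")
        cov = lambda r: {k: r[k] for k in ("age", "sex", "site") if k in r}
        pairs.append(VisitPair(
            subject_id=sid,
            x1=cov(rows[0]), x2=cov(rows[1]),
            y1={c: rows[0][c] for c in idp_cols},
            y2={c: rows[1][c] for c in idp_cols},
        ))
    return pairs


def _pair_arrays(pairs: list[VisitPair], model: PosteriorModel, idp: str):
    """Warped differences, expected differences and model-uncertainty terms.

    Differences use the site-agnostic basis: the site dummy block is
    identical across a subject's visits so it cancels exactly, and this
    also covers adapted sites absent from the training labels.
    """
    x1 = pd.DataFrame([p.x1 for p in pairs])
    x2 = pd.DataFrame([p.x2 for p in pairs])
    dPhi = (design_matrix(x2, model.basis, zero_site_block=True)
            - design_matrix(x1, model.basis, zero_site_block=True))
    y1 = warp(np.array([p.y1[idp] for p in pairs], dtype=float), model.warp)
    y2 = warp(np.array([p.y2[idp] for p in pairs], dtype=float), model.warp)
    resid = (y2 - y1) - dPhi @ model.w_bar
    model_term = model.quad_Ainv(dPhi)
    return resid, model_term


# ---------------------------------------------------------------------------
# noise estimation

def estimate_noise(
    calibration_pairs: list[VisitPair],
    model: NormativeModel | PosteriorModel,
    idp_cols: list[str] | None = None,
) -> dict[str, NoiseEstimate]:
    """Estimate the longitudinal noise scale from control pairs C.

    Per phenotype: mean over C of the squared model-adjusted warped
    difference minus the model-uncertainty term.  Negative estimates
    (possible at finite |C|) are floored at ``1e-8 * 2 sigma^2`` with a
    loud diagnostic; the raw value is always reported.
    """
    if len(calibration_pairs) < 2:
        raise ValueError(f"need at least 2 calibration pairs, got {len(calibration_pairs)}")
    if isinstance(model, PosteriorModel):
        model = NormativeModel(basis=model.basis, idps={idp_cols[0]: model})
    idp_cols = idp_cols or model.idp_names

    out: dict[str, NoiseEstimate] = {}
    for idp in idp_cols:
        m = model.idps[idp]
        resid, model_term = _pair_arrays(calibration_pairs, m, idp)
        raw = float(np.mean(resid**2 - model_term))
        two_sigma2 = 2 * m.sigma2
        floor = NOISE_FLOOR_REL * two_sigma2
        clamped = max(raw, floor)
        if raw < floor:
            logger.warning(
                "noise estimate for %s is %.3g (non-positive after the model-term "
                "subtraction); clamped to %.3g", idp, raw, floor,
            )
        out[idp] = NoiseEstimate(
            idp=idp,
            two_sigma_xi2=clamped,
            raw_value=raw,
            n_calibration=len(calibration_pairs),
            implied_rho=1.0 - clamped / two_sigma2,
            tracking_violation=raw > two_sigma2,
        )
        if raw > two_sigma2:
            logger.warning(
                "noise estimate for %s exceeds the cross-sectional 2*sigma^2 "
                "(%.3g > %.3g): healthy subjects do not track their centile here",
                idp, raw, two_sigma2,
            )
    return out


# ---------------------------------------------------------------------------
# scoring

def zdiff_score(pair: VisitPair, model: PosteriorModel, noise: NoiseEstimate) -> float:
    """The change score for one subject and one phenotype.

    The model-uncertainty term is always included in the denominator; it
    is small in adult cohorts but grows where the normative surface is
    steep or weakly constrained (developmental or ageing ranges).
    """
    resid, model_term = _pair_arrays([pair], model, noise.idp)
    return float(resid[0] / np.sqrt(model_term[0] + noise.two_sigma_xi2))


def naive_zdiff(pair: VisitPair, model: PosteriorModel, idp: str) -> float:
    """Difference of the two cross-sectional z-scores (comparison baseline only)."""
    return zscore(pair.y2[idp], pair.x2, model) - zscore(pair.y1[idp], pair.x1, model)


def flag(z, theta: float = 0.05):
    """Two-sided flag at nominal healthy-flagging rate theta."""
    if not 0 < theta <= 1:
        raise ValueError("theta must be in (0, 1]")
    q = stats.norm.ppf(1 - theta / 2)
    z = np.asarray(z, dtype=float)
    # closed comparison so the degenerate theta = 1 threshold flags everyone
    out = np.abs(z) >= q if theta == 1.0 else np.abs(z) > q
    return bool(out) if out.ndim == 0 else out


def zdiff_frame(
    pairs: list[VisitPair],
    model: NormativeModel,
    noise: dict[str, NoiseEstimate],
    *,
    theta: float = 0.05,
    include_naive: bool = False,
) -> pd.DataFrame:
    """Score every pair and phenotype; long table with columns
    subject_id, idp, zdiff, flag (and optionally naive)."""
    records = []
    for idp, ne in noise.items():
        m = model.idps[idp]
        resid, model_term = _pair_arrays(pairs, m, idp)
        z = resid / np.sqrt(model_term + ne.two_sigma_xi2)
        block = pd.DataFrame({
            "subject_id": [p.subject_id for p in pairs],
            "idp": idp,
            "zdiff": z,
            "flag": flag(z, theta),
        })
        if include_naive:
            block["naive"] = [naive_zdiff(p, m, idp) for p in pairs]
        records.append(block)
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# group-level inference

def group_wilcoxon(scores: pd.DataFrame, *, fdr_level: float = 0.05) -> pd.DataFrame:
    """One-sample Wilcoxon signed-rank of z-diff against zero, per phenotype,
    with Benjamini-Hochberg step-up control of the FDR across phenotypes.

    ``scores`` is long format with columns ``idp`` and ``zdiff``.  Returns
    one row per phenotype: p, q (BH-adjusted), significant, and the sign
    of the median score.
    """
    rows = []
    for idp, grp in scores.groupby("idp", sort=True):
        z = np.asarray(grp["zdiff"], dtype=float)
        nonzero = z[z != 0]
        if nonzero.size == 0:
            p = 1.0
        else:
            p = float(stats.wilcoxon(nonzero).pvalue)
        rows.append({"idp": idp, "p": p, "direction": float(np.sign(np.median(z)))})
    out = pd.DataFrame(rows)
    reject, q, _, _ = multipletests(out["p"], alpha=fdr_level, method="fdr_bh")
    out["q"] = q
    out["significant"] = reject
    return out
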