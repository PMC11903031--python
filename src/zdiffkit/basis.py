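"""Deterministic covariate feature expansion.

The design vector for one subject is the concatenation of

* a B-spline block over a single smooth covariate (age, in years),
* linear covariates taken as-is (e.g. sex coded 0/1),
* a one-hot block over scanner/site labels,
* an optional intercept.

The spline block is a standard open (clamped) B-spline basis: with
``d = spline_degree`` and ``m`` interior knots it contains ``m + d + 1``
functions that form a partition of unity on the boundary interval.
Ages outside the boundary knots are clamped to the boundary, so the
expansion extrapolates as a constant; a warning is logged when this
happens because normative predictions outside the training age range
should be read with care.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)

#: default 0/1 coding applied when the sex column contains strings
DEFAULT_SEX_CODES = {"female": 0.0, "male": 1.0}


@dataclass(frozen=True)
class BasisSpec:
    """Specification of the feature map phi(x).

    Parameters
    ----------
    spline_covariate:
        Name of the covariate expanded with the B-spline block (years).
    spline_degree:
        Polynomial degree of the B-spline (3 = cubic).
    interior_knots:
        Non-decreasing interior knot locations, strictly inside the
        boundary interval.
    boundary_knots:
        ``(low, high)`` pair bracketing all interior knots; ages outside
        are clamped.
    linear_covariates:
        Covariates entered linearly (numeric; sex strings are mapped via
        ``sex_codes``).
    site_labels:
        Ordered site labels expanded to a one-hot block.  May be empty.
    include_intercept:
        Whether a constant 1 column is appended.
    sex_codes:
        Mapping used to encode a string-valued ``sex`` covariate.  Stored
        with the model so scoring cannot silently flip the coding.
    """

    spline_covariate: str = "age"
    spline_degree: int = 3
    interior_knots: tuple[float, ...] = ()
    boundary_knots: tuple[float, float] = (18.0, 80.0)
    linear_covariates: tuple[str, ...] = ("sex",)
    site_labels: tuple[str, ...] = ()
    include_intercept: bool = True
    sex_codes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEX_CODES)
    )

    def __post_init__(self):
        lo, hi = self.boundary_knots
        if not lo < hi:
            raise ValueError(f"boundary knots must satisfy low < high, got {self.boundary_knots}")
        knots = np.asarray(self.interior_knots, dtype=float)
        if knots.size and np.any(np.diff(knots) < 0):
            raise ValueError("interior knots must be non-decreasing")
        if knots.size and (knots[0] < lo or knots[-1] > hi):
            raise ValueError("boundary knots must bracket all interior knots")
        if self.spline_degree < 0:
            raise ValueError("spline degree must be >= 0")
        if len(set(self.site_labels)) != len(self.site_labels):
            raise ValueError("site labels must be unique")

    # -- layout ---------------------------------------------------------
    @property
    def n_spline(self) -> int:
        return len(self.interior_knots) + self.spline_degree + 1

    @property
    def n_features(self) -> int:
        """Output dimension K, constant across rows."""
        return (
            self.n_spline
            + len(self.linear_covariates)
            + len(self.site_labels)
            + int(self.include_intercept)
        )

    @property
    def covariate_names(self) -> tuple[str, ...]:
        names = (self.spline_covariate,) + tuple(self.linear_covariates)
        if self.site_labels:
            names += ("site",)
        return names

    @property
    def knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary_knots
        d = self.spline_degree
        return np.concatenate(
            [np.full(d + 1, lo), np.asarray(self.interior_knots, float), np.full(d + 1, hi)]
        )

    def site_slice(self) -> slice:
        start = self.n_spline + len(self.linear_covariates)
        return slice(start, start + len(self.site_labels))

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "spline_covariate": self.spline_covariate,
            "spline_degree": self.spline_degree,
            "interior_knots": list(map(float, self.interior_knots)),
            "boundary_knots": [float(b) for b in self.boundary_knots],
            "linear_covariates": list(self.linear_covariates),
            "site_labels": list(self.site_labels),
            "include_intercept": self.include_intercept,
            "sex_codes": {k: float(v) for k, v in self.sex_codes.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        return cls(
            spline_covariate=d["spline_covariate"],
            spline_degree=int(d["spline_degree"]),
            interior_knots=tuple(d["interior_knots"]),
            boundary_knots=tuple(d["boundary_knots"]),
            linear_covariates=tuple(d["linear_covariates"]),
            site_labels=tuple(d["site_labels"]),
            include_intercept=bool(d["include_intercept"]),
            sex_codes=dict(d["sex_codes"]),
        )


def _encode_linear(values, name: str, spec: BasisSpec) -> np.ndarray:
    out = np.empty(len(values), dtype=float)
    for i, v in enumerate(values):
        if isinstance(v, str):
            if name != "sex" or v not in spec.sex_codes:
                raise ValueError(f"cannot encode value {v!r} for covariate {name!r}")
            out[i] = spec.sex_codes[v]
        else:
            out[i] = float(v)
    return out


def design_matrix(
    rows: pd.DataFrame | Sequence[Mapping],
    spec: BasisSpec,
    *,
    zero_site_block: bool = False,
) -> np.ndarray:
    """Expand many covariate rows into the N x K design matrix.

    ``zero_site_block=True`` evaluates the site-agnostic basis phi_0 (site
    dummies all zero); this is what site adaptation and between-visit
    differencing use, and it also accepts rows whose site label is not in
    ``spec.site_labels``.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows))

    for name in (spec.spline_covariate, *spec.linear_covariates):
        if name not in df.columns:
            raise ValueError(f"missing covariate {name!r}")
    if spec.site_labels and not zero_site_block and "site" not in df.columns:
        raise ValueError("missing covariate 'site'")

    n = len(df)
    K = spec.n_features
    out = np.zeros((n, K))

    x = np.asarray(df[spec.spline_covariate], dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite values in covariate {spec.spline_covariate!r}")
    lo, hi = spec.boundary_knots
    if np.any(x < lo) or np.any(x > hi):
        logger.warning(
            "%d %s value(s) outside boundary knots [%g, %g]; clamping",
            int(np.sum((x < lo) | (x > hi))), spec.spline_covariate, lo, hi,
        )
        x = np.clip(x, lo, hi)
    out[:, : spec.n_spline] = BSpline.design_matrix(
        x, spec.knot_vector, spec.spline_degree
    ).toarray()

    col = spec.n_spline
    for name in spec.linear_covariates:
        vals = _encode_linear(df[name].tolist(), name, spec)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite values in covariate {name!r}")
        out[:, col] = vals
        col += 1

    if spec.site_labels and not zero_site_block:
        index = {s: j for j, s in enumerate(spec.site_labels)}
        for i, s in enumerate(df["site"]):
            if s not in index:
                raise ValueError(
                    f"unknown site label {s!r}; known sites: {list(spec.site_labels)}. "
                    "Adapt the model to this site first (site_adapt)."
                )
            out[i, col + index[s]] = 1.0
    col += len(spec.site_labels)

    if spec.include_intercept:
        out[:, col] = 1.0
    return out


def expand_basis(x_row: Mapping, spec: BasisSpec, *, zero_site_block: bool = False) -> np.ndarray:
    """Expand one covariate record into the length-K feature vector phi(x)."""
    return design_matrix([dict(x_row)], spec, zero_site_block=zero_site_block)[0]
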