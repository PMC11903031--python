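"""Model serialization.

One JSON document per model collection:

    {
      "schema_version": 1,
      "basis": {...},                     # knots, covariates, sites, sex coding
      "idps": {
        "<name>": {
          "w_bar": [...], "chol_A": [[...]],   # lower Cholesky of A
          "sigma2": ..., "omega2": ..., "n_train": ...,
          "warp": {"family": ..., "gamma": [...], "loc": ..., "scale": ...},
          "adaptations": {"<site>": {"offset": ..., "scale": ..., ...}}
        }, ...
      }
    }

Floats round-trip at full precision (JSON uses repr).  The same schema
can carry models trained elsewhere, as long as they provide these
fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .basis import BasisSpec
from .blr import NormativeModel, PosteriorModel
from .site_adapt import SiteAdaptation
from .warp import WarpSpec

SCHEMA_VERSION = 1


def _posterior_to_dict(m: PosteriorModel) -> dict:
    return {
        "w_bar": m.w_bar.tolist(),
        "chol_A": m.chol_A.tolist(),
        "sigma2": float(m.sigma2),
        "omega2": float(m.omega2),
        "n_train": int(m.n_train),
        "warp": m.warp.to_dict(),
        "adaptations": {s: a.to_dict() for s, a in m.adaptations.items()},
    }


def _posterior_from_dict(d: dict, basis: BasisSpec) -> PosteriorModel:
    return PosteriorModel(
        w_bar=np.asarray(d["w_bar"], dtype=float),
        chol_A=np.asarray(d["chol_A"], dtype=float),
        sigma2=float(d["sigma2"]),
        omega2=float(d["omega2"]),
        warp=WarpSpec.from_dict(d["warp"]),
        basis=basis,
        n_train=int(d["n_train"]),
        adaptations={s: SiteAdaptation.from_dict(a) for s, a in d.get("adaptations", {}).items()},
    )


def save_model(model: NormativeModel, path: str | Path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "basis": model.basis.to_dict(),
        "idps": {name: _posterior_to_dict(m) for name, m in model.idps.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_model(path: str | Path) -> NormativeModel:
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {version!r}")
    basis = BasisSpec.from_dict(doc["basis"])
    idps = {name: _posterior_from_dict(d, basis) for name, d in doc["idps"].items()}
    return NormativeModel(basis=basis, idps=idps)
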