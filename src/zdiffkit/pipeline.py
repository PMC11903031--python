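"""End-to-end orchestration.

Stages: load the long-format table -> surface-quality (Euler) filter ->
site adaptation on a subset of controls -> longitudinal noise
calibration on a disjoint control subset C -> cross-sectional z-scores
and patient-vs-control group tests -> z-diff scores and the group-level
signed-rank test.  All randomness flows from the single config seed; a
rerun with the same config reproduces every output byte for byte.

Subjects are partitioned so that no one appears in more than one of the
adaptation set, the calibration set C, and the evaluation set; scores of
C subjects are never evaluated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import __version__
from .blr import zscore_frame
from .longitudinal import estimate_noise, group_wilcoxon, pairs_from_long, zdiff_frame
from .model_io import load_model, save_model
from .site_adapt import adapt_to_site

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Failure in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Configuration of one full run.

    ``adapt_frac`` and ``calib_frac`` are the control fractions assigned
    to site adaptation and to the noise-calibration set C; the remainder
    are the evaluation controls.  Explicit ``calibration_subjects`` /
    ``evaluation_subjects`` lists override the seeded split and are
    refused if they overlap.
    """

    data: str = ""
    model: str = ""
    out_dir: str = "zdiff_out"
    theta: float = 0.05
    fdr_level: float = 0.05
    adapt_frac: float = 0.4
    calib_frac: float = 0.3
    seed: int = 0
    euler_threshold: float = 10.0
    idps: list[str] | None = None
    exclude_idps: list[str] = field(default_factory=list)
    site_adapt: bool = True
    calibration_subjects: list[str] | None = None
    evaluation_subjects: list[str] | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        for name in ("theta", "fdr_level", "adapt_frac", "calib_frac"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.adapt_frac + self.calib_frac >= 1:
            raise ValueError("adapt_frac + calib_frac must leave room for evaluation controls")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


# ---------------------------------------------------------------------------
# quality control

def qc_euler_filter(
    df: pd.DataFrame, threshold: float = 10.0, euler_col: str = "euler"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop subjects whose rescaled Euler number exceeds ``threshold`` at
    any visit (the whole subject is removed, both visits).

    Returns ``(filtered_table, exclusion_report)``; the report lists one
    row per removed subject with the offending visit and value.
    """
    if euler_col not in df.columns:
        return df, pd.DataFrame(columns=["subject_id", "visit", "euler", "reason"])
    bad = df[df[euler_col] > threshold]
    report = pd.DataFrame({
        "subject_id": bad["subject_id"],
        "visit": bad["visit"] if "visit" in bad else 1,
        "euler": bad[euler_col],
        "reason": f"rescaled Euler number > {threshold:g}",
    }).drop_duplicates("subject_id").reset_index(drop=True)
    keep = ~df["subject_id"].isin(report["subject_id"])
    return df[keep].reset_index(drop=True), report


# ---------------------------------------------------------------------------
# cross-sectional group inference

def cross_sectional_group_test(
    zscores: pd.DataFrame, *, fdr_level: float = 0.05
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U of patients vs controls per phenotype and
    visit, BH-corrected across phenotypes within each visit.

    ``zscores`` is long format with columns subject_id, visit, group,
    idp, z.  Direction is the sign of the median patient-minus-control
    difference (negative = lower in patients).
    """
    rows = []
    for (visit, idp), grp in zscores.groupby(["visit", "idp"], sort=True):
        zp = grp.loc[grp["group"] == "patient", "z"].to_numpy(dtype=float)
        zc = grp.loc[grp["group"] == "control", "z"].to_numpy(dtype=float)
        if zp.size == 0 or zc.size == 0:
            raise ValueError(f"visit {visit}, {idp}: need both groups for the group test")
        p = float(stats.mannwhitneyu(zp, zc, alternative="two-sided").pvalue)
        rows.append({
            "visit": visit, "idp": idp, "p": p,
            "direction": float(np.sign(np.median(zp) - np.median(zc))),
        })
    out = pd.DataFrame(rows)
    parts = []
    for visit, grp in out.groupby("visit", sort=True):
        reject, q, _, _ = multipletests(grp["p"], alpha=fdr_level, method="fdr_bh")
        grp = grp.assign(q=q, significant=reject)
        parts.append(grp)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# control partitioning

def _stratified_assign(df: pd.DataFrame, fracs: tuple[float, float], seed: int):
    """Assign control subjects to (adapt, calibration, evaluation) with
    stratification by age tertile and sex."""
    tertile = pd.qcut(df["age"].rank(method="first"), 3, labels=False)
    strata = tertile.astype(str) + "|" + df["sex"].astype(str)
    rng = np.random.default_rng(seed)
    sets: tuple[list, list, list] = ([], [], [])
    for _, grp in df.groupby(strata.values, sort=True):
        ids = np.sort(grp["subject_id"].to_numpy())
        perm = rng.permutation(len(ids))
        n_adapt = int(round(fracs[0] * len(ids)))
        n_calib = int(round(fracs[1] * len(ids)))
        sets[0].extend(ids[perm[:n_adapt]])
        sets[1].extend(ids[perm[n_adapt:n_adapt + n_calib]])
        sets[2].extend(ids[perm[n_adapt + n_calib:]])
    return tuple(sorted(s) for s in sets)


def _assert_disjoint(stage: str, **groups):
    names = list(groups)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            overlap = set(groups[a]) & set(groups[b])
            if overlap:
                raise PipelineError(
                    stage,
                    f"{a} and {b} sets share subjects {sorted(overlap)[:5]}; "
                    "calibration subjects must not be evaluated",
                )


# ---------------------------------------------------------------------------
# the full run

@dataclass
class PipelineResult:
    out_dir: Path
    zscores: pd.DataFrame
    group_test: pd.DataFrame
    zdiff: pd.DataFrame
    zdiff_test: pd.DataFrame
    noise: dict
    exclusions: pd.DataFrame
    sets: dict


def run_pipeline(config: AnalysisConfig) -> PipelineResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # -- load ----------------------------------------------------------
    stage = "load"
    try:
        df = pd.read_csv(config.data, sep="\t")
        model = load_model(config.model)
        idps = config.idps or [c for c in model.idp_names if c in df.columns]
        idps = [c for c in idps if c not in set(config.exclude_idps)]
        if not idps:
            raise ValueError("no phenotype columns shared between data and model")
        sites = df["site"].unique()
        if len(sites) != 1:
            raise ValueError(
                f"expected a single-site longitudinal table, found sites {list(sites)}"
            )
        site = str(sites[0])
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # -- quality control ----------------------------------------------
    stage = "qc"
    try:
        df, exclusions = qc_euler_filter(df, config.euler_threshold)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # -- partition controls -------------------------------------------
    stage = "split"
    try:
        controls = df[df["group"] == "control"].drop_duplicates("subject_id")
        patients = sorted(df.loc[df["group"] == "patient", "subject_id"].unique())
        if config.calibration_subjects is not None:
            calib = sorted(config.calibration_subjects)
            evaluation = (sorted(config.evaluation_subjects)
                          if config.evaluation_subjects is not None else
                          sorted(set(controls["subject_id"]) - set(calib)))
            adapt_set = sorted(set(controls["subject_id"]) - set(calib) - set(evaluation))
        else:
            adapt_set, calib, evaluation = _stratified_assign(
                controls, (config.adapt_frac, config.calib_frac), config.seed + 11
            )
        _assert_disjoint(stage, adaptation=adapt_set, calibration=calib,
                         evaluation=evaluation)
        sets = {"adaptation": list(adapt_set), "calibration": list(calib),
                "evaluation": list(evaluation), "patients": list(map(str, patients))}
    except Exception as e:
        if isinstance(e, PipelineError):
            raise
        raise PipelineError(stage, str(e)) from e

    # -- site adaptation ----------------------------------------------
    stage = "adapt"
    try:
        if config.site_adapt and site not in model.basis.site_labels:
            adapt_rows = df[df["subject_id"].isin(adapt_set)]
            model = adapt_to_site(model, adapt_rows, site, idps)
        save_model(model, out_dir / "model_adapted.json")
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # -- cross-sectional scores and group test ------------------------
    stage = "cross-sectional"
    try:
        eval_mask = df["subject_id"].isin(list(evaluation) + list(patients))
        z = zscore_frame(df[eval_mask], model, idps)
        group_test = cross_sectional_group_test(z, fdr_level=config.fdr_level)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # -- noise calibration and z-diff ---------------------------------
    stage = "calibrate"
    try:
        calib_pairs = pairs_from_long(df[df["subject_id"].isin(calib)], idps)
        noise = estimate_noise(calib_pairs, model, idps)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    stage = "score"
    try:
        eval_pairs = pairs_from_long(df[eval_mask], idps)
        zdiff = zdiff_frame(eval_pairs, model, noise, theta=config.theta)
        zdiff = zdiff.merge(
            df.drop_duplicates("subject_id")[["subject_id", "group"]], on="subject_id"
        )
        zdiff_test = group_wilcoxon(
            zdiff[zdiff["group"] == "patient"], fdr_level=config.fdr_level
        )
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # -- serialize -----------------------------------------------------
    stage = "write"
    try:
        z.to_csv(out_dir / "zscores.tsv", sep="\t", index=False)
        group_test.to_csv(out_dir / "group_test.tsv", sep="\t", index=False)
        zdiff.to_csv(out_dir / "zdiff.tsv", sep="\t", index=False)
        zdiff_test.to_csv(out_dir / "zdiff_wilcoxon.tsv", sep="\t", index=False)
        exclusions.to_csv(out_dir / "exclusions.tsv", sep="\t", index=False)
        (out_dir / "noise.json").write_text(json.dumps(
            {k: v.to_dict() for k, v in noise.items()}, indent=2, sort_keys=True))
        run_log = {
            "package_version": __version__,
            "seed": config.seed,
            "site": site,
            "idps": idps,
            "n_rows_after_qc": int(len(df)),
            "n_excluded_subjects": int(len(exclusions)),
            "sets": sets,
        }
        (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
        config.to_yaml(out_dir / "config_used.yaml")
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    return PipelineResult(
        out_dir=out_dir, zscores=z, group_test=group_test, zdiff=zdiff,
        zdiff_test=zdiff_test, noise=noise, exclusions=exclusions, sets=sets,
    )
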