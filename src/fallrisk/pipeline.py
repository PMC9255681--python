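"""End-to-end orchestration: cohort -> ascertainment -> predictors ->
Bolasso development -> internal validation -> report tables.

``run_all`` executes the whole strategy from a single config: generate (or
ingest) a cohort, ascertain outcomes and history of falls from the notes,
assemble the 79-candidate design matrix with death weights, run Bolasso at
the primary consistency threshold 1.0 and the 0.8 comparison, refit the final
models, internally validate with nested cross-validation (base cohort plus
the two exclusion sensitivity variants), and write baseline/model/performance
tables and calibration curves. A run manifest records the config hash, the
seed fan-out and a digest of every output, and rerunning the same config
reproduces every result file byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import synthetic as syn
from .model import BolassoConfig, FinalModel, fit_weighted_logistic, run_bolasso
from .textmine import default_lexicon, load_lexicon
from .validation import (
    VARIANTS,
    calibration_curve,
    crossvalidate,
    sensitivity_variant,
)


class PipelineConfigError(ValueError):
    """Configuration schema violation, reported with the offending field path."""


_DEFAULTS: dict = {
    "n_patients": 5000,
    "seed": 0,
    "index_date": "2018-12-31",
    "lexicon": None,  # path; default bundled English lexicon
    "ingest_dir": None,  # read an existing cohort directory instead of simulating
    "cohort": {},  # CohortConfig overrides (death_rate, note_noise, ...)
    "bolasso": {"n_bootstrap": 100, "inner_cv_folds": 10, "nlambda": 30},
    "thresholds": [1.0, 0.8],
    "cv_folds": 10,
    "sensitivity_variants": True,
    "plot": False,
}


def validate_config(cfg: dict) -> dict:
    """Merge with defaults and validate; raises with a field path on error."""
    merged = {**_DEFAULTS, **cfg}
    merged["cohort"] = {**_DEFAULTS["cohort"], **(cfg.get("cohort") or {})}
    merged["bolasso"] = {**_DEFAULTS["bolasso"], **(cfg.get("bolasso") or {})}
    unknown = set(cfg) - set(_DEFAULTS)
    if unknown:
        raise PipelineConfigError(f"unknown config fields: {sorted(unknown)}")
    if not isinstance(merged["n_patients"], int) or merged["n_patients"] < 1:
        raise PipelineConfigError("n_patients: must be a positive integer")
    try:
        date.fromisoformat(merged["index_date"])
    except ValueError as exc:
        raise PipelineConfigError(f"index_date: {exc}") from exc
    if merged["bolasso"]["n_bootstrap"] < 1:
        raise PipelineConfigError("bolasso.n_bootstrap: must be >= 1")
    for t in merged["thresholds"]:
        if not 0.0 < t <= 1.0:
            raise PipelineConfigError(f"thresholds: {t} outside (0, 1]")
    if merged["cv_folds"] < 2:
        raise PipelineConfigError("cv_folds: must be >= 2")
    for k, v in merged["cohort"].items():
        if k.endswith(("fraction", "rate")) and not 0.0 <= v <= 1.0:
            raise PipelineConfigError(f"cohort.{k}: {v} outside [0, 1]")
    return merged


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_seeds: dict[str, int]
    outputs: dict[str, str]  # relative path -> sha256
    started: str
    finished: str

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _pct(n: int, total: int, digits: int = 1) -> float:
    """Percentage as printed in baseline tables: 100*n/total rounded."""
    return round(100.0 * n / total, digits) if total else float("nan")


def report_baseline(dm: feat.DesignMatrix) -> pd.DataFrame:
    """Baseline characteristics by faller status: n (%) per binary predictor,
    median [IQR] for age, with percentages over each column's total."""
    fallers = dm.y == 1
    n_fall, n_non = int(fallers.sum()), int((~fallers).sum())
    rows = []
    for col in dm.columns:
        if col == "age":
            med = lambda m: dm.X.loc[m, "age"].median()
            iqr = lambda m: np.percentile(dm.X.loc[m, "age"], [25, 75])
            lo_n, hi_n = iqr(~fallers)
            lo_f, hi_f = iqr(fallers)
            rows.append(
                {
                    "predictor": "age",
                    "nonfallers": f"{med(~fallers):.1f} [{lo_n:.1f}-{hi_n:.1f}]",
                    "fallers": f"{med(fallers):.1f} [{lo_f:.1f}-{hi_f:.1f}]",
                }
            )
        else:
            cn = int(dm.X.loc[~fallers, col].sum())
            cf = int(dm.X.loc[fallers, col].sum())
            rows.append(
                {
                    "predictor": col,
                    "nonfallers": f"{cn} ({_pct(cn, n_non)})",
                    "fallers": f"{cf} ({_pct(cf, n_fall)})",
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_fallers"] = n_fall
    out.attrs["n_nonfallers"] = n_non
    return out


def _model_report(model: FinalModel) -> pd.DataFrame:
    t = model.to_table()
    t.loc[len(t)] = ["(intercept)", model.intercept, np.nan, np.nan, np.nan]
    return t


def run_all(config: dict | str | Path, outdir: str | Path, seed: int | None = None) -> RunManifest:
    """Execute the full development-and-validation strategy; returns the manifest."""
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    cfg = load_config(config) if isinstance(config, (str, Path)) else validate_config(dict(config))
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # one global seed fans out to per-stage seeds via a fixed splitting rule
    ss = np.random.SeedSequence(cfg["seed"])
    stage_seeds = {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(
            ("cohort", "bolasso", "cv_base", "cv_lookback", "cv_no_consult"),
            ss.spawn(5),
        )
    }

    lexicon = load_lexicon(cfg["lexicon"]) if cfg["lexicon"] else default_lexicon()

    if cfg["ingest_dir"]:
        cohort = syn.read_cohort(cfg["ingest_dir"])
    else:
        cc = syn.CohortConfig(
            n_patients=cfg["n_patients"],
            index_date=date.fromisoformat(cfg["index_date"]),
            seed=stage_seeds["cohort"],
            **{
                k: (syn.NoteNoise(**v) if k == "note_noise" else v)
                for k, v in cfg["cohort"].items()
            },
        )
        cohort = syn.generate_cohort(cc)
        syn.write_cohort(cohort, outdir / "cohort")

    obs_win = cohort.config.observation_window
    fu_win = cohort.config.followup_window
    dm = feat.assemble_design_matrix(
        cohort.patients,
        cohort.medications,
        cohort.diagnoses,
        cohort.notes,
        obs_win,
        fu_win,
        lexicon=lexicon,
    )

    report_baseline(dm).to_csv(outdir / "baseline_table.csv", index=False)

    bl = cfg["bolasso"]
    bcfg = BolassoConfig(
        n_bootstrap=bl["n_bootstrap"],
        inner_cv_folds=bl["inner_cv_folds"],
        nlambda=bl["nlambda"],
        seed=stage_seeds["bolasso"],
    )
    selection = run_bolasso(dm.X, dm.y.to_numpy(), dm.w.to_numpy(), bcfg)
    selection.frequencies.rename("selection_frequency").to_csv(
        outdir / "selection_frequencies.csv"
    )

    models = {}
    for thr in cfg["thresholds"]:
        chosen = selection.selected(thr)
        tag = f"pi{int(round(thr * 100)):03d}"
        if chosen:
            m = fit_weighted_logistic(dm.X[chosen], dm.y.to_numpy(), dm.w.to_numpy(), names=chosen)
            models[tag] = m
            m.to_json(outdir / f"model_{tag}.json")
            _model_report(m).to_csv(outdir / f"model_{tag}.csv", index=False)
        else:
            models[tag] = None
            (outdir / f"model_{tag}.json").write_text(json.dumps({"selected": []}))

    summary: dict = {
        "config_hash": None,
        "n_patients": int(len(dm.X)),
        "n_fallers": int(dm.y.sum()),
        "fall_prevalence_pct": _pct(int(dm.y.sum()), len(dm.X)),
        "selection": {
            f"pi{int(round(t * 100)):03d}": selection.selected(t) for t in cfg["thresholds"]
        },
    }

    cv = crossvalidate(dm, bcfg, k=cfg["cv_folds"], seed=stage_seeds["cv_base"])
    pd.DataFrame([dataclasses.asdict(f) for f in cv.folds]).to_csv(
        outdir / "fold_metrics.csv", index=False
    )
    summary["performance"] = {"base": cv.summary.as_dict()}

    ok = cv.oof_pred.notna()
    for method in ("decile", "loess"):
        curve = calibration_curve(
            cv.oof_pred[ok].to_numpy(), cv.oof_y[ok].to_numpy(), cv.oof_w[ok].to_numpy(),
            method=method,
        )
        pd.DataFrame({"predicted": curve.predicted, "observed": curve.observed}).to_csv(
            outdir / f"calibration_{method}.csv", index=False
        )

    if cfg["sensitivity_variants"]:
        for variant, skey in zip(VARIANTS, ("cv_lookback", "cv_no_consult")):
            res, excluded = sensitivity_variant(
                dm, variant, bcfg, k=cfg["cv_folds"], seed=stage_seeds[skey]
            )
            summary["performance"][variant] = res.summary.as_dict()
            summary["performance"][variant]["n_excluded"] = excluded

    cfg_canon = json.dumps(cfg, sort_keys=True, default=str)
    config_hash = hashlib.sha256(cfg_canon.encode()).hexdigest()
    summary["config_hash"] = config_hash
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    if cfg["plot"]:
        _calibration_plot(cv, outdir / "calibration.png")

    outputs = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config_hash=config_hash,
        seed=cfg["seed"],
        stage_seeds=stage_seeds,
        outputs=outputs,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(outdir / "manifest.json")
    return manifest


def _calibration_plot(cv, path: Path) -> None:
    """Calibration figure: diagonal, loess smooth, decile points, probability
    histogram in a lower panel."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = cv.oof_pred.notna()
    p = cv.oof_pred[ok].to_numpy()
    y = cv.oof_y[ok].to_numpy()
    w = cv.oof_w[ok].to_numpy()
    dec = calibration_curve(p, y, w, method="decile")
    lo = calibration_curve(p, y, w, method="loess")
    fig, (ax, axh) = plt.subplots(
        2, 1, figsize=(5, 6), height_ratios=[4, 1], sharex=True
    )
    lim = max(0.05, p.max() * 1.05)
    ax.plot([0, lim], [0, lim], "k-", lw=1, label="ideal")
    ax.plot(lo.predicted, lo.observed, "b--", label="loess")
    ax.plot(dec.predicted, dec.observed, "ro", ms=4, label="deciles")
    ax.set_ylabel("observed fall rate")
    ax.legend(frameon=False)
    axh.hist(p, bins=40, color="grey")
    axh.set_xlabel("predicted probability")
    axh.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
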