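"""Internal validation: metrics, calibration and nested cross-validation.

The entire development strategy — Bolasso variable selection followed by an
unregularised weighted refit — is repeated on each of k=10 training folds and
evaluated on the held-out fold, so the reported performance accounts for the
selection procedure itself. Discrimination is summarised by the weighted
ROCAUC and PRAUC, overall accuracy of the probabilities by the Brier score,
and classification behaviour by sensitivity/specificity/PPV at each fold's
Youden-index threshold. Fold metrics are summarised as median and IQR.
Calibration is assessed by decile binning (mean predicted vs mean observed
per equal-count bin) and by a local-quadratic (loess-style) smooth of the
outcome on the predicted probability.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .features import DesignMatrix
from .model import (
    BolassoConfig,
    FinalModel,
    fit_weighted_logistic,
    predict_probability,
    run_bolasso,
)


class ValidationError(ValueError):
    pass


def _check(p, y, w):
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if w is None else np.asarray(w, dtype=float)
    return p, y, w


def roc_auc(p, y, w=None) -> float:
    """Weighted concordance probability (ties count 1/2); NaN if single-class."""
    p, y, w = _check(p, y, w)
    if y.min() == y.max():
        return float("nan")
    return float(roc_auc_score(y, p, sample_weight=w))


def pr_auc(p, y, w=None) -> float:
    """Step-interpolated average precision; NaN if single-class."""
    p, y, w = _check(p, y, w)
    if y.min() == y.max():
        return float("nan")
    return float(average_precision_score(y, p, sample_weight=w))


def brier(p, y, w=None) -> float:
    """Weighted mean squared error of the probabilistic predictions."""
    p, y, w = _check(p, y, w)
    return float(np.sum(w * (p - y) ** 2) / np.sum(w))


def youden_threshold(p, y, w=None) -> dict[str, float]:
    """Threshold maximising J = sensitivity + specificity - 1.

    Candidate thresholds are the observed probability values (classification
    rule: predicted positive iff p >= t); the smallest maximising threshold is
    returned with the weighted sensitivity, specificity and PPV at it.
    """
    p, y, w = _check(p, y, w)
    if y.min() == y.max():
        raise ValidationError("Youden threshold undefined for single-class outcome")
    order = np.argsort(p, kind="stable")
    ps, ys, ws = p[order], y[order], w[order]
    pos_total = float(np.sum(ws * ys))
    neg_total = float(np.sum(ws * (1 - ys)))
    # at threshold ps[i], predictions >= ps[i] are positive; aggregate ties
    uniq, first_idx = np.unique(ps, return_index=True)
    pos_below = np.concatenate([[0.0], np.cumsum(ws * ys)])
    neg_below = np.concatenate([[0.0], np.cumsum(ws * (1 - ys))])
    tp = pos_total - pos_below[first_idx]
    fp = neg_total - neg_below[first_idx]
    sens = tp / pos_total
    spec = 1.0 - fp / neg_total
    J = sens + spec - 1.0
    best = int(np.flatnonzero(J == J.max())[0])  # smallest threshold on ties
    ppv = float(tp[best] / (tp[best] + fp[best])) if tp[best] + fp[best] > 0 else float("nan")
    return {
        "threshold": float(uniq[best]),
        "sensitivity": float(sens[best]),
        "specificity": float(spec[best]),
        "ppv": ppv,
        "youden_j": float(J[best]),
    }


@dataclass
class CalibrationCurve:
    """(predicted, observed) calibration pairs, by decile bins or loess smooth."""

    method: str
    predicted: np.ndarray
    observed: np.ndarray
    counts: np.ndarray | None = None


def _loess(x, y, w, grid, span=0.75, degree=2):
    """Tricube-weighted local polynomial regression evaluated on a grid."""
    n = len(x)
    k = max(int(np.ceil(span * n)), degree + 2)
    out = np.empty(len(grid))
    order = np.argsort(x)
    xs, ys, wsamp = x[order], y[order], w[order]
    for gi, g in enumerate(grid):
        d = np.abs(xs - g)
        idx = np.argpartition(d, min(k, n) - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            out[gi] = np.average(ys[idx], weights=wsamp[idx])
            continue
        tri = (1 - (d[idx] / dmax) ** 3) ** 3
        wloc = tri * wsamp[idx]
        V = np.vander(xs[idx] - g, degree + 1, increasing=True)
        WV = wloc[:, None] * V
        try:
            beta = np.linalg.solve(V.T @ WV, WV.T @ ys[idx])
            out[gi] = beta[0]
        except np.linalg.LinAlgError:
            out[gi] = np.average(ys[idx], weights=wloc)
    return out


def calibration_curve(
    p, y, w=None, method: str = "decile", n_bins: int = 10, span: float = 0.75,
    grid_size: int = 100,
) -> CalibrationCurve:
    """Decile or loess calibration curve of observed rate against prediction.

    Decile: equal-count quantile bins of p with per-bin weighted means (fewer
    bins, with a warning, if heavy ties prevent distinct edges). Loess:
    span-0.75 local quadratic smooth on an even grid over the prediction range.
    """
    p, y, w = _check(p, y, w)
    if method == "decile":
        if len(p) < 2 * n_bins:
            raise ValidationError(f"decile calibration needs >= {2 * n_bins} points")
        edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)))
        if len(edges) - 1 < n_bins:
            warnings.warn(
                f"ties reduce calibration bins from {n_bins} to {len(edges) - 1}"
            )
        bins = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
        pred, obs, cnt = [], [], []
        for b in range(len(edges) - 1):
            m = bins == b
            if not m.any():
                continue
            pred.append(np.average(p[m], weights=w[m]))
            obs.append(np.average(y[m], weights=w[m]))
            cnt.append(int(m.sum()))
        return CalibrationCurve("decile", np.array(pred), np.array(obs), np.array(cnt))
    if method == "loess":
        grid = np.linspace(p.min(), p.max(), grid_size)
        return CalibrationCurve("loess", grid, _loess(p, y, w, grid, span=span))
    raise ValidationError(f"unknown calibration method {method!r}")


# ---------------------------------------------------------------------------
# nested cross-validation


@dataclass
class FoldMetrics:
    fold: int
    rocauc: float
    prauc: float
    brier: float
    sensitivity: float
    specificity: float
    ppv: float
    youden_thr: float
    n_test: int
    events_test: int
    n_selected: int

    _METRICS = ("rocauc", "prauc", "sensitivity", "specificity", "ppv", "brier")


@dataclass
class MetricSummary:
    """Median and IQR of each performance measure over folds."""

    table: pd.DataFrame  # index metric, columns median/q25/q75

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            m: {k: float(v) for k, v in row.items()}
            for m, row in self.table.iterrows()
        }


def summarize_folds(folds: list[FoldMetrics]) -> MetricSummary:
    rows = {}
    for m in FoldMetrics._METRICS:
        vals = np.array([getattr(f, m) for f in folds], dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows[m] = {
                "median": np.nanmedian(vals),
                "q25": np.nanpercentile(vals, 25),
                "q75": np.nanpercentile(vals, 75),
            }
    return MetricSummary(pd.DataFrame(rows).T[["median", "q25", "q75"]])


@dataclass
class CrossValidationResult:
    folds: list[FoldMetrics]
    summary: MetricSummary
    oof_pred: pd.Series  # pooled out-of-fold predicted probabilities
    oof_y: pd.Series
    oof_w: pd.Series
    models: list[FinalModel]
    selected_sets: list[list[str]]


def crossvalidate(
    dm: DesignMatrix,
    config: BolassoConfig | None = None,
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
    permute_test_y: bool = False,
) -> CrossValidationResult:
    """Repeat the whole development strategy per fold and score held-out folds.

    Per training fold: Bolasso selection at the configured threshold, then an
    unregularised weighted refit of the selected columns; all metrics are
    computed on the held-out fold with each fold's own Youden threshold. Folds
    are stratified on the outcome by default. ``permute_test_y`` shuffles each
    held-out fold's outcomes before scoring — a leakage diagnostic whose
    median ROCAUC must sit at 0.5.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    config = config or BolassoConfig()
    X, y, w = dm.X, dm.y.to_numpy(), dm.w.to_numpy()
    splitter = (
        StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % 2**32)
        if stratified
        else KFold(n_splits=k, shuffle=True, random_state=seed % 2**32)
    )
    rng = np.random.default_rng(seed)
    folds: list[FoldMetrics] = []
    models: list[FinalModel] = []
    sets: list[list[str]] = []
    oof_p = np.full(len(y), np.nan)
    for fi, (tr, te) in enumerate(splitter.split(X, y)):
        if y[tr].sum() == 0 or y[te].sum() == 0:
            raise ValidationError(
                f"fold {fi} has zero events; use stratified folds or fewer splits"
            )
        fold_cfg = dataclasses.replace(config, seed=int(rng.integers(2**31)))
        selection = run_bolasso(X.iloc[tr], y[tr], w[tr], fold_cfg)
        chosen = selection.selected(config.threshold)
        sets.append(chosen)
        if chosen:
            model = fit_weighted_logistic(
                X.iloc[tr][chosen], y[tr], w[tr], names=chosen
            )
            p_te = predict_probability(model, X.iloc[te])
        else:  # intercept-only: constant event-rate prediction
            model = None
            p_te = np.full(len(te), np.average(y[tr], weights=w[tr]))
        if model is not None:
            models.append(model)
        y_te = y[te].copy()
        if permute_test_y:
            y_te = rng.permutation(y_te)
        oof_p[te] = p_te
        thr = (
            youden_threshold(p_te, y_te, w[te])
            if y_te.min() != y_te.max() and len(np.unique(p_te)) > 1
            else {"threshold": float("nan"), "sensitivity": float("nan"),
                  "specificity": float("nan"), "ppv": float("nan")}
        )
        folds.append(
            FoldMetrics(
                fold=fi,
                rocauc=roc_auc(p_te, y_te, w[te]),
                prauc=pr_auc(p_te, y_te, w[te]),
                brier=brier(p_te, y_te, w[te]),
                sensitivity=thr["sensitivity"],
                specificity=thr["specificity"],
                ppv=thr["ppv"],
                youden_thr=thr["threshold"],
                n_test=len(te),
                events_test=int(y[te].sum()),
                n_selected=len(chosen),
            )
        )
    return CrossValidationResult(
        folds=folds,
        summary=summarize_folds(folds),
        oof_pred=pd.Series(oof_p, index=dm.X.index, name="p_fall"),
        oof_y=pd.Series(y, index=dm.X.index, name="fall"),
        oof_w=pd.Series(w, index=dm.X.index, name="weight"),
        models=models,
        selected_sets=sets,
    )


VARIANTS = ("exclude_lookback", "exclude_no_consult")


def sensitivity_variant(
    dm: DesignMatrix,
    variant: str,
    config: BolassoConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> tuple[CrossValidationResult, int]:
    """Re-run the full cross-validated strategy on an exclusion variant.

    ``exclude_lookback`` drops patients whose condition predictors came from
    prior years; ``exclude_no_consult`` drops patients without a follow-up
    consultation. Returns the result and the number of excluded patients.
    """
    if variant == "exclude_lookback":
        keep = ~dm.flags["lookback_used"]
    elif variant == "exclude_no_consult":
        keep = ~dm.flags["no_followup_consult"]
    else:
        raise ValidationError(f"unknown sensitivity variant {variant!r}")
    excluded = int((~keep).sum())
    return crossvalidate(dm.subset(keep), config, k=k, seed=seed), excluded
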