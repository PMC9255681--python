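"""Weighted logistic regression, the lasso path, and Bolasso variable selection.

The development strategy is bootstrap-enhanced lasso (Bolasso): draw ``b``
bootstrap samples of the full data (rows carry their observation weights),
fit an L1-penalised weighted logistic regression on each with the penalty
chosen by inner cross-validation, and retain the variables selected in a
fraction >= pi of the samples (pi = 1.0 primary, 0.8 comparison). The
retained variables are refit by unregularised weighted logistic regression,
whose linear predictor defines the risk score ``p = 1 / (1 + exp(-LP))``.

The penalised fits use an in-package coordinate-descent path solver
(iteratively reweighted least squares with cyclic soft-thresholding, warm
starts along a geometric lambda grid, active-set iteration) — the standard
glmnet algorithm — operating on unit-variance-standardised columns with an
unpenalised intercept, returning coefficients on the original scale. The
objective is ``-(1/W) sum_i w_i loglik_i + lambda * sum_j |beta_j|`` with
``W = sum_i w_i``. Unpenalised fits and their Wald confidence intervals come
from a weighted GLM.
"""

from __future__ import annotations

import json
import warnings
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numba import njit
from sklearn.model_selection import KFold


class ModelError(ValueError):
    pass


class DegenerateOutcomeError(ModelError):
    """Raised when the outcome has a single class."""


# ---------------------------------------------------------------------------
# coordinate-descent lasso path (numba)


@njit(cache=True)
def _cd_sweep(X, kind, av, bma, nz_ptr, nz_idx, somw_nz, somwx,
              omw, swtot, r, shift, S1w, beta, xsq, lamW, active_only):
    """One cyclic coordinate-descent sweep on the working least-squares problem.

    Two-valued (binary) columns are visited in O(nnz) via their nonzero index
    lists plus a shared scalar residual shift; dense columns (age) in O(n).
    The stored residual relates to the true working residual by
    ``rho_i = r[i] - shift``. Updates beta/r in place; returns
    (max coefficient change, shift, S1w).
    """
    n, p = X.shape
    maxd = 0.0
    for j in range(p):
        if xsq[j] <= 0.0:
            continue
        bj = beta[j]
        if active_only and bj == 0.0:
            continue
        if kind[j] == 0:  # dense column
            s = 0.0
            for i in range(n):
                s += omw[i] * X[i, j] * r[i]
            dot = s - shift * somwx[j]
        else:  # two-valued column: X_ij = av[j] + bma[j] * [i in nz_j]
            t = 0.0
            for k in range(nz_ptr[j], nz_ptr[j + 1]):
                i = nz_idx[k]
                t += omw[i] * r[i]
            dot = av[j] * (S1w - shift * swtot) + bma[j] * (t - shift * somw_nz[j])
        u = dot + xsq[j] * bj
        if u > lamW:
            bnew = (u - lamW) / xsq[j]
        elif u < -lamW:
            bnew = (u + lamW) / xsq[j]
        else:
            bnew = 0.0
        d = bnew - bj
        if d != 0.0:
            if kind[j] == 0:
                for i in range(n):
                    r[i] -= d * X[i, j]
                S1w -= d * somwx[j]
            else:
                shift += d * av[j]
                db = d * bma[j]
                for k in range(nz_ptr[j], nz_ptr[j + 1]):
                    r[nz_idx[k]] -= db
                S1w -= db * somw_nz[j]
            beta[j] = bnew
            ad = abs(d)
            if ad > maxd:
                maxd = ad
    return maxd, shift, S1w


@njit(cache=True)
def _lasso_path(X, kind, av, bma, nz_ptr, nz_idx, y, w, lambdas,
                tol, max_outer, max_inner):
    """IRLS + coordinate descent over a decreasing lambda grid, warm-started.

    X must be standardised (unit variance) and Fortran-ordered; ``kind``,
    ``av``, ``bma``, ``nz_ptr``/``nz_idx`` describe the two-valued columns
    (see :func:`_column_repr`). Returns (intercepts, coefficient matrix,
    converged flags), one row per lambda.
    """
    n, p = X.shape
    nl = lambdas.shape[0]
    W = w.sum()
    B = np.zeros((nl, p))
    B0 = np.zeros(nl)
    conv = np.ones(nl, np.bool_)
    beta = np.zeros(p)
    ybar = (w * y).sum() / W
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.empty(n)
    omw = np.empty(n)
    r = np.empty(n)
    xsq = np.empty(p)
    somw_nz = np.empty(p)
    somwx = np.empty(p)
    for li in range(nl):
        lamW = lambdas[li] * W
        converged = False
        for _outer in range(max_outer):
            # linear predictor at the current fit
            base = b0
            for j in range(p):
                if kind[j] == 1 and beta[j] != 0.0:
                    base += beta[j] * av[j]
            for i in range(n):
                eta[i] = base
            for j in range(p):
                if beta[j] == 0.0:
                    continue
                if kind[j] == 0:
                    for i in range(n):
                        eta[i] += beta[j] * X[i, j]
                else:
                    db = beta[j] * bma[j]
                    for k in range(nz_ptr[j], nz_ptr[j + 1]):
                        eta[nz_idx[k]] += db
            # working weights and residual
            swtot = 0.0
            S1w = 0.0
            for i in range(n):
                e = eta[i]
                if e > 30.0:
                    e = 30.0
                elif e < -30.0:
                    e = -30.0
                pr = 1.0 / (1.0 + np.exp(-e))
                om = pr * (1.0 - pr)
                if om < 1e-5:
                    om = 1e-5
                omw[i] = w[i] * om
                swtot += omw[i]
                r[i] = (y[i] - pr) / om
                S1w += omw[i] * r[i]
            shift = 0.0
            for j in range(p):
                if kind[j] == 1:
                    t = 0.0
                    for k in range(nz_ptr[j], nz_ptr[j + 1]):
                        t += omw[nz_idx[k]]
                    somw_nz[j] = t
                    somwx[j] = 0.0
                    xsq[j] = av[j] * av[j] * swtot + (
                        2.0 * av[j] * bma[j] + bma[j] * bma[j]
                    ) * t
                else:
                    s = 0.0
                    sx = 0.0
                    for i in range(n):
                        s += omw[i] * X[i, j] * X[i, j]
                        sx += omw[i] * X[i, j]
                    xsq[j] = s
                    somwx[j] = sx
                    somw_nz[j] = 0.0
            b0_start = b0
            beta_start = beta.copy()
            # active-set CD with periodic full sweeps to admit new variables
            for _it in range(max_inner):
                d0 = (S1w - shift * swtot) / swtot
                b0 += d0
                shift += d0
                maxd, shift, S1w = _cd_sweep(
                    X, kind, av, bma, nz_ptr, nz_idx, somw_nz, somwx,
                    omw, swtot, r, shift, S1w, beta, xsq, lamW, True
                )
                if abs(d0) > maxd:
                    maxd = abs(d0)
                if maxd < tol:
                    full, shift, S1w = _cd_sweep(
                        X, kind, av, bma, nz_ptr, nz_idx, somw_nz, somwx,
                        omw, swtot, r, shift, S1w, beta, xsq, lamW, False
                    )
                    if full < tol:
                        break
            # outer (IRLS) convergence on the coefficient change
            delta = abs(b0 - b0_start)
            for j in range(p):
                dj = abs(beta[j] - beta_start[j])
                if dj > delta:
                    delta = dj
            if delta < tol * 10.0:
                converged = True
                break
        conv[li] = converged
        B0[li] = b0
        for j in range(p):
            B[li, j] = beta[j]
    return B0, B, conv


def _column_repr(Xs: np.ndarray):
    """Classify standardised columns for the solver: two-valued columns get a
    nonzero-index representation (value ``av`` for the frequent level, step
    ``bma`` for the listed rows); other columns stay dense (kind 0)."""
    n, p = Xs.shape
    kind = np.zeros(p, np.int8)
    av = np.zeros(p)
    bma = np.zeros(p)
    nz_lists = []
    for j in range(p):
        col = Xs[:, j]
        lo = col.min()
        hi = col.max()
        is_hi = col == hi
        if lo < hi and (is_hi | (col == lo)).all():
            if int(is_hi.sum()) * 2 <= n:
                a, b, nz = lo, hi, np.flatnonzero(is_hi)
            else:
                a, b, nz = hi, lo, np.flatnonzero(~is_hi)
            kind[j] = 1
            av[j] = a
            bma[j] = b - a
            nz_lists.append(nz.astype(np.int64))
        else:
            nz_lists.append(np.empty(0, np.int64))
    nz_ptr = np.zeros(p + 1, np.int64)
    for j in range(p):
        nz_ptr[j + 1] = nz_ptr[j] + len(nz_lists[j])
    nz_idx = (
        np.concatenate(nz_lists) if nz_ptr[-1] else np.empty(0, np.int64)
    )
    return kind, av, bma, nz_ptr, nz_idx


def _run_path(Xs, y, w, lambdas, tol, max_outer=100, max_inner=1000):
    kind, av, bma, nz_ptr, nz_idx = _column_repr(Xs)
    return _lasso_path(
        Xs, kind, av, bma, nz_ptr, nz_idx,
        np.ascontiguousarray(y, dtype=np.float64),
        np.ascontiguousarray(w, dtype=np.float64),
        np.ascontiguousarray(lambdas, dtype=np.float64),
        tol, max_outer, max_inner,
    )


def lambda_grid(
    Xs: np.ndarray, y: np.ndarray, w: np.ndarray, nlambda: int, min_ratio: float
) -> np.ndarray:
    """Geometric grid from lambda_max (smallest lambda with an empty active
    set, from the KKT conditions at the intercept-only fit) down to
    ``lambda_max * min_ratio``."""
    W = w.sum()
    ybar = (w * y).sum() / W
    score = np.abs(Xs.T @ (w * (y - ybar))) / W
    lam_max = float(score.max())
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * min_ratio, nlambda)


@dataclass
class BolassoConfig:
    """Bolasso settings: b bootstrap samples, consistency threshold pi, and
    the per-sample penalty rule (lambda minimising 10-fold cross-validated
    weighted deviance by default, with a one-standard-error variant)."""

    n_bootstrap: int = 100
    threshold: float = 1.0
    lambda_rule: str = "cv_min"  # or "cv_1se"
    inner_cv_folds: int = 10
    nlambda: int = 30
    lambda_min_ratio: float = 1e-3
    cv_tol: float = 1e-4
    final_tol: float = 1e-6
    # group the inner CV folds of each bootstrap sample by original row, so
    # resampled duplicates never straddle a train/validation split. Off by
    # default: plain per-sample CV is the published procedure's convention,
    # and its selection behaviour (larger per-sample active sets) is what the
    # reported consistency thresholds were calibrated against.
    group_cv: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ModelError("n_bootstrap must be >= 1")
        if not 0.0 < self.threshold <= 1.0:
            raise ModelError("threshold must lie in (0, 1]")
        if self.lambda_rule not in ("cv_min", "cv_1se"):
            raise ModelError(f"unknown lambda_rule {self.lambda_rule!r}")
        if self.inner_cv_folds < 2:
            raise ModelError("inner_cv_folds must be >= 2")


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return np.asarray(X.to_numpy(), dtype=np.float64), list(X.columns)
    X = np.asarray(X, dtype=np.float64)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _group_splits(groups: np.ndarray, k: int, seed: int):
    """Random k-fold partition at the group level (rows follow their group)."""
    rng = np.random.default_rng(seed)
    uniq = np.unique(groups)
    assignment = dict(zip(uniq[rng.permutation(len(uniq))], np.arange(len(uniq)) % k))
    fold_of = np.array([assignment[g] for g in groups])
    return [
        (np.flatnonzero(fold_of != f), np.flatnonzero(fold_of == f)) for f in range(k)
    ]


def _weighted_deviance(eta: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    eta = np.clip(eta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    ll = y * np.log(p) + (1 - y) * np.log(1 - p)
    return float(-2.0 * np.sum(w * ll) / np.sum(w))


@dataclass
class LassoFit:
    """One penalised fit: the chosen lambda and its active set."""

    names: list[str]
    intercept: float
    coef: pd.Series  # original scale, zeros included
    lambda_chosen: float
    lambda_grid: np.ndarray
    cv_deviance: np.ndarray | None
    converged: bool

    @property
    def active(self) -> list[str]:
        return [n for n, c in self.coef.items() if c != 0.0]


def lasso_logistic_path(X, y, w=None, lambdas=None, tol=1e-6):
    """Fit the weighted L1 logistic path at the given lambdas.

    Returns (intercepts, coefficient DataFrame on the original scale,
    converged flags). Zero-variance columns keep zero coefficients.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=np.float64)
    w = np.ones(len(y)) if w is None else np.asarray(w, dtype=np.float64)
    if y.min() == y.max():
        raise DegenerateOutcomeError("outcome is single-class")
    mu = Xm.mean(axis=0)
    sd = Xm.std(axis=0)
    keep = sd > 0
    Xs = np.asfortranarray((Xm[:, keep] - mu[keep]) / sd[keep])
    lambdas = np.asarray(lambdas, dtype=np.float64)
    B0, Bs, conv = _run_path(Xs, y, w, lambdas, tol)
    B = np.zeros((len(lambdas), Xm.shape[1]))
    B[:, keep] = Bs / sd[keep]
    b0 = B0 - B[:, keep] @ mu[keep]
    coefs = pd.DataFrame(B, columns=names)
    return b0, coefs, conv


def fit_lasso_logistic(
    X, y, w=None, config: BolassoConfig | None = None, groups=None
) -> LassoFit:
    """Penalty-path fit with the lambda chosen by inner cross-validation.

    Cross-validation minimises the held-out weighted deviance over the path
    (``cv_min``), or applies the one-standard-error rule (``cv_1se``). The
    active set is read from a final full-data fit at the chosen lambda.

    ``groups`` assigns rows to cross-validation groups: all rows sharing a
    group label land in the same fold. On bootstrap samples the labels are
    the original row indices, so duplicated rows never sit on both sides of
    a validation split — without this, the duplicates leak across folds and
    bias the chosen penalty towards zero.
    """
    config = config or BolassoConfig()
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=np.float64)
    w = np.ones(len(y)) if w is None else np.asarray(w, dtype=np.float64)
    if y.min() == y.max():
        raise DegenerateOutcomeError("outcome is single-class")

    mu = Xm.mean(axis=0)
    sd = Xm.std(axis=0)
    keep = sd > 0
    if not keep.any():
        warnings.warn("all columns have zero variance; empty active set")
        return LassoFit(names, float(np.log(y.mean() / (1 - y.mean()))),
                        pd.Series(0.0, index=names), np.nan, np.array([]), None, True)
    Xs = np.asfortranarray((Xm[:, keep] - mu[keep]) / sd[keep])
    lambdas = lambda_grid(Xs, y, w, config.nlambda, config.lambda_min_ratio)

    k = min(config.inner_cv_folds, int(y.sum()), int((1 - y).sum()))
    k = max(k, 2)
    if groups is None:
        folds = KFold(n_splits=k, shuffle=True, random_state=config.seed % (2**32))
        splits = list(folds.split(Xs))
    else:
        splits = _group_splits(np.asarray(groups), k, config.seed)
    fold_dev = np.empty((k, len(lambdas)))
    for fi, (tr, va) in enumerate(splits):
        if y[tr].min() == y[tr].max():  # degenerate training fold
            fold_dev[fi] = np.nan
            continue
        B0, B, _ = _run_path(
            np.asfortranarray(Xs[tr]), y[tr], w[tr], lambdas, config.cv_tol,
            max_outer=50, max_inner=500,
        )
        eta = B0[None, :] + Xs[va] @ B.T
        for li in range(len(lambdas)):
            fold_dev[fi, li] = _weighted_deviance(eta[:, li], y[va], w[va])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_dev = np.nanmean(fold_dev, axis=0)
    if not np.isfinite(mean_dev).any():
        # every CV training fold was degenerate (tiny sample): be maximally
        # conservative and keep the empty model at lambda_max
        warnings.warn("inner CV degenerate on every fold; selecting lambda_max")
        mean_dev = np.where(np.arange(len(lambdas)) == 0, 0.0, np.inf)
    mean_dev = np.where(np.isfinite(mean_dev), mean_dev, np.inf)
    i_min = int(np.argmin(mean_dev))
    if config.lambda_rule == "cv_1se":
        se = np.nanstd(fold_dev, axis=0, ddof=1) / np.sqrt(k)
        ok = np.flatnonzero(mean_dev <= mean_dev[i_min] + se[i_min])
        i_choice = int(ok[0])  # grid is decreasing: first index = largest lambda
    else:
        i_choice = i_min

    B0, B, conv = _run_path(Xs, y, w, lambdas[: i_choice + 1], config.final_tol)
    beta_std = B[-1]
    coef = np.zeros(Xm.shape[1])
    coef[keep] = beta_std / sd[keep]
    intercept = float(B0[-1] - coef[keep] @ mu[keep])
    return LassoFit(
        names=names,
        intercept=intercept,
        coef=pd.Series(coef, index=names),
        lambda_chosen=float(lambdas[i_choice]),
        lambda_grid=lambdas,
        cv_deviance=mean_dev,
        converged=bool(conv[-1]),
    )


# ---------------------------------------------------------------------------
# Bolasso


@dataclass
class SelectionResult:
    """Per-variable bootstrap selection frequencies."""

    frequencies: pd.Series  # fraction of bootstrap samples selecting each column
    n_bootstrap: int
    active_sets: list[list[str]] = field(default_factory=list)

    def selected(self, threshold: float) -> list[str]:
        """Columns selected in at least ``threshold`` of the bootstrap samples."""
        if not 0.0 < threshold <= 1.0:
            raise ModelError("threshold must lie in (0, 1]")
        # tiny epsilon guards the frequency==threshold boundary against
        # floating division noise
        return [n for n, f in self.frequencies.items() if f >= threshold - 1e-12]


def run_bolasso(X, y, w=None, config: BolassoConfig | None = None) -> SelectionResult:
    """Bolasso selection frequencies over ``b`` bootstrap samples.

    Each bootstrap draws n rows with replacement (rows carry their weights),
    fits the cross-validated lasso, and records the active set. A replicate
    whose final fit fails to converge is redrawn once, then counted as
    selecting nothing. Frequencies are invariant to column order.
    """
    config = config or BolassoConfig()
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=np.float64)
    w = np.ones(len(y)) if w is None else np.asarray(w, dtype=np.float64)
    n = len(y)
    rng = np.random.default_rng(config.seed)
    counts = pd.Series(0.0, index=names)
    active_sets: list[list[str]] = []
    for bi in range(config.n_bootstrap):
        fit = None
        for attempt in range(2):
            idx = rng.integers(0, n, n)
            if y[idx].min() == y[idx].max():
                continue  # resample a degenerate bootstrap
            sub_cfg = dataclasses.replace(
                config, n_bootstrap=1, seed=int(rng.integers(2**31))
            )
            fit = fit_lasso_logistic(
                Xm[idx], y[idx], w[idx], sub_cfg,
                groups=idx if config.group_cv else None,
            )
            if fit.converged:
                break
        if fit is None or not fit.converged:
            warnings.warn(f"bootstrap replicate {bi} did not converge; counted empty")
            active_sets.append([])
            continue
        active = [names[j] for j in np.flatnonzero(fit.coef.to_numpy() != 0.0)]
        active_sets.append(active)
        counts[active] += 1.0
    return SelectionResult(
        frequencies=counts / config.n_bootstrap,
        n_bootstrap=config.n_bootstrap,
        active_sets=active_sets,
    )


# ---------------------------------------------------------------------------
# unpenalised refit and prediction


@dataclass
class FinalModel:
    """Unregularised weighted logistic fit: coefficients, ORs and Wald CIs."""

    names: list[str]
    intercept: float
    coef: np.ndarray
    se: np.ndarray  # includes the intercept at position 0
    ci_low: np.ndarray  # coefficient scale, predictors only
    ci_high: np.ndarray
    converged: bool
    n_iter: int

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def or_ci(self) -> tuple[np.ndarray, np.ndarray]:
        return np.exp(self.ci_low), np.exp(self.ci_high)

    def linear_predictor(self, rows: pd.DataFrame) -> np.ndarray:
        for name in self.names:
            if name not in rows.columns:
                raise KeyError(f"missing predictor column: {name!r}")
        return self.intercept + rows[self.names].to_numpy(dtype=float) @ self.coef

    def to_table(self) -> pd.DataFrame:
        lo, hi = self.or_ci
        return pd.DataFrame(
            {
                "predictor": self.names,
                "coefficient": self.coef,
                "odds_ratio": self.odds_ratios,
                "or_ci_low": lo,
                "or_ci_high": hi,
            }
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "names": self.names,
            "intercept": self.intercept,
            "coef": self.coef.tolist(),
            "se": self.se.tolist(),
            "ci_low": self.ci_low.tolist(),
            "ci_high": self.ci_high.tolist(),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FinalModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            names=d["names"],
            intercept=d["intercept"],
            coef=np.array(d["coef"]),
            se=np.array(d["se"]),
            ci_low=np.array(d["ci_low"]),
            ci_high=np.array(d["ci_high"]),
            converged=d["converged"],
            n_iter=d["n_iter"],
        )


def fit_weighted_logistic(X, y, w=None, names: list[str] | None = None) -> FinalModel:
    """Maximise the weighted Bernoulli log-likelihood and report Wald 95% CIs.

    Weights enter as likelihood (variance) weights, so halving all weights
    leaves the coefficients unchanged and widens the intervals. Separation is
    flagged (converged=False, fallback point estimates from a negligibly
    ridge-penalised fit) rather than silently reported.
    """
    Xm, auto_names = _as_matrix(X)
    names = names or auto_names
    y = np.asarray(y, dtype=np.float64)
    w = np.ones(len(y)) if w is None else np.asarray(w, dtype=np.float64)
    if y.min() == y.max():
        raise DegenerateOutcomeError("outcome is single-class; cannot fit")
    Xc = sm.add_constant(Xm, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, Xc, family=sm.families.Binomial(), var_weights=w).fit()
        if not np.all(np.isfinite(res.bse)):
            raise ModelError("non-finite standard errors (separation?)")
        params = res.params
        se = res.bse
        ci = res.conf_int()
        # runaway coefficients signal (quasi-)separation: flag, don't hide
        converged = (
            bool(getattr(res, "converged", True))
            and np.all(np.isfinite(se))
            and float(np.abs(params).max()) < 30.0
        )
        n_iter = int(getattr(res, "fit_history", {}).get("iteration", 0) or 0)
    except Exception:
        # separation or non-convergence: keep usable point estimates, flag it
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1e8, max_iter=2000, tol=1e-10)
        lr.fit(Xm, y.astype(int), sample_weight=w)
        params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        se = np.full(len(params), np.nan)
        ci = np.column_stack([np.full(len(params), np.nan)] * 2)
        converged, n_iter = False, 0
    return FinalModel(
        names=names,
        intercept=float(params[0]),
        coef=np.asarray(params[1:]),
        se=np.asarray(se),
        ci_low=np.asarray(ci)[1:, 0],
        ci_high=np.asarray(ci)[1:, 1],
        converged=converged,
        n_iter=n_iter,
    )


def predict_probability(model: FinalModel, rows: pd.DataFrame) -> np.ndarray:
    """Predicted fall probability ``1 / (1 + exp(-LP))``, vectorised over rows."""
    lp = model.linear_predictor(rows)
    return 1.0 / (1.0 + np.exp(-np.clip(lp, -700, 700)))
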