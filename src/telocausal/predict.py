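"""Elastic-net telomere-length prediction.

Combines demographics, a polygenic score (PRS), a transcriptional risk
score (TRS), and an expression-derived gene signature into cross-validated
elastic-net models, mirroring the common glmnet parameterization:

    minimize (1/2n) ||y - X beta||^2 + lambda (alpha ||beta||_1
                                               + (1-alpha)/2 ||beta||^2)

``alpha`` is the L1 mixing weight and ``lambda`` the penalty strength. All
features are standardized to zero mean / unit variance before fitting and
the constants stored so models transfer to new cohorts. The preset
``published-2023`` pins (alpha, lambda) = (0.14, 0.18), a published
placental TL model's fixed choice; the default is a CV grid search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet

__all__ = [
    "EnetModel",
    "Signature",
    "enet_fit",
    "select_signature",
    "compare_models",
    "transfer_predict",
    "PRESETS",
]

PRESETS = {"published-2023": {"alpha": 0.14, "lambda": 0.18}}


@dataclass
class EnetModel:
    feature_names: list[str]
    coef: np.ndarray
    intercept: float
    means: np.ndarray
    scales: np.ndarray
    alpha: float  # L1 mixing in [0, 1]
    lam: float  # penalty strength >= 0
    cv_r2: float = float("nan")
    in_sample_r2: float = float("nan")
    folds: np.ndarray | None = None
    oof_pred: np.ndarray | None = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Z = (X[self.feature_names].to_numpy(dtype=float) - self.means) / self.scales
        return Z @ self.coef + self.intercept

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": 1,
            "feature_names": self.feature_names,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "alpha": self.alpha,
            "lambda": self.lam,
            "cv_r2": self.cv_r2,
            "in_sample_r2": self.in_sample_r2,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "EnetModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=d["feature_names"],
            coef=np.array(d["coef"]),
            intercept=d["intercept"],
            means=np.array(d["means"]),
            scales=np.array(d["scales"]),
            alpha=d["alpha"],
            lam=d["lambda"],
            cv_r2=d["cv_r2"],
            in_sample_r2=d["in_sample_r2"],
        )


def _standardize(X: np.ndarray):
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales[scales == 0] = 1.0
    return (X - means) / scales, means, scales


def _quartile_folds(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Fold assignment stratified by phenotype quartile for stability."""
    rng = np.random.default_rng(seed)
    q = np.searchsorted(np.quantile(y, [0.25, 0.5, 0.75]), y, side="right")
    assign = np.empty(len(y), dtype=int)
    for level in range(4):
        idx = np.where(q == level)[0]
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return assign


def _fit_raw(Z: np.ndarray, y: np.ndarray, alpha: float, lam: float) -> tuple:
    if lam == 0:
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(y)), Z]), y, rcond=None
        )
        return coef[1:], float(coef[0])
    en = ElasticNet(
        alpha=lam, l1_ratio=alpha, fit_intercept=True, tol=1e-7, max_iter=100_000
    )
    en.fit(Z, y)
    return en.coef_, float(en.intercept_)


def enet_fit(
    X: pd.DataFrame,
    y: np.ndarray,
    alpha: float = 0.5,
    lam: float | None = None,
    folds: int = 10,
    seed: int = 0,
    lambda_grid: np.ndarray | None = None,
) -> EnetModel:
    """Fit an elastic net with internal standardization and 10-fold CV r^2.

    If ``lam`` is None the penalty is chosen by grid search on out-of-fold
    predictions (a geometric grid down from the smallest penalty that zeros
    every coefficient). ``cv_r2`` is the squared Pearson correlation between
    the out-of-fold predictions and ``y`` under quartile-stratified folds.
    """
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(Xv).all() and np.isfinite(y).all()):
        raise ValueError("non-finite entries in features or phenotype")
    if len(y) < folds:
        raise ValueError("need n >= folds")
    Z, means, scales = _standardize(Xv)
    assign = _quartile_folds(y, folds, seed)

    if lam is None:
        if lambda_grid is None:
            lam_max = np.abs(Z.T @ (y - y.mean())).max() / (len(y) * max(alpha, 0.01))
            lambda_grid = lam_max * np.power(10.0, np.linspace(0, -3, 20))
        best = (None, -np.inf)
        for l_try in lambda_grid:
            oof = _oof_predict(Z, y, alpha, float(l_try), assign)
            r2 = _safe_r2(oof, y)
            if r2 > best[1]:
                best = (float(l_try), r2)
        lam = best[0]

    oof = _oof_predict(Z, y, alpha, lam, assign)
    coef, intercept = _fit_raw(Z, y, alpha, lam)
    pred_in = Z @ coef + intercept
    return EnetModel(
        feature_names=list(X.columns),
        coef=np.asarray(coef, dtype=float),
        intercept=intercept,
        means=means,
        scales=scales,
        alpha=alpha,
        lam=float(lam),
        cv_r2=_safe_r2(oof, y),
        in_sample_r2=_safe_r2(pred_in, y),
        folds=assign,
        oof_pred=oof,
    )


def _oof_predict(Z, y, alpha, lam, assign) -> np.ndarray:
    oof = np.empty(len(y))
    for f in np.unique(assign):
        tr = assign != f
        te = ~tr
        coef, intercept = _fit_raw(Z[tr], y[tr], alpha, lam)
        oof[te] = Z[te] @ coef + intercept
    return oof


def _safe_r2(pred: np.ndarray, y: np.ndarray) -> float:
    if np.std(pred) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(pred, y)[0, 1] ** 2)


@dataclass
class Signature:
    genes: list[str]
    weights: np.ndarray
    model: EnetModel = field(repr=False, default=None)

    def score(self, expr: pd.DataFrame) -> pd.Series:
        """Transcriptomic score TS = sum_g w_g * expr_gs (samples x genes in)."""
        X = expr[self.genes].to_numpy(dtype=float)
        return pd.Series(X @ self.weights, index=expr.index, name="TS")


def select_signature(
    expr: pd.DataFrame,
    y: np.ndarray,
    prs: np.ndarray,
    demographics: pd.DataFrame,
    alpha: float = 0.5,
    lam: float | None = None,
    seed: int = 0,
    refit_p_max: float = 0.05,
    folds: int = 10,
    lambda_grid: np.ndarray | None = None,
) -> Signature:
    """Expression signature from an elastic net on [expression | PRS | sex].

    Candidate genes are the expression features with nonzero elastic-net
    coefficients in a joint fit with PRS and demographics (so the selection
    is conditional on, hence independent of, the PRS); the signature keeps
    those whose post-selection OLS refit t-test has p < ``refit_p_max``.
    Weights are the refit (standardized-scale) OLS coefficients.
    """
    feats = expr.copy()
    feats["PRS"] = np.asarray(prs, dtype=float)
    for c in demographics.columns:
        feats[c] = demographics[c].to_numpy(dtype=float)
    model = enet_fit(feats, y, alpha=alpha, lam=lam, seed=seed, folds=folds,
                     lambda_grid=lambda_grid)

    gene_names = list(expr.columns)
    nz = [
        g
        for g, c in zip(model.feature_names, model.coef)
        if c != 0 and g in gene_names
    ]
    if not nz:
        import warnings

        warnings.warn("elastic net selected no genes; empty signature")
        return Signature([], np.array([]), model)

    # post-selection OLS refit on the selected genes (+ PRS + demographics)
    keep_cols = nz + ["PRS"] + list(demographics.columns)
    Z, mu, sc = _standardize(feats[keep_cols].to_numpy(dtype=float))
    X = np.column_stack([np.ones(len(y)), Z])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / max(dof, 1)
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.diag(cov))[1:]
    tstat = coef[1:] / se
    p = 2.0 * stats.t.sf(np.abs(tstat), max(dof, 1))

    genes, weights = [], []
    for i, g in enumerate(keep_cols):
        if g in nz and p[i] < refit_p_max:
            genes.append(g)
            # back to the raw expression scale so TS is a plain weighted sum
            weights.append(coef[1 + i] / sc[i])
    return Signature(genes, np.asarray(weights, dtype=float), model)


def compare_models(
    feature_blocks: dict[str, pd.DataFrame],
    y: np.ndarray,
    combinations: list[tuple[str, ...]] | None = None,
    alpha: float = 0.5,
    lam: float | None = None,
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated r^2 for each feature-block combination.

    All combinations share the same quartile-stratified fold assignment so
    their cv_r2 values are directly comparable; both the out-of-fold and the
    in-sample r^2 are reported.
    """
    if combinations is None:
        names = list(feature_blocks)
        combinations = [(n,) for n in names] + [tuple(names)]
    rows = []
    for combo in combinations:
        X = pd.concat([feature_blocks[b] for b in combo], axis=1)
        model = enet_fit(X, y, alpha=alpha, lam=lam, folds=folds, seed=seed)
        rows.append(
            {
                "features": "+".join(combo),
                "cv_r2": model.cv_r2,
                "in_sample_r2": model.in_sample_r2,
                "n_features": X.shape[1],
                "lambda": model.lam,
            }
        )
    return pd.DataFrame(rows)


def transfer_predict(
    model: EnetModel,
    new_features: pd.DataFrame,
    measured_tl: np.ndarray | None = None,
    max_missing_frac: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Apply a trained model to a new cohort.

    Missing feature columns are imputed at the training mean (i.e. they
    contribute nothing after standardization); more than
    ``max_missing_frac`` of the features missing is refused — raise the
    threshold deliberately for genotype-only cohorts where the whole
    expression block is absent and the prediction degrades to the PRS and
    demographic components. Returns ``(predictions, pearson_r)`` with ``r``
    NaN when no measured TL is supplied.
    """
    missing = [f for f in model.feature_names if f not in new_features.columns]
    if len(missing) > max_missing_frac * len(model.feature_names):
        raise ValueError(
            f"{len(missing)}/{len(model.feature_names)} features missing; refusing"
        )
    X = new_features.copy()
    for i, f in enumerate(model.feature_names):
        if f in missing:
            X[f] = model.means[i]
    pred = model.predict(X)
    r = float("nan")
    if measured_tl is not None:
        r = float(np.corrcoef(pred, np.asarray(measured_tl, dtype=float))[0, 1])
    return pred, r
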