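"""Elastic-net multinomial subtype classifier with jackknife tuning.

Core samples are classified from their top-N smoothed features with a
multinomial logistic model under the elastic-net penalty

    lambda * [ (1 - alpha)/2 * ||B||_2^2  +  alpha * ||B||_1 ],

the glmnet parameterization (alpha mixes ridge and lasso, lambda scales the
penalty; the fit itself is delegated to scikit-learn's saga solver with
C = 1/(n * lambda), l1_ratio = alpha, which optimizes the same objective).
The (alpha, lambda) grid is tuned by the jackknife: leave one sample out,
fit on the rest, predict it, and score the grid point by the fraction
misclassified. Genes with a nonzero coefficient for a subtype are that
subtype's biomarkers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.linear_model import LogisticRegression

from .errors import ConfigurationError, DataError
from .features import FeatureSelectionConfig, rank_by_variability

__all__ = ["ElasticNetConfig", "FittedElasticNet", "SubtypeModel", "fit_elastic_net",
           "jackknife_tune", "default_lambda_path", "extract_biomarkers", "top_n_sweep"]


@dataclass(frozen=True)
class ElasticNetConfig:
    alpha_grid: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 11))
    lambda_path: tuple[float, ...] | None = None  # None: auto-scaled from data
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3
    standardize: bool = True
    max_iter: int = 5000
    tol: float = 1e-4

    def __post_init__(self):
        if not self.alpha_grid:
            raise ConfigurationError("alpha grid is empty")
        if any(not (0.0 <= a <= 1.0) for a in self.alpha_grid):
            raise ConfigurationError("alpha values must lie in [0, 1]")
        if self.lambda_path is not None:
            lp = tuple(self.lambda_path)
            if any(l <= 0 for l in lp) or any(b >= a for a, b in zip(lp, lp[1:])):
                raise ConfigurationError("lambda_path must be positive and strictly decreasing")


@dataclass
class FittedElasticNet:
    """One elastic-net fit plus the training standardization it was fit under."""

    coef: np.ndarray  # classes x features, on the standardized scale
    intercept: np.ndarray
    classes: np.ndarray
    alpha: float
    lam: float
    mean: np.ndarray
    scale: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X) - self.mean) / self.scale
        scores = Xs @ self.coef.T + self.intercept
        return self.classes[np.argmax(scores, axis=1)]


@dataclass
class SubtypeModel:
    fit: FittedElasticNet
    chosen_alpha: float
    chosen_lambda: float
    jackknife_error: float
    feature_names: list[str]
    grid_errors: dict[tuple[float, float], float] = field(default_factory=dict)

    @property
    def jackknife_accuracy(self) -> float:
        return 1.0 - self.jackknife_error

    @property
    def biomarkers(self) -> dict:
        names = np.asarray(self.feature_names)
        return {int(c): list(names[self.fit.coef[i] != 0])
                for i, c in enumerate(self.fit.classes)}


def _standardize(X, enabled: bool):
    X = np.asarray(X, dtype=float)
    if not enabled:
        return np.zeros(X.shape[1]), np.ones(X.shape[1])
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return mean, scale


def fit_elastic_net(X, y, alpha: float, lam: float,
                    config: ElasticNetConfig = ElasticNetConfig()) -> FittedElasticNet:
    """Fit one multinomial elastic-net model at a fixed (alpha, lambda)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise DataError("features must be finite")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise DataError("need at least two classes")
    singleton = classes[counts < 2]
    if singleton.size:
        raise DataError(f"degenerate class with a single sample: {singleton.tolist()}")
    mean, scale = _standardize(X, config.standardize)
    Xs = (X - mean) / scale
    C = 1.0 / (len(y) * lam)
    clf = LogisticRegression(solver="saga", C=C, l1_ratio=alpha,
                             max_iter=config.max_iter, tol=config.tol)
    clf.fit(Xs, y)
    coef, intercept = clf.coef_.copy(), clf.intercept_.copy()
    if coef.shape[0] == 1 and classes.size == 2:
        # binary fits return the class-contrast row; expand to per-class rows
        coef = np.vstack([-coef[0] / 2, coef[0] / 2])
        intercept = np.array([-intercept[0] / 2, intercept[0] / 2])
    return FittedElasticNet(coef=coef, intercept=intercept,
                            classes=clf.classes_.copy(), alpha=alpha, lam=lam,
                            mean=mean, scale=scale)


def default_lambda_path(X, y, config: ElasticNetConfig = ElasticNetConfig()) -> tuple[float, ...]:
    """Log-spaced decreasing penalty path auto-scaled from the data.

    The top of the path is the smallest penalty that zeroes every lasso
    coefficient (the glmnet convention), computed from the standardized
    gradient at the null model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    mean, scale = _standardize(X, config.standardize)
    Xs = (X - mean) / scale
    classes = np.unique(y)
    onehot = (y[:, None] == classes[None, :]).astype(float)
    resid = onehot - onehot.mean(axis=0)
    lam_max = np.abs(Xs.T @ resid).max() / len(y)
    lam_max = max(lam_max, 1e-6)
    return tuple(np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambda))


def _loo_error(X, y, alpha: float, lam: float, config: ElasticNetConfig) -> float:
    """Fraction of samples misclassified when held out one at a time.

    Uses one warm-started solver across folds: consecutive folds differ by a
    single sample, so the previous fold's coefficients are an excellent
    starting point. The fold objective is the same as a cold fit; only the
    iteration count changes.
    """
    n = len(y)
    wrong = 0
    clf = LogisticRegression(solver="saga", C=1.0 / ((n - 1) * lam), l1_ratio=alpha,
                             max_iter=config.max_iter, tol=config.tol, warm_start=True)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        mean, scale = _standardize(Xtr, config.standardize)
        clf.fit((Xtr - mean) / scale, ytr)
        pred = clf.predict((X[i:i + 1] - mean) / scale)[0]
        wrong += int(pred != y[i])
    return wrong / n


def jackknife_tune(X, y, config: ElasticNetConfig = ElasticNetConfig(),
                   feature_names=None) -> SubtypeModel:
    """Leave-one-out tuning over the (alpha, lambda) grid.

    Each grid point's error is the fraction of samples misclassified when
    held out one at a time; the winner is the minimal error with ties broken
    toward larger lambda, then smaller alpha (the more parsimonious model).
    The returned model is refit on all samples at the winning grid point.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 10:
        raise ConfigurationError("jackknife tuning needs at least 10 samples")
    lambdas = config.lambda_path or default_lambda_path(X, y, config)
    grid = [(a, l) for a in config.alpha_grid for l in lambdas]
    if not grid:
        raise ConfigurationError("empty tuning grid")
    errors: dict[tuple[float, float], float] = {}
    for alpha, lam in grid:
        errors[(alpha, lam)] = _loo_error(X, y, alpha, lam, config)
    best_alpha, best_lam = min(errors, key=lambda g: (errors[g], -g[1], g[0]))
    final = fit_elastic_net(X, y, best_alpha, best_lam, config)
    return SubtypeModel(fit=final, chosen_alpha=best_alpha, chosen_lambda=best_lam,
                        jackknife_error=errors[(best_alpha, best_lam)],
                        feature_names=list(feature_names) if feature_names is not None
                        else [f"f{j}" for j in range(X.shape[1])],
                        grid_errors=errors)


def extract_biomarkers(model: SubtypeModel):
    """Per-subtype nonzero-coefficient gene lists plus Venn-style overlap counts."""
    lists = model.biomarkers
    union = set().union(*lists.values()) if lists else set()
    overlaps = {
        (a, b): len(set(lists[a]) & set(lists[b]))
        for a, b in combinations(sorted(lists), 2)
    }
    return {"per_subtype": lists, "union_size": len(union), "pairwise_overlap": overlaps}


def top_n_sweep(smoothed, labels, n_values=(300, 400, 500, 600, 700, 800, 900, 1000),
                config: ElasticNetConfig = ElasticNetConfig(),
                variability: str = "variance"):
    """Jackknife accuracy as a function of the number of top-variability genes."""
    table = {}
    for n in n_values:
        if n > len(smoothed.genes):
            raise ConfigurationError(f"top {n} genes requested, only {len(smoothed.genes)} present")
        fs = FeatureSelectionConfig(top_n=n, variability=variability)
        selected = rank_by_variability(smoothed, fs)
        X = smoothed.to_frame()[selected.index].to_numpy()
        model = jackknife_tune(X, np.asarray(labels), config,
                               feature_names=list(selected.index))
        table[n] = model.jackknife_accuracy
    return table
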