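"""Tissue-specific penalized-regression epigenetic clocks.

The clock is the classic two-step construction: a monotone calibration
transform F maps chronological age t (months) onto the regression scale,

    F(t) = b0 + b1*CpG1 + ... + bn*CpGn + error,

and the epigenetic age (DNAge) of a new sample is the inverse transform of
the fitted linear predictor,

    DNAge = F^-1(b0 + sum_i bi * beta_i).

F defaults to the log-linear family standard for epigenetic clocks:
logarithmic below an "adult age" knot a (fast juvenile methylation change),
linear above it, continuously differentiable at the knot:

    F(t) = ln(t + o) - ln(a + o)   for t <= a
    F(t) = (t - a) / (a + o)       for t >  a

The coefficients are fit by elastic net with cross-validated penalty
strength; :class:`EpigeneticClock` is a scikit-learn estimator so the clock
composes with sklearn pipelines and model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold, LeaveOneOut
from sklearn.utils.validation import check_is_fitted

from .io import ClockModel, MethylationMatrix

DEFAULT_ADULT_AGE = 1.5   # months; knot of the log-linear transform
DEFAULT_OFFSET = 1.0      # months; shifts the log branch away from t = 0


@dataclass(frozen=True)
class AgeTransform:
    """Calibration function F and its inverse.

    kind="log_linear" uses the piecewise log/linear family above;
    kind="identity" passes ages through unchanged.
    """

    kind: str = "log_linear"
    adult_age: float = DEFAULT_ADULT_AGE
    offset: float = DEFAULT_OFFSET

    def __post_init__(self):
        if self.kind not in ("log_linear", "identity"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "log_linear" and self.adult_age + self.offset <= 0:
            raise ValueError("adult_age + offset must be positive")

    def __call__(self, t):
        return transform_age(t, self)

    def inverse(self, y):
        return inverse_transform_age(y, self)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "adult_age": self.adult_age, "offset": self.offset}

    @classmethod
    def from_dict(cls, d: dict) -> "AgeTransform":
        return cls(kind=d["kind"], adult_age=float(d["adult_age"]), offset=float(d["offset"]))


def transform_age(t, tr: AgeTransform):
    """Map chronological age (months) to the regression scale; F(a) = 0."""
    t = np.asarray(t, dtype=float)
    if tr.kind == "identity":
        return t if t.ndim else float(t)
    a, o = tr.adult_age, tr.offset
    if np.any(t <= -o):
        raise ValueError(f"age must exceed {-o} months for this transform")
    y = np.where(
        t <= a,
        np.log(np.maximum(t + o, np.finfo(float).tiny)) - np.log(a + o),
        (t - a) / (a + o),
    )
    return y if y.ndim else float(y)


def inverse_transform_age(y, tr: AgeTransform):
    """Exact inverse of :func:`transform_age`; defined on all reals."""
    y = np.asarray(y, dtype=float)
    if tr.kind == "identity":
        return y if y.ndim else float(y)
    a, o = tr.adult_age, tr.offset
    t = np.where(y <= 0, (a + o) * np.exp(y) - o, a + y * (a + o))
    return t if t.ndim else float(t)


@dataclass(frozen=True)
class FitConfig:
    """Penalty and cross-validation settings for clock fitting.

    mixing is the ridge<->lasso balance (sklearn l1_ratio); lambda_grid is
    an explicit alpha grid or "auto"; cv_folds an integer, "loo", or "auto"
    (min(10, n) with leave-one-out below 12 samples).
    """

    mixing: float = 0.5
    lambda_grid: object = "auto"
    cv_folds: object = "auto"
    standardize: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError("mixing must lie in [0, 1]")
        if isinstance(self.cv_folds, int) and self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2 or 'loo'")


class EpigeneticClock(BaseEstimator, RegressorMixin):
    """Elastic-net epigenetic clock on transformed age.

    fit(X, y) regresses F(y) on beta values X (samples x loci) with an
    elastic-net penalty, choosing the penalty strength by cross-validated
    MSE on the transformed scale; predict(X) returns F^-1 of the linear
    predictor, i.e. epigenetic age in months.

    Parameters
    ----------
    transform_kind, adult_age, offset : AgeTransform parameters.
    mixing : l1_ratio of the elastic net.
    lambda_grid : explicit penalty grid, or "auto" for the sklearn path.
    cv_folds : int, "loo", or "auto".
    standardize : scale predictors to unit variance during fitting
        (coefficients are stored on the original beta scale).
    seed : seeds CV fold assignment.

    Attributes
    ----------
    intercept_ : float -- b0 on the transformed-age scale.
    coef_ : ndarray (n_features,) -- per-CpG coefficients, beta scale.
    alpha_ : float -- selected penalty strength.
    feature_means_ : ndarray -- training means (imputation at predict time).
    training_info_ : dict -- penalty settings, n, Pearson r / R^2 / MAE on
        the training samples.
    """

    def __init__(self, transform_kind="log_linear", adult_age=DEFAULT_ADULT_AGE,
                 offset=DEFAULT_OFFSET, mixing=0.5, lambda_grid="auto",
                 cv_folds="auto", standardize=True, seed=0):
        self.transform_kind = transform_kind
        self.adult_age = adult_age
        self.offset = offset
        self.mixing = mixing
        self.lambda_grid = lambda_grid
        self.cv_folds = cv_folds
        self.standardize = standardize
        self.seed = seed

    # ------------------------------------------------------------------
    def _transform(self) -> AgeTransform:
        return AgeTransform(self.transform_kind, self.adult_age, self.offset)

    def _cv(self, n: int):
        folds = self.cv_folds
        if folds == "auto":
            folds = "loo" if n < 12 else min(10, n)
        if folds == "loo":
            return LeaveOneOut()
        if folds > n:
            raise ValueError(f"cv_folds={folds} exceeds the {n} training samples")
        return KFold(n_splits=folds, shuffle=True, random_state=self.seed)

    def fit(self, X, y):
        """Fit on beta values X (n_samples, n_loci) and ages y (months)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_loci) aligned with y")
        n = X.shape[0]
        if n < 3:
            raise ValueError("need at least 3 training samples")
        if np.isnan(X).any():
            raise ValueError("training matrix contains missing values; "
                             "drop or impute loci before fitting")
        tr = self._transform()
        z = np.asarray(transform_age(y, tr))
        if np.allclose(z, z[0]):
            raise ValueError("constant response: all training ages identical")

        scale = X.std(axis=0, ddof=0) if self.standardize else np.ones(X.shape[1])
        scale = np.where(scale > 0, scale, 1.0)
        Xs = X / scale

        cv = self._cv(n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter on tiny folds
            grid = 50 if self.lambda_grid == "auto" else np.asarray(self.lambda_grid, dtype=float)
            enet = ElasticNetCV(l1_ratio=self.mixing, cv=cv, alphas=grid,
                                max_iter=50_000, random_state=self.seed)
            enet.fit(Xs, z)

        self.alpha_ = float(enet.alpha_)
        self.coef_ = enet.coef_ / scale          # back to beta scale
        self.intercept_ = float(enet.intercept_)
        self.feature_means_ = X.mean(axis=0)
        self.n_features_in_ = X.shape[1]

        pred = self.predict(X)
        finite = np.std(pred) > 0 and np.std(y) > 0
        r = float(stats.pearsonr(pred, y)[0]) if finite else float("nan")
        sse = float(np.sum((pred - y) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        self.training_info_ = {
            "n_samples": int(n),
            "n_nonzero": int(np.count_nonzero(self.coef_)),
            "mixing": self.mixing,
            "lambda": self.alpha_,
            "standardize": self.standardize,
            "pearson_r": r,
            "r_squared": r * r if np.isfinite(r) else float("nan"),
            "r_squared_sse": 1.0 - sse / sst if sst > 0 else float("nan"),
            "mae_months": float(np.mean(np.abs(pred - y))),
        }
        return self

    def linear_predictor(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            X = np.where(np.isnan(X), self.feature_means_, X)
        return self.intercept_ + X @ self.coef_

    def predict(self, X):
        """Epigenetic age (months) = F^-1 of the linear predictor."""
        return np.asarray(inverse_transform_age(self.linear_predictor(X), self._transform()))


# ---- MethylationMatrix-level wrappers -------------------------------------------


def fit_clock(train: MethylationMatrix, tissue: str,
              tr: AgeTransform | None = None,
              cfg: FitConfig | None = None) -> ClockModel:
    """Fit a tissue-specific clock on a training cohort.

    The matrix is restricted to ``tissue``; loci with any missing value in
    the restricted cohort are excluded from the predictor set.
    """
    tr = tr or AgeTransform()
    cfg = cfg or FitConfig()
    sub = train.restrict_tissue(tissue)
    if len(sub.samples) < 3:
        raise ValueError(f"need >= 3 {tissue} samples, found {len(sub.samples)}")
    complete = ~sub.mask.any(axis=1)
    if not complete.any():
        raise ValueError("every locus has missing values in the training cohort")
    sub = sub.subset_loci(complete)

    est = EpigeneticClock(
        transform_kind=tr.kind, adult_age=tr.adult_age, offset=tr.offset,
        mixing=cfg.mixing, lambda_grid=cfg.lambda_grid, cv_folds=cfg.cv_folds,
        standardize=cfg.standardize, seed=cfg.seed,
    )
    est.fit(sub.values.T, sub.ages)

    ids = sub.locus_ids
    nz = np.flatnonzero(est.coef_)
    return ClockModel(
        tissue=tissue,
        transform=tr.to_dict(),
        intercept=est.intercept_,
        coefficients={ids[i]: float(est.coef_[i]) for i in nz},
        training_means={ids[i]: float(est.feature_means_[i]) for i in nz},
        training_info=est.training_info_,
    )


def predict_dnage(model: ClockModel, m: MethylationMatrix,
                  warn_counter: dict | None = None) -> np.ndarray:
    """Per-sample epigenetic age in months.

    Missing beta values at clock CpGs are imputed with the training mean;
    the number of imputations per sample is recorded in ``warn_counter``
    (sample_id -> count) and surfaced as a warning.
    """
    ids = model.coefficients.keys()
    index = {lid: i for i, lid in enumerate(m.locus_ids)}
    absent = [lid for lid in ids if lid not in index]
    if absent:
        raise ValueError(f"matrix lacks {len(absent)} clock CpG(s): {absent[:5]}...")
    rows = [index[lid] for lid in ids]
    coefs = np.array([model.coefficients[lid] for lid in ids])
    means = np.array([model.training_means.get(lid, np.nan) for lid in ids])

    vals = m.values[rows, :].copy()
    miss = m.mask[rows, :]
    if miss.any():
        if np.isnan(means[miss.any(axis=1)]).any():
            raise ValueError("missing beta at a clock CpG without a stored training mean")
        vals = np.where(miss, means[:, None], vals)
        counts = miss.sum(axis=0)
        for j, c in enumerate(counts):
            if c and warn_counter is not None:
                warn_counter[m.sample_ids[j]] = int(c)
        warnings.warn(
            f"imputed {int(miss.sum())} missing clock-CpG value(s) with training means",
            stacklevel=2,
        )
    tr = AgeTransform.from_dict(model.transform)
    lin = model.intercept + coefs @ vals
    return np.asarray(inverse_transform_age(lin, tr))


def evaluate_clock(model: ClockModel, test: MethylationMatrix) -> dict:
    """Pearson r, R^2 (squared Pearson; SSE variant also emitted) and MAE."""
    if len(test.samples) < 3:
        raise ValueError("need >= 3 test samples with known ages")
    pred = predict_dnage(model, test)
    age = test.ages
    if np.std(pred) == 0 or np.std(age) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(pred, age)[0])
    sst = float(np.sum((age - age.mean()) ** 2))
    return {
        "pearson_r": r,
        "r_squared": r * r if np.isfinite(r) else float("nan"),
        "r_squared_sse": 1.0 - float(np.sum((pred - age) ** 2)) / sst if sst else float("nan"),
        "mae_months": float(np.mean(np.abs(pred - age))),
    }
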