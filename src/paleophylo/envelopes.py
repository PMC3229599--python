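"""Climate envelope models of suitable habitat.

Two families, seven variants in total, are used for model selection:

* **BIOCLIM** rectilinear envelopes — a hyper-box in climate space bounded
  per variable by order statistics of the training climates.  The (0, 100)
  variant uses the absolute minima/maxima; the (5, 95) variant trims climatic
  outliers.
* **Mahalanobis ellipsoids** — mean vector plus sample covariance of the
  training climates; a query point's squared Mahalanobis distance is turned
  into an upper-tail chi-square probability (df = number of variables), and
  the point is suitable when p exceeds a threshold in {0.1 … 0.5}.

Both are scikit-learn style estimators: ``fit(X)`` learns the envelope from
an (n_occurrences × n_variables) climate matrix, ``predict(X)`` returns a
boolean suitability mask.  Rows with missing values are never suitable.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .grid import ClimateGrid, HabitatDistribution

#: Ellipsoid probability thresholds evaluated in model selection.
ELLIPSOID_THRESHOLDS = (0.1, 0.2, 0.3, 0.4, 0.5)


def _validate_matrix(X, n_features: int | None = None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.ndim != 2:
        raise ValueError("climate data must be a 2-D (points x variables) matrix")
    if n_features is not None and X.shape[1] != n_features:
        raise ValueError(f"expected {n_features} variables, got {X.shape[1]}")
    return X


class BioclimEnvelope(BaseEstimator):
    """Rectilinear (BIOCLIM) climate envelope.

    Parameters
    ----------
    percentile_low, percentile_high : float
        Per-variable percentile bounds of the training climates; (0, 100)
        for the absolute min/max variant, (5, 95) to trim outliers.
        Percentiles use linear interpolation between closest ranks.

    Attributes
    ----------
    lower_, upper_ : ndarray of shape (n_variables,)
        Fitted inclusive bounds.
    """

    def __init__(self, percentile_low: float = 5.0, percentile_high: float = 95.0):
        self.percentile_low = percentile_low
        self.percentile_high = percentile_high

    def fit(self, X, y=None) -> "BioclimEnvelope":
        X = _validate_matrix(X)
        if X.shape[0] == 0:
            raise ValueError("cannot fit an envelope on an empty training set")
        if np.any(np.isnan(X)):
            raise ValueError("training climates must not contain missing values")
        if not (0 <= self.percentile_low <= self.percentile_high <= 100):
            raise ValueError("need 0 <= percentile_low <= percentile_high <= 100")
        self.lower_ = np.percentile(X, self.percentile_low, axis=0, method="linear")
        self.upper_ = np.percentile(X, self.percentile_high, axis=0, method="linear")
        self.n_features_in_ = X.shape[1]
        return self

    @classmethod
    def from_bounds(cls, lower, upper, percentile_low: float = 5.0,
                    percentile_high: float = 95.0) -> "BioclimEnvelope":
        """Construct a fitted envelope directly from per-variable bounds."""
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        if lower.shape != upper.shape or lower.ndim != 1:
            raise ValueError("lower/upper must be matching 1-D arrays")
        if np.any(lower > upper):
            raise ValueError("lower bounds must not exceed upper bounds")
        if not (np.all(np.isfinite(lower)) and np.all(np.isfinite(upper))):
            raise ValueError("bounds must be finite")
        env = cls(percentile_low=percentile_low, percentile_high=percentile_high)
        env.lower_ = lower
        env.upper_ = upper
        env.n_features_in_ = len(lower)
        return env

    def predict(self, X) -> np.ndarray:
        """Boolean suitability: inside all inclusive bounds; NaN row → False."""
        X = _validate_matrix(X, getattr(self, "n_features_in_", None))
        with np.errstate(invalid="ignore"):
            ok = (X >= self.lower_) & (X <= self.upper_)
        return np.all(ok, axis=1) & ~np.any(np.isnan(X), axis=1)

    def to_dict(self) -> dict:
        return {"method": "bioclim",
                "percentile_low": self.percentile_low,
                "percentile_high": self.percentile_high,
                "lower": list(map(float, self.lower_)),
                "upper": list(map(float, self.upper_))}

    @classmethod
    def from_dict(cls, d: dict) -> "BioclimEnvelope":
        return cls.from_bounds(d["lower"], d["upper"],
                               d.get("percentile_low", 5.0),
                               d.get("percentile_high", 95.0))


class MahalanobisEnvelope(BaseEstimator):
    """Ellipsoidal climate probability envelope.

    Fits the mean and sample covariance of the training climates; suitability
    of a query point is the chi-square upper-tail probability of its squared
    Mahalanobis distance (df = n_variables) exceeding ``p_threshold``.
    A singular covariance is ridge-regularized on the diagonal.
    """

    def __init__(self, p_threshold: float = 0.1, reg: float = 1e-8):
        self.p_threshold = p_threshold
        self.reg = reg

    def fit(self, X, y=None) -> "MahalanobisEnvelope":
        X = _validate_matrix(X)
        n, k = X.shape
        if n == 0:
            raise ValueError("cannot fit an envelope on an empty training set")
        if np.any(np.isnan(X)):
            raise ValueError("training climates must not contain missing values")
        self.location_ = X.mean(axis=0)
        if n > 1:
            scatter = np.cov(X, rowvar=False, ddof=1).reshape(k, k)
        else:
            scatter = np.zeros((k, k))
        # regularize if (near-)singular so the precision matrix exists
        eigmin = float(np.linalg.eigvalsh(scatter)[0]) if k > 0 else 0.0
        if eigmin <= 0 or n <= k:
            mean_diag = float(np.mean(np.diag(scatter)))
            eps = self.reg * (mean_diag if mean_diag > 0 else 1.0)
            scatter = scatter + eps * np.eye(k)
        self.scatter_ = scatter
        self.precision_ = np.linalg.inv(scatter)
        self.n_features_in_ = k
        return self

    def mahalanobis_sq(self, X) -> np.ndarray:
        X = _validate_matrix(X, self.n_features_in_)
        diff = X - self.location_
        return np.einsum("ij,jk,ik->i", diff, self.precision_, diff)

    def score_samples(self, X) -> np.ndarray:
        """Chi-square upper-tail p of the squared Mahalanobis distance."""
        d2 = self.mahalanobis_sq(X)
        return stats.chi2.sf(d2, df=self.n_features_in_)

    def predict(self, X) -> np.ndarray:
        X = _validate_matrix(X, self.n_features_in_)
        missing = np.any(np.isnan(X), axis=1)
        p = np.where(missing, 0.0, np.nan_to_num(self.score_samples(X), nan=0.0))
        return (p > self.p_threshold) & ~missing

    def to_dict(self) -> dict:
        return {"method": "ellipsoid",
                "p_threshold": self.p_threshold,
                "location": list(map(float, self.location_)),
                "scatter": [list(map(float, row)) for row in self.scatter_]}

    @classmethod
    def from_dict(cls, d: dict) -> "MahalanobisEnvelope":
        env = cls(p_threshold=d.get("p_threshold", 0.1))
        env.location_ = np.asarray(d["location"], dtype=float)
        env.scatter_ = np.asarray(d["scatter"], dtype=float)
        env.precision_ = np.linalg.inv(env.scatter_)
        env.n_features_in_ = len(env.location_)
        return env


# ----------------------------------------------------------------- functions

def fit_bioclim(training, percentile_pair=(5.0, 95.0)) -> BioclimEnvelope:
    lo, hi = percentile_pair
    return BioclimEnvelope(percentile_low=lo, percentile_high=hi).fit(training)


def fit_ellipsoid(training, p_threshold: float = 0.1) -> MahalanobisEnvelope:
    return MahalanobisEnvelope(p_threshold=p_threshold).fit(training)


def envelope_membership(env, x):
    """Suitability of climate vector(s); for ellipsoids also the p-value(s)."""
    suitable = env.predict(x)
    if isinstance(env, MahalanobisEnvelope):
        return suitable, env.score_samples(x)
    return suitable


def project_envelope(env, grid: ClimateGrid, lineage: str,
                     time_kya: float = 0.0) -> HabitatDistribution:
    """Classify every grid point, returning the suitable subset."""
    if grid.values.shape[1] != env.n_features_in_:
        raise ValueError("grid registry size does not match the envelope")
    mask = env.predict(grid.values)
    return HabitatDistribution(
        name=lineage, time_kya=time_kya,
        member_ids=frozenset(int(i) for i in grid.point_ids[mask]),
        grid_ref=grid.label)


def envelope_to_json(env, path, registry_codes=None) -> None:
    d = env.to_dict()
    if registry_codes is not None:
        d["variables"] = list(registry_codes)
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)


def envelope_from_json(path):
    with open(path) as fh:
        d = json.load(fh)
    if d["method"] == "bioclim":
        return BioclimEnvelope.from_dict(d)
    if d["method"] == "ellipsoid":
        return MahalanobisEnvelope.from_dict(d)
    raise ValueError(f"unknown envelope method: {d['method']}")
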