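"""Group Method of Data Handling (GMDH) polynomial network regression.

The GMDH network of Ivakhnenko grows a feed-forward network layer by layer.
Every candidate unit ("neuron") is a bivariate quadratic polynomial

    Z = c1 + c2*xi + c3*xj + c4*xi^2 + c5*xj^2 + c6*xi*xj

fitted by ordinary least squares on a *fit* subset of the training rows and
ranked by its RMSE on a disjoint *selection* subset (the external, or
regularity, criterion).  The best ``width`` units survive; their outputs
become the inputs of the next layer.  Stacking quadratic units realises
Kolmogorov-Gabor polynomials of progressively higher order, while the
external criterion prunes units that merely memorise the fit subset.

The estimator follows the scikit-learn API (``fit`` / ``predict`` /
``get_params``) and composes with sklearn pipelines and model selection.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, check_random_state, validate_data

logger = logging.getLogger(__name__)

# singular values below RCOND * s_max are treated as zero: rank-deficient
# neuron designs get the deterministic minimum-norm solution
RCOND = 1e-10

# a selection score this small (target normalized to [0, 1]) means the layer
# already fits to numerical precision; growing further cannot help
SCORE_FLOOR = 1e-12

__all__ = [
    "NormalizationParams",
    "QuadraticNeuron",
    "GMDHLayer",
    "GMDHRegressor",
    "fit_neuron",
    "neuron_predict",
    "build_layer",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Per-column min-max normalization, invertible and serialisable.

    Columns with ``max == min`` are flagged constant and map to 0, so a
    degenerate feature cannot produce NaNs downstream.
    """

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        mins = np.atleast_1d(np.asarray(self.mins, dtype=float))
        maxs = np.atleast_1d(np.asarray(self.maxs, dtype=float))
        if mins.shape != maxs.shape:
            raise ValueError("mins and maxs must have identical shapes")
        if np.any(maxs < mins):
            raise ValueError("per-column max must be >= min")
        object.__setattr__(self, "mins", mins)
        object.__setattr__(self, "maxs", maxs)

    @classmethod
    def fit(cls, values: np.ndarray) -> "NormalizationParams":
        """Compute column ranges over the provided samples only."""
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValueError("empty dataset")
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[0] < 2:
            raise ValueError("need at least 2 samples to fit normalization")
        if not np.all(np.isfinite(arr)):
            row, col = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(f"non-finite value at row {row}, column {col}")
        return cls(mins=arr.min(axis=0), maxs=arr.max(axis=0))

    @property
    def constant_mask(self) -> np.ndarray:
        return self.maxs == self.mins

    def transform(self, values: np.ndarray) -> np.ndarray:
        arr = np.asarray(values, dtype=float)
        squeeze = arr.ndim == 1
        if squeeze:
            arr = arr[:, None]
        span = np.where(self.constant_mask, 1.0, self.maxs - self.mins)
        out = (arr - self.mins) / span
        out[:, self.constant_mask] = 0.0
        return out[:, 0] if squeeze else out

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        arr = np.asarray(values, dtype=float)
        squeeze = arr.ndim == 1
        if squeeze:
            arr = arr[:, None]
        span = np.where(self.constant_mask, 0.0, self.maxs - self.mins)
        out = arr * span + self.mins
        return out[:, 0] if squeeze else out


@dataclass(frozen=True)
class QuadraticNeuron:
    """One bivariate quadratic unit: an input pair and six coefficients."""

    input_i: int
    input_j: int
    coefficients: tuple[float, ...]
    criterion_score: float = 0.0

    def __post_init__(self) -> None:
        if self.input_i == self.input_j:
            raise ValueError("neuron inputs must be distinct features")
        coeffs = tuple(float(c) for c in self.coefficients)
        if len(coeffs) != 6:
            raise ValueError("a quadratic neuron has exactly six coefficients")
        if not np.isfinite(self.criterion_score) or self.criterion_score < 0:
            raise ValueError("criterion_score must be finite and non-negative")
        object.__setattr__(self, "coefficients", coeffs)

    def predict(self, x_i: np.ndarray, x_j: np.ndarray) -> np.ndarray:
        return neuron_predict(self, x_i, x_j)


@dataclass(frozen=True)
class GMDHLayer:
    """Surviving neurons of one layer, sorted by ascending criterion score."""

    neurons: tuple[QuadraticNeuron, ...]

    def __post_init__(self) -> None:
        neurons = tuple(self.neurons)
        if not neurons:
            raise ValueError("a layer must contain at least one neuron")
        keys = [(n.criterion_score, n.input_i, n.input_j) for n in neurons]
        if keys != sorted(keys):
            raise ValueError("layer neurons must be sorted by (score, i, j)")
        object.__setattr__(self, "neurons", neurons)

    def __len__(self) -> int:
        return len(self.neurons)

    def forward(self, features: np.ndarray) -> np.ndarray:
        """Evaluate every neuron on a feature matrix; one output column each."""
        return np.column_stack(
            [n.predict(features[:, n.input_i], features[:, n.input_j]) for n in self.neurons]
        )


def _design(x_i: np.ndarray, x_j: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(x_i), x_i, x_j, x_i**2, x_j**2, x_i * x_j]
    )


def fit_neuron(x_i, x_j, y) -> np.ndarray:
    """Least-squares coefficients of one quadratic neuron.

    Returns the minimiser of ``sum((y - Z(x_i, x_j))**2)`` over the six
    coefficients; on a rank-deficient design the minimum-norm solution.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (x_i.shape == x_j.shape == y.shape) or x_i.ndim != 1:
        raise ValueError("x_i, x_j and y must be 1-d sequences of equal length")
    if y.size < 6:
        raise ValueError("underdetermined neuron fit: need at least 6 samples")
    if not (np.all(np.isfinite(x_i)) and np.all(np.isfinite(x_j)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite value in neuron fit inputs")
    coeffs, *_ = np.linalg.lstsq(_design(x_i, x_j), y, rcond=RCOND)
    return coeffs


def neuron_predict(neuron: QuadraticNeuron, x_i, x_j) -> np.ndarray:
    """Evaluate Z = c1 + c2*xi + c3*xj + c4*xi^2 + c5*xj^2 + c6*xi*xj."""
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ValueError("x_i and x_j must have the same length")
    c1, c2, c3, c4, c5, c6 = neuron.coefficients
    return c1 + c2 * x_i + c3 * x_j + c4 * x_i**2 + c5 * x_j**2 + c6 * x_i * x_j


def build_layer(features, y, fit_idx, select_idx, width: int) -> GMDHLayer:
    """Fit one candidate neuron per feature pair and keep the ``width`` best.

    Each candidate is fitted on the rows in ``fit_idx`` and scored by its
    RMSE on the disjoint ``select_idx`` rows (the external criterion).
    Candidates that forecast the selection subset poorly -- "dead" neurons --
    are discarded; ties are broken by the lexicographic input pair.
    """
    features = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    if features.ndim != 2 or features.shape[1] < 2:
        raise ValueError("cannot pair features: need a matrix with >= 2 columns")
    if width < 1:
        raise ValueError("layer width must be >= 1")
    fit_idx = np.asarray(fit_idx, dtype=int)
    select_idx = np.asarray(select_idx, dtype=int)
    if fit_idx.size == 0 or select_idx.size == 0:
        raise ValueError("fit and selection subsets must both be non-empty")
    if np.intersect1d(fit_idx, select_idx).size:
        raise ValueError("fit and selection subsets must be disjoint")

    candidates = []
    for i, j in itertools.combinations(range(features.shape[1]), 2):
        coeffs = fit_neuron(features[fit_idx, i], features[fit_idx, j], y[fit_idx])
        resid = y[select_idx] - neuron_predict(
            QuadraticNeuron(i, j, tuple(coeffs)), features[select_idx, i], features[select_idx, j]
        )
        score = float(np.sqrt(np.mean(resid**2)))
        candidates.append(QuadraticNeuron(i, j, tuple(coeffs), criterion_score=score))

    candidates.sort(key=lambda n: (n.criterion_score, n.input_i, n.input_j))
    return GMDHLayer(tuple(candidates[:width]))


class GMDHRegressor(RegressorMixin, BaseEstimator):
    """Self-organising GMDH polynomial network regressor.

    Parameters
    ----------
    width : int, default=4
        Number of neurons retained per layer (the survivors of the external
        criterion).  Capped at the number of candidate pairs of a layer.
    max_layers : int, default=2
        Maximum network depth.  Growth also stops as soon as a new layer's
        best criterion score fails to improve on the previous layer's best.
    inner_fit_fraction : float, default=0.7
        Fraction of the training rows used to fit neuron coefficients; the
        remainder forms the selection subset that scores candidates.
    min_samples : int, default=50
        Minimum number of training rows accepted by :meth:`fit`.
    random_state : int, RandomState instance or None, default=None
        Seeds the internal fit/selection split; fitting is otherwise
        deterministic.

    Attributes
    ----------
    layers_ : tuple of GMDHLayer
        The retained layers, each holding its surviving neurons.
    normalization_x_, normalization_y_ : NormalizationParams
        Min-max ranges learned from the training data; inputs and the target
        are mapped to [0, 1] before fitting and predictions are mapped back.
    output_neuron_ : int
        Index of the best neuron of the final layer (0 after sorting).
    best_scores_ : list of float
        Best criterion score per retained layer (non-increasing).
    """

    def __init__(
        self,
        width: int = 4,
        max_layers: int = 2,
        inner_fit_fraction: float = 0.7,
        min_samples: int = 50,
        random_state=None,
    ):
        self.width = width
        self.max_layers = max_layers
        self.inner_fit_fraction = inner_fit_fraction
        self.min_samples = min_samples
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_features=2, y_numeric=True)
        n = X.shape[0]
        if n < self.min_samples:
            raise ValueError(
                f"GMDH training needs at least {self.min_samples} samples, got {n}"
            )
        if self.width < 1:
            raise ValueError("width must be >= 1")
        if self.max_layers < 1:
            raise ValueError("max_layers must be >= 1")
        if not 0.0 < self.inner_fit_fraction < 1.0:
            raise ValueError("inner_fit_fraction must lie in (0, 1)")
        if np.ptp(y) == 0:
            raise ValueError("degenerate target: y is constant")

        self.normalization_x_ = NormalizationParams.fit(X)
        self.normalization_y_ = NormalizationParams.fit(y)
        Xn = self.normalization_x_.transform(X)
        yn = self.normalization_y_.transform(y)

        rng = check_random_state(self.random_state)
        perm = rng.permutation(n)
        n_fit = int(np.floor(self.inner_fit_fraction * n))
        n_fit = min(max(n_fit, 6), n - 1)  # both subsets stay non-empty
        fit_idx, select_idx = perm[:n_fit], perm[n_fit:]

        layers: list[GMDHLayer] = []
        best_scores: list[float] = []
        features = Xn
        best_prev = np.inf
        for _ in range(self.max_layers):
            if features.shape[1] < 2:
                break
            layer = build_layer(features, yn, fit_idx, select_idx, self.width)
            best = layer.neurons[0].criterion_score
            if best >= best_prev:
                break  # no improvement: discard this layer and stop
            layers.append(layer)
            best_scores.append(best)
            best_prev = best
            if best <= SCORE_FLOOR:
                break  # an effective neuron fits to numerical precision
            features = layer.forward(features)
        # first layer is always an improvement over +inf, so layers is non-empty
        self.layers_ = tuple(layers)
        self.best_scores_ = best_scores
        self.output_neuron_ = 0
        return self

    def _forward(self, Xn: np.ndarray) -> np.ndarray:
        features = Xn
        for layer in self.layers_:
            features = layer.forward(features)
        return features[:, self.output_neuron_]

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        norm = self.normalization_x_
        if np.any(X < norm.mins) or np.any(X > norm.maxs):
            logger.warning(
                "predict called with inputs outside the training range; "
                "the polynomial network extrapolates"
            )
        yn = self._forward(norm.transform(X))
        return self.normalization_y_.inverse_transform(yn)

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.two_d_array = True
        return tags
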