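"""Error criteria and the train/evaluate experiment harness.

Two criteria quantify the gap between reference kerma values X_exp and
network predictions X_pred over N paired samples:

    MRE%  = 100 * (1/N) * sum |(X_exp - X_pred) / X_pred|
    RMSE  = sqrt( (1/N) * sum (X_exp - X_pred)^2 )

Note the unusual but deliberate denominator of the MRE: the *predicted*
value, not the reference one.  That convention is the default here;
``denominator="expected"`` switches to the conventional form.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .gmdh import GMDHRegressor

__all__ = ["EvaluationReport", "mre_percent", "rmse", "run_experiment", "INPUT_COLUMNS"]

INPUT_COLUMNS = ("phi_deg", "theta_deg", "r_mm", "v_kv")


def _paired(expected, predicted) -> tuple[np.ndarray, np.ndarray]:
    expected = np.asarray(expected, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if expected.shape != predicted.shape or expected.ndim != 1:
        raise ValueError("expected and predicted must be 1-d sequences of equal length")
    if expected.size < 1:
        raise ValueError("need at least one sample pair")
    return expected, predicted


def mre_percent(expected, predicted, denominator: str = "predicted") -> float:
    """Mean relative error in percent, |(X_exp - X_pred) / denominator|.

    The absolute value wraps the whole ratio, so the result is non-negative
    even when a prediction undershoots zero.
    """
    expected, predicted = _paired(expected, predicted)
    if denominator not in ("predicted", "expected"):
        raise ValueError("denominator must be 'predicted' or 'expected'")
    denom = predicted if denominator == "predicted" else expected
    if np.any(denom == 0):
        raise ZeroDivisionError("division by zero in relative error")
    return float(100.0 * np.mean(np.abs((expected - predicted) / denom)))


def rmse(expected, predicted) -> float:
    """Root mean square error."""
    expected, predicted = _paired(expected, predicted)
    return float(np.sqrt(np.mean((expected - predicted) ** 2)))


@dataclass(frozen=True)
class EvaluationReport:
    """Error summary of one model on one data subset, in original units."""

    n_samples: int
    mre_percent: float
    rmse: float
    split_seed: int
    subset_label: str  # "train" or "test"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.mre_percent < 0 or self.rmse < 0:
            raise ValueError("error criteria are non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def _report(model, X, y, seed, label) -> EvaluationReport:
    pred = model.predict(X)
    return EvaluationReport(
        n_samples=len(y),
        mre_percent=mre_percent(y, pred),
        rmse=rmse(y, pred),
        split_seed=seed,
        subset_label=label,
    )


def run_experiment(
    dataset: pd.DataFrame,
    *,
    width: int = 4,
    max_layers: int = 2,
    split_fraction: float = 0.7,
    inner_fit_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[GMDHRegressor, EvaluationReport, EvaluationReport]:
    """Shuffle, split, train and score a GMDH network on a kerma dataset.

    Rows are shuffled with the given seed; the first ``floor(split_fraction
    * N)`` rows train the network and the remainder evaluates it (on the
    default 8250-row grid and the default 0.7 fraction that is exactly
    5775 / 2475).  Both reports are computed in original kerma units.  The
    outer shuffle and the network's internal fit/selection split draw from
    independent streams derived from the one seed.
    """
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must lie in (0, 1)")
    missing = [c for c in (*INPUT_COLUMNS, "kerma") if c not in dataset.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")
    n = len(dataset)
    if n < 50:
        raise ValueError(f"experiment needs at least 50 rows, got {n}")

    outer_seed, inner_seed = derive_seeds(seed, 2)
    X = dataset.loc[:, INPUT_COLUMNS].to_numpy(dtype=float)
    y = dataset["kerma"].to_numpy(dtype=float)
    perm = np.random.default_rng(outer_seed).permutation(n)
    n_train = int(np.floor(split_fraction * n))
    train, test = perm[:n_train], perm[n_train:]

    model = GMDHRegressor(
        width=width,
        max_layers=max_layers,
        inner_fit_fraction=inner_fit_fraction,
        random_state=inner_seed,
    ).fit(X[train], y[train])

    return (
        model,
        _report(model, X[train], y[train], seed, "train"),
        _report(model, X[test], y[test], seed, "test"),
    )


def derive_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent sub-seeds (< 2**31) from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]
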