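"""Reading and writing models, datasets and run configuration.

Formats are deliberately plain: datasets are comma-separated CSV with a
mandatory header and dot decimals; models are human-readable JSON whose
floating-point fields round-trip bit-faithfully (shortest-repr encoding);
configuration is YAML or JSON with unknown keys rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gmdh import GMDHLayer, GMDHRegressor, NormalizationParams, QuadraticNeuron
from .surrogate import GridSpec, SurrogateParams

__all__ = [
    "MODEL_SCHEMA_VERSION",
    "TrainingConfig",
    "RunConfig",
    "save_model",
    "load_model",
    "read_dataset",
    "write_dataset",
    "load_config",
]

MODEL_SCHEMA_VERSION = 1

DATASET_COLUMNS = ("phi_deg", "theta_deg", "r_mm", "v_kv", "kerma")
QUERY_COLUMNS = DATASET_COLUMNS[:4]

#: 17 significant digits: enough to reproduce any float64 exactly
_FLOAT_FMT = "%.17g"


def save_model(model: GMDHRegressor, path) -> None:
    """Serialise a fitted GMDH network to JSON."""
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "n_raw_inputs": int(model.n_features_in_),
        "normalization": {
            "x_min": list(model.normalization_x_.mins),
            "x_max": list(model.normalization_x_.maxs),
            "y_min": list(model.normalization_y_.mins),
            "y_max": list(model.normalization_y_.maxs),
        },
        "layers": [
            [
                {
                    "input_i": n.input_i,
                    "input_j": n.input_j,
                    "coefficients": list(n.coefficients),
                    "criterion_score": n.criterion_score,
                }
                for n in layer.neurons
            ]
            for layer in model.layers_
        ],
        "output_neuron": model.output_neuron_,
        "params": model.get_params(),
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_model(path) -> GMDHRegressor:
    """Reconstruct a fitted GMDH network from its JSON file."""
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"model schema version {version!r} is not supported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    model = GMDHRegressor(**doc.get("params", {}))
    norm = doc["normalization"]
    model.normalization_x_ = NormalizationParams(
        np.asarray(norm["x_min"], dtype=float), np.asarray(norm["x_max"], dtype=float)
    )
    model.normalization_y_ = NormalizationParams(
        np.asarray(norm["y_min"], dtype=float), np.asarray(norm["y_max"], dtype=float)
    )
    model.layers_ = tuple(
        GMDHLayer(
            tuple(
                QuadraticNeuron(
                    n["input_i"],
                    n["input_j"],
                    tuple(n["coefficients"]),
                    criterion_score=n["criterion_score"],
                )
                for n in layer
            )
        )
        for layer in doc["layers"]
    )
    model.output_neuron_ = int(doc["output_neuron"])
    model.n_features_in_ = int(doc["n_raw_inputs"])
    model.best_scores_ = [layer.neurons[0].criterion_score for layer in model.layers_]
    return model


def read_dataset(path, require_kerma: bool = True) -> pd.DataFrame:
    """Read a kerma dataset (or query) CSV with cell-level validation.

    Malformed numeric cells are reported with their 1-based file line
    number; missing columns are reported by name.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    required = DATASET_COLUMNS if require_kerma else QUERY_COLUMNS
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    out = {}
    for col in frame.columns:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.isna() & frame[col].notna()
        if bad.any():
            # +2: one for the header line, one for 1-based numbering
            line = int(bad.idxmax()) + 2
            raise ValueError(
                f"{path.name}: non-numeric value {frame[col][bad.idxmax()]!r} "
                f"in column '{col}' at line {line}"
            )
        if values.isna().any():
            line = int(values.isna().idxmax()) + 2
            raise ValueError(f"{path.name}: empty cell in column '{col}' at line {line}")
        # numpy's string->float64 conversion is correctly rounded, so a
        # %.17g write followed by a read reproduces values bit-for-bit
        out[col] = frame[col].to_numpy(dtype=np.float64)
    return pd.DataFrame(out)


def write_dataset(frame: pd.DataFrame, path) -> None:
    """Write a dataset CSV preserving float64 values exactly."""
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


@dataclass(frozen=True)
class TrainingConfig:
    width: int = 4
    max_layers: int = 2
    inner_fit_fraction: float = 0.7


@dataclass(frozen=True)
class RunConfig:
    """Merged run configuration: grid, surrogate, training and split."""

    grid: GridSpec = field(default_factory=GridSpec)
    surrogate: SurrogateParams = field(default_factory=SurrogateParams)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    split_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "grid": {
                "tangent_angles_deg": list(self.grid.tangent_angles_deg),
                "polar_angles_deg": list(self.grid.polar_angles_deg),
                "distances_mm": list(self.grid.distances_mm),
                "voltages_kv": list(self.grid.voltages_kv),
            },
            "surrogate": {
                "k_ref": self.surrogate.k_ref,
                "r_ref_mm": self.surrogate.r_ref_mm,
                "p_volt": self.surrogate.p_volt,
                "heel_phis_deg": list(self.surrogate.heel_phis_deg),
                "heel_knots": list(self.surrogate.heel_knots),
                "noise_sigma": self.surrogate.noise_sigma,
            },
            "training": {
                "width": self.training.width,
                "max_layers": self.training.max_layers,
                "inner_fit_fraction": self.training.inner_fit_fraction,
            },
            "split_fraction": self.split_fraction,
            "seed": self.seed,
        }


def _build_section(cls, data: dict, section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in '{section}': {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**coerced)


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML/JSON config file and apply keyword overrides.

    Precedence: explicit overrides > file values > built-in defaults.
    Unknown keys anywhere are rejected with the offending names.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
    top_allowed = {"grid", "surrogate", "training", "split_fraction", "seed"}
    unknown = set(data) - top_allowed
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key, value in overrides.items():
        if value is None:
            continue
        if key in ("split_fraction", "seed"):
            data[key] = value
        else:
            section, _, name = key.partition("__")
            data.setdefault(section, {})
            data[section] = dict(data[section])
            data[section][name] = value
    return RunConfig(
        grid=_build_section(GridSpec, data.get("grid", {}), "grid"),
        surrogate=_build_section(SurrogateParams, data.get("surrogate", {}), "surrogate"),
        training=_build_section(TrainingConfig, data.get("training", {}), "training"),
        split_fraction=data.get("split_fraction", 0.7),
        seed=data.get("seed", 0),
    )
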