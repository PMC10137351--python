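"""Analytic surrogate for the air-kerma field of a diagnostic X-ray tube.

The surrogate factorises the noiseless air kerma at a field position
(tangent angle phi, polar angle theta, distance r) and tube voltage V as

    K(phi, theta, r, V) = k_ref * h(phi) * (r_ref / r)**2 * (V / 40)**p

where ``h`` is the anode heel-effect profile (piecewise linear through
knots anchored to the packaged reference table, h(0) = 1, strictly
decreasing toward the anode side), the inverse-square law governs distance,
and a fitted power law governs tube voltage.  The polar angle has no effect:
the beam is treated as azimuthally symmetric, which the reference data
cannot distinguish because polar angle and distance co-vary in it.

Monte-Carlo-like statistical scatter is emulated as multiplicative Gaussian
noise truncated at +/-3 sigma, with sigma at most 4% by default, matching
the uncertainty cap of the transport calculations the surrogate stands in
for.  Kerma is handled throughout in the reference table's relative units
(values of order 1e-5); no absolute gray calibration is attempted.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "FieldPoint",
    "GridSpec",
    "SurrogateParams",
    "heel_factor",
    "kerma_value",
    "generate_grid",
    "generate_dataset",
    "load_table1_fixture",
    "TABLE1_SHA256",
]

#: sha256 of the packaged reference-table fixture, verified on load
TABLE1_SHA256 = "e20c5813bd03354c4d60afbc218c8ba094074f971cb2b0b86d5ad9514fe5ab3e"

PHI_MAX_DEG = 20.0
#: minimum heel factor: keeps extrapolated kerma positive at the cone edge
HEEL_FLOOR = 0.005


@dataclass(frozen=True)
class FieldPoint:
    """A detector position in the conical beam (spherical coordinates)."""

    phi_deg: float   # tangent (heel-direction) angle, 0..20 degrees
    theta_deg: float  # polar (azimuthal) angle, 0..360 degrees
    r_mm: float      # source-detector distance, millimetres

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi_deg <= PHI_MAX_DEG:
            raise ValueError(
                f"phi_deg={self.phi_deg} outside modelled cone [0, {PHI_MAX_DEG}]"
            )
        if not 0.0 <= self.theta_deg <= 360.0:
            raise ValueError(f"theta_deg={self.theta_deg} outside [0, 360]")
        if self.r_mm <= 0:
            raise ValueError("r_mm must be positive")


@dataclass(frozen=True)
class GridSpec:
    """Detector grid: 11 tangent angles x 25 polar angles x 5 distances,
    evaluated at 6 tube voltages (1375 points per voltage, 8250 in all)."""

    tangent_angles_deg: tuple[float, ...] = tuple(float(p) for p in range(0, 22, 2))
    polar_angles_deg: tuple[float, ...] = tuple(float(t) for t in range(0, 375, 15))
    distances_mm: tuple[float, ...] = (250.0, 500.0, 750.0, 1000.0, 1250.0)
    voltages_kv: tuple[float, ...] = (40.0, 60.0, 80.0, 100.0, 120.0, 140.0)

    def __post_init__(self) -> None:
        for name in ("tangent_angles_deg", "polar_angles_deg", "distances_mm", "voltages_kv"):
            values = getattr(self, name)
            if len(values) == 0:
                raise ValueError(f"{name} must be non-empty")
            object.__setattr__(self, name, tuple(float(v) for v in values))

    @property
    def points_per_voltage(self) -> int:
        return (
            len(self.tangent_angles_deg)
            * len(self.polar_angles_deg)
            * len(self.distances_mm)
        )

    @property
    def n_samples(self) -> int:
        return self.points_per_voltage * len(self.voltages_kv)


def load_table1_fixture() -> pd.DataFrame:
    """Load the packaged reference table of simulated and predicted kerma.

    Returns a DataFrame with columns ``phi_deg, theta_deg, r_mm, v_kv,
    kerma, kerma_predicted`` (kerma in the table's relative units, i.e. the
    printed numbers times 1e-5).  The file's checksum is verified so a
    corrupted installation fails loudly.
    """
    ref = resources.files("airkerma").joinpath("data/table1.csv")
    try:
        raw = ref.read_bytes()
    except FileNotFoundError as exc:
        raise FileNotFoundError(
            "reference-table fixture data/table1.csv is missing from the "
            "installed package"
        ) from exc
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE1_SHA256:
        raise ValueError(
            f"reference-table fixture is corrupted: sha256 {digest} != "
            f"expected {TABLE1_SHA256}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), float_precision="round_trip")


@lru_cache(maxsize=1)
def _anchor_constants() -> tuple[float, tuple[float, ...], tuple[float, ...], float]:
    """Heel knots, their angles, the anchor kerma and the voltage exponent,
    all derived once from the packaged reference table.

    * Heel knots: the (theta=0, r=250 mm, V=40 kV) block, normalised to the
      phi=0 value; the block stops at phi=18, so the phi=20 knot is linearly
      extrapolated from the last two and floored at HEEL_FLOOR.
    * Voltage exponent: least-squares slope of log(kerma) against
      log(voltage) over the six anchor-point rows (phi=0, theta=0, r=250).
    """
    table = load_table1_fixture()
    block = table[
        (table.theta_deg == 0) & (table.r_mm == 250) & (table.v_kv == 40)
    ].sort_values("phi_deg")
    phis = block.phi_deg.to_numpy(dtype=float)
    k_ref = float(block.kerma.iloc[0])
    knots = (block.kerma / k_ref).to_numpy(dtype=float)
    if phis[-1] < PHI_MAX_DEG:  # extrapolate the missing cone-edge knot
        edge = max(2 * knots[-1] - knots[-2], HEEL_FLOOR)
        phis = np.append(phis, PHI_MAX_DEG)
        knots = np.append(knots, edge)

    anchor = table[
        (table.phi_deg == 0) & (table.theta_deg == 0) & (table.r_mm == 250)
    ].sort_values("v_kv")
    slope = np.polyfit(
        np.log(anchor.v_kv.to_numpy(dtype=float) / 40.0),
        np.log(anchor.kerma.to_numpy(dtype=float) / k_ref),
        1,
    )[0]
    return k_ref, tuple(phis), tuple(knots), float(slope)


def _default_k_ref() -> float:
    return _anchor_constants()[0]


def _default_heel_phis() -> tuple[float, ...]:
    return _anchor_constants()[1]


def _default_heel_knots() -> tuple[float, ...]:
    return _anchor_constants()[2]


def _default_p_volt() -> float:
    return _anchor_constants()[3]


@dataclass(frozen=True)
class SurrogateParams:
    """Constants of the analytic kerma model.

    Defaults are anchored to the packaged reference table: ``k_ref`` is the
    kerma at (phi=0, theta=0, r=250 mm, V=40 kV); the heel profile and the
    voltage exponent are fitted from the table once at first use.
    """

    k_ref: float = field(default_factory=_default_k_ref)
    r_ref_mm: float = 250.0
    p_volt: float = field(default_factory=_default_p_volt)
    heel_phis_deg: tuple[float, ...] = field(default_factory=_default_heel_phis)
    heel_knots: tuple[float, ...] = field(default_factory=_default_heel_knots)
    noise_sigma: float = 0.04

    def __post_init__(self) -> None:
        knots = np.asarray(self.heel_knots, dtype=float)
        phis = np.asarray(self.heel_phis_deg, dtype=float)
        if knots.shape != phis.shape or knots.ndim != 1 or knots.size < 2:
            raise ValueError("heel profile needs matching angle/knot sequences")
        if knots[0] != 1.0:
            raise ValueError("heel profile must equal 1 at phi = 0")
        if not np.all(np.diff(knots) < 0):
            raise ValueError("heel knots must be strictly decreasing in phi")
        if not np.all(np.diff(phis) > 0):
            raise ValueError("heel knot angles must be strictly increasing")
        if not 0.0 <= self.noise_sigma <= 0.04:
            raise ValueError("noise_sigma must lie in [0, 0.04]")
        if self.k_ref <= 0 or self.r_ref_mm <= 0:
            raise ValueError("k_ref and r_ref_mm must be positive")


def heel_factor(phi_deg, params: SurrogateParams | None = None):
    """Anode heel-effect attenuation factor in (0, 1].

    Piecewise-linear interpolation through the heel knots; equals 1 on the
    central axis and decreases strictly toward the anode side of the beam.
    Accepts a scalar or an array of tangent angles in degrees.
    """
    params = params if params is not None else SurrogateParams()
    phi = np.asarray(phi_deg, dtype=float)
    lo, hi = params.heel_phis_deg[0], params.heel_phis_deg[-1]
    if np.any(phi < lo) or np.any(phi > hi):
        raise ValueError(f"tangent angle outside modelled cone [{lo}, {hi}] degrees")
    out = np.interp(phi, params.heel_phis_deg, params.heel_knots)
    return float(out) if np.isscalar(phi_deg) else out


def _kerma_noiseless(phi_deg, r_mm, v_kv, params: SurrogateParams):
    return (
        params.k_ref
        * heel_factor(phi_deg, params)
        * (params.r_ref_mm / np.asarray(r_mm, dtype=float)) ** 2
        * (np.asarray(v_kv, dtype=float) / 40.0) ** params.p_volt
    )


def kerma_value(
    point: FieldPoint,
    v_kv: float,
    params: SurrogateParams | None = None,
    noise_seed: int | None = None,
) -> float:
    """Air kerma at one field point (relative units of the reference table).

    The polar angle of ``point`` is accepted but has no effect (azimuthal
    symmetry).  With ``noise_seed`` set, a single multiplicative noise draw
    ``(1 + eps)`` with ``eps ~ Normal(0, noise_sigma)`` truncated at
    three sigma is applied.
    """
    params = params if params is not None else SurrogateParams()
    if v_kv <= 0:
        raise ValueError("tube voltage must be positive")
    value = float(_kerma_noiseless(point.phi_deg, point.r_mm, v_kv, params))
    if noise_seed is not None:
        eps = _truncated_noise(np.random.default_rng(noise_seed), 1, params.noise_sigma)[0]
        value *= 1.0 + eps
    return value


def _truncated_noise(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    if sigma == 0:
        return np.zeros(n)
    eps = rng.normal(0.0, sigma, size=n)
    return np.clip(eps, -3.0 * sigma, 3.0 * sigma)


def generate_grid(spec: GridSpec | None = None) -> pd.DataFrame:
    """Cartesian detector grid as a DataFrame (no kerma column).

    Row order is deterministic: voltage slowest, then distance, polar angle,
    and tangent angle fastest, each ascending as given in the spec.
    """
    spec = spec if spec is not None else GridSpec()
    v, r, theta, phi = np.meshgrid(
        spec.voltages_kv,
        spec.distances_mm,
        spec.polar_angles_deg,
        spec.tangent_angles_deg,
        indexing="ij",
    )
    return pd.DataFrame(
        {
            "phi_deg": phi.ravel(),
            "theta_deg": theta.ravel(),
            "r_mm": r.ravel(),
            "v_kv": v.ravel(),
        }
    )


def generate_dataset(
    spec: GridSpec | None = None,
    params: SurrogateParams | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Kerma samples over the full grid, with seeded multiplicative noise.

    With ``params.noise_sigma == 0`` (or ``seed=None`` and sigma 0) every
    value equals the closed-form noiseless kerma; the same seed always
    reproduces the same dataset.
    """
    spec = spec if spec is not None else GridSpec()
    params = params if params is not None else SurrogateParams()
    grid = generate_grid(spec)
    kerma = _kerma_noiseless(
        grid.phi_deg.to_numpy(), grid.r_mm.to_numpy(), grid.v_kv.to_numpy(), params
    )
    rng = np.random.default_rng(seed)
    kerma = kerma * (1.0 + _truncated_noise(rng, len(grid), params.noise_sigma))
    grid["kerma"] = kerma
    return grid
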