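"""Parametric effect sweeps and pore-array geometry.

Response curves of predicted pore diameter against voltage or temperature at
otherwise fixed conditions, a benchmark of the multivariate surrogate
against the empirical 1.29 nm/V rule for oxalic acid, the pore/interpore
regression, hexagonal-packing porosity, and drug-loading capacity of the
pore volume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import FeatureMatrix, apply_encoding
from .regressors import evaluate, predict

__all__ = [
    "SweepResult", "predict_conditions", "voltage_response",
    "temperature_sensitivity", "empirical_rule", "rule_benchmark",
    "pore_interpore_regression", "hexagonal_porosity", "loading_capacity",
    "HEX_POROSITY_LIMIT",
]

#: Close-packing bound pi / (2 sqrt(3)) for a hexagonal pore array.
HEX_POROSITY_LIMIT = math.pi / (2.0 * math.sqrt(3.0))

# default sweep fixed conditions: chilled electrolyte, 1 h anodization
DEFAULT_TEMPERATURE_C = 10.0
DEFAULT_TIME_MIN = 60.0


@dataclass(frozen=True)
class SweepResult:
    parameter: str
    grid: np.ndarray
    predictions: np.ndarray  # nm
    slope: float  # nm per unit of the swept parameter (mean finite difference)
    electrolyte: str
    fixed: dict


def predict_conditions(model, fm: FeatureMatrix, electrolyte: str,
                       voltage, temperature, time_min) -> np.ndarray:
    """Predict pore diameter for raw conditions via the encoding round-trip."""
    v, T, t = np.broadcast_arrays(
        np.atleast_1d(np.asarray(voltage, dtype=float)),
        np.asarray(temperature, dtype=float),
        np.asarray(time_min, dtype=float))
    conditions = pd.DataFrame({
        "electrolyte": electrolyte,
        "voltage_V": v,
        "temperature_C": T,
        "time_min": t,
    })
    return predict(model, apply_encoding(fm, conditions))


def _sweep(model, fm, electrolyte, grid, parameter, fixed):
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with >= 2 points")
    raw = fm.raw_frame()
    col = {"voltage": "voltage_V", "temperature": "temperature_C"}[parameter]
    support = raw[col].min(), raw[col].max()
    if grid.min() < support[0] or grid.max() > support[1]:
        warnings.warn(
            f"{parameter} grid extends beyond the training support "
            f"[{support[0]:.3g}, {support[1]:.3g}]; predictions there are "
            "extrapolations", stacklevel=3)
    kwargs = dict(fixed)
    kwargs[parameter] = grid
    pred = predict_conditions(
        model, fm, electrolyte,
        voltage=kwargs["voltage"], temperature=kwargs["temperature"],
        time_min=kwargs["time_min"])
    slope = float(np.mean(np.diff(pred) / np.diff(grid)))
    return SweepResult(parameter=parameter, grid=grid, predictions=pred,
                       slope=slope, electrolyte=electrolyte,
                       fixed={k: v for k, v in fixed.items() if k != parameter})


def voltage_response(model, fm: FeatureMatrix, electrolyte: str, v_grid,
                     temperature: float = DEFAULT_TEMPERATURE_C,
                     time_min: float = DEFAULT_TIME_MIN) -> SweepResult:
    """Predicted diameter over a voltage grid at fixed temperature and time."""
    return _sweep(model, fm, electrolyte, v_grid, "voltage",
                  {"voltage": None, "temperature": temperature,
                   "time_min": time_min})


def temperature_sensitivity(model, fm: FeatureMatrix, electrolyte: str,
                            t_grid, voltage: float,
                            time_min: float = DEFAULT_TIME_MIN) -> SweepResult:
    """Predicted diameter over a temperature grid; slope in nm/°C."""
    return _sweep(model, fm, electrolyte, t_grid, "temperature",
                  {"voltage": voltage, "temperature": None,
                   "time_min": time_min})


def empirical_rule(voltage) -> np.ndarray | float:
    """The 1.29 nm/V proportionality rule of thumb for oxalic-acid pores."""
    v = np.asarray(voltage, dtype=float)
    if np.any(v < 0):
        raise ValueError("voltage must be non-negative")
    out = 1.29 * v
    return float(out) if out.ndim == 0 else out


def rule_benchmark(model, fm: FeatureMatrix, oxalic_df: pd.DataFrame) -> dict:
    """RMSE of the surrogate vs the 1.29 nm/V rule on the same oxalic records."""
    if len(oxalic_df) == 0:
        raise ValueError("empty oxalic subset")
    if set(oxalic_df["electrolyte"]) != {"H2C2O4"}:
        raise ValueError("subset must contain only oxalic-acid records")
    y = oxalic_df["pore_diameter_nm"].to_numpy(dtype=float)
    pred_model = predict(model, apply_encoding(fm, oxalic_df))
    pred_rule = empirical_rule(oxalic_df["voltage_V"].to_numpy(dtype=float))
    return {
        "rmse_model": evaluate(y, pred_model).rmse,
        "rmse_rule": evaluate(y, np.atleast_1d(pred_rule)).rmse,
        "n": len(y),
    }


def pore_interpore_regression(df: pd.DataFrame) -> dict:
    """OLS of pore diameter on interpore distance over complete pairs."""
    pairs = df[["interpore_distance_nm", "pore_diameter_nm"]].dropna()
    if len(pairs) < 3:
        raise ValueError("need at least 3 records with both measurements")
    fit = stats.linregress(pairs["interpore_distance_nm"],
                           pairs["pore_diameter_nm"])
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "r2": float(fit.rvalue ** 2), "n": len(pairs)}


def hexagonal_porosity(pore_diameter_nm: float, interpore_nm: float) -> float:
    """Areal porosity of a hexagonal pore array: (pi/(2 sqrt 3))·(d/D)²."""
    if pore_diameter_nm < 0:
        raise ValueError("pore diameter must be non-negative")
    if interpore_nm <= 0:
        raise ValueError("interpore distance must be positive")
    if pore_diameter_nm >= interpore_nm:
        raise ValueError("pore diameter must be below the interpore distance "
                         "(pores would merge)")
    return HEX_POROSITY_LIMIT * (pore_diameter_nm / interpore_nm) ** 2


def loading_capacity(pore_diameter_nm: float, interpore_nm: float,
                     depth_um: float, c0_mg_per_ml: float) -> float:
    """Drug load of completely filled pores, in µg/cm².

    porosity × depth × C0, with depth in µm (1e-4 cm) and C0 in mg/mL
    (= mg/cm³); 1 mg = 1000 µg.
    """
    if depth_um < 0:
        raise ValueError("depth must be non-negative")
    if c0_mg_per_ml < 0:
        raise ValueError("concentration must be non-negative")
    eps = hexagonal_porosity(pore_diameter_nm, interpore_nm)
    return eps * (depth_um * 1e-4) * c0_mg_per_ml * 1000.0
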