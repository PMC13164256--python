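"""Anodization dataset schema, I/O and preprocessing.

The canonical in-memory container is a :class:`pandas.DataFrame` with one row
per anodization experiment and the column schema in :data:`SCHEMA_COLUMNS`.
Preprocessing follows the conventions of small-tabular-data surrogate
modelling: electrolyte name canonicalization, case-wise deletion of
incomplete records, one-hot (or compact integer) encoding of the electrolyte
category, and z-standardization of the continuous inputs with scaler
parameters fitted on training rows only.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical electrolyte codes, in fixed order (used for indicator columns
#: and for the compact integer coding).
ELECTROLYTES = ("H2SO4", "H2C2O4", "H3PO4")

#: Reference level dropped from the MLR design under one-hot encoding.
REFERENCE_LEVEL = "H2SO4"

#: Exact CSV header, one column per record field.
SCHEMA_COLUMNS = [
    "source_id",
    "year",
    "electrolyte",
    "concentration_value",
    "concentration_unit",
    "voltage_V",
    "temperature_C",
    "time_min",
    "current_density_mA_cm2",
    "pore_diameter_nm",
    "interpore_distance_nm",
    "pore_depth_um",
    "technique",
]

NUMERIC_COLUMNS = [
    "year",
    "concentration_value",
    "voltage_V",
    "temperature_C",
    "time_min",
    "current_density_mA_cm2",
    "pore_diameter_nm",
    "interpore_distance_nm",
    "pore_depth_um",
]

#: Continuous model inputs, in design-matrix order.
CONTINUOUS_FEATURES = ["voltage_V", "temperature_C", "time_min"]

#: Friendly field names accepted by :func:`complete_cases`.
FIELD_COLUMNS = {
    "voltage": "voltage_V",
    "temperature": "temperature_C",
    "time": "time_min",
    "electrolyte": "electrolyte",
    "pore_diameter": "pore_diameter_nm",
    "interpore_distance": "interpore_distance_nm",
    "pore_depth": "pore_depth_um",
    "concentration": "concentration_value",
    "current_density": "current_density_mA_cm2",
    "year": "year",
    "technique": "technique",
}

#: Default complete-case requirement: the four modelled inputs.
MODEL_FIELDS = ("voltage", "temperature", "time", "electrolyte")

# physically plausible pore diameters for anodic alumina, nm
DIAMETER_BOUNDS = (5.0, 350.0)


@dataclass(frozen=True)
class AnodizationRecord:
    """One anodization experiment; any field except pore_diameter_nm may be missing."""

    source_id: str
    pore_diameter_nm: float
    electrolyte: str | None = None
    year: float | None = None
    concentration_value: float | None = None
    concentration_unit: str | None = None
    voltage_V: float | None = None
    temperature_C: float | None = None
    time_min: float | None = None
    current_density_mA_cm2: float | None = None
    interpore_distance_nm: float | None = None
    pore_depth_um: float | None = None
    technique: str | None = None


def records_to_frame(records) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in SCHEMA_COLUMNS} for r in records]
    df = pd.DataFrame(rows, columns=SCHEMA_COLUMNS)
    for c in NUMERIC_COLUMNS:
        df[c] = pd.to_numeric(df[c])
    return df


_CANONICAL = {
    "h2so4": "H2SO4",
    "sulphuricacid": "H2SO4",
    "sulfuricacid": "H2SO4",
    "sulphuric": "H2SO4",
    "sulfuric": "H2SO4",
    "h2c2o4": "H2C2O4",
    "oxalicacid": "H2C2O4",
    "oxalic": "H2C2O4",
    "h3po4": "H3PO4",
    "phosphoricacid": "H3PO4",
    "phosphoric": "H3PO4",
}


def canonicalize_electrolyte(raw: str) -> str:
    """Map spelling/formatting variants of an electrolyte name to its code.

    "sulphuric acid", "Sulfuric Acid", "H_2_SO_4_" etc. all map to
    ``"H2SO4"``. Names outside the three modelled acids are passed through
    flagged as ``"unknown(<raw>)"`` rather than raising — unknowns are
    excluded downstream by :func:`complete_cases`.
    """
    key = re.sub(r"[\s_\-\.,()]", "", str(raw)).lower()
    # strip unicode subscripts
    key = key.translate(str.maketrans("₀₁₂₃₄₅₆₇₈₉", "0123456789"))
    if key in _CANONICAL:
        return _CANONICAL[key]
    return f"unknown({raw})"


def is_known_electrolyte(value) -> bool:
    return value in ELECTROLYTES


def canonicalize_dataset(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the electrolyte column canonicalized."""
    out = df.copy()
    mask = out["electrolyte"].notna()
    out.loc[mask, "electrolyte"] = out.loc[mask, "electrolyte"].map(
        canonicalize_electrolyte
    )
    return out


def complete_cases(df: pd.DataFrame, required_fields=MODEL_FIELDS) -> pd.DataFrame:
    """Case-wise deletion: keep exactly the rows complete in required_fields.

    Field names may be friendly (``"voltage"``) or schema column names.
    The electrolyte field additionally requires a *known* canonical code.
    Row order is preserved; the kept/total count is logged.
    """
    keep = pd.Series(True, index=df.index)
    for f in required_fields:
        col = FIELD_COLUMNS.get(f, f)
        if col not in df.columns:
            raise KeyError(f"unknown field {f!r}; valid fields: {sorted(FIELD_COLUMNS)}")
        keep &= df[col].notna()
        if col == "electrolyte":
            keep &= df[col].isin(ELECTROLYTES)
    out = df.loc[keep]
    logger.info("complete_cases: kept %d of %d records", len(out), len(df))
    if len(out) == 0 and len(df) > 0:
        warnings.warn("complete_cases produced an empty dataset", stacklevel=2)
    return out


def summarize(df: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter min/max/mean/SD/N over non-missing values.

    SD uses the population convention (divisor N), consistent with the
    cross-validation aggregation convention used throughout the package.
    All-missing columns get N=0 and blank (NaN) statistics.
    """
    if len(df) == 0:
        raise ValueError("summarize requires at least one record")
    rows = []
    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        vals = df[col].dropna().to_numpy(dtype=float)
        n = len(vals)
        if n == 0:
            rows.append({"parameter": col, "min": np.nan, "max": np.nan,
                         "mean": np.nan, "sd": np.nan, "n": 0})
        else:
            rows.append({
                "parameter": col,
                "min": vals.min(),
                "max": vals.max(),
                "mean": vals.mean(),
                "sd": float(np.std(vals)),  # population SD
                "n": n,
            })
    return pd.DataFrame(rows).set_index("parameter")


@dataclass(frozen=True)
class ColumnInfo:
    """Provenance of one design-matrix column."""

    name: str
    source: str  # one of voltage / temperature / time / electrolyte_type
    level: str | None = None  # electrolyte level for indicator columns
    standardized: bool = False


@dataclass
class FeatureMatrix:
    """Encoded, standardized design matrix with its inverse-transform metadata."""

    X: np.ndarray
    y: np.ndarray
    column_map: list[ColumnInfo]
    scaler: dict[str, tuple[float, float]]  # column name -> (mean, sd)
    mode: str  # "onehot" | "compact"

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.column_map]

    def destandardize(self, name: str, values: np.ndarray) -> np.ndarray:
        mean, sd = self.scaler[name]
        return np.asarray(values) * sd + mean

    def raw_frame(self) -> pd.DataFrame:
        """Recover raw inputs (and y) from the encoded matrix — exact inverse."""
        out = {}
        idx = {c.name: i for i, c in enumerate(self.column_map)}
        for feat in CONTINUOUS_FEATURES:
            out[feat] = self.destandardize(feat, self.X[:, idx[feat]])
        if self.mode == "onehot":
            block = np.stack(
                [self.X[:, idx[f"elec_{e}"]] for e in ELECTROLYTES], axis=1
            )
            out["electrolyte"] = [ELECTROLYTES[i] for i in block.argmax(axis=1)]
        else:
            codes = np.rint(
                self.destandardize("elec_code", self.X[:, idx["elec_code"]])
            ).astype(int)
            out["electrolyte"] = [ELECTROLYTES[i] for i in codes]
        out["pore_diameter_nm"] = self.y
        return pd.DataFrame(out)


def _fit_scaler(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values))  # population SD
    if sd == 0.0:
        warnings.warn("constant column; standardization leaves it at zero",
                      stacklevel=3)
        sd = 1.0
    return mean, sd


def _build_matrix(df, mode, scaler, column_map=None):
    cols, infos = [], []
    for feat in CONTINUOUS_FEATURES:
        mean, sd = scaler[feat]
        cols.append((df[feat].to_numpy(dtype=float) - mean) / sd)
        infos.append(ColumnInfo(feat, feat.split("_")[0], standardized=True))
    elec = df["electrolyte"].to_numpy()
    if mode == "onehot":
        for e in ELECTROLYTES:
            cols.append((elec == e).astype(float))
            infos.append(ColumnInfo(f"elec_{e}", "electrolyte_type", level=e))
    else:
        codes = np.array([ELECTROLYTES.index(e) for e in elec], dtype=float)
        mean, sd = scaler["elec_code"]
        cols.append((codes - mean) / sd)
        infos.append(ColumnInfo("elec_code", "electrolyte_type", standardized=True))
    X = np.stack(cols, axis=1)
    y = df["pore_diameter_nm"].to_numpy(dtype=float)
    return FeatureMatrix(X=X, y=y, column_map=infos, scaler=dict(scaler), mode=mode)


def encode(train_df: pd.DataFrame, apply_df: pd.DataFrame | None = None,
           mode: str = "onehot"):
    """Encode complete-case records into a standardized design matrix.

    mode="onehot": 3 electrolyte indicator columns (all levels retained,
    not standardized) plus 3 standardized continuous columns (6 total).
    mode="compact": one integer-coded electrolyte column, standardized like
    the continuous inputs (4 columns total, matching a 4-input network).

    The scaler is fitted on ``train_df`` only and reused for ``apply_df``.
    Returns the train FeatureMatrix, or a ``(train, apply)`` pair when
    ``apply_df`` is given. Raises on electrolyte levels present in the apply
    set but absent from training.
    """
    if mode not in ("onehot", "compact"):
        raise ValueError(f"unknown encoding mode {mode!r}")
    for frame, label in ((train_df, "train"), (apply_df, "apply")):
        if frame is None:
            continue
        missing = [c for c in CONTINUOUS_FEATURES + ["electrolyte"]
                   if frame[c].isna().any()]
        if missing:
            raise ValueError(f"{label} set has missing values in {missing}; "
                             "run complete_cases first")
        bad = set(frame["electrolyte"]) - set(ELECTROLYTES)
        if bad:
            raise ValueError(f"unrecognized electrolyte levels {sorted(bad)}")
    if apply_df is not None:
        unseen = set(apply_df["electrolyte"]) - set(train_df["electrolyte"])
        if unseen:
            raise ValueError(f"electrolyte levels {sorted(unseen)} absent from "
                             "training data (unseen category)")

    scaler = {f: _fit_scaler(train_df[f].to_numpy(dtype=float))
              for f in CONTINUOUS_FEATURES}
    if mode == "compact":
        codes = np.array([ELECTROLYTES.index(e) for e in train_df["electrolyte"]],
                         dtype=float)
        scaler["elec_code"] = _fit_scaler(codes)

    train_fm = _build_matrix(train_df, mode, scaler)
    if apply_df is None:
        return train_fm
    return train_fm, _build_matrix(apply_df, mode, scaler)


def apply_encoding(fm: FeatureMatrix, df: pd.DataFrame) -> FeatureMatrix:
    """Encode new rows with a previously fitted scaler/encoding.

    ``pore_diameter_nm`` may be absent (prediction-only rows).
    """
    work = df.copy()
    if "pore_diameter_nm" not in work.columns:
        work["pore_diameter_nm"] = np.nan
    bad = set(work["electrolyte"]) - set(ELECTROLYTES)
    if bad:
        raise ValueError(f"unrecognized electrolyte levels {sorted(bad)}")
    return _build_matrix(work, fm.mode, fm.scaler)


def stratified_split(df: pd.DataFrame, test_fraction: float, seed: int):
    """Per-electrolyte train/test split.

    Test count per class = round(class_n * test_fraction), with at least one
    training member per class; rows are shuffled within class with a seeded
    generator. Classes with a single record go entirely to train (warning).
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx = []
    for level, group in df.groupby("electrolyte", sort=True):
        n = len(group)
        n_test = int(round(n * test_fraction))
        n_test = min(n_test, n - 1)  # keep >= 1 train member
        if n == 1:
            warnings.warn(f"electrolyte class {level!r} has a single record; "
                          "assigned entirely to train", stacklevel=2)
            n_test = 0
        perm = rng.permutation(n)
        test_idx.extend(group.index[perm[:n_test]])
    test_mask = df.index.isin(test_idx)
    return df.loc[~test_mask], df.loc[test_mask]


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write the dataset CSV (UTF-8, comma-separated, empty field = missing)."""
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")
    df[SCHEMA_COLUMNS].to_csv(path, index=False, na_rep="")


def read_dataset(path) -> pd.DataFrame:
    """Read a dataset CSV, validating the schema and numeric columns.

    Raises on absent required columns (listing them) and on non-numeric
    values in numeric columns (naming the offending 1-based data row).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    out = pd.DataFrame(index=df.index)
    for col in SCHEMA_COLUMNS:
        raw = df[col].mask(df[col] == "", np.nan)
        if col in NUMERIC_COLUMNS:
            converted = pd.to_numeric(raw, errors="coerce")
            bad = converted.isna() & raw.notna()
            if bad.any():
                row = int(bad.idxmax()) + 1
                raise ValueError(
                    f"non-numeric value {raw[bad.idxmax()]!r} in column "
                    f"{col!r} at data row {row}")
            out[col] = converted
        else:
            out[col] = raw
    return out
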