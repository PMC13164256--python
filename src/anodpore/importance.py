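"""Feature importance for the pore-diameter surrogates.

Two deliberately simple, weight-based procedures: for the network, the mean
absolute first-layer weight per input column; for the linear model, the
absolute standardized coefficients. Indicator columns belonging to the
electrolyte category are summed into a single "electrolyte_type" score and
everything is normalized to 100%. These first-layer / coefficient magnitudes
are an indicative proxy, not a faithful attribution — they ignore how
information is transformed in deeper layers — and the report carries that
caveat.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .regressors import LinearModel, NetworkModel

__all__ = ["ImportanceReport", "ann_importance", "mlr_importance", "FEATURES"]

#: Report rows, in fixed order.
FEATURES = ("voltage", "temperature", "time", "electrolyte_type")

_CAVEAT = ("weight-based importance is an indicative proxy; it ignores "
           "deeper-layer transformations and nonlinear interactions")


class ImportanceReport:
    """Per-feature relative importance percentages summing to 100."""

    def __init__(self, percentages: dict[str, float], method: str):
        if set(percentages) != set(FEATURES):
            raise ValueError(f"report must cover exactly {FEATURES}")
        total = sum(percentages.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"percentages sum to {total}, not 100")
        if any(v < 0 for v in percentages.values()):
            raise ValueError("percentages must be non-negative")
        self.percentages = {f: float(percentages[f]) for f in FEATURES}
        self.method = method
        self.caveat = _CAVEAT

    def __getitem__(self, feature):
        return self.percentages[feature]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "feature": list(FEATURES),
            "importance_pct": [self.percentages[f] for f in FEATURES],
        })
        df["rank"] = df["importance_pct"].rank(ascending=False,
                                               method="min").astype(int)
        return df


def _aggregate(scores_by_column, column_map, method):
    """Sum per-column scores into parent features and normalize to 100%."""
    agg = {f: 0.0 for f in FEATURES}
    for info, score in zip(column_map, scores_by_column):
        agg[info.source] += float(score)
    total = sum(agg.values())
    if total == 0.0:
        raise ValueError("all scores are zero; normalization undefined")
    return ImportanceReport({f: 100.0 * v / total for f, v in agg.items()},
                            method=method)


def ann_importance(model: NetworkModel, column_map=None) -> ImportanceReport:
    """Mean |first-layer weight| per input column, aggregated and normalized."""
    column_map = column_map or model.column_map
    W1 = model.weights[0]  # inputs x hidden units
    if W1.shape[0] != len(column_map):
        raise ValueError("column_map does not match the first-layer width")
    scores = np.mean(np.abs(W1), axis=1)
    return _aggregate(scores, column_map, method="ann_first_layer_weights")


def mlr_importance(model: LinearModel, column_map=None) -> ImportanceReport:
    """|standardized coefficient| per design column (intercept excluded),
    indicator coefficients summed by absolute value, normalized to 100%."""
    column_map = column_map or model.column_map
    by_name = {c.name: c for c in column_map}
    infos, scores = [], []
    for name, coef in model.coefficients.items():
        infos.append(by_name[name])
        scores.append(abs(coef))
    return _aggregate(scores, infos, method="mlr_standardized_coefficients")
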