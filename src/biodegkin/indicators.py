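"""Goodness-of-fit indicator panel for measured vs. predicted weight loss.

With residuals d_i = measured_i - predicted_i over n points:

* ``mse``  = (sum d_i^2) / n                     [%^2]  (population form)
* ``rmse`` = sqrt(mse)                           [%]
* ``r``    = Pearson correlation(measured, predicted)
* ``r2``   = 1 - sum d_i^2 / sum (measured_i - mean(measured))^2
* ``rae``  = (sum |d_i| / n) / max(measured)     (mean absolute residual
             relative to the largest measured value)

All points, including a leading (0, 0) observation, enter the panel.
When the measured series has zero variance the correlation-based
indicators are undefined; they are returned as NaN with
``correlation_defined = False`` rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .models import DoubleExpDelayParams, eval_double_exp_delay
from .series import WeightLossSeries

__all__ = ["GoodnessOfFit", "indicator_panel", "residual_table"]


@dataclass(frozen=True)
class GoodnessOfFit:
    """The indicator panel for one model on one series."""

    rmse: float
    mse: float
    r2: float
    r: float
    rae: float
    n: int
    correlation_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mse": self.mse,
            "r2": self.r2,
            "r": self.r,
            "rae": self.rae,
            "n": self.n,
        }

    def to_csv_row(self) -> str:
        """One-row CSV rendering (header + values, 6 significant digits)."""
        keys = ["rmse", "mse", "r2", "r", "rae", "n"]
        vals = [f"{getattr(self, k):.6g}" for k in keys[:-1]] + [str(self.n)]
        return ",".join(keys) + "\n" + ",".join(vals) + "\n"

    def format_table(self, model_label: str = "model") -> str:
        """Formatted text table mirroring the usual indicator layout."""
        head = f"{'Model':<24}{'RMSE':>10}{'MSE':>10}{'R2':>10}{'R':>10}{'rAE':>10}"
        row = (f"{model_label:<24}{self.rmse:>10.4f}{self.mse:>10.4f}"
               f"{self.r2:>10.4f}{self.r:>10.4f}{self.rae:>10.4f}")
        return head + "\n" + row


def indicator_panel(
    measured: Union[WeightLossSeries, np.ndarray], predicted
) -> GoodnessOfFit:
    """Compute the indicator panel from aligned measured/predicted values."""
    w = measured.values if isinstance(measured, WeightLossSeries) else np.asarray(
        measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if w.shape != p.shape:
        raise ValueError(
            f"measured ({w.shape}) and predicted ({p.shape}) must align"
        )
    n = w.size
    if n < 2:
        raise ValueError("indicator panel needs at least 2 points")
    d = w - p
    mse = float(np.sum(d**2) / n)
    rmse = math.sqrt(mse)
    w_max = float(np.max(np.abs(w)))
    rae = float(np.sum(np.abs(d)) / n / w_max) if w_max > 0 else float("nan")
    sst = float(np.sum((w - w.mean()) ** 2))
    if sst > 0 and np.std(p) > 0:
        r = float(_stats.pearsonr(w, p).statistic)
        r2 = 1.0 - float(np.sum(d**2)) / sst
        defined = True
    else:
        r = float("nan")
        r2 = float("nan")
        defined = False
    return GoodnessOfFit(rmse=rmse, mse=mse, r2=r2, r=r, rae=rae, n=n,
                         correlation_defined=defined)


def residual_table(
    measured: WeightLossSeries, params: DoubleExpDelayParams
) -> pd.DataFrame:
    """Per-point table (t, w, CW, dW) for the double-exponential model.

    CW is the model evaluation at each sample time and dW = w - CW the
    residual, mirroring how fitted weight-loss tables are conventionally
    reported.
    """
    cw = np.asarray(eval_double_exp_delay(params, measured.times), dtype=float)
    return pd.DataFrame(
        {
            "t": measured.times,
            "w": measured.values,
            "CW": cw,
            "dW": measured.values - cw,
        }
    )
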