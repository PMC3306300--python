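"""Model validation statistics: residual summaries, through-origin
regression criteria and Roy's r_m^2.

Conventions
-----------
* residual e = observed - predicted (pEC50 units);
* r^2 is the squared Pearson correlation of observed vs predicted (the
  through-origin quantities are reported separately);
* RMSE = sqrt(mean(e^2)), MAE = mean|e|, Delta_max = max|e|;
* s = sqrt(mean(e^2) - mean(|e|)^2), the population standard deviation of
  the absolute residuals, so s^2 + MAE^2 = RMSE^2 identically;
* through-origin slopes and determination coefficients follow the
  external-validation criteria of Golbraikh & Tropsha, with Roy's
  r_m^2 = r^2 * (1 - sqrt(max(0, r^2 - r0^2))).

Acceptability flags: r^2 > 0.6; q^2 > 0.5 (when supplied);
(r^2 - r0^2)/r^2 < 0.1 with 0.85 <= k <= 1.15; |r0^2 - r0'^2| < 0.3;
r_m^2 > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .types import PhesvmError


@dataclass
class ValidationReport:
    label: str
    n: int
    r2: float
    rmse: float
    mae: float
    dmax: float
    s: float
    q2: Optional[float] = None
    k: Optional[float] = None
    k_prime: Optional[float] = None
    r0_2: Optional[float] = None
    r0_2_prime: Optional[float] = None
    rm2: Optional[float] = None
    flags: Dict[str, bool] = field(default_factory=dict)


def _as_vectors(y_obs, y_pred):
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.ndim != 1:
        raise ValueError("y_obs and y_pred must be matching 1-D vectors")
    if len(y_obs) < 2:
        raise ValueError("need at least 2 samples")
    if not (np.all(np.isfinite(y_obs)) and np.all(np.isfinite(y_pred))):
        raise ValueError("non-finite values")
    if np.var(y_obs) <= 0 or np.var(y_pred) <= 0:
        raise PhesvmError("zero variance: correlation undefined")
    return y_obs, y_pred


def residual_stats(y_obs, y_pred, label: str = "") -> ValidationReport:
    """Residual summary block: r^2, RMSE, MAE, Delta_max, s."""
    y_obs, y_pred = _as_vectors(y_obs, y_pred)
    e = y_obs - y_pred
    r = np.corrcoef(y_obs, y_pred)[0, 1]
    mse = float(np.mean(e**2))
    mae = float(np.mean(np.abs(e)))
    return ValidationReport(
        label=label,
        n=len(y_obs),
        r2=float(r * r),
        rmse=float(np.sqrt(mse)),
        mae=mae,
        dmax=float(np.max(np.abs(e))),
        s=float(np.sqrt(max(0.0, mse - mae * mae))),
    )


def golbraikh_criteria(y_obs, y_pred, q2: Optional[float] = None) -> dict:
    """Through-origin external-validation quantities and pass/fail flags."""
    y_obs, y_pred = _as_vectors(y_obs, y_pred)
    r = np.corrcoef(y_obs, y_pred)[0, 1]
    r2 = float(r * r)
    k = float(np.sum(y_obs * y_pred) / np.sum(y_pred**2))
    k_prime = float(np.sum(y_obs * y_pred) / np.sum(y_obs**2))
    r0_2 = float(
        1.0 - np.sum((y_obs - k * y_pred) ** 2) / np.sum((y_obs - y_obs.mean()) ** 2)
    )
    r0_2_prime = float(
        1.0 - np.sum((y_pred - k_prime * y_obs) ** 2) / np.sum((y_pred - y_pred.mean()) ** 2)
    )
    rm2 = float(r2 * (1.0 - np.sqrt(max(0.0, r2 - r0_2))))
    flags = {
        "r2_gt_0.6": r2 > 0.6,
        "slope_window": ((r2 - r0_2) / r2 < 0.1) and (0.85 <= k <= 1.15),
        "r0_gap_lt_0.3": abs(r0_2 - r0_2_prime) < 0.3,
        "rm2_gt_0.5": rm2 > 0.5,
    }
    if q2 is not None:
        flags["q2_gt_0.5"] = q2 > 0.5
    return {
        "r2": r2,
        "k": k,
        "k_prime": k_prime,
        "r0_2": r0_2,
        "r0_2_prime": r0_2_prime,
        "rm2": rm2,
        "flags": flags,
    }


def validation_report(
    y_obs, y_pred, q2: Optional[float] = None, label: str = ""
) -> ValidationReport:
    """Full per-partition report: residual block + through-origin criteria."""
    rep = residual_stats(y_obs, y_pred, label)
    g = golbraikh_criteria(y_obs, y_pred, q2)
    rep.q2 = q2
    rep.k = g["k"]
    rep.k_prime = g["k_prime"]
    rep.r0_2 = g["r0_2"]
    rep.r0_2_prime = g["r0_2_prime"]
    rep.rm2 = g["rm2"]
    rep.flags = g["flags"]
    return rep


_ROW_ORDER = ("r2", "rmse", "dmax", "mae", "s", "q2")
_ROW_LABELS = {
    "r2": "r^2",
    "rmse": "RMSE",
    "dmax": "Delta_max",
    "mae": "MAE",
    "s": "s",
    "q2": "q^2",
}


def _round_half_up(x: float, nd: int = 2) -> float:
    import decimal

    return float(
        decimal.Decimal(repr(x)).quantize(
            decimal.Decimal("1." + "0" * nd), rounding=decimal.ROUND_HALF_UP
        )
    )


def render_statistics_table(
    reports_by_partition: Dict[str, Dict[str, ValidationReport]], sep: str = "\t"
) -> str:
    """Render the statistics grid as delimited text.

    ``reports_by_partition`` maps partition label -> {model label -> report};
    rows follow the order r^2, RMSE, Delta_max, MAE, s, q^2 per partition,
    values displayed half-up at 2 decimals (computation stays full
    precision in the report objects).
    """
    partitions = list(reports_by_partition)
    models = list(next(iter(reports_by_partition.values())))
    lines = [sep.join([""] + models)]
    for part in partitions:
        lines.append(f"{part} set")
        block = reports_by_partition[part]
        for key in _ROW_ORDER:
            vals = []
            for m in models:
                v = getattr(block[m], key)
                vals.append("N/A" if v is None else f"{_round_half_up(v):.2f}")
            if key == "q2" and all(v == "N/A" for v in vals):
                continue
            lines.append(sep.join([_ROW_LABELS[key]] + vals))
    return "\n".join(lines) + "\n"
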