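"""Shelf-life determination under safety, sensory and quality limits.

Three bases are combined:

* safety - time for the fitted growth curve to reach the microbial limit
  (default 5 log10 CFU/g, the regulatory ceiling for fresh-cut produce);
* sensory - last sampling day with mean panel score at or above the
  acceptability score (default 3 on a 1-5 scale);
* quality - time for a fitted kinetic attribute model to reach an
  attribute cut-off.  Cut-offs without an external standard are derived
  from the data itself: the attribute's mean value on the sensory
  shelf-life day of that treatment.

The overall shelf life of a treatment is the minimum across the enabled
bases - the product is unacceptable as soon as any limit is crossed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import StorageDataset
from .errors import LimitAlreadyExceededError, LimitNeverReachedError
from .fitting import GrowthCurveResults, QualityKineticsResults

__all__ = [
    "AcceptabilityLimit",
    "ShelfLifeEstimate",
    "SAFETY_LIMIT_DEFAULT",
    "SENSORY_LIMIT_DEFAULT",
    "sensory_shelf_life",
    "derive_attribute_cutoff",
    "predict_safety_shelf_life",
    "predict_quality_shelf_life",
    "shelf_life_report",
    "overall_shelf_life",
    "format_report_text",
]

#: Microbial ceiling for fresh-cut produce, log10 CFU/g.
SAFETY_LIMIT_DEFAULT = 5.0
#: Sensory acceptability score below which product loses commercial value.
SENSORY_LIMIT_DEFAULT = 3.0


@dataclass(frozen=True)
class AcceptabilityLimit:
    """An acceptability boundary for one attribute.

    ``direction="upper"`` means the product becomes unacceptable when the
    attribute exceeds ``value`` (e.g. bacterial count, weight loss);
    ``"lower"`` when it falls below (e.g. firmness, sensory score).
    """

    attribute: str
    value: float
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in ("upper", "lower"):
            raise ValueError("direction must be 'upper' or 'lower'")
        if not math.isfinite(self.value):
            raise ValueError("limit value must be finite")


@dataclass(frozen=True)
class ShelfLifeEstimate:
    """A shelf-life prediction under one basis.

    ``status`` is ``"ok"``, ``"exceeded_at_start"`` (limit already crossed
    at day 0; ``t_pred = 0``) or ``"never_reached"`` (the model never
    crosses the limit; ``t_pred`` is the censoring time or ``inf``).
    """

    basis: str
    t_pred: float
    limit: AcceptabilityLimit
    model: str
    treatment: str | None = None
    censored: bool = False
    status: str = "ok"


def sensory_shelf_life(
    scores: Sequence[tuple[float, float]],
    limit: float = SENSORY_LIMIT_DEFAULT,
    method: str = "discrete",
    treatment: str | None = None,
) -> ShelfLifeEstimate:
    """Sensory shelf life from (time, mean panel score) pairs.

    ``method="discrete"`` (default) returns the last observed day with
    score >= limit; ``"interpolate"`` returns the linear crossing time
    between the bracketing sampling days.  If the score never falls below
    the limit the estimate is right-censored at the last day; if it is
    below the limit from the start, status is ``exceeded_at_start``.
    """
    if method not in ("discrete", "interpolate"):
        raise ValueError("method must be 'discrete' or 'interpolate'")
    pts = sorted((float(t), float(s)) for t, s in scores)
    if len(pts) < 2:
        raise ValueError("need scores at >= 2 times")
    times = np.array([t for t, _ in pts])
    vals = np.array([s for _, s in pts])
    lim = AcceptabilityLimit("sensory", limit, "lower")
    ok = vals >= limit
    if not ok.any():
        return ShelfLifeEstimate("sensory", 0.0, lim, "empirical", treatment,
                                 censored=False, status="exceeded_at_start")
    if ok.all():
        return ShelfLifeEstimate("sensory", float(times[-1]), lim, "empirical",
                                 treatment, censored=True, status="never_reached")
    # first index where the score drops below the limit
    i = int(np.argmax(~ok))
    if method == "discrete":
        t_pred = float(times[i - 1])
    else:
        t0, t1 = times[i - 1], times[i]
        s0, s1 = vals[i - 1], vals[i]
        t_pred = float(t0 + (s0 - limit) * (t1 - t0) / (s0 - s1))
    return ShelfLifeEstimate("sensory", t_pred, lim, "empirical", treatment)


def derive_attribute_cutoff(
    dataset: StorageDataset,
    attribute: str,
    treatment: str,
    t_sensory: float,
) -> AcceptabilityLimit:
    """Attribute cut-off anchored to the sensory shelf-life day.

    The cut-off is the treatment's mean attribute value at ``t_sensory``
    (interpolated linearly between adjacent sampling days when that exact
    day was not sampled).  Direction follows the attribute's trajectory:
    ``lower`` for declining attributes, ``upper`` for rising ones.
    """
    t, y = dataset.trajectory(treatment, attribute)
    if not (t[0] <= t_sensory <= t[-1]):
        raise ValueError(
            f"t_sensory={t_sensory} outside observed range [{t[0]}, {t[-1]}]"
        )
    value = float(np.interp(t_sensory, t, y))
    direction = "lower" if y[-1] < y[0] else "upper"
    return AcceptabilityLimit(attribute, value, direction)


def predict_safety_shelf_life(
    fit: GrowthCurveResults,
    limit: AcceptabilityLimit | float = SAFETY_LIMIT_DEFAULT,
    treatment: str | None = None,
) -> ShelfLifeEstimate:
    """Days until the fitted growth curve reaches the microbial limit."""
    if not isinstance(limit, AcceptabilityLimit):
        limit = AcceptabilityLimit("tbc_log_cfu_g", float(limit), "upper")
    try:
        t_pred = fit.time_to_limit(limit.value)
    except LimitAlreadyExceededError:
        return ShelfLifeEstimate("safety", 0.0, limit, fit.kind, treatment,
                                 status="exceeded_at_start")
    except LimitNeverReachedError:
        return ShelfLifeEstimate("safety", math.inf, limit, fit.kind, treatment,
                                 censored=True, status="never_reached")
    return ShelfLifeEstimate("safety", float(t_pred), limit, fit.kind, treatment)


def predict_quality_shelf_life(
    fit: QualityKineticsResults,
    cutoff: AcceptabilityLimit,
    treatment: str | None = None,
) -> ShelfLifeEstimate:
    """Days until the fitted attribute kinetics reach the cut-off."""
    model = f"{fit.order}-order"
    try:
        t_pred = fit.time_to_limit(cutoff.value)
    except LimitAlreadyExceededError:
        return ShelfLifeEstimate("quality", 0.0, cutoff, model, treatment,
                                 status="exceeded_at_start")
    except LimitNeverReachedError:
        return ShelfLifeEstimate("quality", math.inf, cutoff, model, treatment,
                                 censored=True, status="never_reached")
    return ShelfLifeEstimate("quality", float(t_pred), cutoff, model, treatment)


_REPORT_COLUMNS = [
    "treatment", "basis", "attribute", "model", "limit", "direction",
    "t_pred_d", "censored_flag",
]


def shelf_life_report(estimates: Iterable[ShelfLifeEstimate]) -> pd.DataFrame:
    """Comparison table of shelf-life estimates, one row per estimate plus
    one ``overall`` row per treatment (minimum across bases)."""
    rows = []
    for est in estimates:
        rows.append(
            {
                "treatment": est.treatment or "",
                "basis": est.basis,
                "attribute": est.limit.attribute,
                "model": est.model,
                "limit": est.limit.value,
                "direction": est.limit.direction,
                "t_pred_d": est.t_pred,
                "censored_flag": est.censored,
            }
        )
    if not rows:
        raise ValueError("no shelf-life estimates supplied")
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    overall_rows = []
    for trt, sub in df.groupby("treatment", sort=False):
        t_min = float(sub["t_pred_d"].min())
        idx = sub["t_pred_d"].idxmin()
        overall_rows.append(
            {
                "treatment": trt,
                "basis": "overall",
                "attribute": sub.loc[idx, "attribute"],
                "model": sub.loc[idx, "model"],
                "limit": sub.loc[idx, "limit"],
                "direction": sub.loc[idx, "direction"],
                "t_pred_d": t_min,
                "censored_flag": bool(sub["censored_flag"].all()),
            }
        )
    return pd.concat([df, pd.DataFrame(overall_rows)], ignore_index=True)


def overall_shelf_life(report: pd.DataFrame) -> dict[str, float]:
    """Per-treatment overall shelf life (days) from a report table."""
    sub = report[report["basis"] == "overall"]
    return dict(zip(sub["treatment"], sub["t_pred_d"]))


def format_report_text(report: pd.DataFrame) -> str:
    """Aligned plain-text rendering of a shelf-life report table."""
    df = report.copy()
    df["t_pred_d"] = df["t_pred_d"].map(lambda v: f"{v:.3f}")
    df["limit"] = df["limit"].map(lambda v: f"{v:.3f}")
    widths = {
        c: max(len(c), *(len(str(v)) for v in df[c])) for c in df.columns
    }
    def fmt_row(vals):
        return "  ".join(str(v).ljust(widths[c]) for c, v in zip(df.columns, vals))
    lines = [fmt_row(df.columns), fmt_row(["-" * widths[c] for c in df.columns])]
    lines += [fmt_row(row) for row in df.itertuples(index=False)]
    return "\n".join(lines)
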