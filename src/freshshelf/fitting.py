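"""Least-squares estimation of growth and quality kinetic models.

The estimation API follows the Model -> fit() -> Results pattern:
:class:`GrowthCurveModel` and :class:`QualityKineticsModel` are built from a
time series (or from a :class:`~freshshelf.dataset.StorageDataset`), and
``fit()`` returns a results object carrying the estimates, the
goodness-of-fit triplet (R^2, RSS, RMSE) and convenience methods
(``predict``, ``time_to_limit``, ``summary``).

Growth curves are fitted by bounded multi-start nonlinear least squares
(deterministic start grid; no randomness), quality kinetics by exact linear
least squares - on ``(t, A)`` for zero order and on ``(t, ln A)`` for first
order, the latter followed by a nonlinear refinement pass on the original
scale so that the reported RSS is the one actually minimised.

RMSE uses the residual-degrees-of-freedom convention
``sqrt(RSS / (n - p))`` by default; ``sqrt(RSS / n)`` is available via
``rmse_convention="n"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from .dataset import StorageDataset
from .errors import DegenerateSeriesError, UndefinedRSquaredError
from .growth import MODEL_KINDS, GrowthParams, evaluate_growth, invert_growth
from .kinetics import ORDERS, QualityParams, evaluate_quality, invert_quality

__all__ = [
    "GoodnessOfFit",
    "FitResult",
    "goodness_of_fit",
    "GrowthCurveModel",
    "GrowthCurveResults",
    "QualityKineticsModel",
    "QualityKineticsResults",
    "fit_growth_model",
    "fit_quality_model",
    "rank_models",
]


class GoodnessOfFit(NamedTuple):
    r_squared: float
    rss: float
    rmse: float


def goodness_of_fit(
    observed: Sequence[float],
    predicted: Sequence[float],
    n_params: int,
    rmse_convention: str = "dof",
) -> GoodnessOfFit:
    """R^2, RSS and RMSE of a fit.

    ``RSS = sum((obs - pred)^2)``; ``R^2 = 1 - RSS / SS_tot`` with the
    centred total sum of squares; ``RMSE = sqrt(RSS / (n - p))`` under the
    default degrees-of-freedom convention or ``sqrt(RSS / n)`` with
    ``rmse_convention="n"``.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    n = obs.size
    if n < n_params + 1:
        raise ValueError(f"need at least n_params+1 = {n_params + 1} observations, got {n}")
    if rmse_convention not in ("dof", "n"):
        raise ValueError("rmse_convention must be 'dof' or 'n'")
    rss = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedRSquaredError("total sum of squares is zero; R^2 undefined")
    r2 = 1.0 - rss / ss_tot
    denom = n - n_params if rmse_convention == "dof" else n
    rmse = float(np.sqrt(rss / denom))
    return GoodnessOfFit(r2, rss, rmse)


@dataclass(frozen=True)
class FitResult:
    """Estimates and diagnostics of a single kinetic-model fit."""

    model: str
    params: Union[GrowthParams, QualityParams]
    r_squared: float
    rss: float
    rmse: float
    n_obs: int
    n_params: int
    converged: bool
    n_starts_used: int = 1


def _prepare_series(times, values) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be equal-length 1-d sequences")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("times and values must be finite")
    order = np.argsort(t, kind="stable")
    return t[order], y[order]


class _ResultsBase:
    """Shared surface of fitted-model results."""

    fit_result: FitResult

    @property
    def params(self):
        return self.fit_result.params

    @property
    def rsquared(self) -> float:
        return self.fit_result.r_squared

    @property
    def rss(self) -> float:
        return self.fit_result.rss

    @property
    def rmse(self) -> float:
        return self.fit_result.rmse

    @property
    def nobs(self) -> int:
        return self.fit_result.n_obs

    @property
    def converged(self) -> bool:
        return self.fit_result.converged


class GrowthCurveResults(_ResultsBase):
    """Results of fitting a primary growth model to a count series."""

    def __init__(self, model: "GrowthCurveModel", fit_result: FitResult):
        self.model = model
        self.fit_result = fit_result

    @property
    def kind(self) -> str:
        return self.fit_result.model

    def predict(self, t) -> np.ndarray:
        """Fitted count (log10 CFU/g) at times ``t``."""
        return evaluate_growth(self.kind, t, self.fit_result.params)

    def time_to_limit(self, limit: float) -> float:
        """Days until the fitted curve reaches a count ``limit``."""
        return invert_growth(self.kind, self.fit_result.params, limit)

    def summary(self) -> str:
        p = self.fit_result.params
        f = self.fit_result
        lines = [
            f"Primary growth model: {self.kind}",
            f"  n_obs {f.n_obs}   n_params {f.n_params}   converged {f.converged}"
            f"   starts {f.n_starts_used}",
            f"  N0     {p.n0:10.4f}  log10 CFU/g",
            f"  Nmax   {p.nmax:10.4f}  log10 CFU/g",
            f"  mu_max {p.mu_max:10.4f}  1/d",
            f"  lag    {p.lag:10.4f}  d   (h0 = {p.h0:.4f})",
            f"  R^2  {f.r_squared:8.4f}   RSS {f.rss:10.5f}   RMSE {f.rmse:8.4f}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<GrowthCurveResults {self.kind} R2={self.rsquared:.4f} "
            f"rmse={self.rmse:.4f}>"
        )


class GrowthCurveModel:
    """Primary growth model to be fitted to a (time, log-count) series.

    Parameters
    ----------
    times, counts : sequences
        Storage times (d) and log10 CFU/g counts; at least 5 distinct times.
    kind : str
        One of ``gompertz``, ``logistic``, ``baranyi``, ``huang``.
    """

    N_PARAMS = 4

    def __init__(self, times, counts, kind: str = "gompertz"):
        if kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
        self.kind = kind
        self.times, self.counts = _prepare_series(times, counts)
        if np.unique(self.times).size < 5:
            raise DegenerateSeriesError("growth fitting needs >= 5 distinct time points")
        if np.ptp(self.counts) == 0:
            raise DegenerateSeriesError(
                "counts are constant: Nmax > N0 is unsatisfiable"
            )

    @classmethod
    def from_dataset(
        cls,
        dataset: StorageDataset,
        treatment: str,
        kind: str = "gompertz",
        attribute: str = "tbc_log_cfu_g",
    ) -> "GrowthCurveModel":
        """Build from per-day replicate means of a storage dataset."""
        t, y = dataset.trajectory(treatment, attribute)
        return cls(t, y, kind=kind)

    # deterministic start grid (see module docstring)
    def _starts(self) -> list[np.ndarray]:
        t, y = self.times, self.counts
        n0 = float(y.min())
        nmax = float(y.max())
        dt = t[:, None] - t[None, :]
        dy = y[:, None] - y[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            slopes = np.where(dt != 0, dy / dt, -np.inf)
        mu = float(np.clip(np.max(slopes), 1e-2, 10.0))
        w = float(t.max())
        return [
            np.array([n0, nmax, mu, lag]) for lag in (0.0, 0.25 * w, 0.5 * w)
        ]

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        y, t = self.counts, self.times
        lo = np.array([0.0, float(y.max()) - 1.0, 1e-6, 0.0])
        hi = np.array([float(y.min()) + 1.0, float(y.max()) + 3.0, 10.0, float(t.max())])
        return lo, hi

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        n0, nmax, mu, lag = theta
        if nmax <= n0:  # guard: trf keeps within bounds, but bounds overlap
            nmax = n0 + 1e-9
        p = GrowthParams(n0, nmax, mu, lag)
        return np.asarray(evaluate_growth(self.kind, self.times, p)) - self.counts

    def fit(self, rmse_convention: str = "dof") -> GrowthCurveResults:
        """Bounded multi-start nonlinear least squares."""
        lo, hi = self._bounds()
        best = None
        n_ok = 0
        starts = self._starts()
        for x0 in starts:
            x0c = np.clip(x0, lo + 1e-9, hi - 1e-9)
            try:
                sol = least_squares(
                    self._residuals,
                    x0c,
                    bounds=(lo, hi),
                    method="trf",
                    xtol=1e-13,
                    ftol=1e-13,
                    gtol=1e-13,
                    max_nfev=2000,
                )
            except Exception:
                continue
            if sol.success:
                n_ok += 1
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise DegenerateSeriesError("all optimisation starts failed")
        n0, nmax, mu, lag = best.x
        params = GrowthParams(float(n0), max(float(nmax), float(n0) + 1e-9),
                              float(mu), float(lag))
        pred = np.asarray(evaluate_growth(self.kind, self.times, params))
        gof = goodness_of_fit(self.counts, pred, self.N_PARAMS, rmse_convention)
        fr = FitResult(
            model=self.kind,
            params=params,
            r_squared=gof.r_squared,
            rss=gof.rss,
            rmse=gof.rmse,
            n_obs=self.counts.size,
            n_params=self.N_PARAMS,
            converged=bool(n_ok > 0),
            n_starts_used=len(starts),
        )
        return GrowthCurveResults(self, fr)


class QualityKineticsResults(_ResultsBase):
    """Results of fitting a zero- or first-order kinetic model."""

    def __init__(self, model: "QualityKineticsModel", fit_result: FitResult):
        self.model = model
        self.fit_result = fit_result

    @property
    def order(self) -> str:
        return self.fit_result.model

    def predict(self, t) -> np.ndarray:
        return evaluate_quality(t, self.fit_result.params)

    def time_to_limit(self, limit: float) -> float:
        """Days until the fitted attribute reaches ``limit`` (closed form)."""
        return invert_quality(self.fit_result.params, limit)

    def summary(self) -> str:
        p = self.fit_result.params
        f = self.fit_result
        unit = "units/d" if p.order == "zero" else "1/d"
        return "\n".join(
            [
                f"Quality kinetics: {p.order}-order ({p.direction})",
                f"  A0 {p.a0:12.4f}   k {p.k:12.5f} {unit}",
                f"  R^2 {f.r_squared:8.4f}   RSS {f.rss:10.5f}   RMSE {f.rmse:8.4f}"
                f"   n {f.n_obs}",
            ]
        )

    def __repr__(self) -> str:
        return (
            f"<QualityKineticsResults {self.order} R2={self.rsquared:.4f} "
            f"k={self.fit_result.params.k:.4g}>"
        )


class QualityKineticsModel:
    """Zero- or first-order kinetic model for a quality-attribute series."""

    N_PARAMS = 2

    def __init__(self, times, values, order: str = "zero"):
        if order not in ORDERS:
            raise ValueError(f"order must be one of {ORDERS}, got {order!r}")
        self.order = order
        self.times, self.values = _prepare_series(times, values)
        if np.unique(self.times).size < 3:
            raise DegenerateSeriesError("quality fitting needs >= 3 distinct time points")
        if order == "first" and np.any(self.values <= 0):
            raise ValueError("first-order kinetics require strictly positive values")

    @classmethod
    def from_dataset(
        cls, dataset: StorageDataset, treatment: str, attribute: str, order: str = "zero"
    ) -> "QualityKineticsModel":
        t, y = dataset.trajectory(treatment, attribute)
        return cls(t, y, order=order)

    def fit(self, rmse_convention: str = "dof") -> QualityKineticsResults:
        t, y = self.times, self.values
        if self.order == "zero":
            k, a0 = np.polyfit(t, y, 1)
            params = QualityParams("zero", float(a0), float(k) if k != 0 else 1e-300)
        else:
            # log-linear start, then refine on the original scale
            kl, la0 = np.polyfit(t, np.log(y), 1)
            x0 = np.array([float(np.exp(la0)), float(kl)])

            def resid(theta):
                return theta[0] * np.exp(theta[1] * t) - y

            sol = least_squares(resid, x0, xtol=1e-13, ftol=1e-13, gtol=1e-13)
            a0, k = sol.x
            params = QualityParams("first", float(a0), float(k) if k != 0 else 1e-300)
        pred = np.asarray(evaluate_quality(t, params))
        gof = goodness_of_fit(y, pred, self.N_PARAMS, rmse_convention)
        fr = FitResult(
            model=self.order,
            params=params,
            r_squared=gof.r_squared,
            rss=gof.rss,
            rmse=gof.rmse,
            n_obs=y.size,
            n_params=self.N_PARAMS,
            converged=True,
        )
        return QualityKineticsResults(self, fr)


def fit_growth_model(series, kind: str = "gompertz",
                     rmse_convention: str = "dof") -> GrowthCurveResults:
    """Fit one primary growth model to ``series`` of (time, count) pairs."""
    arr = np.asarray(series, dtype=float)
    return GrowthCurveModel(arr[:, 0], arr[:, 1], kind=kind).fit(rmse_convention)


def fit_quality_model(series, order: str = "zero",
                      rmse_convention: str = "dof") -> QualityKineticsResults:
    """Fit one kinetic order to ``series`` of (time, value) pairs."""
    arr = np.asarray(series, dtype=float)
    return QualityKineticsModel(arr[:, 0], arr[:, 1], order=order).fit(rmse_convention)


def rank_models(fits: Iterable[_ResultsBase]) -> list[_ResultsBase]:
    """Order fits best-first: descending R^2, then ascending RMSE, then
    ascending number of parameters.  The sort is stable, so identical fits
    keep their input order."""
    items = list(fits)
    return sorted(
        items,
        key=lambda f: (-f.fit_result.r_squared, f.fit_result.rmse, f.fit_result.n_params),
    )
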