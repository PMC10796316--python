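"""Kinetic models of color change and their fitting machinery.

Three model families describe how a quality attribute C evolves over
storage time t:

* zero order            C(t) = C0 -/+ k t
* first order           C(t) = C0 exp(-/+ k t)
* first-order fractional conversion (FOFC)
                        f(t) = (C0 - C(t)) / (C0 - Cinf) = 1 - exp(-k t)

k is stored as a positive magnitude with a separate decay/growth direction
flag.  Goodness of fit (R^2, RMSE) is always evaluated on the original
attribute scale so the three families are directly comparable, whatever
scale the estimation itself used.

The API follows the Model/Results pattern: construct a model from data
(``ZeroOrder(days, values)`` or ``FirstOrder.from_series(ts)``), call
``fit()``, and read estimates, standard errors and diagnostics off the
returned :class:`KineticResults`.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .features import ColorTimeSeries

__all__ = [
    "KineticModel",
    "ZeroOrder",
    "FirstOrder",
    "FractionalConversion",
    "KineticResults",
    "FractionalConversionSeries",
    "fit_zero_order",
    "fit_first_order",
    "fit_fofc",
    "fractional_conversion",
    "goodness_of_fit",
    "select_model",
    "evaluate_kinetic_law",
]

Direction = Literal["decay", "growth"]

#: ranking used for the parsimony tie-break in :func:`select_model`
_PARAM_RANK = {"zero": 0, "first": 1, "fofc": 2}


class InsufficientDataError(ValueError):
    """Too few (retained) time points for the requested fit."""


class DegenerateRangeError(ValueError):
    """C0 equals Cinf: the fractional conversion is undefined."""


def evaluate_kinetic_law(
    model: str,
    t: np.ndarray | float,
    *,
    c0: float,
    k: float,
    direction: Direction = "decay",
    cinf: float | None = None,
) -> np.ndarray | float:
    """Closed-form value of a kinetic law at times ``t``."""
    t = np.asarray(t, dtype=float)
    sign = -1.0 if direction == "decay" else 1.0
    if model == "zero":
        out = c0 + sign * k * t
    elif model == "first":
        out = c0 * np.exp(sign * k * t)
    elif model == "fofc":
        if cinf is None:
            raise ValueError("fofc law requires cinf")
        out = cinf + (c0 - cinf) * np.exp(-k * t)
    else:
        raise ValueError(f"unknown kinetic model {model!r}")
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FractionalConversionSeries:
    """Fraction converted f(t) with days excluded from the log-linear stage."""

    days: tuple[float, ...]
    f: tuple[float, ...]
    excluded_days: tuple[float, ...]

    def retained(self) -> tuple[np.ndarray, np.ndarray]:
        keep = [i for i, d in enumerate(self.days) if d not in self.excluded_days]
        return (
            np.asarray([self.days[i] for i in keep]),
            np.asarray([self.f[i] for i in keep]),
        )


@dataclass
class KineticResults:
    """Estimates and diagnostics from a fitted kinetic model.

    Attributes
    ----------
    model : str
        Family name: ``"zero"``, ``"first"`` or ``"fofc"``.
    k : float
        Rate constant magnitude, per day (>= 0).
    k_se : float
        Standard error of the rate constant (NaN when unavailable).
    direction : str
        ``"decay"`` or ``"growth"``.
    c0 : float
        Fitted initial attribute value.
    cinf : float or None
        Fitted/fixed equilibrium value (FOFC only).
    intercept : float
        Regression intercept on the linearized scale used for estimation.
    rsquared, rmse : float
        Goodness of fit on the original attribute scale.  ``rsquared`` is
        NaN for zero-variance (degenerate) series.
    excluded_days : tuple
        Days dropped before fitting (FOFC log-domain exclusions, or the
        leading non-positive values of a dE series under first order).
    degenerate : bool
        Constant input series; ``k`` is 0 and R^2 undefined.
    """

    model: str
    k: float
    direction: Direction
    c0: float
    intercept: float
    rsquared: float
    rmse: float
    method: str
    k_se: float = math.nan
    cinf: float | None = None
    excluded_days: tuple[float, ...] = ()
    degenerate: bool = False
    notes: tuple[str, ...] = ()
    attribute: str | None = None
    treatment: str | None = None
    nobs: int = 0
    days: tuple[float, ...] = field(default=(), repr=False)
    values: tuple[float, ...] = field(default=(), repr=False)

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the fitted kinetic curve at times ``t`` (days)."""
        return evaluate_kinetic_law(
            self.model, t, c0=self.c0, k=self.k, direction=self.direction, cinf=self.cinf
        )

    def shelf_life(self, threshold: float):
        """Invert the fitted curve at a quality threshold (see shelf_life module)."""
        from .shelf_life import predict_shelf_life

        return predict_shelf_life(self, threshold)

    def to_dict(self) -> dict:
        return {
            "treatment": self.treatment,
            "attribute": self.attribute,
            "model": self.model,
            "k": self.k,
            "k_se": self.k_se,
            "direction": self.direction,
            "C0_hat": self.c0,
            "Cinf_hat": self.cinf,
            "intercept": self.intercept,
            "R2": self.rsquared,
            "RMSE": self.rmse,
            "method": self.method,
            "excluded_days": list(self.excluded_days),
            "degenerate": self.degenerate,
            "notes": list(self.notes),
        }

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            f"{'Kinetic fit':<24}{self.model} ({self.method})",
            f"{'Treatment/attribute':<24}{self.treatment or '-'} / {self.attribute or '-'}",
            f"{'Observations':<24}{self.nobs}",
            f"{'k (per day)':<24}{self.k:.6g}"
            + (f"  (se {self.k_se:.3g})" if np.isfinite(self.k_se) else ""),
            f"{'direction':<24}{self.direction}",
            f"{'C0':<24}{self.c0:.6g}",
        ]
        if self.cinf is not None:
            lines.append(f"{'Cinf':<24}{self.cinf:.6g}")
        lines += [
            f"{'intercept (lin. scale)':<24}{self.intercept:.6g}",
            f"{'R^2 (original scale)':<24}"
            + ("undefined" if not np.isfinite(self.rsquared) else f"{self.rsquared:.6g}"),
            f"{'RMSE (original scale)':<24}{self.rmse:.6g}",
        ]
        if self.excluded_days:
            lines.append(f"{'excluded days':<24}{list(self.excluded_days)}")
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)


def _gof(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    resid = observed - predicted
    sse = float(np.sum(resid**2))
    sst = float(np.sum((observed - observed.mean()) ** 2))
    rmse = math.sqrt(sse / len(observed))
    r2 = math.nan if sst == 0 else 1.0 - sse / sst
    return r2, rmse


class KineticModel:
    """Base class: holds the (day, value) data a kinetic family is fitted to."""

    model_name: str = ""

    def __init__(
        self,
        days: Sequence[float],
        values: Sequence[float],
        *,
        attribute: str | None = None,
        treatment: str | None = None,
    ):
        self.days = np.asarray(days, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.days.shape != self.values.shape or self.days.ndim != 1:
            raise ValueError("days and values must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attribute values must be finite")
        if len(np.unique(self.days)) < 3:
            raise InsufficientDataError(
                f"kinetic fitting needs >= 3 distinct days, got {len(np.unique(self.days))}"
            )
        if not np.all(np.diff(self.days) > 0):
            raise ValueError("days must be strictly increasing")
        self.attribute = attribute
        self.treatment = treatment

    @classmethod
    def from_series(cls, series: ColorTimeSeries, **kwargs) -> "KineticModel":
        return cls(
            series.days,
            series.values,
            attribute=series.attribute,
            treatment=series.treatment,
            **kwargs,
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, *, day: str = "day", value: str = "value", **kwargs
    ) -> "KineticModel":
        d = df.sort_values(day)
        return cls(d[day].to_numpy(float), d[value].to_numpy(float), **kwargs)

    def fit(self) -> KineticResults:  # pragma: no cover - overridden
        raise NotImplementedError

    def _results(self, *, retained_days, retained_values, **kw) -> KineticResults:
        res = KineticResults(
            attribute=self.attribute,
            treatment=self.treatment,
            nobs=len(retained_days),
            days=tuple(float(d) for d in retained_days),
            values=tuple(float(v) for v in retained_values),
            **kw,
        )
        r2, rmse = _gof(np.asarray(retained_values), np.asarray(res.predict(retained_days)))
        res.rsquared, res.rmse = r2, rmse
        if math.isnan(r2):
            res.degenerate = True
            res.notes = res.notes + ("zero-variance series: R^2 undefined",)
        return res


class ZeroOrder(KineticModel):
    """Linear-in-time kinetics ``C(t) = C0 -/+ k t``, fitted by OLS."""

    model_name = "zero"

    def fit(self) -> KineticResults:
        if np.ptp(self.values) == 0:
            # constant series: slope 0, direction conventionally decay
            return self._results(
                retained_days=self.days,
                retained_values=self.values,
                model="zero",
                k=0.0,
                k_se=math.nan,
                direction="decay",
                c0=float(self.values[0]),
                intercept=float(self.values[0]),
                rsquared=math.nan,
                rmse=0.0,
                method="linearized",
            )
        reg = stats.linregress(self.days, self.values)
        direction: Direction = "decay" if reg.slope < 0 else "growth"
        return self._results(
            retained_days=self.days,
            retained_values=self.values,
            model="zero",
            k=abs(float(reg.slope)),
            k_se=float(reg.stderr),
            direction=direction,
            c0=float(reg.intercept),
            intercept=float(reg.intercept),
            rsquared=0.0,
            rmse=0.0,
            method="linearized",
        )


class FirstOrder(KineticModel):
    """Exponential kinetics ``C(t) = C0 exp(-/+ k t)``.

    ``method="linearized"`` regresses ln C on t; ``method="nonlinear"``
    (default) minimises squared error on the original scale, initialised
    from the linearized fit.  A dE trajectory starts at exactly 0, where
    the exponential family is ill-posed, so for that attribute the leading
    non-positive values are excluded and flagged.
    """

    model_name = "first"

    def __init__(self, days, values, *, method: str = "nonlinear", **kwargs):
        super().__init__(days, values, **kwargs)
        if method not in ("linearized", "nonlinear"):
            raise ValueError(f"method must be 'linearized' or 'nonlinear', got {method!r}")
        self.method = method

    def fit(self) -> KineticResults:
        days, values = self.days, self.values
        excluded: tuple[float, ...] = ()
        notes: tuple[str, ...] = ()
        if self.attribute == "dE":
            keep = values > 0
            # drop non-positive values (the day-0 zero in particular)
            if not keep.all():
                excluded = tuple(float(d) for d in days[~keep])
                notes = (
                    "first-order fit on dE excludes non-positive values "
                    f"(days {sorted(excluded)}); C0 taken from the first positive value",
                )
                days, values = days[keep], values[keep]
            if len(np.unique(days)) < 3:
                raise InsufficientDataError(
                    "fewer than 3 positive dE values remain for the first-order fit"
                )
        if np.any(values <= 0):
            raise ValueError(
                "first-order fitting requires strictly positive values in the log "
                "domain; use the nonlinear method on a shifted attribute instead"
            )
        if np.ptp(values) == 0:
            return self._results(
                retained_days=days,
                retained_values=values,
                model="first",
                k=0.0,
                k_se=math.nan,
                direction="decay",
                c0=float(values[0]),
                intercept=float(np.log(values[0])),
                rsquared=math.nan,
                rmse=0.0,
                method=self.method,
                excluded_days=excluded,
                notes=notes,
            )

        lin = stats.linregress(days, np.log(values))
        slope, intercept, slope_se = float(lin.slope), float(lin.intercept), float(lin.stderr)
        if self.method == "nonlinear":
            popt, pcov = optimize.curve_fit(
                lambda t, c0, s: c0 * np.exp(s * t),
                days,
                values,
                p0=[math.exp(intercept), slope],
                maxfev=10000,
            )
            c0, slope = float(popt[0]), float(popt[1])
            with np.errstate(invalid="ignore"):
                slope_se = float(np.sqrt(pcov[1, 1]))
            intercept = math.log(c0) if c0 > 0 else math.nan
        else:
            c0 = math.exp(intercept)
        direction: Direction = "decay" if slope < 0 else "growth"
        return self._results(
            retained_days=days,
            retained_values=values,
            model="first",
            k=abs(slope),
            k_se=slope_se,
            direction=direction,
            c0=c0,
            intercept=intercept,
            rsquared=0.0,
            rmse=0.0,
            method=self.method,
            excluded_days=excluded,
            notes=notes,
        )


class FractionalConversion(KineticModel):
    """First-order fractional-conversion kinetics toward a non-zero plateau.

    The fraction converted ``f(t) = (C0 - C(t)) / (C0 - Cinf)`` follows
    ``1 - exp(-k t)``; k and the intercept come from OLS of ln(1 - f) on
    storage day.  ``cinf`` may be a fixed number, ``"last_observation"``,
    or ``"fit"`` — a bounded 1-D search beyond the observed extreme value
    minimising the RMSE of the reconstructed trajectory.
    """

    model_name = "fofc"

    def __init__(self, days, values, *, cinf: float | str = "fit", **kwargs):
        super().__init__(days, values, **kwargs)
        self.cinf_mode = cinf

    # -- fractional conversion -------------------------------------------------
    def conversion(self, cinf: float) -> FractionalConversionSeries:
        c0 = float(self.values[0])
        if cinf == c0:
            raise DegenerateRangeError("C0 equals Cinf: fractional conversion undefined")
        f = (c0 - self.values) / (c0 - cinf)
        # the first day has f = 0 by construction and is always retained;
        # later days must satisfy 0 < f < 1 in the log domain
        excluded = [
            float(d)
            for d, fi in zip(self.days[1:], f[1:])
            if not (0.0 < fi < 1.0)
        ]
        return FractionalConversionSeries(
            days=tuple(float(d) for d in self.days),
            f=tuple(float(fi) for fi in f),
            excluded_days=tuple(excluded),
        )

    def _loglinear(self, cinf: float):
        fc = self.conversion(cinf)
        t, f = fc.retained()
        if len(t) < 3:
            raise InsufficientDataError(
                f"fewer than 3 retained points for the FOFC log-linear fit "
                f"(excluded days: {list(fc.excluded_days)})"
            )
        reg = stats.linregress(t, np.log1p(-f))
        return fc, float(reg.slope), float(reg.intercept), float(reg.stderr)

    def _resolve_cinf(self) -> float:
        if isinstance(self.cinf_mode, (int, float)):
            return float(self.cinf_mode)
        if self.cinf_mode == "last_observation":
            return float(self.values[-1])
        if self.cinf_mode != "fit":
            raise ValueError(f"invalid cinf mode {self.cinf_mode!r}")
        c0 = float(self.values[0])
        decay = float(self.values[-1]) < c0
        extreme = float(self.values.min()) if decay else float(self.values.max())
        span = abs(c0 - extreme)
        if span == 0:
            raise DegenerateRangeError("constant series: Cinf cannot be fitted")
        eps = 1e-9 * span

        def objective(cinf: float) -> float:
            try:
                _, slope, intercept, _ = self._loglinear(cinf)
            except (InsufficientDataError, DegenerateRangeError):
                return math.inf
            pred = self._reconstruct(cinf, slope, intercept)
            return float(np.sqrt(np.mean((self.values - pred) ** 2)))

        # The plateau search extends half the observed span beyond the extreme
        # value.  FOFC presumes the trajectory levels off near the end of the
        # window; a plateau far below (above) the data would reduce the model
        # to an over-parameterised exponential, indistinguishable from plain
        # first-order kinetics.
        if decay:
            lo, hi = extreme - 0.5 * span, extreme - eps
        else:
            lo, hi = extreme + eps, extreme + 0.5 * span
        res = optimize.minimize_scalar(
            objective, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10 * span}
        )
        return float(res.x)

    def _reconstruct(self, cinf: float, slope: float, intercept: float) -> np.ndarray:
        c0 = float(self.values[0])
        one_minus_f = np.exp(intercept + slope * self.days)
        return c0 - (1.0 - one_minus_f) * (c0 - cinf)

    def fit(self) -> KineticResults:
        cinf = self._resolve_cinf()
        fc, slope, intercept, slope_se = self._loglinear(cinf)
        c0 = float(self.values[0])
        direction: Direction = "decay" if cinf < c0 else "growth"
        return self._results(
            retained_days=[d for d in fc.days if d not in fc.excluded_days],
            retained_values=[
                v for d, v in zip(fc.days, self.values) if d not in fc.excluded_days
            ],
            model="fofc",
            k=abs(slope),
            k_se=slope_se,
            direction=direction,
            c0=c0,
            cinf=cinf,
            intercept=intercept,
            rsquared=0.0,
            rmse=0.0,
            method="linearized",
        )


# ---------------------------------------------------------------------------
# Functional surface over the model classes


def fit_zero_order(series: ColorTimeSeries) -> KineticResults:
    """OLS fit of the zero-order law to an attribute trajectory."""
    return ZeroOrder.from_series(series).fit()


def fit_first_order(series: ColorTimeSeries, method: str = "nonlinear") -> KineticResults:
    """Fit of the first-order exponential law (see :class:`FirstOrder`)."""
    return FirstOrder.from_series(series, method=method).fit()


def fit_fofc(series: ColorTimeSeries, cinf: float | str = "fit") -> KineticResults:
    """Fit of first-order fractional-conversion kinetics."""
    return FractionalConversion.from_series(series, cinf=cinf).fit()


def fractional_conversion(
    series: ColorTimeSeries, cinf: float | str
) -> FractionalConversionSeries:
    """Fraction converted f(t) for a trajectory, given the plateau Cinf."""
    model = FractionalConversion.from_series(series, cinf=cinf)
    return model.conversion(model._resolve_cinf())


def goodness_of_fit(fit: KineticResults, series: ColorTimeSeries) -> tuple[float, float]:
    """(R^2, RMSE) of a fit on the original scale of its series.

    Evaluated over the days the fit retained (FOFC/dE exclusions honoured).
    """
    days = np.asarray(series.days, dtype=float)
    values = np.asarray(series.values, dtype=float)
    keep = ~np.isin(days, np.asarray(fit.excluded_days, dtype=float))
    return _gof(values[keep], np.asarray(fit.predict(days[keep])))


def select_model(fits: Sequence[KineticResults]) -> list[KineticResults]:
    """Rank candidate fits of one series: R^2 desc, RMSE, then parsimony.

    Fits whose R^2 is within 1e-6 of each other are treated as tied and
    ordered by lower RMSE, then by fewer parameters (zero < first < fofc).
    Degenerate fits (undefined R^2) sort last.
    """
    if len(fits) < 2:
        raise ValueError("select_model needs at least 2 candidate fits")

    def cmp(x: KineticResults, y: KineticResults) -> int:
        x_nan, y_nan = not np.isfinite(x.rsquared), not np.isfinite(y.rsquared)
        if x_nan or y_nan:
            return (x_nan > y_nan) - (x_nan < y_nan)
        if abs(x.rsquared - y.rsquared) >= 1e-6:
            return -1 if x.rsquared > y.rsquared else 1
        if x.rmse != y.rmse:
            return -1 if x.rmse < y.rmse else 1
        rx, ry = _PARAM_RANK.get(x.model, 99), _PARAM_RANK.get(y.model, 99)
        return (rx > ry) - (rx < ry)

    return sorted(fits, key=functools.cmp_to_key(cmp))
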