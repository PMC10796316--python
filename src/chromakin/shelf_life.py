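"""Shelf-life prediction by inverting fitted color kinetics at a threshold.

The predicted shelf-life (PSL) is the storage time at which the fitted
kinetic curve crosses a user-supplied quality threshold C_t:

* zero order    PSL = |C_t - C0| / k
* first order   PSL = |ln C_t - ln C0| / k
* FOFC          PSL = -ln(1 - f*) / k,  f* = (C0 - C_t) / (C0 - Cinf)

Thresholds are deliberately mandatory inputs — an acceptability limit is a
product decision, not a property of the data — and may be given either in
attribute units or as a fraction of the fitted initial value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .kinetics import KineticResults

__all__ = ["ShelfLifePrediction", "UnreachableThresholdError", "predict_shelf_life", "psl_table"]


class UnreachableThresholdError(ValueError):
    """The threshold lies beyond the asymptote of the fitted model."""


@dataclass(frozen=True)
class ShelfLifePrediction:
    """Predicted shelf-life for one (treatment, attribute, model) fit."""

    treatment: str | None
    attribute: str | None
    model: str
    threshold: float
    C0_used: float
    k_used: float
    psl_days: float
    warning: str | None = None

    def to_dict(self) -> dict:
        return {
            "treatment": self.treatment,
            "attribute": self.attribute,
            "model": self.model,
            "threshold": self.threshold,
            "C0_used": self.C0_used,
            "k_used": self.k_used,
            "psl_days": self.psl_days,
            "warning": self.warning,
        }


def predict_shelf_life(fit: KineticResults, threshold: float) -> ShelfLifePrediction:
    """Invert a fitted kinetic model at a quality threshold.

    The fit's decay/growth direction resolves the sign so PSL >= 0.  A
    threshold already passed at t = 0 yields PSL 0 with a warning; a
    threshold beyond the FOFC plateau (or non-positive for a first-order
    decay) raises :class:`UnreachableThresholdError`; k = 0 yields an
    infinite shelf-life flag.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    c0, k = fit.c0, fit.k
    decay = fit.direction == "decay"

    def result(psl: float, warning: str | None = None) -> ShelfLifePrediction:
        return ShelfLifePrediction(
            treatment=fit.treatment,
            attribute=fit.attribute,
            model=fit.model,
            threshold=threshold,
            C0_used=c0,
            k_used=k,
            psl_days=psl,
            warning=warning,
        )

    if threshold == c0:
        return result(0.0)
    already_past = threshold > c0 if decay else threshold < c0
    if already_past:
        return result(0.0, warning="threshold already passed at day 0")
    if k == 0:
        return result(math.inf, warning="k = 0: attribute never reaches the threshold")

    if fit.model == "zero":
        return result(abs(threshold - c0) / k)
    if fit.model == "first":
        if threshold <= 0 or c0 <= 0:
            raise UnreachableThresholdError(
                "first-order kinetics never cross a non-positive threshold"
            )
        return result(abs(math.log(threshold) - math.log(c0)) / k)
    if fit.model == "fofc":
        if fit.cinf is None:
            raise ValueError("FOFC fit is missing Cinf")
        f_star = (c0 - threshold) / (c0 - fit.cinf)
        if f_star >= 1.0:
            raise UnreachableThresholdError(
                f"threshold {threshold} lies beyond the FOFC plateau Cinf={fit.cinf:.6g}"
            )
        return result(-math.log1p(-f_star) / k)
    raise ValueError(f"unknown kinetic model {fit.model!r}")


def resolve_threshold(spec: float | Mapping[str, float], c0: float) -> float:
    """A threshold given directly or as ``{"fraction_of_C0": x}``."""
    if isinstance(spec, Mapping):
        if set(spec) != {"fraction_of_C0"}:
            raise ValueError(f"unrecognised threshold spec {spec!r}")
        return float(spec["fraction_of_C0"]) * c0
    return float(spec)


def psl_table(
    fits: Sequence[KineticResults],
    thresholds: Mapping[str, float | Mapping[str, float]],
) -> pd.DataFrame:
    """Shelf-life predictions for every fit whose attribute has a threshold.

    One row per (treatment, attribute, model) fit; within each attribute
    rows are sorted by predicted days, longest shelf-life first.  A fit
    whose attribute appears in ``thresholds`` but cannot be inverted
    (unreachable threshold) is reported with NaN days and a warning.
    """
    requested = {f.attribute for f in fits if f.attribute is not None}
    missing = requested - set(thresholds)
    if missing:
        raise KeyError(
            f"no threshold configured for requested attribute(s) {sorted(missing)}"
        )
    rows = []
    for fit in fits:
        thr = resolve_threshold(thresholds[fit.attribute], fit.c0)
        try:
            pred = predict_shelf_life(fit, thr)
            rows.append(pred.to_dict())
        except UnreachableThresholdError as exc:
            rows.append(
                {
                    "treatment": fit.treatment,
                    "attribute": fit.attribute,
                    "model": fit.model,
                    "threshold": thr,
                    "C0_used": fit.c0,
                    "k_used": fit.k,
                    "psl_days": math.nan,
                    "warning": str(exc),
                }
            )
    df = pd.DataFrame(rows)
    return (
        df.sort_values(["attribute", "psl_days"], ascending=[True, False])
        .reset_index(drop=True)
    )
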