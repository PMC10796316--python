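"""Derived color attributes and tidy per-treatment time series.

Per-image :class:`~chromakin.imaging.ColorMeasurement` records are turned
into ordered trajectories of a single attribute (L*, a*, b*, hue angle H*,
or total color difference dE) versus storage day, the form the kinetic
models consume.  Hue and dE are computed per replicate before averaging;
the dE reference is each replicate's own day-0 measurement, so every dE
trajectory starts at exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .imaging import ColorMeasurement

__all__ = [
    "ColorTimeSeries",
    "AcidityInputs",
    "ATTRIBUTES",
    "delta_e",
    "hue_angle",
    "build_time_series",
    "titratable_acidity",
]

ATTRIBUTES = ("L", "a", "b", "H", "dE")


@dataclass(frozen=True)
class ColorTimeSeries:
    """One attribute of one treatment over storage days (replicate-averaged)."""

    attribute: str
    treatment: str
    days: tuple[float, ...]
    values: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.attribute not in ATTRIBUTES:
            raise ValueError(f"attribute must be one of {ATTRIBUTES}, got {self.attribute!r}")
        if len(self.values) != len(self.days) or len(self.sds) != len(self.days):
            raise ValueError("days, values and sds must have equal length")
        d = np.asarray(self.days, dtype=float)
        if len(d) >= 2 and not np.all(np.diff(d) > 0):
            raise ValueError("days must be strictly increasing")

    def __len__(self) -> int:
        return len(self.days)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "treatment": self.treatment,
                "attribute": self.attribute,
                "day": self.days,
                "value": self.values,
                "sd": self.sds,
            }
        )


@dataclass(frozen=True)
class AcidityInputs:
    """Inputs to the titratable-acidity titration formula.

    ``equivalent_weight`` is the equivalent weight of the NaOH titrant in
    g/eq (40 for NaOH), following the source formulation of the assay.
    """

    titre_value: float  # mL of NaOH consumed
    normality: float  # eq/L
    v1: float  # mL, volume of mixture
    v2: float  # mL, volume of extract
    equivalent_weight: float  # g/eq
    sample_weight: float  # g

    def __post_init__(self) -> None:
        if self.titre_value < 0:
            raise ValueError("titre_value must be >= 0")
        for name in ("normality", "v1", "v2", "equivalent_weight", "sample_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def delta_e(meas: Sequence[float], ref: Sequence[float]) -> float:
    """Total color difference: Euclidean distance between two CIELAB triplets."""
    m = np.asarray(meas, dtype=float)
    r = np.asarray(ref, dtype=float)
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(r))):
        raise ValueError("CIELAB triplets must be finite")
    return float(np.linalg.norm(m - r))


def hue_angle(a: float, b: float) -> float:
    """Hue angle of the (a*, b*) chroma pair, in degrees in [0, 360).

    Uses the quadrant-aware arctangent: fresh fruit surfaces sit in the
    second quadrant (a* < 0, b* > 0), where a naive arctan(b*/a*) is wrong
    by 180 degrees.
    """
    if a == 0 and b == 0:
        raise ValueError("hue angle is undefined at a* = b* = 0")
    return float(np.degrees(np.arctan2(b, a)) % 360.0)


def titratable_acidity(x: AcidityInputs) -> float:
    """Percent acidity from an NaOH titration.

    ``(titre x normality x V1 x E x 100) / (V2 x W x 1000)``.
    """
    return (
        x.titre_value * x.normality * x.v1 * x.equivalent_weight * 100.0
    ) / (x.v2 * x.sample_weight * 1000.0)


def _attribute_value(m: ColorMeasurement, attribute: str, ref: ColorMeasurement | None) -> float:
    if attribute == "L":
        return m.L_mean
    if attribute == "a":
        return m.a_mean
    if attribute == "b":
        return m.b_mean
    if attribute == "H":
        return hue_angle(m.a_mean, m.b_mean)
    if attribute == "dE":
        assert ref is not None
        return delta_e((m.L_mean, m.a_mean, m.b_mean), (ref.L_mean, ref.a_mean, ref.b_mean))
    raise ValueError(f"unknown attribute {attribute!r}")


def build_time_series(
    measurements: Iterable[ColorMeasurement], attribute: str
) -> ColorTimeSeries:
    """Assemble a replicate-averaged attribute trajectory from measurements.

    All measurements must share one treatment.  Duplicate (day, replicate)
    pairs are rejected.  H and dE are computed per replicate and then
    averaged; the dE reference is the same replicate's day-0 record.
    """
    ms = list(measurements)
    if not ms:
        raise ValueError("no measurements supplied")
    treatments = {m.treatment for m in ms}
    if len(treatments) != 1:
        raise ValueError(f"measurements span multiple treatments: {sorted(treatments)}")
    treatment = ms[0].treatment

    seen: set[tuple[int, int]] = set()
    for m in ms:
        key = (m.day, m.replicate)
        if key in seen:
            raise ValueError(
                f"duplicate measurement for treatment {treatment!r}, day {m.day}, "
                f"replicate {m.replicate}"
            )
        seen.add(key)

    refs: dict[int, ColorMeasurement] = {}
    if attribute == "dE":
        first_day = min(m.day for m in ms)
        if first_day != 0:
            raise ValueError("dE series requires day-0 measurements as the reference")
        refs = {m.replicate: m for m in ms if m.day == 0}
        missing = {m.replicate for m in ms} - set(refs)
        if missing:
            raise ValueError(f"replicates {sorted(missing)} lack a day-0 reference for dE")

    per_day: dict[int, list[float]] = {}
    for m in ms:
        per_day.setdefault(m.day, []).append(
            _attribute_value(m, attribute, refs.get(m.replicate))
        )
    days = sorted(per_day)
    values = [float(np.mean(per_day[d])) for d in days]
    sds = [float(np.std(per_day[d], ddof=1)) if len(per_day[d]) > 1 else 0.0 for d in days]
    return ColorTimeSeries(
        attribute=attribute,
        treatment=treatment,
        days=tuple(float(d) for d in days),
        values=tuple(values),
        sds=tuple(sds),
    )


def series_from_frame(df: pd.DataFrame) -> list[ColorTimeSeries]:
    """Rebuild ColorTimeSeries objects from a tidy long-format table."""
    out = []
    for (treatment, attribute), grp in df.groupby(["treatment", "attribute"], sort=False):
        grp = grp.sort_values("day")
        out.append(
            ColorTimeSeries(
                attribute=str(attribute),
                treatment=str(treatment),
                days=tuple(float(d) for d in grp["day"]),
                values=tuple(float(v) for v in grp["value"]),
                sds=tuple(float(s) for s in grp["sd"]),
            )
        )
    return out
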