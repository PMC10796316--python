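"""Synthetic browning data: ground-truth color trajectories and rendered images.

The generator emulates the structure of a cold-storage browning study on
coated fruit slices: a cohort of 13 treatments (an uncoated control plus
three herb-extract coatings applied by spray or by 2/4/6-minute dip),
each photographed on days 0, 3, 6, 9, 12 and 15 in 3 replicates.  Per
treatment, each CIELAB attribute follows a chosen kinetic law:

* L* (lightness) decays first-order from ~91 toward the high 60s for the
  gentlest coatings and to ~42 for the harshest,
* a* (green-to-red) rises by first-order fractional conversion from
  slightly negative values toward a brown plateau near +17,
* b* (yellowness) grows zero-order from ~24 to ~40,

one law from each family so model selection is exercised end to end.
Scenes are uniform discs of the (possibly noise-perturbed) trajectory
color on a near-white background, with optional per-pixel Gaussian noise;
every image carries a sidecar record of the exact generating parameters.

All randomness flows through one seeded ``numpy`` generator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
from PIL import Image

from .imaging import RGBImage, lab_to_rgb
from .kinetics import evaluate_kinetic_law

__all__ = [
    "AttributeLaw",
    "TrajectorySpec",
    "SimulatedTrajectory",
    "SyntheticScene",
    "DatasetConfig",
    "default_cohort",
    "simulate_trajectory",
    "render_slice_image",
    "generate_dataset",
]

DEFAULT_DAYS = (0.0, 3.0, 6.0, 9.0, 12.0, 15.0)


@dataclass(frozen=True)
class AttributeLaw:
    """Kinetic law generating one attribute: family, C0, k and (FOFC) Cinf."""

    model: Literal["zero", "first", "fofc"]
    c0: float
    k: float
    cinf: float | None = None
    direction: Literal["decay", "growth"] = "decay"

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("rate constant k must be >= 0")
        if self.model == "fofc":
            if self.cinf is None:
                raise ValueError("fofc law requires cinf")
            if self.cinf == self.c0:
                raise ValueError("fofc law requires cinf != c0")

    def curve(self, days) -> np.ndarray:
        return np.asarray(
            evaluate_kinetic_law(
                self.model, days, c0=self.c0, k=self.k, direction=self.direction, cinf=self.cinf
            )
        )

    def crossing_day(self, threshold: float) -> float:
        """Exact day the noise-free law reaches ``threshold`` (ground truth)."""
        if self.model == "zero":
            return abs(threshold - self.c0) / self.k
        if self.model == "first":
            return abs(math.log(threshold) - math.log(self.c0)) / self.k
        f_star = (self.c0 - threshold) / (self.c0 - self.cinf)
        return -math.log1p(-f_star) / self.k

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "c0": self.c0,
            "k": self.k,
            "cinf": self.cinf,
            "direction": self.direction,
        }


@dataclass(frozen=True)
class TrajectorySpec:
    """Generating laws, sampling grid and noise model for one treatment."""

    laws: Mapping[str, AttributeLaw]
    days: tuple[float, ...] = DEFAULT_DAYS
    noise_sd: float = 0.5
    replicates: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.days, dtype=float)
        if len(d) < 2 or not np.all(np.diff(d) > 0):
            raise ValueError("days must be a strictly increasing grid")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if "L" in self.laws:
            curve = self.laws["L"].curve(d)
            if curve.min() <= 0 or curve.max() > 100:
                raise ValueError(
                    f"L* law drives lightness outside (0, 100]: range "
                    f"[{curve.min():.3g}, {curve.max():.3g}]"
                )


@dataclass(frozen=True)
class SimulatedTrajectory:
    """Noise-free truth curves plus per-replicate noisy observations."""

    days: tuple[float, ...]
    truth: Mapping[str, np.ndarray]
    replicates: Mapping[str, np.ndarray]  # attr -> (n_reps, n_days)
    spec: TrajectorySpec


@dataclass(frozen=True)
class SyntheticScene:
    """One rendered slice image together with its exact generating color."""

    image: RGBImage
    truth_lab: tuple[float, float, float]
    meta: Mapping[str, object]
    pixel_noise_sd: float
    geometry: tuple[int, int, int]  # center_row, center_col, radius
    background: tuple[int, int, int]


def simulate_trajectory(
    spec: TrajectorySpec, rng: np.random.Generator | None = None
) -> SimulatedTrajectory:
    """Evaluate each attribute's law on the day grid and add replicate noise.

    Deterministic given the spec's seed (or a caller-supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    days = np.asarray(spec.days, dtype=float)
    truth: dict[str, np.ndarray] = {}
    reps: dict[str, np.ndarray] = {}
    for attr in sorted(spec.laws):
        curve = spec.laws[attr].curve(days)
        truth[attr] = curve
        noise = rng.normal(0.0, spec.noise_sd, size=(spec.replicates, len(days)))
        reps[attr] = curve[None, :] + noise
    return SimulatedTrajectory(
        days=tuple(float(d) for d in days), truth=truth, replicates=reps, spec=spec
    )


def render_slice_image(
    truth_lab,
    *,
    frame: tuple[int, int] = (140, 200),
    center: tuple[int, int] | None = None,
    radius: int = 50,
    pixel_noise_sd: float = 2.0,
    background: tuple[int, int, int] = (250, 250, 250),
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    meta: Mapping[str, object] | None = None,
    clip_gamut: bool = False,
) -> SyntheticScene:
    """Render a uniform disc of a CIELAB color on a near-white background.

    The disc color is the sRGB rendering of ``truth_lab`` (raises a gamut
    error naming the channel if unrepresentable); per-pixel Gaussian noise
    in 8-bit units is added and clipped to [0, 255].
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    h, w = frame
    cy, cx = center if center is not None else (h // 2, w // 2)
    if cy - radius < 0 or cy + radius >= h or cx - radius < 0 or cx + radius >= w:
        raise ValueError(f"disc (center ({cy},{cx}), radius {radius}) not inside {h}x{w} frame")
    disc_rgb = lab_to_rgb(np.asarray(truth_lab, dtype=float), clip_gamut=clip_gamut)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(background, dtype=np.float64)
    rr, cc = np.ogrid[:h, :w]
    mask = (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2
    img[mask] = disc_rgb
    if pixel_noise_sd > 0:
        img += rng.normal(0.0, pixel_noise_sd, size=img.shape)
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return SyntheticScene(
        image=RGBImage(pixels=pixels),
        truth_lab=tuple(float(v) for v in np.asarray(truth_lab, dtype=float)),
        meta=dict(meta or {}),
        pixel_noise_sd=pixel_noise_sd,
        geometry=(cy, cx, radius),
        background=background,
    )


def _fofc_rate(c0: float, c15: float, cinf: float, horizon: float = 15.0) -> float:
    """Rate constant putting the FOFC curve through (horizon, c15)."""
    f = (c0 - c15) / (c0 - cinf)
    return -math.log1p(-f) / horizon


def _first_rate(c0: float, c15: float, horizon: float = 15.0) -> float:
    return math.log(c0 / c15) / horizon


def default_cohort() -> dict[str, dict[str, AttributeLaw]]:
    """Generating laws for the 13-treatment default cohort.

    Calibrated to the qualitative structure of refrigerated pear-slice
    browning: spray coatings keep L* near 67.5 at day 15, dip coatings
    fall to the low 50s or to 42, the uncoated control browns fastest;
    a* rises from slightly negative starts toward a plateau near +17-20;
    b* climbs roughly linearly from the mid 20s to ~40.
    """

    def laws(L0, L15, a0, a15, a_inf, b0, b15) -> dict[str, AttributeLaw]:
        return {
            "L": AttributeLaw("first", L0, _first_rate(L0, L15), direction="decay"),
            "a": AttributeLaw("fofc", a0, _fofc_rate(a0, a15, a_inf), cinf=a_inf),
            "b": AttributeLaw("zero", b0, (b15 - b0) / 15.0, direction="growth"),
        }

    return {
        # uncoated control: fastest browning of the cohort
        "control": laws(91.0, 38.0, -3.0, 18.0, 20.5, 24.0, 39.0),
        # spray coatings (gentlest): L* 91 -> ~67.5
        "greentea-spray": laws(91.0, 69.5, -4.5, 15.5, 18.5, 25.0, 38.5),
        "basil-spray": laws(91.0, 67.5, -1.5, 17.0, 20.0, 24.5, 40.0),
        "oregano-spray": laws(91.0, 65.5, -2.5, 13.0, 16.0, 24.0, 39.0),
        # 2-minute dips: L* 90.5 -> ~52
        "greentea-dip2": laws(90.5, 54.0, -3.2, 15.0, 18.0, 24.5, 39.5),
        "basil-dip2": laws(90.5, 52.0, -3.0, 15.5, 18.5, 24.5, 40.0),
        "oregano-dip2": laws(90.5, 50.5, -3.1, 14.0, 17.0, 24.0, 40.5),
        # 4-minute dips: L* 85.5 -> ~51
        "greentea-dip4": laws(85.5, 52.5, -3.3, 15.5, 18.5, 24.5, 39.5),
        "basil-dip4": laws(85.5, 51.0, -3.4, 15.0, 18.0, 24.5, 40.0),
        "oregano-dip4": laws(85.5, 49.5, -3.2, 14.5, 17.5, 24.0, 40.5),
        # 6-minute dips (harshest coating): L* 87 -> ~42
        "greentea-dip6": laws(87.0, 44.5, -3.0, 16.1, 19.0, 25.0, 39.5),
        "basil-dip6": laws(87.0, 42.0, -3.5, 14.5, 17.5, 24.5, 40.0),
        "oregano-dip6": laws(87.0, 40.5, -3.5, 14.5, 17.5, 24.0, 40.5),
    }


@dataclass
class DatasetConfig:
    """Configuration for a full synthetic study."""

    treatments: Mapping[str, Mapping[str, AttributeLaw]] = field(default_factory=default_cohort)
    days: tuple[float, ...] = DEFAULT_DAYS
    replicates: int = 3
    traj_noise_sd: float = 0.5
    pixel_noise_sd: float = 2.0
    image_format: Literal["png", "jpeg"] = "png"
    jpeg_quality: int = 95
    frame: tuple[int, int] = (140, 200)
    radius: int = 50
    background: tuple[int, int, int] = (250, 250, 250)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DatasetConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        treatments = raw.pop("treatments", None)
        cfg = {}
        for key in (
            "days",
            "replicates",
            "traj_noise_sd",
            "pixel_noise_sd",
            "image_format",
            "jpeg_quality",
            "frame",
            "radius",
            "background",
            "seed",
        ):
            if key in raw:
                cfg[key] = raw[key]
        for key in ("days", "frame", "background"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        if treatments is not None:
            cfg["treatments"] = {
                name: {attr: AttributeLaw(**law) for attr, law in attrs.items()}
                for name, attrs in treatments.items()
            }
        return cls(**cfg)


def generate_dataset(
    config: DatasetConfig, out_dir: str | Path, *, force: bool = False
) -> Path:
    """Write a full synthetic study: images, manifest CSV and truth JSON.

    Default configuration: 13 treatments x 6 days x 3 replicates = 234
    PNG images.  Two runs with the same config and seed are byte-identical.
    Returns the path of the manifest.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out_dir} exists and is not empty (use force=True)"
        )
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest_rows = []
    truth: dict = {
        "days": list(config.days),
        "replicates": config.replicates,
        "traj_noise_sd": config.traj_noise_sd,
        "pixel_noise_sd": config.pixel_noise_sd,
        "seed": config.seed,
        "treatments": {},
    }
    ext = "png" if config.image_format == "png" else "jpg"
    for name in sorted(config.treatments):
        spec = TrajectorySpec(
            laws=config.treatments[name],
            days=config.days,
            noise_sd=config.traj_noise_sd,
            replicates=config.replicates,
        )
        sim = simulate_trajectory(spec, rng)
        truth["treatments"][name] = {
            "laws": {attr: law.to_dict() for attr, law in spec.laws.items()},
            "truth_curves": {attr: list(map(float, c)) for attr, c in sim.truth.items()},
        }
        for rep in range(1, config.replicates + 1):
            for j, day in enumerate(config.days):
                lab = [sim.replicates[attr][rep - 1, j] for attr in ("L", "a", "b")]
                scene = render_slice_image(
                    lab,
                    frame=config.frame,
                    radius=config.radius,
                    pixel_noise_sd=config.pixel_noise_sd,
                    background=config.background,
                    rng=rng,
                    meta={"treatment": name, "day": day, "replicate": rep},
                    clip_gamut=True,
                )
                fname = f"{name}_d{int(day):02d}_r{rep}.{ext}"
                path = out_dir / "images" / fname
                im = Image.fromarray(scene.image.pixels)
                if config.image_format == "png":
                    im.save(path, format="PNG")
                else:
                    im.save(path, format="JPEG", quality=config.jpeg_quality)
                manifest_rows.append(
                    {
                        "path": str(Path("images") / fname),
                        "treatment": name,
                        "day": int(day),
                        "replicate": rep,
                    }
                )
    import pandas as pd

    manifest = out_dir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest, index=False)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return manifest
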