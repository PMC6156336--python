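"""Simulation configuration: distance models, expression models, optics, noise.

A :class:`SimConfig` fully determines one synthetic embryo field (including
its random seed), so identical configs produce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml
from shapely.geometry import Polygon, box

from .stack_io import STAGE_CLASSES

#: FISH channel labels in locus order A, B, C (dyes used for triple labelling)
FISH_CHANNELS = ("A488", "A555", "A647")

#: locus-pair keys, matching the channel order above
PAIRS = ("ab", "bc", "ac")


class ConfigError(ValueError):
    """Raised when a simulation config violates its invariants."""


@dataclass
class DistanceModel:
    """Distribution of a pairwise locus distance (nm) within one parasegment.

    Families: ``constant`` (point mass at ``loc``), ``normal`` (mean ``loc``,
    sd ``scale``, truncated to [0, upper]), ``lognormal`` (``loc`` = median,
    ``scale`` = sigma of log), ``uniform`` (on [loc - scale, loc + scale]).
    ``upper`` defaults to 1500 nm, the support of measured distance
    distributions (the triplet acceptance rule discards anything larger).
    """

    family: str = "normal"
    loc: float = 400.0
    scale: float = 100.0
    upper: float = 1500.0

    def __post_init__(self) -> None:
        if self.family not in ("constant", "normal", "lognormal", "uniform"):
            raise ConfigError(f"unknown distance distribution family {self.family!r}")
        if self.loc < 0 or self.scale < 0 or self.upper <= 0:
            raise ConfigError("distance model parameters must be non-negative, upper > 0")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        out = self.draw_raw(rng, n)
        # redraw out-of-support values (truncation by rejection, not clipping,
        # so the configured median survives for symmetric families)
        bad = (out < 0) | (out > self.upper)
        tries = 0
        while np.any(bad):
            out[bad] = self.draw_raw(rng, int(bad.sum()))
            bad = (out < 0) | (out > self.upper)
            tries += 1
            if tries > 1000:
                raise ConfigError("distance model support [0, upper] has negligible mass")
        return out

    def draw_raw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "constant":
            return np.full(n, float(self.loc))
        if self.family == "normal":
            return rng.normal(self.loc, self.scale, size=n)
        if self.family == "lognormal":
            return self.loc * np.exp(rng.normal(0.0, self.scale, size=n))
        return rng.uniform(self.loc - self.scale, self.loc + self.scale, size=n)


@dataclass
class NoiseModel:
    """Confocal noise: Poisson shot noise plus Gaussian read noise.

    ``photons_per_unit`` scales intensities to photon counts before Poisson
    resampling (0 disables shot noise); ``background`` is an additive offset
    (intensity units) applied before the Poisson step; ``read_sigma`` is the
    sd of additive Gaussian readout noise. All zeros yield a clean image.
    """

    photons_per_unit: float = 0.0
    background: float = 0.0
    read_sigma: float = 0.0

    def __post_init__(self) -> None:
        if min(self.photons_per_unit, self.background, self.read_sigma) < 0:
            raise ConfigError("noise parameters must be >= 0")

    @property
    def is_clean(self) -> bool:
        return self.photons_per_unit == 0 and self.background == 0 and self.read_sigma == 0

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = img + self.background
        if self.photons_per_unit > 0:
            out = rng.poisson(out * self.photons_per_unit) / self.photons_per_unit
        if self.read_sigma > 0:
            out = out + rng.normal(0.0, self.read_sigma, size=out.shape)
        return np.clip(out, 0.0, None)


@dataclass
class SimConfig:
    """Everything needed to simulate one embryo field deterministically.

    Geometry defaults follow DNA FISH acquisition (73 nm xy pixels, 300 nm
    z-step); parasegment polygons are xy-pixel rectangles tiled along the
    anteroposterior axis unless given explicitly.
    """

    seed: int = 0
    field_size: tuple[int, int, int] = (192, 128, 24)  # (nx, ny, nz) voxels
    voxel_size_xy: float = 73.0  # nm
    voxel_size_z: float = 300.0  # nm
    parasegments: list[tuple[str, np.ndarray]] = dc_field(default_factory=list)
    nuclei_per_ps: int = 10
    nucleus_radius: float = 1500.0  # nm
    distance_model: dict = dc_field(default_factory=dict)  # (ps, pair) or pair -> DistanceModel
    expression_model: dict = dc_field(default_factory=dict)  # (ps, gene) or gene -> fraction
    genes: tuple[str, ...] = ()
    chromatic_shift: dict = dc_field(default_factory=dict)  # channel -> (dx, dy, dz) nm
    psf_sigma_xy: float = 150.0  # nm
    psf_sigma_z: float = 400.0  # nm
    spot_amplitude: float = 100.0  # peak intensity units
    noise: NoiseModel = dc_field(default_factory=NoiseModel)
    stage_class: str = STAGE_CLASSES[0]
    embryo_id: str = "sim"

    def __post_init__(self) -> None:
        nx, ny, nz = self.field_size
        if min(nx, ny, nz) < 1:
            raise ConfigError("field_size components must be >= 1")
        if not (self.voxel_size_xy > 0 and self.voxel_size_z > 0):
            raise ConfigError("voxel sizes must be > 0")
        if self.voxel_size_z < self.voxel_size_xy:
            raise ConfigError("voxel_size_z must be >= voxel_size_xy (axial anisotropy)")
        if self.nucleus_radius <= 0 or self.psf_sigma_xy <= 0 or self.psf_sigma_z <= 0:
            raise ConfigError("nucleus radius and PSF sigmas must be > 0")
        if self.stage_class not in STAGE_CLASSES:
            raise ConfigError(f"stage_class must be one of {STAGE_CLASSES}")
        if not self.parasegments:
            self.parasegments = tiled_parasegments(["PS0"], nx, ny)
        self._validate_parasegments()
        for frac in self._expression_fractions():
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("expression fractions must lie in [0, 1]")

    def _expression_fractions(self):
        return [v for v in self.expression_model.values()]

    def _validate_parasegments(self) -> None:
        nx, ny, _ = self.field_size
        frame = box(-0.5, -0.5, nx - 0.5, ny - 0.5)
        shapes = []
        for label, poly in self.parasegments:
            shape = Polygon(np.asarray(poly, dtype=float))
            if not shape.is_valid or shape.area <= 0:
                raise ConfigError(f"parasegment {label!r}: invalid polygon")
            if not frame.contains(shape):
                raise ConfigError(f"parasegment {label!r}: polygon outside the field")
            for other_label, other in shapes:
                if shape.intersection(other).area > 1e-9:
                    raise ConfigError(
                        f"parasegments {label!r} and {other_label!r} overlap")
            shapes.append((label, shape))

    # -- model lookups ------------------------------------------------------

    def distance_model_for(self, ps: str, pair: str) -> DistanceModel:
        """Resolve the distance model for (parasegment, pair) with fallbacks."""
        for key in ((ps, pair), pair):
            if key in self.distance_model:
                model = self.distance_model[key]
                return model if isinstance(model, DistanceModel) else DistanceModel(**model)
        return DistanceModel()

    def expression_fraction_for(self, ps: str, gene: str) -> float:
        for key in ((ps, gene), gene):
            if key in self.expression_model:
                return float(self.expression_model[key])
        return 0.0

    def shift_for(self, channel: str) -> np.ndarray:
        return np.asarray(self.chromatic_shift.get(channel, (0.0, 0.0, 0.0)), dtype=float)

    @property
    def ps_labels(self) -> list[str]:
        return [label for label, _ in self.parasegments]


def tiled_parasegments(labels: list[str], nx: int, ny: int,
                       margin_px: int = 2) -> list[tuple[str, np.ndarray]]:
    """Tile rectangular PS polygons left-to-right along the x (A/P) axis."""
    n = len(labels)
    if n == 0:
        raise ConfigError("need at least one parasegment label")
    width = (nx - 2 * margin_px) / n
    out = []
    for i, label in enumerate(labels):
        x0 = margin_px + i * width
        x1 = margin_px + (i + 1) * width - 1e-6  # open seam keeps tiles disjoint
        y0, y1 = margin_px, ny - 1 - margin_px
        out.append((label, np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])))
    return out


# ---------------------------------------------------------------------------
# YAML config files (nested key-value sections)


def load_sim_config(path) -> SimConfig:
    """Load a :class:`SimConfig` from a YAML file.

    Section layout mirrors the dataclass; ``distance_model`` and
    ``expression_model`` keys may be "pair", "ps/pair", "gene" or "ps/gene"
    strings (the slash separates parasegment from pair/gene).
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return sim_config_from_dict(raw)


def sim_config_from_dict(raw: dict) -> SimConfig:
    raw = dict(raw)
    if "seed" not in raw:
        raise ConfigError("config must state an explicit seed")
    if "field_size" in raw:
        raw["field_size"] = tuple(raw["field_size"])
    if "noise" in raw and isinstance(raw["noise"], dict):
        raw["noise"] = NoiseModel(**raw["noise"])
    if "genes" in raw:
        raw["genes"] = tuple(raw["genes"])
    for section in ("distance_model", "expression_model"):
        if section in raw:
            parsed = {}
            for key, value in raw[section].items():
                parts = str(key).split("/")
                new_key = tuple(parts) if len(parts) == 2 else parts[0]
                if section == "distance_model" and isinstance(value, dict):
                    value = DistanceModel(**value)
                parsed[new_key] = value
            raw[section] = parsed
    if "parasegments" in raw:
        ps = raw["parasegments"]
        if ps and isinstance(ps[0], str):
            nx, ny, _ = raw.get("field_size", SimConfig.field_size)
            raw["parasegments"] = tiled_parasegments(ps, nx, ny)
        else:
            raw["parasegments"] = [(label, np.asarray(poly, dtype=float))
                                   for label, poly in ps]
    return SimConfig(**raw)
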