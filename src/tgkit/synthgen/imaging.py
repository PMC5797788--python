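"""Synthetic dentate-gyrus FISH z-stacks with known ground truth.

A stack is rendered as laminar bands (granule cell layer and molecular
layers) of distinct base labeling intensity, Poisson-placed diffraction-
limited mRNA puncta (2-D Gaussians spread across z slices), an optional
circular transcription-block region whose intensity is scaled by the
remaining fraction f (with a darker damaged core around the pipette track,
which quantification excludes), and detector noise (Poisson shot + Gaussian
read), in that order — so the planted f is exact before noise.

Three presets mirror the imaging designs:

* ``puncta_field``  — 63x confocal field (204.8 um side, 0.2 um/px) for
  dendritic puncta counting;
* ``lamina_field``  — 20x field with GCL/IML/MML/OML bands for line profiles;
* ``actd_field``    — 20x field with a 400-um transcription-block region and
  150-um damage core for decay-ratio measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ..fish_quant import ImageStack


@dataclass(frozen=True)
class BandSpec:
    name: str
    width_um: float
    puncta_density: float   # puncta per um^2
    level: float            # base labeling intensity (photons)


@dataclass(frozen=True)
class DecayRegionSpec:
    center_um: tuple[float, float] | None = None   # None = field centre
    diameter_um: float = 400.0
    core_diameter_um: float = 150.0
    remaining_fraction: float = 0.75
    core_level_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 < self.remaining_fraction <= 1.0):
            raise ValueError("remaining fraction must be in (0, 1]")
        if self.core_diameter_um >= self.diameter_um:
            raise ValueError("damage core must be smaller than the region")


@dataclass
class FishImageSpec:
    side_um: float = 204.8
    um_per_px: float = 0.2
    n_slices: int = 4
    z_step_um: float = 0.55
    background_level: float = 20.0
    bands: tuple[BandSpec, ...] = ()
    bands_start_um: float = 0.0
    puncta_amplitude: float = 80.0
    psf_sigma_um: float = 0.25
    psf_sigma_z_um: float = 0.45
    shot_noise: bool = True
    read_noise_sd: float = 2.0
    min_separation_um: float = 0.0
    puncta_positions: Sequence[tuple[float, float, float]] | None = None
    decay_region: DecayRegionSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1 or self.z_step_um <= 0:
            raise ValueError("need >= 1 slice with a positive z step")
        if self.bands and (
            self.bands_start_um + sum(b.width_um for b in self.bands) > self.side_um
        ):
            raise ValueError("bands exceed the field")
        if self.decay_region is not None:
            r = self.decay_region
            cx, cy = r.center_um or (self.side_um / 2, self.side_um / 2)
            half = r.diameter_um / 2
            if (cx - half < 0 or cy - half < 0
                    or cx + half > self.side_um or cy + half > self.side_um):
                raise ValueError("decay region extends outside the field")

    @property
    def z_range_um(self) -> float:
        return (self.n_slices - 1) * self.z_step_um

    @classmethod
    def puncta_field(cls, density: float = 0.005, **kw) -> "FishImageSpec":
        kw.setdefault("bands", (BandSpec("stratum_radiatum", 204.8, density, 20.0),))
        return cls(**kw)

    @classmethod
    def lamina_field(cls, **kw) -> "FishImageSpec":
        # 20x wide-field acquisition: a single optical plane, not a z-stack.
        kw.setdefault("n_slices", 1)
        kw.setdefault("side_um", 409.6)
        kw.setdefault("um_per_px", 0.8)
        kw.setdefault("psf_sigma_um", 0.6)
        kw.setdefault("puncta_amplitude", 60.0)
        kw.setdefault("bands_start_um", 100.0)
        kw.setdefault(
            "bands",
            (
                BandSpec("GCL", 60.0, 0.05, 180.0),
                BandSpec("IML", 40.0, 0.02, 60.0),
                BandSpec("MML", 40.0, 0.08, 120.0),
                BandSpec("OML", 60.0, 0.02, 60.0),
            ),
        )
        return cls(**kw)

    @classmethod
    def actd_field(cls, remaining_fraction: float = 0.75, **kw) -> "FishImageSpec":
        """Transcription-block field; the 60-min transgenic default leaves 75%
        of the surround level inside the region of blockade."""
        # 20x wide-field acquisition: a single optical plane, not a z-stack.
        kw.setdefault("n_slices", 1)
        kw.setdefault("side_um", 819.2)
        kw.setdefault("um_per_px", 1.6)
        kw.setdefault("psf_sigma_um", 1.0)
        kw.setdefault("puncta_amplitude", 60.0)
        kw.setdefault("bands", (BandSpec("dentate", 819.2, 0.01, 120.0),))
        kw.setdefault("decay_region", DecayRegionSpec(remaining_fraction=remaining_fraction))
        return cls(**kw)


@dataclass
class FishTruth:
    puncta: pd.DataFrame                 # x_um, y_um, z_um, band
    counts_per_band: dict[str, int]
    remaining_fraction: float | None


def _draw_positions(rng, band: BandSpec, y0: float, side: float, min_sep: float,
                    existing: list[tuple[float, float]]) -> list[tuple[float, float]]:
    n = rng.poisson(band.puncta_density * band.width_um * side)
    pts: list[tuple[float, float]] = []
    attempts = 0
    while len(pts) < n and attempts < 50 * n + 100:
        attempts += 1
        x = rng.uniform(0, side)
        y = rng.uniform(y0, y0 + band.width_um)
        if min_sep > 0 and any(
            (x - px) ** 2 + (y - py) ** 2 < min_sep**2 for px, py in existing + pts
        ):
            continue
        pts.append((x, y))
    return pts


def render_fish_stack(spec: FishImageSpec | None = None) -> tuple[ImageStack, FishTruth]:
    """Render a stack and return it with its ground truth."""
    spec = spec or FishImageSpec.puncta_field()
    rng = np.random.default_rng(spec.seed)
    npx = int(round(spec.side_um / spec.um_per_px))
    img = np.full((spec.n_slices, npx, npx), float(spec.background_level))

    # Laminar base levels.
    y0 = spec.bands_start_um
    band_rows: list[tuple[str, float, float]] = []
    for band in spec.bands:
        r0 = int(round(y0 / spec.um_per_px))
        r1 = int(round((y0 + band.width_um) / spec.um_per_px))
        img[:, r0:r1, :] = band.level
        band_rows.append((band.name, y0, y0 + band.width_um))
        y0 += band.width_um

    # Puncta placement.
    puncta: list[tuple[float, float, float, str]] = []
    if spec.puncta_positions is not None:
        for x, y, z in spec.puncta_positions:
            name = next((b for b, lo, hi in band_rows if lo <= y < hi), "background")
            puncta.append((x, y, z, name))
    else:
        placed: list[tuple[float, float]] = []
        y0 = spec.bands_start_um
        for band in spec.bands:
            pts = _draw_positions(rng, band, y0, spec.side_um,
                                  spec.min_separation_um, placed)
            placed += pts
            zs = rng.uniform(0, max(spec.z_range_um, 1e-9), size=len(pts))
            puncta += [(x, y, float(z), band.name) for (x, y), z in zip(pts, zs)]
            y0 += band.width_um

    # Stamp 2-D Gaussians distributed across z.
    sig = spec.psf_sigma_um / spec.um_per_px
    rad = max(2, int(math.ceil(4 * sig)))
    w = np.arange(-rad, rad + 1)
    z_slices = np.arange(spec.n_slices) * spec.z_step_um
    for x_um, y_um, z_um, _ in puncta:
        cx, cy = x_um / spec.um_per_px, y_um / spec.um_per_px
        ix, iy = int(round(cx)), int(round(cy))
        xs, ys = ix + w, iy + w
        mx = (xs >= 0) & (xs < npx)
        my = (ys >= 0) & (ys < npx)
        if not mx.any() or not my.any():
            continue
        gx = np.exp(-((xs[mx] - cx) ** 2) / (2 * sig**2))
        gy = np.exp(-((ys[my] - cy) ** 2) / (2 * sig**2))
        patch = np.outer(gy, gx)
        zamp = spec.puncta_amplitude * np.exp(
            -((z_slices - z_um) ** 2) / (2 * spec.psf_sigma_z_um**2)
        )
        for zi, a in enumerate(zamp):
            if a > 0.01 * spec.puncta_amplitude:
                img[zi, ys[my][:, None], xs[mx][None, :]] += a * patch

    # Transcription-block region, applied before noise.
    f = None
    if spec.decay_region is not None:
        reg = spec.decay_region
        f = reg.remaining_fraction
        cx_um, cy_um = reg.center_um or (spec.side_um / 2, spec.side_um / 2)
        yy, xx = np.mgrid[0:npx, 0:npx]
        r_um = np.hypot(xx - cx_um / spec.um_per_px, yy - cy_um / spec.um_per_px) * spec.um_per_px
        annulus = (r_um <= reg.diameter_um / 2) & (r_um > reg.core_diameter_um / 2)
        core = r_um <= reg.core_diameter_um / 2
        img[:, annulus] *= f
        img[:, core] *= reg.core_level_fraction

    if spec.shot_noise:
        img = rng.poisson(img).astype(float)
    if spec.read_noise_sd > 0:
        img = np.clip(img + rng.normal(0, spec.read_noise_sd, img.shape), 0, None)

    truth = FishTruth(
        puncta=pd.DataFrame(puncta, columns=["x_um", "y_um", "z_um", "band"]),
        counts_per_band={
            b.name: sum(1 for p in puncta if p[3] == b.name) for b in spec.bands
        },
        remaining_fraction=f,
    )
    return ImageStack(img, spec.um_per_px, spec.z_step_um), truth
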