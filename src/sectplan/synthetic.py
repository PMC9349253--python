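"""Synthetic phantoms: position-known blocks, noise, and section rendering.

Everything downstream (localization, planning, simulation, statistics) is
testable against these generators without any external data: the
three-targeted phantom with the reference positions, randomized blocks for
property sweeps, organ-scale frame presets, grid-quantized measurement
noise, and a deterministic raster rendering of a section over a 1 mm grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw

from .exceptions import ConfigError, GenerationError
from .geometry import BlockFrame, TargetCenter, plane_through_targets
from .localization import MEASUREMENT_GRID, quantize_measurement
from .sectioning import SectionObservation, TargetCut, VirtualBlock

#: default phantom target radius, µm — chosen so a 100 µm survey interval
#: yields ~10 positive sections per target
DEFAULT_RADIUS = 500.0

_COLORS = {
    "Red": (200, 30, 30),
    "Green": (30, 160, 30),
    "Blue": (30, 30, 200),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Serializable description of a synthetic block with ground truth."""

    frame: BlockFrame
    targets: tuple[tuple[str, tuple[float, float, float], float, str], ...]
    grid: float = MEASUREMENT_GRID
    seed: int | None = None

    def to_block(self) -> VirtualBlock:
        return VirtualBlock(
            self.frame,
            tuple(
                (TargetCenter(name, *center), radius)
                for name, center, radius, _color in self.targets
            ),
        )

    def to_dict(self) -> dict:
        return {
            "frame": self.frame.to_dict(),
            "targets": [
                {"name": n, "center_um": list(c), "radius_um": r, "color": col}
                for n, c, r, col in self.targets
            ],
            "grid_um": self.grid,
            "seed": self.seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(
            frame=BlockFrame.from_dict(d["frame"]),
            targets=tuple(
                (t["name"], tuple(map(float, t["center_um"])),
                 float(t["radius_um"]), t.get("color", "gray"))
                for t in d["targets"]
            ),
            grid=float(d.get("grid_um", MEASUREMENT_GRID)),
            seed=d.get("seed"),
        )

    @classmethod
    def from_block(cls, block: VirtualBlock, seed: int | None = None) -> "PhantomSpec":
        return cls(
            frame=block.frame,
            targets=tuple(
                (t.name, (t.x, t.y, t.z), r, t.name if t.name in _COLORS else "gray")
                for t, r in block.targets
            ),
            seed=seed,
        )


def make_three_target_model(radius: float = DEFAULT_RADIUS) -> VirtualBlock:
    """The position-known three-targeted phantom.

    Colored targets Red (2000, 1000, 4000), Green (8000, 3000, 5000) and
    Blue (5000, 7000, 6000) µm in a 10 x 10 x 8 mm frame; Blue is the
    deepest target.
    """
    frame = BlockFrame(10000.0, 10000.0, 8000.0)
    targets = (
        (TargetCenter("Red", 2000.0, 1000.0, 4000.0), radius),
        (TargetCenter("Green", 8000.0, 3000.0, 5000.0), radius),
        (TargetCenter("Blue", 5000.0, 7000.0, 6000.0), radius),
    )
    return VirtualBlock(frame, targets)


def make_random_block(
    n_targets: int = 3,
    frame: BlockFrame | None = None,
    radius_range: tuple[float, float] = (250.0, 500.0),
    seed: int | None = None,
    min_separation: float = 2500.0,
    min_xy_area: float = 2.0e6,
    depth_range: tuple[float, float] = (3000.0, 6500.0),
    max_tries: int = 1000,
) -> VirtualBlock:
    """A reproducible random block with well-separated, non-collinear targets.

    Targets are drawn uniformly inside the frame (margin = radius), with
    pairwise 3D separation at least ``min_separation`` and, for the first
    three targets, a footprint-triangle area of at least ``min_xy_area`` so
    the defined plane is well conditioned (never near-perpendicular to the
    block bottom).  Identical seeds give identical blocks.
    """
    if n_targets < 3:
        raise ConfigError("a block needs at least 3 targets to define a plane")
    if frame is None:
        frame = BlockFrame(10000.0, 10000.0, 8000.0)
    rng = np.random.default_rng(seed)
    lo_r, hi_r = radius_range
    for _ in range(max_tries):
        radii = rng.uniform(lo_r, hi_r, size=n_targets)
        margin = radii.max()
        xs = rng.uniform(margin, frame.footprint_x - margin, size=n_targets)
        ys = rng.uniform(margin, frame.footprint_y - margin, size=n_targets)
        z_lo = max(depth_range[0], margin)
        z_hi = min(depth_range[1], frame.height - margin)
        if z_hi <= z_lo:
            raise ConfigError("depth range incompatible with frame and radii")
        zs = rng.uniform(z_lo, z_hi, size=n_targets)
        pts = np.column_stack([xs, ys, zs])
        dists = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        if dists.min() < min_separation:
            continue
        v1 = pts[1, :2] - pts[0, :2]
        v2 = pts[2, :2] - pts[0, :2]
        if 0.5 * abs(v1[0] * v2[1] - v1[1] * v2[0]) < min_xy_area:
            continue
        targets = tuple(
            (TargetCenter(f"T{i + 1}", *pts[i]), float(radii[i]))
            for i in range(n_targets)
        )
        return VirtualBlock(frame, targets)
    raise GenerationError(
        f"could not place {n_targets} targets after {max_tries} tries"
    )


def make_organ_preset(name: str) -> VirtualBlock:
    """Organ-scale geometry fixtures: ``aortic_root``, ``orbit`` or ``thorax``.

    The frame dimensions are organ-scale (aortic root 6 x 6 x 5 mm, orbit
    12 x 8 x 6 mm, thorax 25 x 25 x 17 mm); the aortic root carries the
    three valve midpoints, the orbit the two optic-nerve endpoints (optic
    duct and eyeball connection), and the thorax the tracheal first-rib
    center and the bifurcation center.  Target placements are plausible
    in-frame geometry fixtures, not anatomical claims.
    """
    if name == "aortic_root":
        frame = BlockFrame(6000.0, 6000.0, 5000.0)
        targets = (
            (TargetCenter("left_valve", 2300.0, 3500.0, 2400.0), 300.0),
            (TargetCenter("right_valve", 3700.0, 3500.0, 2400.0), 300.0),
            (TargetCenter("posterior_valve", 3000.0, 2300.0, 2700.0), 300.0),
        )
    elif name == "orbit":
        frame = BlockFrame(12000.0, 8000.0, 6000.0)
        targets = (
            (TargetCenter("nerve_in_duct", 2500.0, 4000.0, 3000.0), 400.0),
            (TargetCenter("nerve_at_eyeball", 9000.0, 4200.0, 3600.0), 400.0),
        )
    elif name == "thorax":
        frame = BlockFrame(25000.0, 25000.0, 17000.0)
        targets = (
            (TargetCenter("trachea_first_rib", 12500.0, 8000.0, 6000.0), 600.0),
            (TargetCenter("trachea_bifurcation", 12500.0, 15000.0, 9000.0), 600.0),
        )
    else:
        raise ConfigError(
            f"unknown organ preset {name!r}; "
            "choose from aortic_root, orbit, thorax"
        )
    return VirtualBlock(frame, targets)


def add_measurement_noise(
    observations,
    grid: float = MEASUREMENT_GRID,
    jitter_sd: float = 0.0,
    seed: int | None = None,
):
    """Gaussian jitter followed by grid quantization on section (x, y) readings.

    Emulates reading target centroids off checked paper: the reading wobbles
    by ``jitter_sd`` µm and is then snapped to the nearest ``grid`` multiple.
    Seeded and reproducible; section advances (Z) are left untouched, as they
    come from the cut schedule, not from the image.
    """
    if grid <= 0:
        raise ConfigError("grid must be positive")
    if jitter_sd < 0:
        raise ConfigError("jitter sd must be non-negative")
    rng = np.random.default_rng(seed)
    noisy: list[SectionObservation] = []
    for obs in observations:
        cuts = []
        for c in obs.cuts:
            if not c.present:
                cuts.append(c)
                continue
            x = quantize_measurement(c.x + rng.normal(0.0, jitter_sd), grid)
            y = quantize_measurement(c.y + rng.normal(0.0, jitter_sd), grid)
            cuts.append(TargetCut(c.name, True, float(x), float(y), c.cross_radius))
        noisy.append(SectionObservation(obs.section_index, obs.advance, tuple(cuts)))
    return noisy


def render_section(
    obs: SectionObservation,
    frame: BlockFrame,
    scale: float = 10.0,
    grid_mm: float = 1000.0,
) -> Image.Image:
    """Raster image of one section: target disks over a 1 mm reference grid.

    ``scale`` is µm per pixel.  Pixel (0, 0) is the frame origin; a µm
    position maps to pixel ``round(um / scale)``, so disk centroids map back
    to µm within one pixel.  Rendering is deterministic for identical input.
    """
    w = int(round(frame.footprint_x / scale)) + 1
    h = int(round(frame.footprint_y / scale)) + 1
    img = Image.new("RGB", (w, h), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    step = grid_mm / scale
    k = 0
    while True:
        pos = int(round(k * step))
        if pos >= max(w, h):
            break
        if pos < w:
            draw.line([(pos, 0), (pos, h - 1)], fill=(230, 120, 120), width=1)
        if pos < h:
            draw.line([(0, pos), (w - 1, pos)], fill=(230, 120, 120), width=1)
        k += 1
    ox, oy = frame.origin
    for c in obs.cuts:
        if not c.present:
            continue
        cx = (c.x - ox) / scale
        cy = (c.y - oy) / scale
        r = max(c.cross_radius / scale, 1.0)
        color = _COLORS.get(c.name, (90, 90, 90))
        draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=color)
    return img


def expected_plane_of(block: VirtualBlock):
    """Expected sectioning plane of a 3-target block (convenience)."""
    centers = block.centers
    if len(centers) != 3:
        raise ConfigError("expected_plane_of is defined for 3-target blocks")
    return plane_through_targets(*centers)
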