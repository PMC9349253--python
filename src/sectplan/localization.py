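"""Target-center localization from per-section 2D observations.

Mimics the bench workflow: every section image is registered to the
positioning-plate reference (and mirror-flipped, because the block bottom is
cut first so images are seen reversed), the target central point is read off
a 100 µm grid in each section where it appears, and the per-axis average
across those sections is taken as the target center.  The section's Z is its
mid-plane advance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import RegistrationError
from .geometry import BlockFrame, TargetCenter, mirror_x
from .sectioning import SectionObservation, TargetCut

#: default measurement grid of the coordinate/checked paper, µm
MEASUREMENT_GRID = 100.0


def quantize_measurement(value: float, grid: float = MEASUREMENT_GRID) -> float:
    """Round a reading to the nearest grid multiple; ties round away from zero.

    Emulates reading coordinates off checked paper ruled every ``grid`` µm.
    The quantization error is at most ``grid / 2``.
    """
    if grid <= 0:
        raise ValueError("grid must be positive")
    v = np.asarray(value, dtype=float)
    q = np.sign(v) * np.floor(np.abs(v) / grid + 0.5) * grid
    if np.ndim(value) == 0:
        return float(q)
    return q


def register_observation(
    obs: SectionObservation, frame: BlockFrame, mirror: bool = False
) -> SectionObservation:
    """Re-express a section observation in the block frame of reference.

    Coordinates are referenced to the plate X-axis and the virtual Y-axis
    through the origin; when ``mirror`` is set the image X is flipped about
    the origin (the bottom-first mirror).  Registered coordinates must fall
    on the block bottom face.
    """
    cuts = []
    for c in obs.cuts:
        if not c.present:
            cuts.append(c)
            continue
        x, y = c.x, c.y
        if mirror:
            x = float(mirror_x(np.array([x, y]), frame)[0])
        if not frame.contains_bottom_point(x, y, tol=MEASUREMENT_GRID):
            raise RegistrationError(
                f"section {obs.section_index}, target {c.name!r}: registered "
                f"position ({x:.1f}, {y:.1f}) lies outside the block frame"
            )
        cuts.append(TargetCut(c.name, True, x, y, c.cross_radius))
    return SectionObservation(obs.section_index, obs.advance, tuple(cuts))


@dataclass(frozen=True)
class TargetEstimate:
    """Localized center of one target with per-axis spread across sections."""

    name: str
    x: float
    y: float
    z: float
    sd_x: float
    sd_y: float
    sd_z: float
    n_sections: int

    def to_target_center(self) -> TargetCenter:
        return TargetCenter(self.name, self.x, self.y, self.z)


@dataclass(frozen=True)
class LocalizationResult:
    """Per-target localization estimates from a registered section stack."""

    estimates: tuple[TargetEstimate, ...]

    def __getitem__(self, name: str) -> TargetEstimate:
        for e in self.estimates:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.estimates]

    def to_target_centers(self) -> list[TargetCenter]:
        return [e.to_target_center() for e in self.estimates]


def estimate_centers(stack: Sequence[SectionObservation]) -> LocalizationResult:
    """Average per-axis readings over the sections where each target appears.

    X and Y come from the recorded section centroids, Z from the section
    mid-plane advances.  The estimate is the unweighted arithmetic mean over
    all sections with the target present (small peripheral cross-sections
    included); a target never observed is omitted with a warning.
    """
    names: list[str] = []
    for obs in stack:
        for c in obs.cuts:
            if c.name not in names:
                names.append(c.name)
    estimates: list[TargetEstimate] = []
    for name in names:
        xs, ys, zs = [], [], []
        for obs in stack:
            try:
                c = obs.cut(name)
            except KeyError:
                continue
            if c.present:
                xs.append(c.x)
                ys.append(c.y)
                zs.append(obs.advance)
        if not xs:
            warnings.warn(
                f"target {name!r} was never observed in the section stack; "
                "it is absent from the localization result",
                stacklevel=2,
            )
            continue
        xs, ys, zs = np.asarray(xs), np.asarray(ys), np.asarray(zs)
        sd = lambda a: float(a.std(ddof=1)) if a.size > 1 else 0.0
        estimates.append(
            TargetEstimate(
                name,
                float(xs.mean()), float(ys.mean()), float(zs.mean()),
                sd(xs), sd(ys), sd(zs),
                int(xs.size),
            )
        )
    return LocalizationResult(tuple(estimates))
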