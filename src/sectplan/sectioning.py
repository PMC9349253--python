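"""Serial-sectioning simulation of a virtual embedding block.

A :class:`VirtualBlock` is a block frame plus spherical targets.  A
:class:`SectionPlan` is the ordered schedule of trim (discarded) and collect
(retained) cuts; :func:`simulate_cut` samples the block at each collected
section's mid-plane, reporting per-target presence, centroid and
cross-section radius by sphere-plane intersection.

The protocol simulated is the bench one: trim in thick steps until an
approach margin before the expected position, then switch to thin sections;
or, for a survey of an uncut block, collect one thin section at every fixed
interval of advance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ConfigError, PlanningError
from .geometry import (
    ABS_TOL,
    BlockFrame,
    CuttingPlane,
    TargetCenter,
    mirror_x,
)

#: default retained-section thickness, µm
FINE_THICKNESS = 7.0
#: default trimming step, µm
TRIM_THICKNESS = 20.0
#: default approach margin before the expected position, µm
APPROACH_MARGIN = 1000.0
#: default survey interval between collected sections, µm
SURVEY_INTERVAL = 100.0


@dataclass(frozen=True)
class VirtualBlock:
    """An embedding block with spherical targets of known centers and radii."""

    frame: BlockFrame
    targets: tuple[tuple[TargetCenter, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        for t, r in self.targets:
            if r <= 0:
                raise ConfigError(f"target {t.name!r} has non-positive radius {r}")
            fx, fy, h = self.frame.footprint_x, self.frame.footprint_y, self.frame.height
            ox, oy = self.frame.origin
            inside = (
                ox + r <= t.x <= ox + fx - r
                and oy + r <= t.y <= oy + fy - r
                and r <= t.z <= h - r
            )
            if not inside:
                raise ConfigError(
                    f"target sphere {t.name!r} (center ({t.x}, {t.y}, {t.z}), "
                    f"radius {r}) is not fully inside the block frame"
                )

    @property
    def centers(self) -> list[TargetCenter]:
        return [t for t, _ in self.targets]


@dataclass(frozen=True)
class SectionEvent:
    advance_start: float
    thickness: float
    kind: str  # "trim" | "collect"

    @property
    def advance_end(self) -> float:
        return self.advance_start + self.thickness

    @property
    def mid_advance(self) -> float:
        return self.advance_start + 0.5 * self.thickness


@dataclass(frozen=True)
class SectionPlan:
    """Ordered, contiguous schedule of trim/collect cuts."""

    events: tuple[SectionEvent, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        prev_end = 0.0
        for ev in self.events:
            if ev.thickness <= 0:
                raise ConfigError("section thickness must be positive")
            if ev.kind not in ("trim", "collect"):
                raise ConfigError(f"unknown event kind {ev.kind!r}")
            if abs(ev.advance_start - prev_end) > ABS_TOL:
                raise ConfigError("plan events must be contiguous and increasing")
            prev_end = ev.advance_end

    @property
    def total_advance(self) -> float:
        return sum(ev.thickness for ev in self.events)

    @property
    def collect_events(self) -> list[SectionEvent]:
        return [ev for ev in self.events if ev.kind == "collect"]

    @property
    def n_trims(self) -> int:
        return sum(1 for ev in self.events if ev.kind == "trim")


@dataclass(frozen=True)
class TargetCut:
    """One target's appearance (or absence) in a collected section."""

    name: str
    present: bool
    x: float | None
    y: float | None
    cross_radius: float | None


@dataclass(frozen=True)
class SectionObservation:
    """Per-target content of one collected section, evaluated at its mid-plane."""

    section_index: int  # 1-based, in advance order
    advance: float      # mid-plane advance, µm
    cuts: tuple[TargetCut, ...]

    def cut(self, name: str) -> TargetCut:
        for c in self.cuts:
            if c.name == name:
                return c
        raise KeyError(name)


def plan_schedule(
    expected_advance: float,
    trim_thickness: float = TRIM_THICKNESS,
    fine_thickness: float = FINE_THICKNESS,
    approach_margin: float = APPROACH_MARGIN,
) -> SectionPlan:
    """Trim-then-fine schedule toward an expected position.

    Trimming proceeds in ``trim_thickness`` steps until the advance reaches
    ``expected_advance - approach_margin`` (the last trim never crosses it);
    from there thin sections of ``fine_thickness`` are collected until the
    plan covers ``expected_advance + approach_margin``.
    """
    if trim_thickness <= 0 or fine_thickness <= 0:
        raise ConfigError("section thicknesses must be positive")
    if approach_margin < 0:
        raise ConfigError("approach margin must be non-negative")
    if expected_advance <= approach_margin:
        raise PlanningError(
            f"expected advance ({expected_advance} µm) must exceed the "
            f"approach margin ({approach_margin} µm)"
        )
    n_trims = int(math.floor((expected_advance - approach_margin) / trim_thickness))
    events: list[SectionEvent] = []
    for i in range(n_trims):
        events.append(SectionEvent(i * trim_thickness, trim_thickness, "trim"))
    pos = n_trims * trim_thickness
    end = expected_advance + approach_margin
    n_fine = int(math.ceil((end - pos) / fine_thickness))
    for j in range(n_fine):
        events.append(SectionEvent(pos + j * fine_thickness, fine_thickness, "collect"))
    return SectionPlan(tuple(events))


def plan_serial_survey(
    block_height: float,
    fine_thickness: float = FINE_THICKNESS,
    interval: float = SURVEY_INTERVAL,
) -> SectionPlan:
    """Survey schedule: one collected thin section every ``interval`` of advance.

    Each cycle trims ``interval - fine_thickness`` and then collects a
    ``fine_thickness`` section, so collected mid-planes are spaced exactly
    ``interval`` apart; cycles repeat while they fit within the block height.
    """
    if fine_thickness <= 0 or interval <= 0:
        raise ConfigError("thickness and interval must be positive")
    if interval < fine_thickness:
        raise ConfigError("interval cannot be smaller than the section thickness")
    if block_height <= interval:
        raise ConfigError("block height must exceed the survey interval")
    n_cycles = int(math.floor(block_height / interval))
    gap = interval - fine_thickness
    events: list[SectionEvent] = []
    pos = 0.0
    for _ in range(n_cycles):
        if gap > 0:
            events.append(SectionEvent(pos, gap, "trim"))
            pos += gap
        events.append(SectionEvent(pos, fine_thickness, "collect"))
        pos += fine_thickness
    return SectionPlan(tuple(events))


def simulate_cut(
    block: VirtualBlock,
    plane: CuttingPlane,
    plan: SectionPlan,
    mirror: bool = False,
) -> list[SectionObservation]:
    """Cut the block along ``plan`` with the blade oriented/positioned by ``plane``.

    ``plane`` is the blade plane at advance 0 (the plan's reference plane).
    For each collect event the blade mid-plane is ``plane`` translated by the
    event's mid advance; each spherical target is present when the
    perpendicular distance ``d`` from its center to that mid-plane is smaller
    than its radius, with cross-section radius ``sqrt(r**2 - d**2)`` and
    centroid at the orthogonal projection of the center onto the plane,
    reported as (x, y) in the section frame (mirrored when requested).
    """
    centers = np.array([t.point for t, _ in block.targets])
    radii = np.array([r for _, r in block.targets])
    names = [t.name for t, _ in block.targets]
    observations: list[SectionObservation] = []
    n = plane.normal
    for idx, ev in enumerate(plan.collect_events, start=1):
        mid = plane.translated(ev.mid_advance)
        cuts: list[TargetCut] = []
        if len(centers):
            d = (centers - mid.point) @ n
            present = np.abs(d) < radii
            proj = centers - d[:, None] * n[None, :]
            for i, name in enumerate(names):
                if present[i]:
                    x, y = float(proj[i, 0]), float(proj[i, 1])
                    if mirror:
                        x = float(mirror_x(np.array([x, y]), block.frame)[0])
                    rad = float(math.sqrt(max(radii[i] ** 2 - d[i] ** 2, 0.0)))
                    cuts.append(TargetCut(name, True, x, y, rad))
                else:
                    cuts.append(TargetCut(name, False, None, None, None))
        observations.append(
            SectionObservation(idx, float(ev.mid_advance), tuple(cuts))
        )
    return observations


def actual_hit_advances(
    block: VirtualBlock, plane: CuttingPlane
) -> dict[str, float]:
    """Advance at which the blade mid-plane passes exactly through each center.

    ``plane`` is the blade plane at advance 0.  Mirrors the bench record of
    the actual cutting-forward distance per target.
    """
    n = plane.normal
    nz = float(n @ np.array([0.0, 0.0, 1.0]))
    out: dict[str, float] = {}
    for t, _ in block.targets:
        s = float((t.point - plane.point) @ n)
        out[t.name] = s / nz
    return out
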