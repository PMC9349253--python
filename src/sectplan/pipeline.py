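"""End-to-end planning workflow: centers -> plane -> guide -> schedule -> cut.

Ties the geometry, sectioning and localization modules into the four-step
bench workflow, and provides the seeded recovery trial used to validate the
whole chain on synthetic blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConfigError, InputError
from .geometry import (
    BlockFrame,
    CuttingPlane,
    FeasibilityVerdict,
    GuideModel,
    TargetCenter,
    check_feasibility,
    cutting_forward_distance,
    fit_plane,
    tilt_angle,
    virtual_plane,
)
from .localization import MEASUREMENT_GRID, estimate_centers, register_observation
from .sectioning import (
    APPROACH_MARGIN,
    FINE_THICKNESS,
    SURVEY_INTERVAL,
    TRIM_THICKNESS,
    SectionObservation,
    SectionPlan,
    VirtualBlock,
    plan_schedule,
    plan_serial_survey,
    simulate_cut,
)
from .synthetic import add_measurement_noise, make_random_block


@dataclass(frozen=True)
class SectioningPlan:
    """Complete plan for one block: planes, guide model, advance, schedule."""

    frame: BlockFrame
    targets: tuple[TargetCenter, ...]
    expected_plane: CuttingPlane
    virtual_plane: CuttingPlane
    guide: GuideModel
    tilt_deg: float
    feasibility: FeasibilityVerdict
    expected_advance: float
    schedule: SectionPlan

    def to_dict(self) -> dict:
        return {
            "frame": self.frame.to_dict(),
            "targets": [
                {"name": t.name, "x_um": t.x, "y_um": t.y, "z_um": t.z}
                for t in self.targets
            ],
            "expected_plane": self.expected_plane.to_dict(),
            "virtual_plane": self.virtual_plane.to_dict(),
            "guide": [
                {"name": nd.name, "base_x_um": nd.base[0],
                 "base_y_um": nd.base[1], "tip_height_um": nd.tip_height}
                for nd in self.guide.needles
            ],
            "tilt_deg": self.tilt_deg,
            "feasibility": self.feasibility.to_dict(),
            "expected_advance_um": self.expected_advance,
            "schedule": [
                {"advance_start_um": ev.advance_start,
                 "thickness_um": ev.thickness, "kind": ev.kind}
                for ev in self.schedule.events
            ],
        }


def plan_from_centers(
    centers: Sequence[TargetCenter],
    frame: BlockFrame,
    capacity_deg: float = 20.0,
    trim_thickness: float = TRIM_THICKNESS,
    fine_thickness: float = FINE_THICKNESS,
    approach_margin: float = APPROACH_MARGIN,
) -> SectioningPlan:
    """Build the full sectioning plan from localized target centers.

    The expected plane is fitted through the centers, the virtual plane and
    needle-guide model are derived from it, the cutting-forward distance is
    measured from the virtual-plane start to the deepest target's footprint
    mark, and a trim/fine schedule is laid out around that advance.
    """
    if len(centers) < 3:
        raise InputError("planning needs at least 3 target centers")
    for t in centers:
        if t.z > frame.height:
            raise InputError(
                f"target {t.name!r} depth {t.z} µm exceeds block height"
            )
    expected = fit_plane(centers)
    virt, guide = virtual_plane(centers)
    deepest = max(centers, key=lambda t: t.z)
    advance = cutting_forward_distance(
        expected, deepest.footprint, frame, start=virt
    )
    schedule = plan_schedule(
        advance, trim_thickness, fine_thickness, approach_margin
    )
    tilt = tilt_angle(expected)
    verdict = check_feasibility(expected, capacity_deg)
    return SectioningPlan(
        frame=frame,
        targets=tuple(centers),
        expected_plane=expected,
        virtual_plane=virt,
        guide=guide,
        tilt_deg=tilt,
        feasibility=verdict,
        expected_advance=advance,
        schedule=schedule,
    )


def survey_localize(
    block: VirtualBlock,
    interval: float = SURVEY_INTERVAL,
    fine_thickness: float = FINE_THICKNESS,
    grid: float = MEASUREMENT_GRID,
    jitter_sd: float = 0.0,
    seed: int | None = None,
    mirror: bool = False,
):
    """Serially survey a block bottom-up and localize its targets.

    Cuts the block perpendicular to the bottom face with one collected thin
    section per ``interval`` of advance, optionally degrades the section
    readings with jitter+grid quantization, registers each section into the
    block frame and averages per-axis.  Returns a LocalizationResult.
    """
    survey_plane = CuttingPlane(np.array([0.0, 0.0, 1.0]), np.zeros(3))
    plan = plan_serial_survey(block.frame.height, fine_thickness, interval)
    observations = simulate_cut(block, survey_plane, plan, mirror=mirror)
    if jitter_sd > 0 or grid > 0:
        observations = add_measurement_noise(
            observations, grid=grid, jitter_sd=jitter_sd, seed=seed
        )
    registered = [
        register_observation(obs, block.frame, mirror=mirror)
        for obs in observations
    ]
    return estimate_centers(registered)


@dataclass(frozen=True)
class RecoveryTrial:
    """Outcome of one synthetic localize-plan-cut round trip."""

    success: bool
    delivered_section_index: int
    delivered_advance: float
    miss_distances: dict  # target -> unsigned distance to delivered mid-plane, µm
    plan: SectioningPlan


def plane_hit_distances(
    block: VirtualBlock, plan: SectioningPlan, advance: float | None = None
) -> dict[str, float]:
    """Unsigned distance of each true target center to the blade plane.

    The blade starts at the plan's virtual plane and is advanced by
    ``advance`` (default: the plan's expected advance).
    """
    if advance is None:
        advance = plan.expected_advance
    blade = plan.virtual_plane.translated(advance)
    return {
        t.name: abs(float(blade.signed_distance(t.point)))
        for t in block.centers
    }


def run_recovery_trial(
    block: VirtualBlock,
    jitter_sd: float = 0.0,
    grid: float = MEASUREMENT_GRID,
    seed: int | None = None,
    capacity_deg: float = 20.0,
    interval: float = SURVEY_INTERVAL,
) -> RecoveryTrial:
    """Survey-localize a block, plan from the estimates, cut, and score.

    The delivered section is the collected section whose mid-plane is
    closest to the expected advance; the trial succeeds when every true
    target sphere is present in that single section.
    """
    result = survey_localize(
        block, interval=interval, grid=grid, jitter_sd=jitter_sd, seed=seed
    )
    centers = result.to_target_centers()
    if len(centers) < 3:
        raise InputError("survey recovered fewer than 3 targets")
    plan = plan_from_centers(centers, block.frame, capacity_deg=capacity_deg)
    observations = simulate_cut(block, plan.virtual_plane, plan.schedule)
    best = min(
        observations, key=lambda o: abs(o.advance - plan.expected_advance)
    )
    blade = plan.virtual_plane.translated(best.advance)
    miss = {
        t.name: abs(float(blade.signed_distance(t.point)))
        for t in block.centers
    }
    success = all(c.present for c in best.cuts)
    return RecoveryTrial(
        success=success,
        delivered_section_index=best.section_index,
        delivered_advance=best.advance,
        miss_distances=miss,
        plan=plan,
    )
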