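"""CSV/JSON serialization for targets, planes, guides, plans and observations.

All text outputs carry a provenance comment/field (package version, config
hash, seed) and contain no timestamps, so identical inputs give identical
bytes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import InputError
from .geometry import BlockFrame, CuttingPlane, GuideModel, TargetCenter
from .localization import LocalizationResult
from .sectioning import SectionObservation, SectionPlan


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_dict(config: dict | None = None, seed=None) -> dict:
    return {
        "package": "sectplan",
        "version": __version__,
        "config_hash": config_hash(config or {}),
        "seed": seed,
    }


def _provenance_comment(config: dict | None = None, seed=None) -> str:
    p = provenance_dict(config, seed)
    return (f"# sectplan v{p['version']} config_hash={p['config_hash']} "
            f"seed={p['seed']}\n")


# ---------------------------------------------------------------------------
# target tables

def write_targets_csv(
    path, targets: Sequence[TargetCenter],
    config: dict | None = None, seed=None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_comment(config, seed))
        fh.write("name,x_um,y_um,z_um\n")
        for t in targets:
            fh.write(f"{t.name},{t.x:.6g},{t.y:.6g},{t.z:.6g}\n")


def read_targets_csv(path) -> list[TargetCenter]:
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pandas raises several parse error types
        raise InputError(f"cannot parse targets CSV {path}: {exc}") from exc
    if "target" in df.columns and "name" not in df.columns:
        df = df.rename(columns={"target": "name"})  # localization-result schema
    required = {"name", "x_um", "y_um", "z_um"}
    if df.empty or not required.issubset(df.columns):
        raise InputError(
            f"targets CSV {path} must have non-empty columns {sorted(required)}"
        )
    return [
        TargetCenter(str(r["name"]), float(r["x_um"]), float(r["y_um"]),
                     float(r["z_um"]))
        for _, r in df.iterrows()
    ]


def write_centers_csv(
    path, result: LocalizationResult,
    config: dict | None = None, seed=None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_comment(config, seed))
        fh.write("target,x_um,y_um,z_um,n_sections\n")
        for e in result.estimates:
            fh.write(
                f"{e.name},{e.x:.6g},{e.y:.6g},{e.z:.6g},{e.n_sections}\n"
            )


# ---------------------------------------------------------------------------
# planes and guides

def write_plane_json(path, plane: CuttingPlane) -> None:
    Path(path).write_text(json.dumps(plane.to_dict(), indent=2) + "\n")


def read_plane_json(path) -> CuttingPlane:
    return CuttingPlane.from_dict(json.loads(Path(path).read_text()))


def write_guide_csv(
    path, guide: GuideModel, config: dict | None = None, seed=None
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_comment(config, seed))
        fh.write("name,base_x_um,base_y_um,tip_height_um\n")
        for nd in guide.needles:
            fh.write(
                f"{nd.name},{nd.base[0]:.6g},{nd.base[1]:.6g},"
                f"{nd.tip_height:.6g}\n"
            )


# ---------------------------------------------------------------------------
# plans and observations

def write_plan_csv(
    path, plan: SectionPlan, config: dict | None = None, seed=None
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_comment(config, seed))
        fh.write("section_index,advance_um,kind,thickness_um\n")
        for i, ev in enumerate(plan.events, start=1):
            fh.write(
                f"{i},{ev.advance_start:.6g},{ev.kind},{ev.thickness:.6g}\n"
            )


def write_observations_csv(
    path, observations: Iterable[SectionObservation],
    config: dict | None = None, seed=None,
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_comment(config, seed))
        fh.write("section_index,advance_um,target,present,x_um,y_um,rad_um\n")
        for obs in observations:
            for c in obs.cuts:
                if c.present:
                    fh.write(
                        f"{obs.section_index},{obs.advance:.6g},{c.name},1,"
                        f"{c.x:.6g},{c.y:.6g},{c.cross_radius:.6g}\n"
                    )
                else:
                    fh.write(
                        f"{obs.section_index},{obs.advance:.6g},{c.name},0,,,\n"
                    )


def read_observations_csv(path) -> list[SectionObservation]:
    from .sectioning import TargetCut

    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise InputError(f"cannot parse observations CSV {path}: {exc}") from exc
    required = {"section_index", "advance_um", "target", "present"}
    if df.empty or not required.issubset(df.columns):
        raise InputError(
            f"observations CSV {path} must have non-empty columns "
            f"{sorted(required)}"
        )
    observations: list[SectionObservation] = []
    for (idx, adv), grp in df.groupby(["section_index", "advance_um"], sort=True):
        cuts = []
        for _, r in grp.iterrows():
            present = bool(int(r["present"]))
            if present:
                cuts.append(TargetCut(
                    str(r["target"]), True, float(r["x_um"]), float(r["y_um"]),
                    float(r["rad_um"]) if not pd.isna(r.get("rad_um")) else None,
                ))
            else:
                cuts.append(TargetCut(str(r["target"]), False, None, None, None))
        observations.append(SectionObservation(int(idx), float(adv), tuple(cuts)))
    return observations
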