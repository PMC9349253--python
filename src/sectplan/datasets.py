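"""Bundled validation-run tables for the position-known three-targeted phantom.

Two small CSV fixtures ship with the package: the repeated coordinate
measurements of the three colored targets (foreknown magnitudes plus four
measurement runs) and the expected/actual cutting-forward distances of the
four paired sectioning runs.  They are the reference inputs for
:func:`sectplan.validation.build_report`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("sectplan.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#")


def three_target_positions() -> pd.DataFrame:
    """Foreknown and repeatedly measured target coordinates (magnitudes, µm).

    Columns: ``target, axis, foreknown, run1..run4``.
    """
    return _load("three_target_positions.csv")


def cutting_forward_distances() -> pd.DataFrame:
    """Expected and actual cutting-forward distances of four paired runs (µm).

    Columns: ``target, run, actual, expected``; the expected distance is a
    single predetermined value per run, shared by that run's targets.
    """
    return _load("cutting_forward_distances.csv")
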