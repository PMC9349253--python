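"""Exception hierarchy for sectplan.

All planner errors derive from :class:`SectPlanError` so callers (and the CLI)
can distinguish user-input problems from internal geometry failures.
"""


class SectPlanError(Exception):
    """Base class for all sectplan errors."""


class InputError(SectPlanError):
    """Malformed or inconsistent user input (tables, configs, shapes)."""


class ConfigError(InputError):
    """Invalid configuration value (e.g. angle capacity outside (0, 90))."""


class GeometryError(SectPlanError):
    """Invalid geometric operation (non-parallel planes, mark behind start)."""


class DegenerateGeometryError(GeometryError):
    """Target set does not define a usable plane (collinear/coincident points,
    or a plane perpendicular to the block bottom)."""


class PlanningError(SectPlanError):
    """Sectioning schedule cannot be constructed from the given parameters."""


class RegistrationError(SectPlanError):
    """Section observation cannot be registered into the block frame."""


class ConsistencyError(SectPlanError):
    """Two artifacts that must describe the same block disagree (e.g. a plan
    built for a different frame than the block being cut)."""


class UndefinedStatisticError(SectPlanError):
    """A statistic is undefined for the given data (zero mean CV, zero
    variance correlation, zero-variance paired differences)."""


class GenerationError(SectPlanError):
    """Random phantom generation failed within the retry budget."""
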