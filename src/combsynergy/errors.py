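"""Typed exceptions raised across the package.

Every validation failure raises one of these (never a silent pass), so
callers and the CLI can distinguish bad input from internal faults.
"""


class CombSynergyError(Exception):
    """Base class for all package errors."""


class DesignError(CombSynergyError):
    """Invalid experimental design: bad roles, doses, or duplicate ids."""


class SchemaError(CombSynergyError):
    """Malformed input table: missing column, dangling id, experiment
    without an untreated control, negative signal, ..."""


class InvalidInputError(CombSynergyError, ValueError):
    """A numeric argument outside its domain (nonpositive SF, diameter,
    volume, time interval, ...)."""


class DegenerateFitError(CombSynergyError):
    """A regression that cannot be inverted (zero slope, <2 distinct x)."""


class UninterpretablePlateError(CombSynergyError):
    """Background correction left the untreated-control mean nonpositive."""


class AnalysisError(CombSynergyError):
    """A downstream computation cannot proceed (too few experiments,
    missing group at the endpoint day, ...)."""
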