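"""Exception hierarchy.

Two broad families matter for the CLI exit-code contract: schema/validation
problems (exit code 2) and numerical/degeneracy problems (exit code 3).
"""


class MisosipError(Exception):
    """Base class for all package errors."""


class SchemaError(MisosipError):
    """Malformed input: table, pathway definition, or config."""


class PathwayValidationError(SchemaError):
    """Pathway definition violates the atom-map schema (names the reaction)."""


class NumericalError(MisosipError):
    """Degenerate or infeasible numerical situation."""


class InvalidIsotopeError(NumericalError):
    """Isotope value outside its physical domain (delta < -1000, F outside [0,1))."""


class DegenerateEndmemberError(NumericalError):
    """Two-end-member sources too close to apportion between."""


class DegenerateLabelError(NumericalError):
    """Label strength is zero or negative; incorporation ratio undefined."""


class NoEnrichmentError(NumericalError):
    """Both incorporation ratios are zero: sample looks unlabeled."""


class EmptyPoolError(NumericalError):
    """Pool mixing requested over pools with no carbon."""


class InconsistentMeasurementError(NumericalError):
    """Measured mixture fraction not bracketed by its endmembers."""


class InvalidDensityError(NumericalError):
    """Buoyant density outside the plausible CsTFA gradient range."""


class DegenerateCorrelationError(NumericalError):
    """Correlation undefined (n < 3 or zero variance)."""


class InfeasibleConfigError(NumericalError):
    """Simulation stoichiometry drove a pool negative."""
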