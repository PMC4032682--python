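"""Exception hierarchy for avscreen.

All input-validation failures derive from :class:`ValueError` so callers can
catch broadly; the finer classes exist because the CLI maps them to distinct
diagnostics.
"""


class DomainError(ValueError):
    """An argument lies outside the physical/mathematical domain of an operation."""


class DegenerateLoopError(DomainError):
    """The loop-site supracritical Reynolds number is (numerically) zero, so the
    per-unit normalisation is undefined — the loop site sits exactly at the
    laminar/turbulent transition point."""


class DegenerateHueError(ValueError):
    """All three class-average gray grades coincide; the hue angle has no
    geometric meaning and the pattern cannot be classified."""


class IncompleteSubjectError(ValueError):
    """A subject is missing one or more of the three measurement sites (A, L, V)."""


class SchemaError(ValueError):
    """A file does not match the expected column/field schema."""


class SchemaVersionError(SchemaError):
    """A persisted model file declares an unsupported schema version."""


class MeasurementValidationError(SchemaError):
    """One or more rows of a measurements table violate a physical constraint.

    Attributes
    ----------
    row_errors : list of (row_number, message)
        1-based data-row numbers (header excluded) with the violated constraint.
    """

    def __init__(self, row_errors):
        self.row_errors = list(row_errors)
        lines = "; ".join(f"row {n}: {msg}" for n, msg in self.row_errors)
        super().__init__(f"{len(self.row_errors)} invalid row(s): {lines}")


class ConfigError(ValueError):
    """A configuration value is inconsistent or makes sampling infeasible."""


class ExtractionError(RuntimeError):
    """Velocity-landmark extraction failed (e.g. no periodicity in the series)."""


class OptimizerError(RuntimeError):
    """The swarm optimizer received a non-finite fitness value or every
    evaluation was degenerate."""
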