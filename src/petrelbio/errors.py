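"""Exception hierarchy for the pipeline.

``SchemaError`` signals malformed input data (exit code 2 at the CLI),
``ParameterError`` signals an infeasible or inconsistent configuration
(exit code 1 at the CLI).
"""


class PetrelbioError(Exception):
    """Base class for all package errors."""


class ParameterError(PetrelbioError, ValueError):
    """Invalid or infeasible configuration / parameter value."""


class SchemaError(PetrelbioError, ValueError):
    """Input data violates the expected schema or invariants."""
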