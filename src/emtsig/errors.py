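"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`EmtsigError` so callers can trap
pipeline failures without catching unrelated exceptions.
"""


class EmtsigError(Exception):
    """Base class for all package errors."""


class FormatError(EmtsigError):
    """A table file is malformed (missing columns, unparseable values)."""


class IntegrityError(EmtsigError):
    """A table violates an integrity constraint (e.g. duplicate genes)."""


class ParameterError(EmtsigError, ValueError):
    """A parameter record violates its invariants."""


class SampleSizeError(EmtsigError, ValueError):
    """A statistical routine received fewer observations than it requires."""


class ScanEmptyError(EmtsigError):
    """The cutpoint scan found no admissible candidate threshold."""


class InsufficientDataError(EmtsigError, ValueError):
    """Too few complete observations after missing-value removal."""
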