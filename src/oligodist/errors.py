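"""Exception types shared across the package.

All precondition failures raise a subclass of :class:`OligodistError` so
callers (the CLI in particular) can distinguish user error from bugs.
"""


class OligodistError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(OligodistError, ValueError):
    """A parameter violates its documented domain."""


class FormatError(OligodistError, ValueError):
    """An input file does not conform to the expected schema."""


class EmptyInputError(OligodistError, ValueError):
    """No qualifying records/nodes remain after filtering."""


class InsufficientDataError(OligodistError, ValueError):
    """Too few observations for the requested estimate."""


class DivergentEstimateError(OligodistError, ValueError):
    """The likelihood has no finite maximizer (e.g. degenerate tail)."""
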