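"""Exception hierarchy shared across the package."""


class HKMError(Exception):
    """Base class for all package-specific errors."""


class InputError(HKMError, ValueError):
    """Raised when a caller passes malformed or inconsistent input."""


class DegenerateDataError(HKMError, ValueError):
    """Raised when data is too degenerate to work with.

    Examples: a constant truth table handed to the simplifier, a
    single-class target handed to the searcher.
    """
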