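"""Exception types shared across the package."""


class EmgSynergyError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EmgSynergyError):
    """A container file does not have the expected layout."""


class IntegrityError(EmgSynergyError):
    """Arrays that must be aligned (signal vs. labels) disagree."""


class DegenerateDataError(EmgSynergyError):
    """Input is structurally valid but numerically unusable
    (constant channel, empty pool, all-zero matrix, ...)."""
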