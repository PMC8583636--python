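"""Exception types shared across the toolkit."""


class FrailSenseError(Exception):
    """Base class for all toolkit errors."""


class InsufficientSignal(FrailSenseError, ValueError):
    """The signal is too short (or empty) for the requested operation."""


class FramingError(FrailSenseError, ValueError):
    """A transfer block is malformed (wrong length, bad header, truncated payload)."""


class MissingProfile(FrailSenseError, ValueError):
    """A required anthropometric parameter is not configured."""


class NoValidData(FrailSenseError, ValueError):
    """Every candidate cycle was rejected (e.g. all breath cycles artifact-gated)."""
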