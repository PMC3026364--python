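"""Exception hierarchy."""


class SiddPromError(Exception):
    """Base class for all package errors."""


class ProfileFormatError(SiddPromError):
    """Malformed or incomplete SIDD energy track file."""


class TssTableError(SiddPromError):
    """Malformed transcription-start-site table."""


class DatasetFormatError(SiddPromError):
    """Malformed window-dataset file."""


class WindowOutOfRangeError(SiddPromError):
    """A window does not fit inside a linear profile."""


class SamplingError(SiddPromError):
    """Negative sampling or TSS placement cannot satisfy its constraints."""


class TrainingError(SiddPromError):
    """Neural-network training failed (single class, diverged loss, ...)."""
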