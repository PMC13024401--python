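"""Package exception hierarchy."""


class EcgRhythmError(Exception):
    """Base class for all package errors."""


class FormatError(EcgRhythmError):
    """A file could not be parsed under the requested dialect."""


class MissingChannelError(EcgRhythmError):
    """None of the preferred leads is present in a multi-channel record."""


class DegenerateSignalError(EcgRhythmError):
    """The signal is constant (zero variance) and carries no rhythm."""


class InputTooShortError(EcgRhythmError):
    """The record is shorter than one analysis window."""
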