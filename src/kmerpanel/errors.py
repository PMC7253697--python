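"""Exception hierarchy shared across the package.

CLI maps these to exit codes: usage/parameter problems -> 1,
data/format problems -> 2.
"""


class KmerPanelError(Exception):
    """Base class for all package errors."""


class ParameterError(KmerPanelError, ValueError):
    """An argument violates a documented precondition."""


class InputError(KmerPanelError, ValueError):
    """Input collection is unusable (e.g. empty where non-empty required)."""


class FormatError(KmerPanelError, ValueError):
    """A file violates its format contract.

    Carries optional location info (file, line or record ordinal).
    """

    def __init__(self, message, *, source=None, line=None, record=None):
        loc = []
        if source is not None:
            loc.append(str(source))
        if line is not None:
            loc.append(f"line {line}")
        if record is not None:
            loc.append(f"record {record}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.source = source
        self.line = line
        self.record = record
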