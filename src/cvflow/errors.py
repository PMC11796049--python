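"""Exception hierarchy for the cvflow pipeline.

Every error raised on a user-facing path derives from :class:`CVFlowError`
so the CLI can map failures to exit codes without pattern-matching on
library exceptions.
"""

from __future__ import annotations


class CVFlowError(Exception):
    """Base class for all cvflow errors."""


class ParseError(CVFlowError):
    """A vendor file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, source: str | None = None, line: int | None = None):
        self.source = source
        self.line = line
        loc = ""
        if source is not None:
            loc += f"{source}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)


class UnknownDialectError(CVFlowError):
    """No reader recognizes the file; lists the dialects that were tried."""

    def __init__(self, path: str, tried: list[str]):
        self.path = path
        self.tried = list(tried)
        super().__init__(f"{path}: unknown dialect (tried: {', '.join(tried)})")


class ProfileError(CVFlowError):
    """A conversion profile or profile store is malformed."""


class NoProfileError(ProfileError):
    """No stored profile matches the file; the file is parked, not converted."""


class AmbiguousProfileError(ProfileError):
    """More than one profile survives the tie-break."""

    def __init__(self, candidates: list[str]):
        self.candidates = list(candidates)
        super().__init__(f"ambiguous profile match: {', '.join(candidates)}")


class ConversionError(CVFlowError):
    """Profile application failed (missing table/column, bad trace)."""


class NoSweepError(ConversionError):
    """The potential is constant; no sweep boundaries exist."""


class ScanRateUnavailableError(ConversionError):
    """The trace has no measured time axis, so nu cannot be inferred."""


class JcampError(CVFlowError):
    """Malformed JCAMP-DX content."""


class JcampIntegrityError(JcampError):
    """Declared NPOINTS disagrees with the actual pair count."""


class JcampTruncationError(JcampError):
    """A block is not terminated by ##END=."""


class AnalysisError(CVFlowError):
    """Peak picking or descriptor computation failed."""


class PackagingError(CVFlowError):
    """Bag or archive construction failed."""


class SimulationError(CVFlowError):
    """Simulator parameters violate a stability or validity constraint."""


class WatchError(CVFlowError):
    """Watcher configuration or directory access failed."""
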