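"""Exception hierarchy.

``UserInputError`` maps to CLI exit code 1, anything else unexpected to 2.
"""


class ProxhrvError(Exception):
    """Base class for all package-specific errors."""


class UserInputError(ProxhrvError, ValueError):
    """Bad user-supplied input (files, config, CLI arguments)."""


class StreamFormatError(UserInputError):
    """A stream file does not follow the documented format."""


class DesignError(ProxhrvError, ValueError):
    """A statistical design violates a precondition (levels, sample sizes, rank)."""


class PipelineError(ProxhrvError, RuntimeError):
    """A pipeline stage failed; carries stage and participant context."""

    def __init__(self, stage: str, participant: str | None, message: str):
        self.stage = stage
        self.participant = participant
        who = f" [participant={participant}]" if participant else ""
        super().__init__(f"stage '{stage}'{who}: {message}")
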