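"""Exception hierarchy for the neurovote pipeline."""


class NeurovoteError(Exception):
    """Base class for all package errors."""


class ParameterError(NeurovoteError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(NeurovoteError):
    """An on-disk container is malformed (missing or inconsistent metadata)."""


class AlignmentError(NeurovoteError):
    """Trial metadata and epoch arrays disagree in length or order."""


class ScoringError(NeurovoteError):
    """A behavioral score cannot be computed (e.g. an empty IAT block)."""


class SeparationError(NeurovoteError):
    """Perfect separation detected in a logistic fit.

    The fit is aborted rather than silently penalized; callers who want a
    penalized fit must opt in explicitly.
    """


class PipelineError(NeurovoteError):
    """A pipeline stage failed; carries the stage and participant context."""

    def __init__(self, stage: str, participant: str | None, message: str):
        self.stage = stage
        self.participant = participant
        ctx = f"stage={stage}" + (f", participant={participant}" if participant else "")
        super().__init__(f"[{ctx}] {message}")
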