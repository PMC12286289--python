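"""Exception hierarchy shared across the package.

Everything derives from :class:`NrlabError` so callers can catch broadly;
the finer classes distinguish bad arguments from degenerate data and from
misconfiguration, mirroring how the pipeline stages report failure.
"""


class NrlabError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(NrlabError, ValueError):
    """An argument violates a stated precondition (range, shape, sign)."""


class DegenerateInputError(NrlabError, ValueError):
    """Input is syntactically valid but carries no usable signal
    (zero-RMS waveform, zero-variance group, zero envelope peak)."""


class ConfigurationError(NrlabError, ValueError):
    """A configuration object is internally inconsistent or incompatible
    with the data it is applied to (missing channels, short noise lead)."""


class ContractViolationError(NrlabError, RuntimeError):
    """A user-supplied callable broke its contract (e.g. a processor that
    changed the signal length inside the phase-inversion measurement)."""


class InsufficientAveragingError(NrlabError, ValueError):
    """Too few averaging segments for a spectral estimate to be meaningful."""


class IncompleteParticipantError(NrlabError, ValueError):
    """A ratings dataset is missing domains/sentences for some participants."""

    def __init__(self, participant_ids, message=None):
        self.participant_ids = list(participant_ids)
        super().__init__(
            message or f"incomplete data for participants: {self.participant_ids}"
        )
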