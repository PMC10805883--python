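"""Exception hierarchy shared across the pipeline."""


class StopCancelError(Exception):
    """Base class for all package-specific errors."""


class DesignError(StopCancelError):
    """Requested trial counts cannot satisfy the cell structure."""


class ProcessingError(StopCancelError):
    """A signal-processing step received input it cannot handle."""


class UndefinedSSRTError(StopCancelError):
    """SSRT is undefined (stop-respond rate of exactly 0 or 1)."""


class ConfigurationError(StopCancelError):
    """A constant or configuration value is unusable (e.g. singular extinction matrix)."""


class MissingInputError(StopCancelError):
    """A required pipeline input artefact is absent."""

    def __init__(self, artefact: str):
        self.artefact = artefact
        super().__init__(f"missing required input: {artefact}")
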