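"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
StageError -> 4 (everything else propagates as an ordinary traceback).
"""


class BraincoexError(Exception):
    """Base class for all package errors."""


class ConfigError(BraincoexError):
    """Invalid configuration: bad parameter values, inconsistent settings."""


class DataError(BraincoexError):
    """Invalid or inconsistent input data: missing genes, malformed tables."""


class StageError(BraincoexError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
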