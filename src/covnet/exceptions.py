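"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input table, cohort, or parameter fails validation."""


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; message names the stage and entity."""
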