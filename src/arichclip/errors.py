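"""Exception hierarchy shared across the pipeline."""


class ArichClipError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ArichClipError):
    """Invalid parameter combination (caught before any computation)."""


class InputError(ArichClipError):
    """Malformed or inconsistent input files (CLI exit code 2)."""


class AnnotationError(InputError):
    """Annotation is missing features/attributes a rule requires."""


class StageError(ArichClipError):
    """A pipeline stage failed mid-run (CLI exit code 3)."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
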