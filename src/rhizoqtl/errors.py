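"""Exception hierarchy shared across the pipeline stages."""


class RhizoqtlError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RhizoqtlError):
    """Invalid or self-contradictory configuration."""


class InvalidSampleError(RhizoqtlError):
    """A phenotype observation violates a physical constraint (e.g. RT <= 0)."""


class FormatError(RhizoqtlError):
    """A file does not carry the fields the pipeline requires."""


class ChromosomeMismatchError(RhizoqtlError):
    """Two inputs use disjoint chromosome naming schemes."""

    def __init__(self, left_only, right_only):
        self.left_only = sorted(left_only)
        self.right_only = sorted(right_only)
        super().__init__(
            "no chromosome names in common; "
            f"first input only: {self.left_only}, second input only: {self.right_only}"
        )


class StageError(RhizoqtlError):
    """A pipeline stage failed; carries a stable machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")
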