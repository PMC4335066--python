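"""Exception types shared across the package."""


class ConetdiffError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ConetdiffError, ValueError):
    """A file does not conform to the expected on-disk format
    (duplicate identifiers, missing cells, non-numeric values, ...)."""


class DesignError(ConetdiffError, ValueError):
    """The data violate a requirement of the experimental design
    (wrong number of conditions, too few replicates, empty target set, ...)."""


class StageError(ConetdiffError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
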