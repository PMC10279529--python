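"""Exception hierarchy for tetherscore.

Every error raised by the library derives from :class:`TetherscoreError` so
callers (and the CLI) can distinguish usage, parse and computation failures.
"""


class TetherscoreError(Exception):
    """Base class for all tetherscore errors."""


class ConfigError(TetherscoreError):
    """Invalid configuration value or combination."""


class SizingError(ConfigError):
    """Requested gene count / lengths cannot fit on the requested genome."""


class CoordinateError(TetherscoreError):
    """A genomic interval falls outside the genome or is malformed."""


class MappingError(TetherscoreError):
    """A fragment cannot be mapped onto protein coordinates."""


class GenerationError(TetherscoreError):
    """Random generation failed (e.g. barcode space exhausted)."""


class InputError(TetherscoreError):
    """An operation received empty or structurally invalid input."""


class EstimationError(TetherscoreError):
    """The activity estimator received counts it cannot score."""


class DegeneratePopulationError(EstimationError):
    """Score standardization is undefined (zero variance population)."""


class InsufficientOverlapError(TetherscoreError):
    """Too few fragments shared between replicates for a correlation."""


class FormatError(TetherscoreError):
    """A file does not conform to its declared format."""


class SchemaError(FormatError):
    """A tabular file violates its schema; message names the offending cell."""


class StageError(TetherscoreError):
    """A pipeline stage failed; wraps the underlying error with stage context."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original!r}")
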