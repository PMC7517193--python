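"""Exception hierarchy for gwdemons."""


class GwdemonsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GwdemonsError):
    """Undecodable or structurally invalid file content."""


class ShapeError(GwdemonsError):
    """Array arguments whose shapes are incompatible."""


class ConfigError(GwdemonsError):
    """Invalid configuration value or unknown component name."""


class EvaluationError(GwdemonsError):
    """An objective evaluation produced a non-finite or invalid result."""


class UndefinedMetricError(GwdemonsError):
    """A metric is mathematically undefined for the given inputs."""
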