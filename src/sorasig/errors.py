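"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes (config 2, data 3, degeneracy 4);
library callers catch them like any other ValueError.
"""


class SorasigError(ValueError):
    """Base class for all pipeline errors."""


class ConfigError(SorasigError):
    """Invalid or incomplete run configuration."""


class DataError(SorasigError):
    """Malformed, inconsistent or missing input data."""


class DegenerateDataError(SorasigError):
    """Input is formally valid but statistically degenerate
    (single-class cohort, constant scores, empty signature...)."""
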