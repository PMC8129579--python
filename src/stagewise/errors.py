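"""Exception hierarchy shared across the pipeline."""


class StagewiseError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(StagewiseError, ValueError):
    """Invalid configuration values (sizes, proportions, thresholds)."""


class DataError(StagewiseError, ValueError):
    """Invalid data values (negative counts, non-finite profiles)."""


class ScaleError(StagewiseError, ValueError):
    """Operation applied to a series on the wrong scale."""


class AxisError(StagewiseError, ValueError):
    """Stage-axis problems (missing baseline, bad ordering)."""


class InsufficientReplicationError(StagewiseError, ValueError):
    """Too few replicates (or no replicate variability) to fit a null."""


class ParseError(StagewiseError, ValueError):
    """Malformed input file."""
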