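"""Exception hierarchy for the prophagescan pipeline.

Each user-facing failure mode gets its own class so the CLI can map it to a
distinct exit code.
"""


class ProphageScanError(Exception):
    """Base class for all package-specific errors."""


class GenomeParseError(ProphageScanError):
    """An annotation flat file could not be parsed."""


class NoCodingFeaturesError(ProphageScanError):
    """The genome contains no CDS features, so the pipeline cannot run."""


class HitsParseError(ProphageScanError):
    """A tabular homology-hits file is malformed."""


class AlignerNotFoundError(ProphageScanError):
    """No compatible protein aligner executable was found on PATH."""


class ConfigError(ProphageScanError):
    """A pipeline parameter failed validation."""


class UndefinedMetricError(ProphageScanError):
    """A cluster-validity metric is undefined for the given labeling."""


class UndefinedGcError(ProphageScanError):
    """G+C fraction is undefined (no countable A/C/G/T bases)."""


class PlacementError(ProphageScanError):
    """Synthetic prophage cassettes could not be placed without overlap."""
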