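"""Exception hierarchy.

Configuration errors indicate bad user input (CLI exit code 2); processing
errors indicate a failure while transforming valid-looking data (exit code 3).
"""


class EcseqError(Exception):
    """Base class for all ecseq errors."""


class ConfigurationError(EcseqError):
    """Invalid configuration, parameters, or input metadata."""


class ProcessingError(EcseqError):
    """Data could not be processed (malformed records, internal inconsistency)."""


class SaturationError(ProcessingError):
    """Poisson occupancy is saturated (no negative droplets): lambda is unbounded."""
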