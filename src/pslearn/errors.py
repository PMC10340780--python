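"""Exception types raised across the pipeline."""


class PslearnError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PslearnError, ValueError):
    """A configuration value is invalid or inconsistent."""


class GenerationError(PslearnError, RuntimeError):
    """Procedural generation failed (e.g. retry budget exhausted)."""


class PlacementError(PslearnError, RuntimeError):
    """No admissible placement exists for a lesion in a slice."""


class ArchMismatchError(PslearnError, ValueError):
    """Encoder weights were loaded into an incompatible architecture."""
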