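"""Exception hierarchy.

All package errors derive from :class:`SalientSortError` so callers (and the
CLI) can distinguish configuration problems, malformed data, and internal
failures by class.
"""


class SalientSortError(Exception):
    """Base class for all package errors."""


class ParameterError(SalientSortError, ValueError):
    """An argument or configuration value is invalid."""


class FormatError(SalientSortError, ValueError):
    """A file or payload does not conform to the expected on-disk format."""


class GenerationError(SalientSortError, RuntimeError):
    """Synthetic-data generation cannot satisfy the requested constraints."""


class EstimationError(SalientSortError, ValueError):
    """Class statistics cannot be estimated from the given data."""


class TrainingError(SalientSortError, ValueError):
    """Window fitting / training cannot proceed on the given data."""


class ConfigurationError(SalientSortError, ValueError):
    """A sorter configuration violates hardware width constraints."""
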