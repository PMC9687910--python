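"""Exception hierarchy shared across the pipeline.

Validation errors cover malformed user input (tables, labels, file
formats); parameter errors cover out-of-contract arguments; resource
errors cover guarded blow-ups (packing failures, path explosions).
"""


class MapoccError(Exception):
    """Base class for all package errors."""


class MapFormatError(MapoccError):
    """A density map file is unreadable or its header is inconsistent."""


class ModelFormatError(MapoccError):
    """An atomic-model file could not be parsed."""


class ValidationError(MapoccError):
    """User-supplied tabular input or label violates its contract."""


class ParameterError(MapoccError):
    """An argument is outside the operation's documented domain."""


class EmptyMaskError(MapoccError):
    """Mask thresholding selected no voxels."""


class ResourceError(MapoccError):
    """A guarded resource limit (retries, path count) was exceeded."""
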