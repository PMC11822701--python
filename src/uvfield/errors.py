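"""Exception hierarchy for uvfield."""


class UVFieldError(Exception):
    """Base class for all uvfield errors."""


class ValidationError(UVFieldError, ValueError):
    """An input violates a documented invariant (non-unit normal, bad pose, ...)."""


class MeshFormatError(UVFieldError):
    """An STL file is unreadable, truncated or malformed."""


class EmptyMeshError(UVFieldError):
    """A mesh contains no (usable) facets."""


class NearFieldError(UVFieldError):
    """An examined point is too close to a source for the far-field model."""


class AxisProximityError(NearFieldError):
    """An examined point lies (almost) on a line source's axis."""


class ConfigError(UVFieldError):
    """A light-environment configuration is schema-invalid.

    ``problems`` holds every violation as ``(path, message)`` so users can fix
    a config in one pass rather than one failure at a time.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        lines = [f"  {path}: {msg}" for path, msg in self.problems]
        super().__init__("invalid configuration:\n" + "\n".join(lines))


class FitError(UVFieldError):
    """A dose-response model fit failed to converge."""


class EvaluationError(UVFieldError):
    """A source-model error during field evaluation, annotated with context."""

    def __init__(self, message, element_id=None, timestamp=None):
        self.element_id = element_id
        self.timestamp = timestamp
        super().__init__(message)
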