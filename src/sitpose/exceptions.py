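"""Exception hierarchy shared across the package."""


class SitposeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SitposeError, ValueError):
    """A parameter or configuration value is invalid (e.g. non-positive
    amplitude, cutoff at or above Nyquist, latent outside [0, 1])."""


class DataQualityError(SitposeError, ValueError):
    """Recorded data violates a quality contract (non-monotone timestamps,
    gaps too long to repair, degenerate zero-variance samples)."""


class DegenerateGeometryError(SitposeError, ValueError):
    """Point sets that do not define a usable polygon (fewer than three
    distinct points, or all collinear)."""


class DesignError(SitposeError, ValueError):
    """The study design table is malformed for the requested analysis
    (unbalanced cells, missing time points, groups too small)."""
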