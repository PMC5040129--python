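"""Exception hierarchy for the aneuflow pipeline."""


class AneuflowError(Exception):
    """Base class for all pipeline errors."""


class GeometryError(AneuflowError):
    """Invalid or unresolvable synthetic geometry."""


class ConfigError(AneuflowError):
    """Invalid case configuration."""


class WaveformError(AneuflowError):
    """Inlet waveform violates its constraints (e.g. non-positive flow)."""


class SolverError(AneuflowError):
    """Flow or scalar-transport solve failed."""


class CFLError(SolverError):
    """Time step violates the advective/viscous stability limit."""
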