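"""Exception hierarchy shared across the package."""


class CytosigError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CytosigError):
    """A configuration value violates its contract; the message names the field."""


class QcError(CytosigError):
    """Plate cleaning produced an unusable result (e.g. a cell with no replicates)."""


class FitError(CytosigError):
    """A model could not be fitted (rank deficiency, non-convergence, bad shapes)."""
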