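"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
ModelingError -> 4.
"""


class NirscalibError(ValueError):
    """Base class for all package errors."""


class ConfigError(NirscalibError):
    """Invalid configuration or unknown option names."""


class DataError(NirscalibError):
    """Malformed or inconsistent input data (spectra, references, grids)."""


class ModelingError(NirscalibError):
    """Numerical/statistical failure during calibration or prediction."""
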