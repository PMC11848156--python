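"""Exception hierarchy for the cellprs pipeline."""


class CellPrsError(Exception):
    """Base class for all cellprs errors."""


class FormatError(CellPrsError):
    """A file does not conform to its declared format (e.g. missing column)."""


class LoadError(CellPrsError):
    """A file parsed but violates a load-time invariant (duplicates, empties)."""


class ConfigError(CellPrsError):
    """An invalid run-configuration or simulation-architecture value."""


class DataError(CellPrsError):
    """Inconsistent data passed between pipeline stages."""


class MissingSnpError(CellPrsError, KeyError):
    """A SNP was requested from a table that does not contain it."""


class HarmonizationError(CellPrsError):
    """Exposure and outcome summary statistics cannot be harmonized."""


class ConsistencyError(CellPrsError):
    """An internal mathematical identity was violated (indicates a bug upstream)."""
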