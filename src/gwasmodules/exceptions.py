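"""Exception hierarchy for the pipeline."""


class GwasModulesError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GwasModulesError):
    """A file does not conform to its expected layout (missing columns, bad BED line)."""


class DataError(GwasModulesError):
    """The file parsed but its content is inconsistent (duplicate ids, irreconcilable alleles)."""


class SimulationError(GwasModulesError):
    """A synthetic-data request cannot be satisfied (genome too short, graph too sparse)."""
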