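"""Exception hierarchy for the malespec pipeline."""


class MalespecError(Exception):
    """Base class for all malespec errors."""


class InvalidSequenceError(MalespecError):
    """A sequence contains characters outside {A, C, G, T} where forbidden."""


class MalformedRecordError(MalespecError):
    """A FASTQ/FASTA record is truncated or internally inconsistent."""


class DuplicateContigError(MalespecError):
    """Two contigs in one assembly share an identifier."""


class ConfigError(MalespecError):
    """Inconsistent configuration between pipeline stages (e.g. k mismatch)."""


class SimulationSpecError(MalespecError):
    """A synthetic-data specification is internally inconsistent."""
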