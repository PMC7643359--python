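"""Exception hierarchy for the neurocx pipeline."""


class NeurocxError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(NeurocxError, ValueError):
    """A synthetic-data specification violates its invariants."""


class SchemaError(NeurocxError, ValueError):
    """A file or table does not match the expected schema."""


class FormatError(NeurocxError, ValueError):
    """Unknown or unreadable file format."""


class MissingChannelError(NeurocxError, KeyError):
    """A requested channel label is absent from a recording."""


class NoUsableEpochsError(NeurocxError, ValueError):
    """Every candidate epoch was rejected by amplitude QC."""


class DegenerateChannelError(NeurocxError, ValueError):
    """A channel has zero variance and cannot be normalized."""


class InsufficientSamplesError(NeurocxError, ValueError):
    """Too few samples to build the requested delay vectors."""


class UndefinedSimilarityError(NeurocxError, ValueError):
    """Similarity fraction requested for fewer than two vectors."""


class UndefinedEntropyError(NeurocxError, ValueError):
    """Entropy is undefined (zero match count) at every scale."""


class DegenerateBatteryError(NeurocxError, ValueError):
    """Test-score battery unsuitable for factor extraction."""


class EmptyGroupError(NeurocxError, ValueError):
    """A sex-stratified group contains no (or too few) subjects."""


class ConsistencyError(NeurocxError, ValueError):
    """Cross-referenced subject identifiers disagree."""


class ConfigError(NeurocxError, ValueError):
    """Pipeline configuration invalid or incomplete."""
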