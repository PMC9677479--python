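"""Exception hierarchy for kgfuse.

All library errors derive from :class:`KgfuseError` so callers (and the CLI)
can catch one base class.
"""


class KgfuseError(Exception):
    """Base class for all kgfuse errors."""


class TripleParseError(KgfuseError):
    """A triple file line could not be parsed; message names the line number."""


class EntityTypingError(KgfuseError):
    """An entity in the triple file has no entry in the type map."""


class ConfigError(KgfuseError):
    """Invalid configuration (bad ratios, unknown interaction, mixed methods...)."""


class DataError(KgfuseError):
    """Structurally valid input that the operation cannot work with
    (no drug-disease triples, empty test set, empty candidate space...)."""


class ThresholdError(KgfuseError):
    """Percentile thresholding would retain zero entries."""


class EmbeddingLookupError(KgfuseError):
    """Entity or relation not known to an embedding model."""


class TrainingError(KgfuseError):
    """Training cannot proceed (e.g. no negatives constructible)."""


class EvaluationError(KgfuseError):
    """Evaluation request inconsistent with the ranking (K too large...)."""
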