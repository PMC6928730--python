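"""Exception hierarchy.

Every reader/validator rejects bad input loudly instead of repairing it;
parse-time errors carry the offending line number.
"""


class Cavity2VecError(Exception):
    """Base class for all package errors."""


class ParseError(Cavity2VecError):
    """A file could not be parsed; carries path and 1-based line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class SchemaError(ParseError):
    """A structured record is missing a key or violates an invariant."""


class DegenerateNodeError(Cavity2VecError):
    """Four lining atoms are not distinct — no valid Voronoi vertex."""


class EmptyVocabularyError(Cavity2VecError):
    """Every token fell below min_count; nothing to train on."""


class TrainingError(Cavity2VecError):
    """Skip-gram training cannot proceed (no pairs, non-finite update)."""


class EmptyEmbeddingError(Cavity2VecError):
    """No in-vocabulary token left to average for a cavity."""


class UndefinedSimilarityError(Cavity2VecError):
    """Cosine similarity requested against a zero-norm vector."""


class GenerationError(Cavity2VecError):
    """Synthetic data generation failed (e.g. too few atoms near a template)."""


class PipelineError(Cavity2VecError):
    """A pipeline stage failed; names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
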