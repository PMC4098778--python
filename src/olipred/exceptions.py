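"""Exception hierarchy for olipred.

Every error raised on purpose by the package derives from :class:`OlipredError`,
so callers (and the CLI) can distinguish data-contract problems from bugs.
"""


class OlipredError(Exception):
    """Base class for all olipred errors."""


class ParseError(OlipredError):
    """A file did not conform to its declared format (FASTA, MEME minimal, ...)."""


class StructureError(OlipredError):
    """A dot-bracket string is unbalanced, ill-nested, or inconsistent with its sequence."""


class DomainError(OlipredError):
    """An argument is outside the mathematical domain of an operation."""


class ConfigurationError(OlipredError):
    """A feature schema was requested without the inputs it needs."""


class SchemaMismatchError(OlipredError):
    """Feature matrix and model disagree on the feature schema."""


class BalanceError(OlipredError):
    """SMOTE cannot run (e.g. fewer than two minority samples)."""


class ProtocolError(OlipredError):
    """The cross-validation protocol was violated (leakage, balancing a test fold)."""


class TrainingError(OlipredError):
    """Training inputs are unusable (single class, non-finite features)."""


class ModelVersionError(OlipredError):
    """A persisted model is incompatible with the current feature-schema version."""


class FoldingUnavailableError(OlipredError):
    """No external RNA folding program is available on this host."""


class AdapterError(OlipredError):
    """The external folding program produced unparseable output."""
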