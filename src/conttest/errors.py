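"""Exception hierarchy shared across the package.

Each error category corresponds to a distinct failure mode a pipeline
run can hit, so the CLI can map them to exit codes and messages.
"""


class ContTestError(Exception):
    """Base class for all package errors."""


class FormatError(ContTestError):
    """Malformed input text (FASTA, PDB, Newick, prediction lists)."""


class AlignmentShapeError(FormatError):
    """Rows of an alignment do not all have the same length."""


class LookupError_(ContTestError):
    """A requested identifier (row id, chain id) is absent."""


class UnsupportedTopologyError(ContTestError):
    """A tree is not strictly binary."""


class MappingQualityError(ContTestError):
    """Pairwise identity between MSA target row and structure sequence
    is too low to trust the column mapping."""


class DegenerateInputError(ContTestError):
    """Input is structurally valid but carries no usable signal
    (no long-range predictions, empty pair set, ...)."""


class NumericalError(ContTestError):
    """A numerical step failed (singular matrix after regularization)."""


class PairingError(ContTestError):
    """Paired comparison requested over mismatched case-id sets."""


class GenerationError(ContTestError):
    """Synthetic structure generation failed to satisfy its guarantees."""


class ConsistencyError(ContTestError):
    """Two inputs that must agree (de-gapped sequences) do not."""
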