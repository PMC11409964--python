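"""Exception hierarchy.

Every error raised on bad user input derives from :class:`NessieError`
so the CLI can distinguish validated-input failures (exit 1, one-line
diagnostic) from genuine bugs.
"""


class NessieError(Exception):
    """Base class for all validated-input and consistency errors."""


class FormatError(NessieError):
    """A file does not conform to the expected dialect."""


class MutationLookupError(NessieError):
    """A mutation references a protein absent from the reference proteome."""


class CoordinateError(NessieError):
    """A residue position falls outside the protein sequence."""


class ConsistencyError(NessieError):
    """Internal cross-checks failed (e.g. reference-residue mismatch)."""


class ParameterError(NessieError):
    """Infeasible or invalid simulation / configuration parameters."""


class DesignError(NessieError):
    """Construct-design failures."""


class SiteCollisionError(DesignError):
    """A restriction recognition sequence occurs inside an insert."""


class CatalogExhaustedError(DesignError):
    """Not enough collision-free restriction enzymes for a vector."""
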