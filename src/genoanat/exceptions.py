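"""Exception hierarchy.

All package errors derive from :class:`GenoanatError` so callers can catch
one base class; the subclasses mirror the distinct failure modes of the
pipeline (bad lookups, impossible requests, malformed volumes, broken
cross-references).
"""


class GenoanatError(Exception):
    """Base class for all genoanat errors."""


class LookupError_(GenoanatError, KeyError):
    """An identifier (ontology term, gene) does not resolve."""


class DomainError(GenoanatError, ValueError):
    """A request is outside the mathematical/semantic domain of an operation
    (e.g. up-propagating *down* the tree, perplexity >= n-1, k > n)."""


class ShapeError(GenoanatError, ValueError):
    """Array dimensions disagree."""


class IntegrityError(GenoanatError, ValueError):
    """Cross-referenced data structures are mutually inconsistent
    (e.g. an annotation label absent from the ontology)."""


class SpecError(GenoanatError, ValueError):
    """A synthetic-atlas or experiment specification is invalid."""


class ValidationError(GenoanatError, ValueError):
    """Generic invalid input (non-finite values, length mismatches...)."""
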