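"""Exception hierarchy shared across the package."""


class HdmlError(Exception):
    """Base class for all package errors."""


class SpecSyntaxError(HdmlError):
    """The document is not syntactically valid YAML/JSON.

    Carries ``line`` and ``column`` (1-based) when the parser reports them.
    """

    def __init__(self, message, line=None, column=None):
        super().__init__(message)
        self.line = line
        self.column = column


class SpecError(HdmlError):
    """A definition violates the specification-language grammar."""


class RegistryError(HdmlError):
    """Base for type-registry failures."""


class ConflictError(RegistryError):
    """Duplicate type or incompatible re-registration."""


class DependencyError(RegistryError):
    """A referenced namespace or import cannot be resolved."""


class CycleError(RegistryError):
    """Inheritance chain contains a cycle."""


class RefinementError(RegistryError):
    """A subtype attempts to widen an inherited constraint."""


class UnknownTypeError(RegistryError, KeyError):
    """Lookup of an unregistered (namespace, type) pair."""

    def __str__(self):  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


class InvariantError(HdmlError):
    """A container invariant is violated at construction time."""


class MappingError(HdmlError):
    """Container -> builder translation failed."""


class ConstructError(HdmlError):
    """Builder -> container translation failed."""


class StorageError(HdmlError):
    """Backend read/write failure."""


class NamingError(HdmlError):
    """An identifier does not match the required pattern or is taken."""
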