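"""Exception hierarchy shared across the package."""


class BoolpathError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BoolpathError):
    """A file or object violates its documented schema; the message names the field."""


class IntegrityError(BoolpathError):
    """Referential integrity is broken (dangling ids, cyclic containment, empty containers)."""


class FormatError(BoolpathError):
    """An input file could not be parsed at all under the requested dialect."""


class ResolutionError(BoolpathError):
    """A referenced variable or target does not exist in the network."""


class EmptyTargetError(BoolpathError):
    """A drug has no target that maps onto the pathway under study."""


class AttractorError(BoolpathError):
    """A trace has no detected attractor; raise the iteration cap and re-simulate."""


class ContractError(BoolpathError):
    """Two objects that must agree (variables, lengths) do not."""
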