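"""Exception hierarchy for the BORG toolkit.

Every error raised on a user-facing code path derives from :class:`BorgError`
so callers (and the CLI) can catch one base class.
"""


class BorgError(Exception):
    """Base class for all BORG errors."""


class OboParseError(BorgError):
    """Malformed OBO input (e.g. a [Term] stanza without an id)."""


class DuplicateTermError(BorgError):
    """The same term id appears in more than one stanza."""


class CycleError(BorgError):
    """The is_a/part_of relation structure contains a directed cycle."""


class UnknownTermError(BorgError, KeyError):
    """A term id was looked up that the ontology does not contain."""


class LoadOrderError(BorgError):
    """A graph load step was attempted out of the mandated sequence."""


class ReferentialError(BorgError):
    """An edge refers to a node that is not in the graph."""


class GraphLookupError(BorgError, KeyError):
    """A gene or term reference could not be resolved in the graph."""


class StateError(BorgError):
    """The graph is not in the state the operation requires."""


class ConfigError(BorgError):
    """A disease-model or fixture configuration is invalid."""


class ParameterError(BorgError, ValueError):
    """An out-of-range tuning parameter."""


class InputError(BorgError, ValueError):
    """Invalid analysis input (set containment, value domain, ...)."""
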