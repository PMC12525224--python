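"""Exception hierarchy.

All package-specific failures derive from :class:`HerbwalkError` so callers
can catch one base class at pipeline boundaries.
"""


class HerbwalkError(Exception):
    """Base class for all herbwalk errors."""


class ParseError(HerbwalkError):
    """An input file line could not be parsed; message names the line."""


class EmptyInputError(HerbwalkError):
    """An input that must be nonempty was empty."""


class ConsistencyError(HerbwalkError):
    """Inputs contradict each other (e.g. one id used in two node classes)."""


class UnlinkedEntityError(HerbwalkError):
    """An entity has no target that maps onto the network; callers must
    exclude it from downstream scoring."""


class UndefinedCorrelationError(HerbwalkError):
    """Correlation requested between profiles where one has zero variance."""


class SizeLimitError(HerbwalkError):
    """A dense/exact routine was asked to run above its size guard."""


class ConfigError(HerbwalkError):
    """Invalid parameter or configuration value."""
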