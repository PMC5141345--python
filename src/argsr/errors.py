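"""Exception hierarchy shared across the pipeline stages."""


class ArgsrError(Exception):
    """Base class for all errors raised by this package."""


class DegenerateJunctionError(ArgsrError):
    """Two identical forward breakends do not describe a rearrangement."""


class CoordinateError(ArgsrError):
    """A position falls outside the reference or derivative bounds."""


class NotationParseError(ArgsrError):
    """Breakend notation text could not be parsed."""


class ConfigurationError(ArgsrError):
    """A simulation or pipeline configuration is infeasible."""


class InputError(ArgsrError):
    """An input stream or call set violates a precondition."""


class NormalizationError(ArgsrError):
    """Copy-number normalization is undefined (e.g. a zero-coverage control)."""


class UndefinedVafError(ArgsrError):
    """Variant allele fraction is undefined at zero total depth."""


class JunctionApplicationError(ArgsrError):
    """A junction cannot be applied to the current derivative."""


class CycleError(ArgsrError):
    """The splice-junction graph contains a cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(f"cyclic junction graph: {' -> '.join(map(str, self.cycle))}")
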