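"""Exception hierarchy for cosegmap."""


class CosegmapError(Exception):
    """Base class for all cosegmap errors."""


class ConfigurationError(CosegmapError):
    """Invalid run configuration (bad parameter, missing sample column, ...)."""


class ValidationError(CosegmapError):
    """Input data inconsistent with its own declared structure."""


class NoInformativeWindowsError(CosegmapError):
    """Raised when interval calling is attempted on windows that are all NA."""


class InconsistentRecombinantsError(CosegmapError):
    """Recombinant breakpoint constraints have an empty intersection.

    Signals genotyping error or a wrong candidate interval; the offending
    individual ids are carried in ``individuals``.
    """

    def __init__(self, message: str, individuals=()):
        super().__init__(message)
        self.individuals = list(individuals)


class PipelineError(CosegmapError):
    """A pipeline stage failed or its declared inputs are missing."""
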