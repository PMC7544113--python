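"""Exception hierarchy shared across the package."""


class PlastotypeError(Exception):
    """Base class for all package errors."""


class PlastomeIOError(PlastotypeError):
    """Malformed or inconsistent sequence / annotation input."""


class StructureNotFoundError(PlastotypeError):
    """No quadripartite structure (inverted-repeat pair) could be detected."""


class DegenerateGenomeError(PlastotypeError):
    """The genome violates an assumption of the analysis (e.g. equal arcs)."""


class AlignerUnavailableError(PlastotypeError):
    """The external alignment engine could not be executed."""
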