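"""Exception hierarchy shared across the pipeline stages."""


class GorgedynError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GorgedynError):
    """A structure or trajectory file could not be parsed."""


class TopologyError(GorgedynError):
    """Atom counts or connectivity are inconsistent with the topology."""


class SelectionError(GorgedynError):
    """An atom/residue selection is malformed or matches nothing required."""


class SpecError(GorgedynError):
    """A synthetic-data specification violates its invariants."""


class InputError(GorgedynError):
    """Input data are empty, out of range, or otherwise unusable."""


class FitError(GorgedynError):
    """A model fit failed to converge from every starting point."""
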