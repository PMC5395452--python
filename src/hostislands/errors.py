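"""Exception hierarchy for the host-islands pipeline.

Every stage raises a subclass of :class:`HostIslandsError` so the CLI can
abort with a stage-tagged message and a nonzero exit code.
"""


class HostIslandsError(Exception):
    """Base class for all pipeline errors."""


class NewickParseError(HostIslandsError):
    """Malformed Newick input; message names the offending position."""


class ValidationError(HostIslandsError):
    """Input violates a documented invariant (duplicate labels, bad cells ...)."""


class DegenerateResponseError(HostIslandsError):
    """Binary response is constant (all 0 or all 1); no logit fit exists."""


class SeparationError(HostIslandsError):
    """Fit is completely separated; derived quantities refuse to compute."""


class DegenerateNullError(HostIslandsError):
    """Random and Brownian null means coincide; D standardization undefined."""
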