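"""Exception hierarchy.

All pamksea errors derive from :class:`PamkseaError` so callers can catch the
package's failures with a single except clause while still distinguishing
file-format problems from statistical degeneracies.
"""


class PamkseaError(Exception):
    """Base class for all pamksea errors."""


class FormatError(PamkseaError):
    """A file does not conform to the documented CSV dialect."""


class ValidationError(PamkseaError):
    """A table violates a content invariant (e.g. a negative prediction score)."""


class DesignError(PamkseaError):
    """The experimental design implied by the inputs is unusable
    (e.g. no vehicle arm for a duration, or an empty allow-list)."""


class DegenerateDataError(PamkseaError):
    """A required statistic cannot be computed, e.g. a fold-change column
    with zero variance."""


class ContractError(PamkseaError, ValueError):
    """A function was called with arguments that violate its contract."""
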