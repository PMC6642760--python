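"""Exception hierarchy for harkit.

All errors derive from :class:`HarkitError` so callers can catch the
package's failures with one clause; each also derives from the closest
builtin so generic handling (``except ValueError``) keeps working.
"""


class HarkitError(Exception):
    """Base class for all harkit errors."""


class UnknownActivityError(HarkitError, KeyError):
    """An activity label outside the 12-class set 1a..6b."""


class OutOfSpanError(HarkitError, ValueError):
    """A requested window does not lie within the recorded span."""


class DegenerateVectorError(HarkitError, ValueError):
    """Unit-interval normalization of a vector with no positive value."""


class DegenerateSubjectError(HarkitError, ValueError):
    """A subject whose stored per-sensor maximum is not strictly positive."""


class LayoutError(HarkitError, ValueError):
    """A pressure sensel-to-region layout that is not a partition."""
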