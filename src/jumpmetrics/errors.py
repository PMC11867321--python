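"""Exception hierarchy for jump analysis failures.

Detection failures (no movement, no flight, no landing, no countermovement)
subclass :class:`DetectionError` so pipeline code can trap them as a group
and route the trial to a QC report instead of aborting the run.
"""


class JumpMetricsError(Exception):
    """Base class for all package errors."""


class FormatError(JumpMetricsError):
    """A delimited-text recording or table violates the expected format."""


class SpecificationError(JumpMetricsError):
    """A simulation spec or analysis configuration is internally inconsistent."""


class DetectionError(JumpMetricsError):
    """An event detector could not locate the event it looks for."""


class NoMovementError(DetectionError):
    """The force trace never leaves the body-weight threshold band."""


class NoFlightError(DetectionError):
    """Force never drops below the take-off threshold after onset."""


class NoLandingError(DetectionError):
    """Force never rises above the threshold again after take-off."""


class NoCountermovementError(DetectionError):
    """A trial labelled CMJ shows no negative COM velocity excursion."""


class InvalidJumpError(JumpMetricsError):
    """Computed metrics are physically inconsistent (e.g. v_TO <= 0)."""
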