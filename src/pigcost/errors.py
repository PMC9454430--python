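"""Exception types raised by the cost engine."""

from __future__ import annotations


class PigcostError(Exception):
    """Base class for all package errors."""


class ConfigError(PigcostError):
    """A farm configuration is missing, malformed, or internally
    inconsistent (e.g. a diet line referencing an unknown herd phase,
    or a capital asset with zero useful life)."""


class UndefinedIndicatorError(PigcostError):
    """An economic indicator is undefined for the given inputs (for
    example a per-head cost when no pigs are finished). Raised instead
    of silently returning infinity or NaN."""
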