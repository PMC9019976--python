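"""Structured errors raised by copriss.

All copriss-specific failures derive from :class:`CoprissError` so callers can
catch the package's errors with a single handler while still distinguishing
invalid inputs from numerical failures.
"""


class CoprissError(Exception):
    """Base class for all copriss errors."""


class ZeroDifferenceError(CoprissError, ZeroDivisionError):
    """Superiority sizing requires a nonzero accuracy difference."""


class InvalidDependenceError(CoprissError, ValueError):
    """A discordance proportion is incompatible with the marginal accuracies."""


class InfeasiblePowerError(CoprissError, ValueError):
    """A per-endpoint power allocation cannot reach the overall power target."""


class ConvergenceError(CoprissError, RuntimeError):
    """A root-finder failed to bracket or converge; never silently truncated."""


class ConfigError(CoprissError, ValueError):
    """A configuration file failed schema validation.

    ``errors`` holds one message per offending field path.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(self.errors))
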