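"""Exception hierarchy shared across the package.

Each class carries a distinct process exit code so the command-line
interface can fail with a structured, greppable status.
"""


class GlocalError(Exception):
    """Base class for all errors raised by glocalsvm."""

    exit_code = 1


class ConfigError(GlocalError):
    """Invalid configuration value or unknown configuration key."""

    exit_code = 3


class InputError(GlocalError):
    """Malformed input data (shape mismatch, non-numeric cells, ...)."""

    exit_code = 4


class UnfittableError(GlocalError):
    """A model cannot be fitted, e.g. a single-class training set."""

    exit_code = 5


class NumericalError(GlocalError):
    """A linear solve failed or left an unacceptably large residual."""

    exit_code = 6


class ModelIOError(GlocalError):
    """A model archive is corrupt, unreadable, or of a wrong version."""

    exit_code = 7
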