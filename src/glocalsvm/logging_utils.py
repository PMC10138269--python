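"""Package-wide logging setup."""

from __future__ import annotations

import logging

_FORMAT = "%(asctime)s %(levelname)s %(name)s: %(message)s"


def get_logger(name: str) -> logging.Logger:
    return logging.getLogger(name)


def configure_logging(verbose: bool = False) -> None:
    """Install a stderr handler for the package's loggers (CLI entry)."""
    level = logging.DEBUG if verbose else logging.INFO
    root = logging.getLogger("glocalsvm")
    root.setLevel(level)
    if not root.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(_FORMAT))
        root.addHandler(handler)
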