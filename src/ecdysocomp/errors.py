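"""Exception types shared across the package.

Reader errors always carry the offending file path and, where meaningful,
a 1-based line number, so a failing pipeline run points at the exact input
record that broke it.
"""

from __future__ import annotations


class EcdysocompError(Exception):
    """Base class for all package errors."""


class FormatError(EcdysocompError):
    """A file could not be parsed (malformed field, bad header, bad syntax)."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(f"{message}{loc}")


class IntegrityError(EcdysocompError):
    """Parsed content violates a data-model invariant (e.g. a protein listed
    under two orthogroups, an exon outside its gene span)."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(f"{message}{loc}")


class ConfigError(EcdysocompError):
    """Run configuration is invalid or inconsistent."""
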