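"""Exception types shared across the pipeline."""


class SkinremsError(Exception):
    """Base class for package-specific failures."""


class ConfigurationError(SkinremsError):
    """Invalid cohort/run configuration (e.g. non-integral frame count)."""


class InputError(SkinremsError):
    """Missing or unusable input data (empty frame directory, no rows)."""


class IntegrityError(SkinremsError):
    """Data present but inconsistent with its declared structure."""


class ParseError(SkinremsError):
    """Malformed on-disk artifact; carries row/column location where known."""

    def __init__(self, message: str, row=None, column=None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.row = row
        self.column = column
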