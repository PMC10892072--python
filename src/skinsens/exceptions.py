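"""Exception types shared across the package."""


class SkinsensError(Exception):
    """Base class for package errors."""


class SchemaError(SkinsensError, ValueError):
    """A required column is missing or the input table layout is wrong."""


class ValidationError(SkinsensError, ValueError):
    """Input values violate an invariant (duplicate ids, out-of-range category...)."""


class BackendError(SkinsensError, RuntimeError):
    """An embedding backend failed or is unavailable."""
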