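"""Exception types shared across the package."""


class MrevoError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(MrevoError, ValueError):
    """A configuration value violates its documented range."""


class InvalidInputError(MrevoError, ValueError):
    """An input table or argument violates a precondition."""


class ValidationError(MrevoError, ValueError):
    """A file failed schema validation; message lists offending rows."""


class NoDataError(MrevoError, ValueError):
    """An operation received no usable observations."""


class DegenerateSiteError(MrevoError, ValueError):
    """A site has no DNA under the given purity/copy-number state."""


class OrphanRootError(MrevoError, ValueError):
    """No VAF cluster qualifies as the founding clone."""


class InvalidTreeError(MrevoError, ValueError):
    """A parent mapping is cyclic or otherwise not a rooted tree."""
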