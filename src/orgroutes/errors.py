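"""Exception types shared across the package."""


class OrgRoutesError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OrgRoutesError, ValueError):
    """A database component failed cross-reference or consistency checks."""


class UnknownIdError(OrgRoutesError, ValueError):
    """An identifier does not resolve against the database."""


class UniverseMismatchError(OrgRoutesError, ValueError):
    """Bit-set operands belong to different organism universes."""


class EmptySelectionError(OrgRoutesError, ValueError):
    """An organism query or reaction/selection intersection matched nothing."""


class BundleFormatError(OrgRoutesError, ValueError):
    """A flat-file bundle failed to parse or has an unrecognized version."""


class OracleBoundError(OrgRoutesError, RuntimeError):
    """An exhaustive test oracle exceeded its combinatorial budget."""
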