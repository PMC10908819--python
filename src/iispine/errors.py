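"""Exception hierarchy shared across the package."""


class IISpineError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IISpineError):
    """A file violates the MetaImage format or one of its header invariants."""


class DialectError(IISpineError):
    """A label value falls outside the declared label-encoding dialect."""


class LabelConventionError(IISpineError):
    """The bottom-up instance labelling convention is violated (e.g. a gap)."""


class ManifestError(IISpineError):
    """The study manifest cannot be built (duplicate stems, missing dirs)."""


class PhantomConfigError(IISpineError):
    """The requested phantom geometry cannot be realised on the given grid."""


class ConvergenceFailure(IISpineError):
    """The patch re-centering loop lost its fragment or hit the relocation cap."""


class DuplicateInstanceError(IISpineError):
    """A candidate instance overlaps the vertebra memory beyond the guard threshold."""
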