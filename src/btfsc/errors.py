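"""Exception hierarchy shared by all pipeline stages.

Every error raised on bad user input derives from :class:`BtfscError` so
callers (and the CLI) can catch one base class; the subclasses mirror the
kinds of contract violations the stages document.
"""


class BtfscError(ValueError):
    """Base class for all btfsc input/contract errors."""


class ParameterError(BtfscError):
    """A scalar parameter is out of its documented domain."""


class ShapeError(BtfscError):
    """Array arguments have incompatible or unsupported shapes."""


class SizeError(BtfscError):
    """An image is too small for the requested operation."""


class GeometryError(BtfscError):
    """Phantom geometry is inconsistent (e.g. tumor outside the skull)."""


class DegenerateInputError(BtfscError):
    """The input has no structure for the operation (e.g. constant image)."""


class StateError(BtfscError):
    """Operation requested on an object in the wrong state (e.g. untrained model)."""
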