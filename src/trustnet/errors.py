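"""Exception hierarchy shared across the package."""


class TrustNetError(Exception):
    """Base class for package-specific failures."""


class ParameterError(TrustNetError, ValueError):
    """A parameter is outside its documented range or malformed."""


class DataError(TrustNetError, ValueError):
    """Input data is empty, mis-sized, or otherwise unusable."""


class IntegrityError(TrustNetError, RuntimeError):
    """A persisted dataset is inconsistent with its manifest."""


class CalibrationError(TrustNetError, RuntimeError):
    """A threshold cannot be fitted from the provided records."""


class StateError(TrustNetError, RuntimeError):
    """An operation requires a trained / fitted object that is not."""
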