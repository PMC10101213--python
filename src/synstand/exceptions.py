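"""Exception types raised across the package."""


class SynstandError(ValueError):
    """Base class for domain errors raised by this package."""


class NoCyclesError(SynstandError):
    """No sit-to-stand cycle could be identified in a marker trace."""


class DegenerateChannelError(SynstandError):
    """A muscle channel carries no usable signal (e.g. zero median peak)."""


class NyquistError(SynstandError):
    """A filter corner frequency is at or above the Nyquist frequency."""


class ZeroVarianceError(SynstandError):
    """The noise variance is zero somewhere, making the AIC residual term undefined."""
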