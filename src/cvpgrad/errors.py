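"""Package exception hierarchy."""


class CvpgradError(Exception):
    """Base class for all package errors."""


class ParameterError(CvpgradError, ValueError):
    """Invalid parameter value (non-positive dwell, unstable model, ...)."""


class TimingError(CvpgradError, ValueError):
    """Gradient events overlap or a readout lies outside waveform support."""


class StructureError(CvpgradError, ValueError):
    """Dataset shape/step structure incompatible with the requested method."""


class FormatError(CvpgradError, ValueError):
    """File content does not match any recognized layout."""
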