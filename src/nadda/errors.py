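"""Exception hierarchy for the nadda pipeline."""


class NaddaError(Exception):
    """Base class for all pipeline errors."""


class FormatError(NaddaError, ValueError):
    """A file does not conform to its declared format."""


class InputError(NaddaError, ValueError):
    """Well-formed input that violates a semantic contract."""


class ParameterError(NaddaError, ValueError):
    """A parameter value outside its allowed range."""


class ModelLoadError(NaddaError, ValueError):
    """A persisted model file is corrupt or of an unsupported version."""
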