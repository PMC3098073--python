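"""Exception types shared across the package."""


class PaasError(ValueError):
    """Base class for domain errors raised by this package."""


class FormatError(PaasError):
    """A file does not conform to its expected format."""


class ModelVersionError(PaasError):
    """A model file carries an unsupported format/version tag."""
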