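"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A parameter, image, or configuration violates a documented contract."""


class PlacementError(RuntimeError):
    """Scene geometry could not be placed without overlap within the retry budget."""


class PairingError(ValueError):
    """A treated replicate has no matching control replicate for normalization."""
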