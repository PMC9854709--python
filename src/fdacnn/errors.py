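"""Package-level exception types."""


class ConfigurationError(ValueError):
    """A spec/config object violates one of its invariants."""


class ValidationError(ValueError):
    """Runtime data fails a precondition (shape mismatch, non-finite, ...)."""
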