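"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A physical or numerical parameter is outside its valid domain."""


class DegenerateProfileError(ValueError):
    """A molecule allocation was requested on a profile with zero total weight."""
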