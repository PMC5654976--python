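"""Exception types shared across the package."""


class InputError(ValueError):
    """Invalid user-supplied data (bad scan file, malformed options, ...).

    The command-line interface maps this to exit code 2.
    """


class ScanFormatError(InputError):
    """A star-scan file violates the JSON schema; message names field and spoke."""
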