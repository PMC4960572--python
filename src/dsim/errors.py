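"""Exception types shared across the package.

The CLI maps :class:`InputError` to exit code 2 and
:class:`DataIntegrityError` to exit code 3.
"""


class InputError(ValueError):
    """A user-supplied argument or file is malformed or missing."""


class DataIntegrityError(ValueError):
    """Loaded data violates a structural invariant (cycle, dangling edge, ...)."""
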